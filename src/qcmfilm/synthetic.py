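"""Synthetic QCM-D adsorption experiments with realistic noise structure.

The generator evaluates the exact layer model along a thickness trajectory
d_f(t), references the shifts to the bulk-loaded baseline, and adds two
kinds of noise observed on real crystals:

* per-crystal constant offsets -- irregularities of magnitude ~0.1 Hz that
  differ between overtones and channels but are constant in time (they go
  back to poorly controlled compressional-wave admixtures and cannot be
  averaged away);
* white statistical noise per sample, which averaging does reduce.

Offsets are drawn once per overtone per channel from a zero-mean uniform
distribution of half-width ``offset_scale``.  A fixed seed reproduces the
experiment bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import numpy as np

from .materials import BulkMedium, Layer, PowerLawMaterial
from .model import OvertoneShiftSet, Resonator, predict_film

__all__ = [
    "NoiseModel",
    "GrowthModel",
    "ExperimentDesign",
    "SyntheticExperiment",
    "generate_timeseries",
    "pre_average",
    "baseline_subtract",
]


@dataclass(frozen=True)
class NoiseModel:
    """Noise scales in Hz (both applied to the per-n normalized shifts)."""

    offset_scale: float = 0.1
    white_scale: float = 0.02

    def __post_init__(self):
        if self.offset_scale < 0 or self.white_scale < 0:
            raise ValueError("noise scales must be non-negative")


@dataclass(frozen=True)
class GrowthModel:
    """Thickness trajectory d_f(t).

    kinds: ``step`` (d_max for t >= t0), ``langmuir``
    (d_max (1 - exp(-t/tau)), the saturating adsorption shape) and
    ``linear`` (rate * t, capped at d_max if given).
    """

    kind: str
    d_max: float = 0.0
    tau: float = 1.0
    t0: float = 0.0
    rate: float = 0.0

    def __post_init__(self):
        if self.kind not in ("step", "langmuir", "linear"):
            raise ValueError(f"unknown growth kind {self.kind!r}")
        if self.d_max < 0 or self.tau <= 0:
            raise ValueError("d_max must be >= 0 and tau > 0")

    @classmethod
    def step(cls, d_max: float, t0: float = 0.0):
        return cls("step", d_max=d_max, t0=t0)

    @classmethod
    def langmuir(cls, d_max: float, tau: float):
        return cls("langmuir", d_max=d_max, tau=tau)

    @classmethod
    def linear(cls, rate: float, d_max: float = np.inf):
        return cls("linear", rate=rate, d_max=d_max)

    def thickness(self, t):
        t = np.asarray(t, float)
        if self.kind == "step":
            d = np.where(t >= self.t0, self.d_max, 0.0)
        elif self.kind == "langmuir":
            d = self.d_max * (1.0 - np.exp(-np.maximum(t, 0.0) / self.tau))
        else:
            d = np.minimum(self.rate * np.maximum(t, 0.0), self.d_max)
        return d


@dataclass(frozen=True)
class ExperimentDesign:
    """Everything needed to synthesize one adsorption experiment."""

    material: PowerLawMaterial
    growth: GrowthModel
    res: Resonator = field(default_factory=Resonator)
    bulk: BulkMedium = field(default_factory=BulkMedium.water)
    n_list: Tuple[int, ...] = (3, 5, 7, 9, 11)
    times: np.ndarray = field(default_factory=lambda: np.arange(0.0, 300.0, 1.0))
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0


@dataclass
class SyntheticExperiment:
    """Generated overtone time series (arrays are time x overtone)."""

    design: ExperimentDesign
    times: np.ndarray
    n: np.ndarray
    df_n: np.ndarray
    dg_n: np.ndarray
    clean_df_n: np.ndarray
    clean_dg_n: np.ndarray
    offsets_f: np.ndarray
    offsets_g: np.ndarray

    def shift_set_at(self, index: int = -1) -> OvertoneShiftSet:
        """A single-time snapshot as an :class:`OvertoneShiftSet`.

        The attached noise scale combines the white noise with the standard
        deviation of the per-crystal offsets (uniform half-width s has
        variance s^2/3): for a single snapshot the constant irregularities
        act as per-overtone noise, which is exactly why they limit the
        identifiability of curvatures.
        """
        nm = self.design.noise
        s = float(np.hypot(nm.white_scale, nm.offset_scale / np.sqrt(3.0)))
        sigma = np.full(len(self.n), s) if s > 0 else None
        return OvertoneShiftSet(
            self.n, self.df_n[index], self.dg_n[index],
            sigma_f=sigma, sigma_g=sigma, reference="bulk",
        )


def generate_timeseries(design: ExperimentDesign) -> SyntheticExperiment:
    """Synthesize the experiment defined by ``design`` (deterministic in seed)."""
    times = np.asarray(design.times, float)
    n = np.asarray(design.n_list, int)
    d_t = design.growth.thickness(times)
    if np.any(np.diff(d_t) < -1e-18):
        raise ValueError("adsorption designs require non-decreasing d_f(t)")

    clean = np.empty((len(times), len(n)), dtype=complex)
    # vectorize over time per overtone; material properties depend only on n
    for j, nv in enumerate(n):
        shifts = np.array([
            predict_film(design.res, Layer(design.material, d), design.bulk,
                         int(nv), reference="bulk")
            for d in np.unique(d_t)
        ])
        lookup = dict(zip(np.unique(d_t), shifts))
        clean[:, j] = np.array([lookup[d] for d in d_t]) / nv

    rng = np.random.default_rng(design.seed)
    offs_f = rng.uniform(-design.noise.offset_scale, design.noise.offset_scale,
                         size=len(n))
    offs_g = rng.uniform(-design.noise.offset_scale, design.noise.offset_scale,
                         size=len(n))
    white_f = rng.normal(0.0, design.noise.white_scale, size=clean.shape) \
        if design.noise.white_scale > 0 else np.zeros(clean.shape)
    white_g = rng.normal(0.0, design.noise.white_scale, size=clean.shape) \
        if design.noise.white_scale > 0 else np.zeros(clean.shape)

    df_n = clean.real + offs_f[None, :] + white_f
    dg_n = clean.imag + offs_g[None, :] + white_g
    return SyntheticExperiment(
        design=design, times=times, n=n,
        df_n=df_n, dg_n=dg_n,
        clean_df_n=clean.real, clean_dg_n=clean.imag,
        offsets_f=offs_f, offsets_g=offs_g,
    )


def pre_average(exp: SyntheticExperiment, k: int) -> SyntheticExperiment:
    """Non-overlapping k-point block means along the time axis.

    Shrinks white noise roughly k-fold while leaving the constant
    per-crystal offsets untouched; the output has floor(N/k) samples.
    """
    if k < 1:
        raise ValueError("window must be >= 1")
    N = len(exp.times)
    if k > N:
        raise ValueError("window longer than the series")
    m = (N // k) * k

    def block(a):
        return a[:m].reshape(N // k, k, *a.shape[1:]).mean(axis=1)

    return replace(
        exp,
        times=block(exp.times),
        df_n=block(exp.df_n), dg_n=block(exp.dg_n),
        clean_df_n=block(exp.clean_df_n), clean_dg_n=block(exp.clean_dg_n),
    )


def baseline_subtract(exp: SyntheticExperiment,
                      window: Tuple[float, float]) -> SyntheticExperiment:
    """Subtract the per-overtone mean over a time window from each channel.

    The usual referencing step: a window over a quiescent segment removes
    the constant offsets (up to the white-noise error of the mean).
    """
    t0, t1 = window
    mask = (exp.times >= t0) & (exp.times <= t1)
    if not np.any(mask):
        raise ValueError("empty baseline window")
    mf = exp.df_n[mask].mean(axis=0)
    mg = exp.dg_n[mask].mean(axis=0)
    return replace(exp, df_n=exp.df_n - mf[None, :], dg_n=exp.dg_n - mg[None, :])
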