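"""Forward prediction of overtone shifts for layered films on a resonator.

Everything here works in the small-load approximation: the complex frequency
shift of a thickness-shear resonator with fundamental f0 and quartz shear
impedance Zq is

    Delta f + i Delta Gamma = i f0 Z_load / (pi Zq)

where Z_load is the shear-wave impedance the sample presents at the
resonator surface.  For a single viscoelastic film of impedance Z_f and
wavenumber k_f under a semi-infinite bulk of impedance Z_bulk,

    Z_load = Z_f (Z_bulk + i Z_f tan(k_f d_f)) / (Z_f + i Z_bulk tan(k_f d_f))

which contains no expansion in the film thickness d_f.  Shifts are returned
relative to the bare (unloaded) resonator by default; ``reference="bulk"``
subtracts the d_f = 0 prediction, matching adsorption experiments referenced
to the pure-liquid baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .materials import BulkMedium, Layer, evaluate_material

__all__ = [
    "Resonator",
    "OvertoneShiftSet",
    "predict_film",
    "predict_multilayer",
    "taylor_air",
    "taylor_liquid",
    "sauerbrey",
    "sauerbrey_mass",
    "kanazawa",
    "acoustic_ratio",
    "dissipation_to_bandwidth",
]

#: Shear-wave impedance of AT-cut quartz, kg m^-2 s^-1.
ZQ_AT_CUT = 8.8e6


@dataclass(frozen=True)
class Resonator:
    """An AT-cut thickness-shear resonator.

    ``f0`` is the fundamental resonance frequency (Hz) and ``Zq`` the
    shear-wave impedance of the quartz plate.  The areal mass of the plate
    is the exact identity m_q = Zq / (2 f0).
    """

    f0: float = 5e6
    Zq: float = ZQ_AT_CUT

    def __post_init__(self):
        if self.f0 <= 0 or self.Zq <= 0:
            raise ValueError("f0 and Zq must be positive")

    @property
    def mq(self) -> float:
        """Areal mass of the quartz plate, kg m^-2."""
        return self.Zq / (2.0 * self.f0)

    def overtone_frequency(self, n):
        return np.asarray(n) * self.f0


def _check_overtones(n) -> np.ndarray:
    n = np.asarray(n)
    if np.any(n < 1) or np.any(n % 2 == 0):
        raise ValueError("overtone orders must be odd and >= 1")
    return n


def stable_tan(z):
    """tan(z) for complex z with Im(z) <= 0, safe against overflow.

    Uses tan(z) = -i (1 - w) / (1 + w) with w = exp(-2 i z); |w| <= 1 on the
    decaying branch, so the expression saturates smoothly to -i for thick,
    lossy films instead of overflowing.
    """
    z = np.asarray(z, dtype=complex)
    if np.any(z.imag > 1e-9 * np.maximum(1.0, np.abs(z.real))):
        # not the passive branch; fall back to the library routine
        return np.tan(z)
    w = np.exp(-2j * z)
    return -1j * (1.0 - w) / (1.0 + w)


def load_impedance(layers: Sequence[Layer], bulk: BulkMedium, f):
    """Shear-wave impedance at the resonator surface for a layer stack.

    ``layers`` are ordered from the resonator surface outward; the recursion
    starts at the terminating bulk and transfers the impedance inward through
    each film.  A rigid layer contributes its inertial load i omega m_f.
    """
    f = np.asarray(f, dtype=float)
    omega = 2.0 * np.pi * f
    Z = bulk.impedance(f)
    Z = Z * np.ones_like(f, dtype=complex) if np.ndim(f) > 0 else Z
    for layer in reversed(list(layers)):
        if layer.d_f == 0:
            continue
        if layer.material.is_rigid:
            Z = Z + 1j * omega * layer.areal_mass
            continue
        state = evaluate_material(layer.material, f)
        t = stable_tan(state.k * layer.d_f)
        Z = state.Z * (Z + 1j * state.Z * t) / (state.Z + 1j * Z * t)
    return Z


def _small_load_shift(res: Resonator, Z_load):
    return 1j * res.f0 * Z_load / (np.pi * res.Zq)


def predict_multilayer(res: Resonator, layers: Sequence[Layer], bulk: BulkMedium,
                       n, reference: str = "bare"):
    """Exact complex shift Delta f + i Delta Gamma (Hz) for a layer stack.

    ``n`` may be a scalar or an array of odd overtone orders.  Material
    properties are evaluated at f = n f0.  ``reference="bulk"`` subtracts the
    prediction for an empty stack (the bulk-loaded baseline).
    """
    n = _check_overtones(n)
    if reference not in ("bare", "bulk"):
        raise ValueError("reference must be 'bare' or 'bulk'")
    f = res.overtone_frequency(n)
    shift = _small_load_shift(res, load_impedance(layers, bulk, f))
    if reference == "bulk":
        shift = shift - _small_load_shift(res, bulk.impedance(f))
    return shift


def predict_film(res: Resonator, layer: Layer, bulk: BulkMedium, n,
                 reference: str = "bare"):
    """Exact complex shift (Hz) for a single film under a bulk medium."""
    return predict_multilayer(res, [layer], bulk, n, reference=reference)


def taylor_air(res: Resonator, layer: Layer, n, variant: str = "corrected"):
    """Third-order small-thickness shift (Hz) for a film in air/vacuum.

    (Delta f + i Delta Gamma)/n =
        -(m_f/m_q) f0 [1 + (n pi)^2/3 (J~_f Zq^2/rho_f - c) (m_f/m_q)^2]

    with the complex compliance J~ = J' - iJ'' evaluated at n f0.  The
    ``corrected`` variant includes the constant c = 1 correction (a slightly
    better approximation); ``plain`` sets c = 0 and is exactly Sauerbrey for
    a rigid film.  Relative deviation from the exact model is O(d_f^4).
    """
    n = _check_overtones(n)
    if variant not in ("plain", "corrected"):
        raise ValueError("variant must be 'plain' or 'corrected'")
    c = 1.0 if variant == "corrected" else 0.0
    mat = layer.material
    mf_mq = layer.areal_mass / res.mq
    if mat.is_rigid:
        Jt = np.zeros_like(np.asarray(n), dtype=complex)[()] if np.ndim(n) == 0 \
            else np.zeros(np.shape(n), dtype=complex)
    else:
        Jt = 1.0 / mat.complex_modulus(res.overtone_frequency(n))
    bracket = 1.0 + (n * np.pi) ** 2 / 3.0 * (Jt * res.Zq**2 / mat.rho - c) * mf_mq**2
    return n * (-mf_mq * res.f0 * bracket)


def taylor_liquid(res: Resonator, layer: Layer, bulk: BulkMedium, n,
                  equal_densities: bool = False):
    """First-order small-thickness shift (Hz) for a film in a Newtonian liquid.

    (Delta f + i Delta Gamma)/n =
        -(2 f0^2/Zq) rho_f d_f [1 - Z~_bulk^2 / Z~_f^2]

    referenced to the bulk-loaded baseline.  With ``equal_densities`` the
    bracket becomes 1 - i omega eta_bulk J~_f (rho_f = rho_bulk assumed).
    Relative deviation from the exact model is O(d_f^2).  For a rigid film
    the bracket is 1 and the Sauerbrey value is recovered.
    """
    n = _check_overtones(n)
    if bulk.kind != "newtonian":
        raise ValueError("taylor_liquid requires a Newtonian bulk")
    mat = layer.material
    omega = 2.0 * np.pi * res.overtone_frequency(n)
    if mat.is_rigid:
        bracket = np.ones_like(np.asarray(omega), dtype=complex)
    else:
        Jt = 1.0 / mat.complex_modulus(res.overtone_frequency(n))
        r = 1.0 if equal_densities else bulk.rho / mat.rho
        bracket = 1.0 - 1j * omega * bulk.eta * Jt * r
    return n * (-2.0 * res.f0**2 / res.Zq * mat.rho * layer.d_f * bracket)


def sauerbrey(res: Resonator, m_f: float, n=1):
    """Sauerbrey shift per overtone order, Delta f / n = -2 f0^2 m_f / Zq (Hz).

    Independent of ``n``; the argument is accepted for interface symmetry.
    """
    if np.any(np.asarray(m_f) < 0):
        raise ValueError("areal mass must be non-negative")
    return -2.0 * res.f0**2 * np.asarray(m_f) / res.Zq + 0.0 * np.asarray(n)


def sauerbrey_mass(df_over_n, res: Resonator):
    """Invert the Sauerbrey relation: areal mass (kg m^-2) from Delta f/n (Hz)."""
    return -np.asarray(df_over_n) * res.Zq / (2.0 * res.f0**2)


def kanazawa(res: Resonator, bulk: BulkMedium, n):
    """Complex shift (Hz) of the bare resonator immersed in the bulk.

    For a Newtonian liquid Delta Gamma = -Delta f exactly and
    Delta f / n scales as n^(-1/2).  Vacuum gives zero.
    """
    n = _check_overtones(n)
    f = res.overtone_frequency(n)
    return _small_load_shift(res, bulk.impedance(f))


def dissipation_to_bandwidth(dD, res: Resonator, units: str = "ppm"):
    """Convert a dissipation-factor shift to Delta Gamma / n (Hz).

    Gamma = D f_res / 2 with f_res = n f0, hence Delta Gamma / n = dD f0 / 2,
    independent of the overtone order.  ``units="ppm"`` scales the input by
    1e-6 (2.5 Hz per ppm for a 5 MHz resonator); ``units="absolute"`` takes
    dD as a pure number.
    """
    if units not in ("ppm", "absolute"):
        raise ValueError("units must be 'ppm' or 'absolute'")
    scale = 1e-6 if units == "ppm" else 1.0
    return np.asarray(dD) * scale * res.f0 / 2.0


def bandwidth_to_dissipation(dG_over_n, res: Resonator, units: str = "ppm"):
    """Inverse of :func:`dissipation_to_bandwidth`."""
    scale = 1e-6 if units == "ppm" else 1.0
    return np.asarray(dG_over_n) * 2.0 / (res.f0 * scale)


@dataclass
class OvertoneShiftSet:
    """Per-overtone normalized shifts Delta f/n and Delta Gamma/n (Hz).

    ``reference`` records what the shifts are relative to: the bare
    resonator (``"bare"``) or the bulk-loaded baseline (``"bulk"``).
    Optional per-overtone noise scales sigma_f, sigma_g (Hz) feed the
    weighted fits.
    """

    n: np.ndarray
    df_n: np.ndarray
    dg_n: np.ndarray
    sigma_f: Optional[np.ndarray] = None
    sigma_g: Optional[np.ndarray] = None
    reference: str = "bulk"

    def __post_init__(self):
        self.n = np.asarray(self.n, dtype=int)
        self.df_n = np.asarray(self.df_n, dtype=float)
        self.dg_n = np.asarray(self.dg_n, dtype=float)
        if np.any(np.diff(self.n) <= 0):
            raise ValueError("overtone orders must be strictly increasing")
        _check_overtones(self.n)
        if len(self.df_n) != len(self.n) or len(self.dg_n) != len(self.n):
            raise ValueError("array lengths must match the overtone list")
        for name in ("sigma_f", "sigma_g"):
            s = getattr(self, name)
            if s is not None:
                s = np.broadcast_to(np.asarray(s, dtype=float), self.n.shape).copy()
                setattr(self, name, s)
        if self.reference not in ("bare", "bulk"):
            raise ValueError("reference must be 'bare' or 'bulk'")

    @property
    def complex_per_n(self):
        return self.df_n + 1j * self.dg_n

    def acoustic_ratio(self):
        return acoustic_ratio(self)


def acoustic_ratio(shifts: OvertoneShiftSet):
    """Dimensionless acoustic ratio Delta Gamma/(-Delta f) per overtone.

    Overtones with Delta f = 0 yield NaN (the ratio is undefined there)
    rather than raising.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(shifts.df_n != 0, shifts.dg_n / (-shifts.df_n), np.nan)
    return ratio


def shift_set_from_model(res: Resonator, layer: Layer, bulk: BulkMedium,
                         n_list, reference: str = "bulk",
                         sigma_f=None, sigma_g=None) -> OvertoneShiftSet:
    """Convenience: evaluate the exact model on a set of overtones."""
    n = np.asarray(n_list)
    shift = predict_film(res, layer, bulk, n, reference=reference)
    return OvertoneShiftSet(n, (shift / n).real, (shift / n).imag,
                            sigma_f=sigma_f, sigma_g=sigma_g, reference=reference)
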