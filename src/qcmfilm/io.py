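"""CSV I/O for overtone time series, plus flat config files.

The dialect is a wide UTF-8 CSV with ``#``-prefixed metadata lines:

    # f0 = 5000000.0
    # Zq = 8800000.0
    # freq_units = hz_per_n
    # diss_units = hz_per_n
    # reference = bulk
    time,f3,f5,...,gamma3,gamma5,...

Frequency columns match ``f<n>``; the dissipative channel is either
``gamma<n>`` (half-bandwidth, Hz) or ``D<n>`` (dissipation factor).  Units
must be declared (no silent defaults): ``freq_units`` is ``hz_per_n``
(already overtone-normalized) or ``hz`` (raw, divided by n on load);
``diss_units`` is ``hz_per_n``, ``hz``, or ``ppm`` (dissipation shift,
converted via Delta Gamma/n = Delta D * f0/2).  Internally everything is
per-n-normalized Hz.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd
import yaml

from .model import OvertoneShiftSet, Resonator, dissipation_to_bandwidth

__all__ = ["OvertoneTable", "read_overtone_csv", "write_overtone_csv",
           "load_config"]

_FREQ_UNITS = ("hz_per_n", "hz")
_DISS_UNITS = ("hz_per_n", "hz", "ppm")
_COL_RE = re.compile(r"^(f|gamma|D)(\d+)$")


@dataclass
class OvertoneTable:
    """A time-indexed set of per-n-normalized overtone shifts (Hz)."""

    times: np.ndarray
    n: np.ndarray
    df_n: np.ndarray  # time x overtone
    dg_n: np.ndarray
    metadata: Dict[str, str] = field(default_factory=dict)

    @property
    def resonator(self) -> Resonator:
        return Resonator(float(self.metadata.get("f0", 5e6)),
                         float(self.metadata.get("Zq", 8.8e6)))

    def shift_set_at(self, index: int = -1,
                     sigma_f=None, sigma_g=None) -> OvertoneShiftSet:
        return OvertoneShiftSet(
            self.n, self.df_n[index], self.dg_n[index],
            sigma_f=sigma_f, sigma_g=sigma_g,
            reference=self.metadata.get("reference", "bulk"),
        )


def _parse_metadata(path) -> Dict[str, str]:
    meta = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "=" in line:
                key, _, val = line.lstrip("#").partition("=")
                meta[key.strip()] = val.strip()
    return meta


def read_overtone_csv(path, freq_units: Optional[str] = None,
                      diss_units: Optional[str] = None,
                      f0: Optional[float] = None) -> OvertoneTable:
    """Read an overtone CSV; keyword arguments override file metadata.

    Raises on unknown columns, undeclared units, or non-monotone time.
    """
    meta = _parse_metadata(path)
    freq_units = freq_units or meta.get("freq_units")
    diss_units = diss_units or meta.get("diss_units")
    if freq_units not in _FREQ_UNITS:
        raise ValueError(f"freq_units must be declared as one of {_FREQ_UNITS}")
    if diss_units not in _DISS_UNITS:
        raise ValueError(f"diss_units must be declared as one of {_DISS_UNITS}")
    if f0 is not None:
        meta["f0"] = str(f0)
    df = pd.read_csv(path, comment="#")
    if "time" not in df.columns:
        raise ValueError("missing 'time' column")
    times = df["time"].to_numpy(float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("time column must be strictly increasing")

    fcols, dcols = {}, {}
    for col in df.columns:
        if col == "time":
            continue
        m = _COL_RE.match(col)
        if not m:
            raise ValueError(f"unknown column {col!r}")
        kind, n = m.group(1), int(m.group(2))
        (fcols if kind == "f" else dcols)[n] = (kind, col)
    if sorted(fcols) != sorted(dcols):
        raise ValueError("mismatched overtone lists between channels")
    n = np.array(sorted(fcols))

    res = Resonator(float(meta.get("f0", 5e6)), float(meta.get("Zq", 8.8e6)))
    df_n = np.stack([df[fcols[k][1]].to_numpy(float) for k in n], axis=1)
    if freq_units == "hz":
        df_n = df_n / n[None, :]
    dg_n = np.stack([df[dcols[k][1]].to_numpy(float) for k in n], axis=1)
    if diss_units == "hz":
        dg_n = dg_n / n[None, :]
    elif diss_units == "ppm":
        dg_n = dissipation_to_bandwidth(dg_n, res, units="ppm")
    meta["freq_units"] = "hz_per_n"
    meta["diss_units"] = "hz_per_n"
    return OvertoneTable(times, n, df_n, dg_n, meta)


def write_overtone_csv(path, table: OvertoneTable) -> None:
    """Write per-n-normalized data in the documented dialect (lossless to
    the 17-significant-digit precision used)."""
    cols = {"time": table.times}
    for j, nv in enumerate(table.n):
        cols[f"f{nv}"] = table.df_n[:, j]
    for j, nv in enumerate(table.n):
        cols[f"gamma{nv}"] = table.dg_n[:, j]
    meta = dict(table.metadata)
    meta.setdefault("f0", "5000000.0")
    meta.setdefault("Zq", "8800000.0")
    meta["freq_units"] = "hz_per_n"
    meta["diss_units"] = "hz_per_n"
    with open(path, "w", encoding="utf-8") as fh:
        for key, val in meta.items():
            fh.write(f"# {key} = {val}\n")
        pd.DataFrame(cols).to_csv(fh, index=False, float_format="%.17g")


def load_config(path) -> dict:
    """Load a flat key-value config file (YAML mapping)."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a flat key-value mapping")
    # YAML 1.1 leaves exponent forms like 5.0e6 as strings; coerce them
    for key, val in cfg.items():
        if isinstance(val, str):
            try:
                cfg[key] = float(val)
            except ValueError:
                pass
    return cfg
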