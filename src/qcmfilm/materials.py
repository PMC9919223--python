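"""Viscoelastic materials with power-law frequency dispersion.

A material is described by two values at a reference frequency ``f_cen``
plus two power-law exponents, in any of four equivalent representations:

* ``compliance``      -- (J', J''), shear compliance, Pa^-1
* ``modulus``         -- (G', G''), shear modulus, Pa
* ``viscosity``       -- (eta', eta''), complex viscosity, Pa s
* ``magnitude_loss``  -- (|G|, tan delta), Pa and dimensionless

Sign conventions: G = G' + iG'', J = 1/G = J' - iJ'', eta = G/(i omega)
= eta' - i eta''.  The loss tangent tan delta = G''/G' = J''/J' = eta'/eta''
is the same in every representation.  Within the roughly one decade of
frequency a thickness-shear resonator covers, both values of the native
pair are taken to follow independent power laws (f/f_cen)**beta.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

REPRESENTATIONS = ("compliance", "modulus", "viscosity", "magnitude_loss")

#: Default reference frequency, Hz -- the centre of the overtone range of a
#: 5 MHz resonator driven on n = 3..11.
DEFAULT_F_CEN = 30e6


def _check_representation(rep: str) -> None:
    if rep not in REPRESENTATIONS:
        raise ValueError(
            f"unknown representation {rep!r}; expected one of {REPRESENTATIONS}"
        )


def pair_to_modulus(value1, value2, rep: str, omega=None) -> complex:
    """Convert a representation pair to the complex shear modulus G' + iG''."""
    _check_representation(rep)
    if rep == "modulus":
        return value1 + 1j * value2
    if rep == "compliance":
        J = value1 - 1j * value2
        if np.any(np.abs(J) == 0):
            raise ZeroDivisionError("zero compliance has no finite modulus")
        return 1.0 / J
    if rep == "viscosity":
        if omega is None:
            raise ValueError("viscosity conversions require omega")
        eta = value1 - 1j * value2
        return 1j * omega * eta
    # magnitude_loss: G = |G| (1 + i tan d)/sqrt(1 + tan^2 d), algebraic form
    # (avoids trig round-off at extreme loss tangents)
    t = np.asarray(value2, dtype=float)
    return value1 * (1.0 + 1j * t) / np.sqrt(1.0 + t * t)


def modulus_to_pair(G, rep: str, omega=None):
    """Convert a complex shear modulus to the pair of a given representation."""
    _check_representation(rep)
    G = np.asarray(G, dtype=complex)
    if rep == "modulus":
        return G.real, G.imag
    if rep == "compliance":
        if np.any(np.abs(G) == 0):
            raise ZeroDivisionError("zero modulus has no finite compliance")
        J = 1.0 / G
        return J.real, -J.imag
    if rep == "viscosity":
        if omega is None:
            raise ValueError("viscosity conversions require omega")
        eta = G / (1j * omega)
        return eta.real, -eta.imag
    absG = np.abs(G)
    with np.errstate(divide="ignore", invalid="ignore"):
        tand = np.where(G.real != 0, G.imag / G.real, np.inf)
    return absG, tand


def convert_representation(value1, value2, from_rep: str, to_rep: str, omega=None):
    """Convert a material pair between representations at a single frequency.

    ``omega`` (rad/s) is required whenever the viscosity representation is
    involved.  Round trips are identities to floating-point accuracy.
    """
    G = pair_to_modulus(value1, value2, from_rep, omega=omega)
    return modulus_to_pair(G, to_rep, omega=omega)


@dataclass(frozen=True)
class PowerLawMaterial:
    """A viscoelastic material with power-law dispersion of its native pair.

    Parameters
    ----------
    rep:
        Representation tag, one of :data:`REPRESENTATIONS`.
    value1, value2:
        The native pair at ``f_cen`` (e.g. J', J'' for ``compliance``).
    beta1, beta2:
        Power-law exponents of value1 and value2.
    f_cen:
        Reference frequency, Hz.
    rho:
        Density, kg m^-3.
    """

    rep: str
    value1: float
    value2: float
    beta1: float = 0.0
    beta2: float = 0.0
    f_cen: float = DEFAULT_F_CEN
    rho: float = 1000.0

    def __post_init__(self):
        _check_representation(self.rep)
        if self.rho <= 0:
            raise ValueError("density must be positive")
        if self.f_cen <= 0:
            raise ValueError("f_cen must be positive")
        if self.rep in ("compliance", "viscosity", "magnitude_loss"):
            if self.value1 < 0 or self.value2 < 0:
                raise ValueError(f"{self.rep} values must be non-negative")

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_compliance(cls, J1, J2, beta1=0.0, beta2=0.0, **kw):
        return cls("compliance", J1, J2, beta1, beta2, **kw)

    @classmethod
    def from_modulus(cls, G1, G2, beta1=0.0, beta2=0.0, **kw):
        return cls("modulus", G1, G2, beta1, beta2, **kw)

    @classmethod
    def from_viscosity(cls, eta1, eta2, beta1=0.0, beta2=0.0, **kw):
        return cls("viscosity", eta1, eta2, beta1, beta2, **kw)

    @classmethod
    def from_magnitude_loss(cls, absG, tand, beta1=0.0, beta2=0.0, **kw):
        return cls("magnitude_loss", absG, tand, beta1, beta2, **kw)

    @classmethod
    def newtonian(cls, eta: float, rho: float = 1000.0, f_cen: float = DEFAULT_F_CEN):
        """A Newtonian liquid: eta' constant, eta'' = 0."""
        return cls("viscosity", eta, 0.0, 0.0, 0.0, f_cen=f_cen, rho=rho)

    @classmethod
    def rigid(cls, rho: float = 1000.0, f_cen: float = DEFAULT_F_CEN):
        """An infinitely stiff (Sauerbrey) material, J = 0."""
        return cls("compliance", 0.0, 0.0, 0.0, 0.0, f_cen=f_cen, rho=rho)

    # -- evaluation -------------------------------------------------------
    @property
    def is_rigid(self) -> bool:
        return self.rep == "compliance" and self.value1 == 0 and self.value2 == 0

    def pair_at(self, f):
        """The native pair evaluated at frequency ``f`` (Hz; scalar or array)."""
        f = np.asarray(f, dtype=float)
        if np.any(f <= 0):
            raise ValueError("frequency must be positive")
        scale = f / self.f_cen
        return self.value1 * scale**self.beta1, self.value2 * scale**self.beta2

    def complex_modulus(self, f):
        """G' + iG'' at frequency ``f`` (Hz)."""
        if self.is_rigid:
            raise ZeroDivisionError("rigid material has infinite modulus")
        v1, v2 = self.pair_at(f)
        return pair_to_modulus(v1, v2, self.rep, omega=2.0 * np.pi * np.asarray(f))

    def as_representation(self, rep: str, f: Optional[float] = None) -> "PowerLawMaterial":
        """Re-express the material pair at ``f_cen`` in another representation.

        The exponents of the new pair are obtained from a two-point log-log
        secant across the overtone range (a power law in one representation is
        not exactly a power law in another; the secant matches the pair at the
        edges of one decade around ``f_cen``).
        """
        _check_representation(rep)
        if rep == self.rep:
            return self
        f_lo, f_hi = self.f_cen / np.sqrt(10.0), self.f_cen * np.sqrt(10.0)
        pairs = {}
        for fx in (f_lo, self.f_cen, f_hi):
            v1, v2 = self.pair_at(fx)
            pairs[fx] = convert_representation(
                v1, v2, self.rep, rep, omega=2.0 * np.pi * fx
            )
        w1c, w2c = pairs[self.f_cen]
        span = np.log(f_hi / f_lo)
        b1 = float(np.log(pairs[f_hi][0] / pairs[f_lo][0]) / span)
        b2 = float(np.log(pairs[f_hi][1] / pairs[f_lo][1]) / span)
        return PowerLawMaterial(
            rep, float(w1c), float(w2c), b1, b2, f_cen=self.f_cen, rho=self.rho
        )


@dataclass(frozen=True)
class AcousticState:
    """Derived acoustic quantities of a material at one angular frequency.

    Attributes
    ----------
    omega:
        Angular frequency, rad/s.
    G:
        Complex shear modulus, Pa.
    k:
        Complex wavenumber omega*sqrt(rho/G), 1/m, with Im(k) <= 0
        (decaying wave).
    Z:
        Complex shear-wave impedance sqrt(rho*G), kg m^-2 s^-1, with
        Re(Z) > 0 (passivity branch).
    delta_pen:
        Penetration depth -1/Im(k), m (inf for a lossless medium).
    lambda_shear:
        Shear wavelength 2 pi / Re(k), m.
    """

    omega: float
    G: complex
    k: complex
    Z: complex
    delta_pen: float
    lambda_shear: float


def shear_impedance(G, rho):
    """sqrt(rho*G) on the passivity branch Re(Z) > 0."""
    Z = np.sqrt(np.asarray(rho * G, dtype=complex))
    Z = np.where(Z.real < 0, -Z, Z)
    if np.any((Z.real < 0) | ((Z.real == 0) & (np.abs(Z) > 0))):
        raise ValueError("non-passive material: Re(Z) <= 0")
    return Z[()] if np.ndim(Z) == 0 else Z


def evaluate_material(material: PowerLawMaterial, f) -> AcousticState:
    """Evaluate a material at frequency ``f`` (Hz) and derive wave quantities."""
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0):
        raise ValueError("frequency must be positive")
    omega = 2.0 * np.pi * f
    G = material.complex_modulus(f)
    Z = shear_impedance(G, material.rho)
    k = omega * material.rho / Z  # equals omega*sqrt(rho/G) on the decaying branch
    with np.errstate(divide="ignore"):
        k_im = np.asarray(k).imag
        delta = np.where(k_im < 0, -1.0 / np.where(k_im < 0, k_im, -1.0), np.inf)
        lam = 2.0 * np.pi / np.asarray(k).real
    if np.ndim(f) == 0:
        return AcousticState(float(omega), complex(G), complex(k), complex(Z),
                             float(delta), float(lam))
    return AcousticState(omega, G, k, Z, delta, lam)


@dataclass(frozen=True)
class Layer:
    """A planar film: a material plus a thickness d_f (m)."""

    material: PowerLawMaterial
    d_f: float

    def __post_init__(self):
        if self.d_f < 0:
            raise ValueError("thickness must be non-negative")

    @property
    def areal_mass(self) -> float:
        """Mass per unit area m_f = rho_f * d_f, kg m^-2."""
        return self.material.rho * self.d_f

    def with_thickness(self, d_f: float) -> "Layer":
        return replace(self, d_f=d_f)


@dataclass(frozen=True)
class BulkMedium:
    """The semi-infinite ambient medium terminating the layer stack."""

    kind: str  # vacuum | newtonian | viscoelastic
    rho: Optional[float] = None
    eta: Optional[float] = None
    material: Optional[PowerLawMaterial] = None

    def __post_init__(self):
        if self.kind not in ("vacuum", "newtonian", "viscoelastic"):
            raise ValueError(f"unknown bulk kind {self.kind!r}")
        if self.kind == "newtonian":
            if self.rho is None or self.eta is None:
                raise ValueError("newtonian bulk needs rho and eta")
            if self.rho <= 0 or self.eta < 0:
                raise ValueError("newtonian bulk needs rho > 0 and eta >= 0")
        if self.kind == "viscoelastic" and self.material is None:
            raise ValueError("viscoelastic bulk needs a material")

    @classmethod
    def vacuum(cls) -> "BulkMedium":
        return cls("vacuum")

    @classmethod
    def newtonian(cls, rho: float = 1000.0, eta: float = 1.0e-3) -> "BulkMedium":
        return cls("newtonian", rho=rho, eta=eta)

    @classmethod
    def water(cls) -> "BulkMedium":
        """Water at ambient conditions (rho = 1000 kg/m^3, eta = 1 mPa s)."""
        return cls.newtonian(1000.0, 1.0e-3)

    @classmethod
    def viscoelastic(cls, material: PowerLawMaterial) -> "BulkMedium":
        return cls("viscoelastic", rho=material.rho, material=material)

    def impedance(self, f):
        """Complex shear-wave impedance at frequency ``f`` (Hz)."""
        f = np.asarray(f, dtype=float)
        if self.kind == "vacuum":
            return np.zeros_like(f, dtype=complex)[()] if np.ndim(f) == 0 \
                else np.zeros_like(f, dtype=complex)
        if self.kind == "newtonian":
            omega = 2.0 * np.pi * f
            return shear_impedance(1j * omega * self.eta, self.rho)
        return evaluate_material(self.material, f).Z
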