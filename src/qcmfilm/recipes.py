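"""Closed-form graphical recipes for thin films.

These invert the small-thickness limits of the layer model: offsets, slopes
and curvatures of Delta f/n against n^2 (film in air) or n (stiff film in a
liquid) map onto {m_f, J', J'', beta', beta''}, and the acoustic ratio
Delta Gamma/(-Delta f) carries the complementary compliance.  The recipes
are approximate by construction -- accurate values come from the full fit of
the exact model (:mod:`qcmfilm.fitting`) -- but they are transparent, and
they are exact on data generated by their own defining equations.

Each estimator performs a quadratic ordinary-least-squares fit in the
stated abscissa (kept for diagnostics and as the initializer) followed by a
least-squares fit of the recipe's own generating shape A + B x^(1+beta/2),
which removes the shape bias a pure quadratic leaves when the dispersion
exponent is far from zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import least_squares

from .materials import BulkMedium, PowerLawMaterial
from .model import OvertoneShiftSet, Resonator

__all__ = [
    "RecipeEstimate",
    "DoubleLayerResult",
    "estimate_film_in_air",
    "estimate_stiff_film_in_liquid",
    "validate_stiffness",
    "double_layer_analysis",
    "acoustic_ratio_compliance",
    "acoustic_ratio_viscosity",
]


@dataclass
class RecipeEstimate:
    """Outcome of a graphical recipe.

    All values are approximate (the recipes are limits of the exact model);
    ``diagnostics`` carries the quadratic-plot coefficients and standard
    errors, ``validity`` the assumption checks.
    """

    mode: str
    m_f: float
    d_f: float
    J1: float
    J2: float
    beta1: Optional[float]
    beta2: Optional[float]
    f_cen: float
    rho_f: float
    diagnostics: dict = field(default_factory=dict)
    validity: dict = field(default_factory=dict)

    def material(self) -> PowerLawMaterial:
        """The estimated film material in the compliance representation."""
        return PowerLawMaterial.from_compliance(
            max(self.J1, 0.0), max(self.J2, 0.0),
            self.beta1 or 0.0, self.beta2 or 0.0,
            f_cen=self.f_cen, rho=self.rho_f,
        )


@dataclass
class DoubleLayerResult:
    """Near-Newtonian (viscosity-increment) interpretation of overtone data.

    ``visc_mass`` is the thickness-viscosity product d_f * (eta'_f -
    eta_bulk) in Pa s m; the layer thickness itself cannot be separated from
    the viscosity increment, so no gravimetric statement is made.
    ``tan_delta_inv`` estimates the inverse loss tangent of the near-surface
    layer; ``delta_eta`` is the complex viscosity increment if a thickness
    was supplied.
    """

    visc_mass: float
    elastic_mass: float
    tan_delta_inv: float
    delta_eta: Optional[complex]
    per_overtone: dict
    validity: dict


def _quadratic_ols(x, y):
    """OLS fit y = a0 + a1 x + a2 x^2 with standard errors.

    With fewer than three points the missing coefficients are NaN.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    order = min(2, len(x) - 1)
    V = np.vander(x, order + 1, increasing=True)
    coef, res_ss, *_ = np.linalg.lstsq(V, y, rcond=None)
    dof = len(x) - (order + 1)
    if dof > 0:
        resid = y - V @ coef
        s2 = float(resid @ resid) / dof
    else:
        s2 = 0.0
    cov = s2 * np.linalg.pinv(V.T @ V)
    stderr = np.sqrt(np.diag(cov))
    full = np.full(3, np.nan)
    full_se = np.full(3, np.nan)
    full[: order + 1] = coef
    full_se[: order + 1] = stderr
    return full, full_se


def _loglog_fit(n_eff, values):
    """Fit log(values) = log(v_cen) + beta*log(n_eff); return v_cen, beta, se."""
    mask = np.asarray(values) > 0
    if mask.sum() < 2:
        return 0.0, 0.0, np.array([np.nan, np.nan]), False
    lx = np.log(np.asarray(n_eff, float)[mask])
    ly = np.log(np.asarray(values, float)[mask])
    V = np.vander(lx, 2, increasing=True)
    coef, *_ = np.linalg.lstsq(V, ly, rcond=None)
    dof = len(lx) - 2
    resid = ly - V @ coef
    s2 = (float(resid @ resid) / dof) if dof > 0 else 0.0
    cov = s2 * np.linalg.pinv(V.T @ V)
    return float(np.exp(coef[0])), float(coef[1]), np.sqrt(np.diag(cov)), bool(mask.all())


def estimate_film_in_air(data: OvertoneShiftSet, res: Resonator,
                         rho_f: float = 1000.0, f_cen: Optional[float] = None,
                         variant: str = "corrected") -> RecipeEstimate:
    """Film-in-air recipe: five parameters from the overtone plots.

    * m_f from the intercept of Delta f/n vs n^2,
    * J' from the slope, beta' from the curvature of that plot,
    * J'' per overtone from Delta Gamma/n (equivalently from the acoustic
      ratio, which grows as n^2 m_f^2), beta'' from its log-log slope.

    ``variant`` selects which third-order bracket generated the data
    ("corrected" keeps the constant -1 correction).  With fewer than three
    overtones the curvature is unidentifiable and beta' is returned as None.
    """
    if f_cen is None:
        f_cen = 30e6
    n = np.asarray(data.n, float)
    if len(n) < 2:
        raise ValueError("at least two overtones are required")
    if np.any(data.df_n >= 0):
        raise ValueError("no film: Delta f/n must be negative on every overtone")
    c = 1.0 if variant == "corrected" else 0.0
    x = n**2
    y = data.df_n

    coef, coef_se = _quadratic_ols(x, y)
    mq = res.mq
    m_f0 = -coef[0] * mq / res.f0
    d_scale = res.Zq**2 / rho_f  # converts compliance to the dimensionless bracket

    def model(theta, xv):
        m_f, J1, b1 = theta
        A = -(m_f / mq) * res.f0
        neff = np.sqrt(xv) * res.f0 / f_cen
        Jx = J1 * neff**b1
        return A * (1.0 + (np.pi**2 / 3.0) * (Jx * d_scale - c) * (m_f / mq) ** 2 * xv)

    beta1_avail = len(n) >= 3 and np.isfinite(coef[2])
    if beta1_avail:
        xc = x.mean()
        yp = coef[1] + 2.0 * coef[2] * xc
        ypp = 2.0 * coef[2]
        beta1_init = float(np.clip(2.0 * xc * ypp / yp if yp != 0 else 0.0, -3.0, 3.0))
        A0 = -(m_f0 / mq) * res.f0
        K = (np.pi**2 / 3.0) * d_scale * (m_f0 / mq) ** 2
        slope_J = (coef[1] / A0 + (np.pi**2 / 3.0) * (m_f0 / mq) ** 2 * c)
        Jc0 = max(slope_J / (K * (1.0 + beta1_init / 2.0)), 1e-12)
        J1_init = Jc0 * (np.sqrt(xc) * res.f0 / f_cen) ** (-beta1_init)
        sol = least_squares(
            lambda th: model(th, x) - y,
            x0=[max(m_f0, 1e-12), J1_init, beta1_init],
            bounds=([1e-15, 0.0, -3.0], [1.0, 1.0, 3.0]),
            xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
        m_f, J1, beta1 = sol.x
        # stderr of beta' from the local quadratic approximation of the fit
        J = sol.jac
        try:
            cov = np.linalg.pinv(J.T @ J) * (2 * sol.cost / max(len(y) - 3, 1))
            beta1_se = float(np.sqrt(cov[2, 2]))
        except np.linalg.LinAlgError:  # pragma: no cover
            beta1_se = np.nan
    else:
        m_f, J1, beta1, beta1_se = m_f0, np.nan, None, np.nan
        # two-point data: slope only, dispersion not identifiable
        K = (np.pi**2 / 3.0) * d_scale * (m_f0 / mq) ** 2
        A0 = -(m_f0 / mq) * res.f0
        J1 = max((coef[1] / A0 + (np.pi**2 / 3.0) * (m_f0 / mq) ** 2 * c) / K, 0.0)

    # viscous channel:
    # Delta Gamma/n = (m_f/m_q)^3 f0 (pi^2/3)(Zq^2/rho_f) J''(n) n^2
    denom = (m_f / mq) ** 3 * res.f0 * (np.pi**2 / 3.0) * d_scale * x
    J2_n = data.dg_n / denom
    J2, beta2, ll_se, all_pos = _loglog_fit(n * res.f0 / f_cen, J2_n)
    if not all_pos and not np.any(J2_n > 0):
        J2, beta2 = 0.0, 0.0

    return RecipeEstimate(
        mode="air",
        m_f=float(m_f), d_f=float(m_f / rho_f),
        J1=float(J1), J2=float(J2),
        beta1=None if beta1 is None else float(beta1),
        beta2=float(beta2), f_cen=f_cen, rho_f=rho_f,
        diagnostics={
            "quad_coef": coef, "quad_stderr": coef_se,
            "beta1_stderr": beta1_se, "beta2_stderr": float(ll_se[1]),
            "J2_per_overtone": J2_n,
        },
        validity={
            "beta1_available": beta1 is not None,
            "all_gamma_positive": bool(np.all(data.dg_n >= 0)),
        },
    )


def estimate_stiff_film_in_liquid(data: OvertoneShiftSet, res: Resonator,
                                  bulk: BulkMedium, rho_f: float = 1000.0,
                                  f_cen: Optional[float] = None,
                                  equal_densities: bool = False,
                                  stiffness_threshold: float = 10.0
                                  ) -> RecipeEstimate:
    """Stiff-film-in-liquid recipe (data referenced to the bulk baseline).

    * d_f from the intercept of Delta f/n vs n,
    * J'' from the slope, beta'' from the curvature of that plot,
    * J' per overtone from the dissipative channel (the acoustic-ratio
      route with the full denominator of the ratio retained),
      beta' from its log-log slope.

    Valid only for films much stiffer than the ambient liquid
    (eta'_f >> eta_bulk); :func:`validate_stiffness` is applied to the
    estimate and reported in ``validity`` -- estimates are returned either
    way, flagged when the assumption fails.
    """
    if f_cen is None:
        f_cen = 30e6
    if bulk.kind != "newtonian":
        raise ValueError("the liquid recipe requires a Newtonian bulk")
    if data.reference != "bulk":
        raise ValueError("data must be referenced to the bulk-loaded baseline")
    n = np.asarray(data.n, float)
    if len(n) < 2:
        raise ValueError("at least two overtones are required")
    if np.any(data.df_n >= 0):
        raise ValueError("no film: Delta f/n must be negative on every overtone")
    r = 1.0 if equal_densities else bulk.rho / rho_f
    x = n
    y = data.df_n
    coef, coef_se = _quadratic_ols(x, y)
    A_pref = -2.0 * res.f0**2 / res.Zq  # per unit areal mass
    m_f0 = coef[0] / A_pref

    # Delta f/n = A_pref m_f [1 - 2 pi f0 eta_b r J''(n) n],  J''(n) ~ n^beta2
    def model(theta, xv):
        m_f, J2, b2 = theta
        Jx = J2 * (xv * res.f0 / f_cen) ** b2
        return A_pref * m_f * (1.0 - 2.0 * np.pi * res.f0 * bulk.eta * r * Jx * xv)

    beta2_avail = len(n) >= 3 and np.isfinite(coef[2])
    if beta2_avail:
        xc = x.mean()
        yp = coef[1] + 2.0 * coef[2] * xc
        ypp = 2.0 * coef[2]
        beta2_init = float(np.clip(xc * ypp / yp if yp != 0 else 0.0, -3.0, 3.0))
        slope_term = -coef[1] / (A_pref * m_f0 * 2.0 * np.pi * res.f0 * bulk.eta * r)
        Jc0 = max(slope_term / (1.0 + beta2_init), 1e-12)
        J2_init = Jc0 * (xc * res.f0 / f_cen) ** (-beta2_init)
        sol = least_squares(
            lambda th: model(th, x) - y,
            x0=[max(m_f0, 1e-12), J2_init, beta2_init],
            bounds=([1e-15, 0.0, -3.0], [1.0, 1.0, 3.0]),
            xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
        m_f, J2, beta2 = sol.x
        J = sol.jac
        cov = np.linalg.pinv(J.T @ J) * (2 * sol.cost / max(len(y) - 3, 1))
        beta2_se = float(np.sqrt(cov[2, 2]))
    else:
        m_f = m_f0
        slope_term = -coef[1] / (A_pref * m_f0 * 2.0 * np.pi * res.f0 * bulk.eta * r)
        J2, beta2, beta2_se = max(slope_term, 0.0), None, np.nan

    # elastic channel: Delta Gamma/n = -A_pref m_f (2 pi f0 eta_b r) J'(n) n
    denom = -A_pref * m_f * 2.0 * np.pi * res.f0 * bulk.eta * r * n
    J1_n = data.dg_n / denom
    J1, beta1, ll_se, _ = _loglog_fit(n * res.f0 / f_cen, J1_n)

    est = RecipeEstimate(
        mode="liquid",
        m_f=float(m_f), d_f=float(m_f / rho_f),
        J1=float(J1), J2=float(J2),
        beta1=float(beta1),
        beta2=None if beta2 is None else float(beta2),
        f_cen=f_cen, rho_f=rho_f,
        diagnostics={
            "quad_coef": coef, "quad_stderr": coef_se,
            "beta2_stderr": beta2_se, "beta1_stderr": float(ll_se[1]),
            "J1_per_overtone": J1_n,
        },
    )
    est.validity = validate_stiffness(est.material(), bulk,
                                      float(np.median(n)) * res.f0,
                                      threshold=stiffness_threshold)
    est.validity["beta2_available"] = beta2 is not None
    return est


def validate_stiffness(material: PowerLawMaterial, bulk: BulkMedium, f: float,
                       threshold: float = 10.0) -> dict:
    """Check the stiff-film assumption J''_f << J''_bulk (eta'_f >> eta_bulk).

    Returns the two equivalent ratios and a boolean verdict at the given
    threshold (default: a factor of ten separation).
    """
    if bulk.kind != "newtonian":
        raise ValueError("stiffness validation requires a Newtonian bulk")
    omega = 2.0 * np.pi * f
    J2_bulk = 1.0 / (omega * bulk.eta)
    if material.is_rigid:
        compliance_ratio = 0.0
        viscosity_ratio = np.inf
    else:
        G = material.complex_modulus(f)
        J = 1.0 / G
        compliance_ratio = float(-J.imag / J2_bulk)
        viscosity_ratio = float(G.imag / omega / bulk.eta)
    return {
        "compliance_ratio": compliance_ratio,
        "viscosity_ratio": viscosity_ratio,
        "stiff": bool(compliance_ratio < 1.0 / threshold),
        "threshold": threshold,
    }


def acoustic_ratio_compliance(J1, J2, eta_bulk, f, rho_ratio: float = 1.0):
    """Thin stiff film: Delta Gamma/(-Delta f) = w J' / (1 - w J''),
    w = 2 pi f eta_bulk * (rho_bulk/rho_f).

    Dropping the denominator gives the leading-order form in which the
    acoustic ratio is thickness-independent and proportional to J'.
    """
    w = 2.0 * np.pi * np.asarray(f) * eta_bulk * rho_ratio
    return w * J1 / (1.0 - w * J2)


def acoustic_ratio_viscosity(abs_eta_f, tan_delta, eta_bulk):
    """The thin-film acoustic ratio in the {|eta~_f|, tan delta} coordinates.

    Algebraically identical to :func:`acoustic_ratio_compliance` via
    J' = eta''/(omega |eta~|^2), J'' = eta'/(omega |eta~|^2):

        Delta Gamma/(-Delta f) = r / (sqrt(1 + tan^2 d) - r tan d),
        r = eta_bulk/|eta~_f|.

    For a nearly Newtonian layer (tan delta -> infinity) with |eta~_f| =
    eta_bulk this tends to 2 tan delta; equivalently the reciprocal
    (-Delta f)/Delta Gamma tends to 1/(2 tan delta), which is the invertible
    small quantity the double-layer analysis uses.
    """
    t = np.asarray(tan_delta, float)
    r = eta_bulk / np.asarray(abs_eta_f, float)
    return r / (np.sqrt(1.0 + t**2) - r * t)


def double_layer_analysis(data: OvertoneShiftSet, res: Resonator,
                          bulk: BulkMedium, d_f: Optional[float] = None,
                          ratio_bound: float = 0.2) -> DoubleLayerResult:
    """Viscosity-increment interpretation of near-Newtonian layer data.

    From the first-order bracket Delta eta~/eta_bulk:

    * ``visc_mass`` = d_f (eta'_f - eta_bulk) = -(Delta f/n) Zq eta_b/(2 f0^2 rho),
      the only accessible combination -- thickness and viscosity increment
      cannot be separated, so no statement on d_f is made;
    * ``elastic_mass`` = d_f eta''_f from the bandwidth channel;
    * ``tan_delta_inv`` = 2 (-Delta f)/Delta Gamma, the inverse loss tangent
      of the layer in the regime |eta~_f| ~ eta_bulk (where the acoustic
      ratio is 2 tan delta to leading order).

    Data with a mean acoustic ratio above ``ratio_bound`` are not
    Sauerbrey-type (the increment is not mostly real); the viscosity-mass
    interpretation is then flagged, not suppressed.
    """
    if bulk.kind != "newtonian":
        raise ValueError("the double-layer analysis requires a Newtonian bulk")
    if data.reference != "bulk":
        raise ValueError("data must be referenced to the bulk-loaded baseline")
    pref = res.Zq * bulk.eta / (2.0 * res.f0**2 * bulk.rho)
    visc_mass_n = -data.df_n * pref
    elastic_mass_n = data.dg_n * pref
    ratio = data.acoustic_ratio()
    with np.errstate(divide="ignore", invalid="ignore"):
        cot_n = np.where(data.dg_n != 0, 2.0 * (-data.df_n) / data.dg_n, np.nan)
    visc_mass = float(np.mean(visc_mass_n))
    elastic_mass = float(np.mean(elastic_mass_n))
    valid = np.isfinite(cot_n)
    tan_delta_inv = float(np.mean(cot_n[valid])) if valid.any() else np.nan
    delta_eta = None
    if d_f is not None:
        if d_f <= 0:
            raise ValueError("thickness must be positive")
        delta_eta = complex(visc_mass / d_f, -elastic_mass / d_f)
    mean_ratio = float(np.nanmean(np.abs(ratio)))
    return DoubleLayerResult(
        visc_mass=visc_mass,
        elastic_mass=elastic_mass,
        tan_delta_inv=tan_delta_inv,
        delta_eta=delta_eta,
        per_overtone={
            "visc_mass": visc_mass_n,
            "elastic_mass": elastic_mass_n,
            "acoustic_ratio": ratio,
            "tan_delta_inv": cot_n,
        },
        validity={
            "sauerbrey_type": mean_ratio < ratio_bound,
            "mean_acoustic_ratio": mean_ratio,
            "ratio_bound": ratio_bound,
        },
    )
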