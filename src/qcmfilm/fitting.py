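"""Five-parameter fits of the exact layer model and chi-square landscapes.

The free parameters are the film thickness, the two material values at the
reference frequency in the chosen representation, and the two power-law
exponents.  chi^2 is the unnormalized weighted sum of squared residuals

    chi^2 = sum_n [ (df/n|model - df/n|data)^2/sigma_f^2
                  + (dG/n|model - dG/n|data)^2/sigma_G^2 ]

matching the qualitative usage in identifiability discussions; the reduced
chi^2 is reported alongside.  Positivity of thickness and the stiffness pair
is enforced by fitting their log10; the exponents are bounded to [-3, 3].
Because the chi^2 valley can be long and shallow (thin films trade
thickness against compliance), the minimizer is restarted from a
deterministic Latin-hypercube of the bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

from .materials import BulkMedium, Layer, PowerLawMaterial
from .model import OvertoneShiftSet, Resonator, predict_film, sauerbrey_mass

__all__ = [
    "PARAM_NAMES",
    "FitProblem",
    "FitResult",
    "Chi2Profile",
    "fit_viscoelastic",
    "chi2_landscape",
    "identifiability_report",
    "IdentifiabilityReport",
]

PARAM_NAMES = ("d_f", "value1", "value2", "beta1", "beta2")
_LOG_PARAMS = ("d_f", "value1", "value2")

#: Default noise scale, Hz -- the magnitude of per-crystal irregularities.
DEFAULT_SIGMA = 0.1

_DEFAULT_BOUNDS = {
    "compliance": {"value1": (1e-10, 1e-3), "value2": (1e-10, 1e-3)},
    "modulus": {"value1": (1e3, 1e10), "value2": (1e3, 1e10)},
    "viscosity": {"value1": (1e-6, 1e2), "value2": (1e-6, 1e2)},
    "magnitude_loss": {"value1": (1e3, 1e10), "value2": (1e-3, 1e3)},
}


@dataclass
class FitProblem:
    """Specification of a weighted five-parameter fit.

    ``free`` lists the parameters to optimize; the rest must appear in
    ``fixed``.  ``init`` may give starting values for any free parameter;
    missing ones are filled by a Sauerbrey-based heuristic.  Weights default
    to the data's noise scales, then to 0.1 Hz.
    """

    data: OvertoneShiftSet
    res: Resonator = field(default_factory=Resonator)
    bulk: BulkMedium = field(default_factory=BulkMedium.water)
    representation: str = "compliance"
    rho_f: float = 1000.0
    f_cen: float = 30e6
    free: Tuple[str, ...] = PARAM_NAMES
    fixed: Dict[str, float] = field(default_factory=dict)
    bounds: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    init: Dict[str, float] = field(default_factory=dict)
    sigma_f: Optional[float] = None
    sigma_g: Optional[float] = None

    def __post_init__(self):
        free = tuple(self.free)
        names = set(free) | set(self.fixed)
        if names != set(PARAM_NAMES) or len(free) + len(self.fixed) != 5:
            raise ValueError(
                f"free+fixed must cover {PARAM_NAMES} exactly once; "
                f"got free={free}, fixed={tuple(self.fixed)}"
            )
        self.free = free
        if len(self.data.n) * 2 < len(free):
            raise ValueError("fewer observations than free parameters")

    # -- plumbing ---------------------------------------------------------
    def param_bounds(self, name: str) -> Tuple[float, float]:
        if name in self.bounds:
            return self.bounds[name]
        if name == "d_f":
            return (1e-11, 1e-6)
        if name in ("beta1", "beta2"):
            return (-3.0, 3.0)
        return _DEFAULT_BOUNDS[self.representation][name]

    def weights(self) -> Tuple[np.ndarray, np.ndarray]:
        sf = self.sigma_f if self.sigma_f is not None else self.data.sigma_f
        sg = self.sigma_g if self.sigma_g is not None else self.data.sigma_g
        n = len(self.data.n)
        sf = np.broadcast_to(np.asarray(sf if sf is not None else DEFAULT_SIGMA,
                                        float), (n,))
        sg = np.broadcast_to(np.asarray(sg if sg is not None else DEFAULT_SIGMA,
                                        float), (n,))
        return sf, sg

    def make_layer(self, params: Dict[str, float]) -> Layer:
        mat = PowerLawMaterial(
            self.representation, params["value1"], params["value2"],
            params["beta1"], params["beta2"], f_cen=self.f_cen, rho=self.rho_f,
        )
        return Layer(mat, params["d_f"])

    def model_per_n(self, params: Dict[str, float]):
        layer = self.make_layer(params)
        shift = predict_film(self.res, layer, self.bulk, self.data.n,
                             reference=self.data.reference)
        return shift / self.data.n

    def residuals(self, params: Dict[str, float]) -> np.ndarray:
        sf, sg = self.weights()
        m = self.model_per_n(params)
        return np.concatenate([(m.real - self.data.df_n) / sf,
                               (m.imag - self.data.dg_n) / sg])

    def chi2(self, params: Dict[str, float]) -> float:
        r = self.residuals(params)
        return float(r @ r)

    def default_init(self) -> Dict[str, float]:
        """Heuristic start: Sauerbrey thickness, mid-range stiffness, flat."""
        init = {}
        m_f = abs(float(sauerbrey_mass(self.data.df_n[0], self.res)))
        lo, hi = self.param_bounds("d_f")
        init["d_f"] = float(np.clip(m_f / self.rho_f, lo * 1.01, hi * 0.99))
        for name in ("value1", "value2"):
            lo, hi = self.param_bounds(name)
            init[name] = float(np.sqrt(lo * hi))
        init["beta1"] = 0.0
        init["beta2"] = 0.0
        init.update({k: v for k, v in self.init.items() if k in PARAM_NAMES})
        return init


@dataclass
class FitResult:
    """A converged (or best-effort) fit with per-parameter uncertainties."""

    params: Dict[str, float]
    chi2: float
    reduced_chi2: float
    residuals: np.ndarray
    stderr: Dict[str, float]
    n_obs: int
    converged: bool
    n_starts_used: int
    problem: Optional[FitProblem] = None


@dataclass
class Chi2Profile:
    """Profile-likelihood curve: chi^2 minimized over all but one parameter."""

    param_name: str
    grid: np.ndarray
    chi2_curve: np.ndarray
    co_fitted: list
    chi2_free: float
    converged: np.ndarray

    @property
    def chi2_min(self) -> float:
        return float(np.min(self.chi2_curve))

    @property
    def argmin(self) -> float:
        return float(self.grid[int(np.argmin(self.chi2_curve))])


# -- transforms -----------------------------------------------------------

def _to_theta(params: Dict[str, float], free: Sequence[str]) -> np.ndarray:
    return np.array([np.log10(params[k]) if k in _LOG_PARAMS else params[k]
                     for k in free])


def _from_theta(theta: np.ndarray, free: Sequence[str],
                fixed: Dict[str, float]) -> Dict[str, float]:
    params = dict(fixed)
    for k, t in zip(free, theta):
        params[k] = 10.0**t if k in _LOG_PARAMS else float(t)
    return params


def _theta_bounds(problem: FitProblem):
    lo, hi = [], []
    for k in problem.free:
        a, b = problem.param_bounds(k)
        if k in _LOG_PARAMS:
            if a <= 0:
                raise ValueError(f"bounds for {k} must be positive")
            a, b = np.log10(a), np.log10(b)
        lo.append(a)
        hi.append(b)
    return np.array(lo), np.array(hi)


def _start_points(problem: FitProblem, n_starts: int, seed: int) -> list:
    lo, hi = _theta_bounds(problem)
    starts = [np.clip(_to_theta(problem.default_init(), problem.free), lo, hi)]
    if n_starts > 1 and len(problem.free) > 0:
        sampler = qmc.LatinHypercube(d=len(problem.free), seed=seed)
        pts = qmc.scale(sampler.random(n_starts - 1), lo, hi)
        starts.extend(list(pts))
    return starts


def fit_viscoelastic(problem: FitProblem, n_starts: int = 8,
                     seed: int = 0) -> FitResult:
    """Minimize chi^2 over the free parameters with deterministic multi-start.

    Returns the best converged solution; if no start converges, the
    best-so-far solution is returned with ``converged=False``.
    """
    lo, hi = _theta_bounds(problem)
    if np.all(problem.data.df_n == 0) and np.all(problem.data.dg_n == 0):
        raise ValueError("degenerate data: all shifts are zero")

    def fun(theta):
        return problem.residuals(_from_theta(theta, problem.free, problem.fixed))

    best = None
    n_used = 0
    for theta0 in _start_points(problem, n_starts, seed):
        n_used += 1
        try:
            sol = least_squares(fun, theta0, bounds=(lo, hi), method="trf",
                                xtol=1e-12, ftol=1e-12, gtol=1e-12)
        except (ValueError, np.linalg.LinAlgError):  # pragma: no cover
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:  # pragma: no cover
        raise RuntimeError("all starts failed")

    params = _from_theta(best.x, problem.free, problem.fixed)
    chi2 = 2.0 * best.cost
    n_obs = 2 * len(problem.data.n)
    dof = max(n_obs - len(problem.free), 1)

    # covariance in transformed space; propagate to physical units
    stderr = {}
    try:
        cov = np.linalg.pinv(best.jac.T @ best.jac)
        for i, k in enumerate(problem.free):
            se = float(np.sqrt(max(cov[i, i], 0.0)))
            if k in _LOG_PARAMS:
                se *= params[k] * np.log(10.0)
            stderr[k] = se
    except np.linalg.LinAlgError:  # pragma: no cover
        stderr = {k: np.nan for k in problem.free}

    return FitResult(
        params=params, chi2=chi2, reduced_chi2=chi2 / dof,
        residuals=best.fun, stderr=stderr, n_obs=n_obs,
        converged=bool(best.status > 0), n_starts_used=n_used,
        problem=problem,
    )


def chi2_landscape(problem: FitProblem, param_name: str, grid,
                   seed: int = 0, n_starts: int = 2) -> Chi2Profile:
    """Profile likelihood: fix one parameter on a grid, refit the rest.

    Each grid point is warm-started from the neighboring solution and from
    the fully free fit (the valley is continuous, so the neighbor is usually
    the best start); every profile point is then >= the free-fit chi^2.
    """
    if param_name not in PARAM_NAMES:
        raise ValueError(f"unknown parameter {param_name!r}")
    if param_name not in problem.free:
        raise ValueError(f"{param_name} is not free in this problem")
    grid = np.asarray(grid, float)
    free_fit = fit_viscoelastic(problem, n_starts=max(n_starts, 4), seed=seed)

    sub_free = tuple(k for k in problem.free if k != param_name)
    chi2_curve = np.empty_like(grid)
    co_fitted = []
    converged = np.zeros(len(grid), dtype=bool)
    prev_params = None
    for i, g in enumerate(grid):
        fixed = dict(problem.fixed)
        fixed[param_name] = float(g)
        sub = replace(problem, free=sub_free, fixed=fixed, init=dict(problem.init))
        best = None
        inits = [dict(free_fit.params)]
        if prev_params is not None:
            inits.insert(0, dict(prev_params))
        for ip in inits:
            sub_i = replace(sub, init={k: v for k, v in ip.items() if k in sub_free})
            r = fit_viscoelastic(sub_i, n_starts=n_starts, seed=seed)
            if best is None or r.chi2 < best.chi2:
                best = r
        chi2_curve[i] = best.chi2
        converged[i] = best.converged
        co_fitted.append({k: best.params[k] for k in sub_free})
        prev_params = best.params
    return Chi2Profile(param_name, grid, chi2_curve, co_fitted,
                       chi2_free=free_fit.chi2, converged=converged)


@dataclass
class IdentifiabilityReport:
    """Counts of robust observables in the overtone plots and a verdict."""

    robust_observables: int
    verdict: str
    channels: dict
    sigma_estimated: bool
    threshold: float


def identifiability_report(data: OvertoneShiftSet, k: float = 2.0
                           ) -> IdentifiabilityReport:
    """Classify offsets/slopes/curvatures of df/n and dG/n versus n.

    Offsets and slopes of the two channels give four observables that are
    essentially always robust; each curvature counts as a fifth/sixth robust
    observable when it exceeds ``k`` times its standard error.  Six robust
    observables overdetermine the five-parameter model; four leave it
    underdetermined.  Missing noise scales are estimated from the quadratic
    residual scatter and flagged.
    """
    n = np.asarray(data.n, float)
    if len(n) < 3:
        raise ValueError("at least three overtones are required")
    sigma_estimated = data.sigma_f is None or data.sigma_g is None
    channels = {}
    robust = 4
    for name, y, sig in (("df_n", data.df_n, data.sigma_f),
                         ("dg_n", data.dg_n, data.sigma_g)):
        V = np.vander(n, 3, increasing=True)
        if sig is None:
            coef, *_ = np.linalg.lstsq(V, y, rcond=None)
            resid = y - V @ coef
            dof = max(len(n) - 3, 1)
            s = float(np.sqrt(resid @ resid / dof))
            sig = np.full_like(n, max(s, 1e-12))
        W = 1.0 / np.asarray(sig, float)
        coef, *_ = np.linalg.lstsq(V * W[:, None], y * W, rcond=None)
        cov = np.linalg.pinv((V * W[:, None]).T @ (V * W[:, None]))
        se = np.sqrt(np.diag(cov))
        curv_robust = bool(abs(coef[2]) > k * se[2])
        channels[name] = {
            "offset": float(coef[0]), "slope": float(coef[1]),
            "curvature": float(coef[2]),
            "stderr": se, "curvature_robust": curv_robust,
        }
        robust += int(curv_robust)
    verdict = {6: "overdetermined", 5: "determined", 4: "underdetermined"}[robust]
    return IdentifiabilityReport(robust, verdict, channels, sigma_estimated, k)
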