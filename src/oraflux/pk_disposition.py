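"""Systemic disposition: linear mammillary compartment models.

Simulation, weighted least-squares fitting (Hooke--Jeeves pattern search
with ``1/Yhat**2`` weighting, AIC/SC model selection) and non-compartmental
metrics for 1-, 2- and 3-compartment models with optional first-order oral
absorption.

Units: time h, concentration ug/L (= ng/mL), dose mg, clearance L/h,
volumes L/kg (scaled by body mass in kg).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Callable, Iterable, Sequence

import numpy as np
from numpy.typing import ArrayLike
from scipy.integrate import solve_ivp
from scipy.linalg import expm
from scipy.optimize import minimize

__all__ = [
    "Route",
    "DispositionParams",
    "ConcentrationTimeProfile",
    "PKMetrics",
    "FitReport",
    "Bolus",
    "FirstOrderOral",
    "simulate_disposition",
    "fit_compartment_model",
    "compute_pk_metrics",
]

DEFAULT_BODY_MASS_KG = 70.0


class Route(str, Enum):
    oral_solution = "oral_solution"
    oral_tablet = "oral_tablet"
    exogenous_input = "exogenous_input"


class InvalidParameterError(ValueError):
    pass


class DegenerateDataError(ValueError):
    pass


@dataclass(frozen=True)
class DispositionParams:
    """Micro-constant parameterization of a mammillary disposition model.

    ``clearance`` in L/h, per-kg volumes in L/kg, transfer rates in 1/h.
    Unused transfer rates must be zero for the declared compartment count.
    """

    n_compartments: int
    clearance: float
    vc_per_kg: float
    k12: float = 0.0
    k21: float = 0.0
    k13: float = 0.0
    k31: float = 0.0
    v2_per_kg: float = 0.0
    v3_per_kg: float = 0.0
    body_mass: float = DEFAULT_BODY_MASS_KG

    def __post_init__(self) -> None:
        if self.n_compartments not in (1, 2, 3):
            raise InvalidParameterError("n_compartments must be 1, 2 or 3")
        vals = (self.clearance, self.vc_per_kg, self.k12, self.k21,
                self.k13, self.k31, self.v2_per_kg, self.v3_per_kg,
                self.body_mass)
        if not all(np.isfinite(v) for v in vals):
            raise InvalidParameterError("non-finite disposition parameter")
        if any(v < 0 for v in vals):
            raise InvalidParameterError("rates and volumes must be >= 0")
        if self.clearance <= 0 or self.vc_per_kg <= 0 or self.body_mass <= 0:
            raise InvalidParameterError("clearance, vc and body mass must be > 0")
        if self.n_compartments <= 2 and (self.k13 != 0 or self.k31 != 0):
            raise InvalidParameterError("k13/k31 must be 0 for <=2 compartments")
        if self.n_compartments == 1 and (self.k12 != 0 or self.k21 != 0):
            raise InvalidParameterError("k12/k21 must be 0 for 1 compartment")

    @property
    def vc(self) -> float:
        """Central volume in L."""
        return self.vc_per_kg * self.body_mass

    @property
    def k10(self) -> float:
        """First-order elimination rate from the central compartment, 1/h."""
        return self.clearance / self.vc

    def rate_matrix(self) -> np.ndarray:
        """Disposition rate matrix over compartment amounts (central first)."""
        n = self.n_compartments
        a = np.zeros((n, n))
        a[0, 0] = -(self.k10 + self.k12 + self.k13)
        if n >= 2:
            a[0, 1] = self.k21
            a[1, 0] = self.k12
            a[1, 1] = -self.k21
        if n == 3:
            a[0, 2] = self.k31
            a[2, 0] = self.k13
            a[2, 2] = -self.k31
        return a

    @property
    def t_half_terminal(self) -> float:
        """Terminal half-life: ln2 over the smallest-magnitude eigenvalue (h)."""
        lam = np.linalg.eigvals(self.rate_matrix())
        return math.log(2.0) / np.min(np.abs(lam.real))


@dataclass(frozen=True)
class ConcentrationTimeProfile:
    """Plasma concentration--time course for one subject/arm."""

    times: np.ndarray
    concentrations: np.ndarray
    dose: float
    route: Route = Route.oral_solution

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        if t.ndim != 1 or c.shape != t.shape:
            raise ValueError("times and concentrations must be 1-D and same length")
        if t.size and (np.any(np.diff(t) <= 0) or t[0] < 0):
            raise ValueError("times must be strictly increasing and start >= 0")
        if np.any(c < 0):
            raise ValueError("concentrations must be >= 0")
        if self.dose < 0:
            raise ValueError("dose must be >= 0")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", c)


@dataclass(frozen=True)
class PKMetrics:
    cmax: float
    tmax: float
    auc_last: float
    auc_inf: float | None
    f_percent: float | None = None
    lambda_z: float | None = None


@dataclass(frozen=True)
class FitReport:
    params: DispositionParams
    ka: float | None
    t_lag: float
    aic: float
    sc: float
    weighted_rss: float
    converged: bool
    n_obs: int
    n_params: int


@dataclass(frozen=True)
class Bolus:
    """Instantaneous IV dose into the central compartment (mg)."""

    dose: float


@dataclass(frozen=True)
class FirstOrderOral:
    """Oral dose absorbed from a depot with first-order rate ka (1/h)."""

    dose: float
    ka: float
    t_lag: float = 0.0


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def _linear_solution(a: np.ndarray, x0: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Solve x' = A x, x(0)=x0 on times t via eigendecomposition.

    Falls back to stepping with the matrix exponential when A is close to
    defective.
    """
    lam, vec = np.linalg.eig(a)
    cond = np.linalg.cond(vec)
    if np.isfinite(cond) and cond < 1e8:
        coef = np.linalg.solve(vec, x0.astype(complex))
        out = (vec @ (coef[:, None] * np.exp(np.outer(lam, t)))).real
        return out
    out = np.empty((a.shape[0], t.size))
    prev_t, state = 0.0, x0.astype(float)
    for j, tj in enumerate(t):
        state = expm(a * (tj - prev_t)) @ state
        out[:, j] = state
        prev_t = tj
    return out


def simulate_disposition(
    params: DispositionParams,
    input_rate: Bolus | FirstOrderOral | Callable[[float], float],
    grid: ArrayLike,
) -> ConcentrationTimeProfile:
    """Simulate the central-compartment concentration on a time grid.

    ``input_rate`` may be a :class:`Bolus` (IV), a :class:`FirstOrderOral`
    depot, or a callable giving a nonnegative systemic input rate in mg/h
    delivered to the central compartment.  Central concentration is the
    central amount divided by Vc; amounts in mg over volumes in L give mg/L,
    reported as ug/L.
    """
    t = np.asarray(grid, dtype=float)
    if t.ndim != 1 or np.any(np.diff(t) <= 0):
        raise ValueError("grid must be 1-D strictly increasing")
    n = params.n_compartments
    a = params.rate_matrix()
    scale = 1000.0 / params.vc  # mg/L -> ug/L

    if isinstance(input_rate, Bolus):
        if input_rate.dose < 0:
            raise ValueError("negative dose")
        x0 = np.zeros(n)
        x0[0] = input_rate.dose
        amounts = _linear_solution(a, x0, t)
        conc = amounts[0] * scale
        return ConcentrationTimeProfile(t, np.maximum(conc, 0.0),
                                        input_rate.dose, Route.exogenous_input)

    if isinstance(input_rate, FirstOrderOral):
        if input_rate.dose < 0:
            raise ValueError("negative dose")
        if input_rate.ka <= 0 or input_rate.t_lag < 0:
            raise InvalidParameterError("ka must be > 0 and t_lag >= 0")
        aug = np.zeros((n + 1, n + 1))
        aug[0, 0] = -input_rate.ka
        aug[1, 0] = input_rate.ka
        aug[1:, 1:] = a
        x0 = np.zeros(n + 1)
        x0[0] = input_rate.dose
        tl = input_rate.t_lag
        conc = np.zeros_like(t)
        after = t > tl
        if np.any(after):
            amounts = _linear_solution(aug, x0, t[after] - tl)
            conc[after] = amounts[1] * scale
        route = Route.oral_solution
        return ConcentrationTimeProfile(t, np.maximum(conc, 0.0),
                                        input_rate.dose, route)

    rate = input_rate

    def rhs(ti: float, x: np.ndarray) -> np.ndarray:
        dx = a @ x
        dx[0] += max(float(rate(ti)), 0.0)
        return dx

    t_span = (min(0.0, t[0]), t[-1])
    sol = solve_ivp(rhs, t_span, np.zeros(n), t_eval=t, method="LSODA",
                    rtol=1e-9, atol=1e-12)
    if not sol.success:
        raise RuntimeError(f"disposition integration failed: {sol.message}")
    conc = sol.y[0] * scale
    total = np.trapezoid([max(float(rate(ti)), 0.0) for ti in t], t)
    return ConcentrationTimeProfile(t, np.maximum(conc, 0.0), total,
                                    Route.exogenous_input)


# ---------------------------------------------------------------------------
# Non-compartmental metrics
# ---------------------------------------------------------------------------

def compute_pk_metrics(
    profile: ConcentrationTimeProfile,
    dose_reference: PKMetrics | None = None,
    reference_dose: float | None = None,
) -> PKMetrics:
    """Cmax/Tmax, trapezoidal AUC, and extrapolated AUCinf via lambda_z.

    ``lambda_z`` comes from a log-linear regression on the terminal points
    after Tmax; the number of terminal points (3..8) is chosen by best R^2.
    ``f_percent`` is the dose-normalized AUC ratio against
    ``dose_reference`` (whose dose is ``reference_dose`` or this profile's).
    """
    t, c = profile.times, profile.concentrations
    if t.size < 3:
        raise ValueError("need at least 3 points")
    imax = int(np.argmax(c))
    cmax, tmax = float(c[imax]), float(t[imax])
    auc_last = float(np.trapezoid(c, t))

    auc_inf: float | None = None
    lam_z: float | None = None
    tail_t, tail_c = t[imax + 1:], c[imax + 1:]
    pos = tail_c > 0
    tail_t, tail_c = tail_t[pos], tail_c[pos]
    if tail_t.size >= 3:
        best_r2 = -np.inf
        for k in range(3, min(8, tail_t.size) + 1):
            tt, cc = tail_t[-k:], np.log(tail_c[-k:])
            slope, intercept = np.polyfit(tt, cc, 1)
            resid = cc - (slope * tt + intercept)
            ss_tot = np.sum((cc - cc.mean()) ** 2)
            r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else -np.inf
            if slope < 0 and r2 > best_r2:
                best_r2, lam_z = r2, -float(slope)
        # a flat tail is not a terminal phase: require a real decline
        if lam_z is not None and lam_z * (tail_t[-1] - tail_t[0]) < 0.05:
            warnings.warn("no identifiable terminal decline; "
                          "auc_inf reported absent")
            lam_z = None
        if lam_z is not None and lam_z > 0:
            auc_inf = auc_last + float(c[-1]) / lam_z

    f_percent = None
    if dose_reference is not None and dose_reference.auc_inf:
        ref_dose = reference_dose if reference_dose else profile.dose
        own = auc_inf if auc_inf is not None else auc_last
        f_percent = 100.0 * (own / profile.dose) / (dose_reference.auc_inf / ref_dose)
    return PKMetrics(cmax=cmax, tmax=tmax, auc_last=auc_last,
                     auc_inf=auc_inf, f_percent=f_percent, lambda_z=lam_z)


# ---------------------------------------------------------------------------
# Fitting: 1/Yhat^2 weighted least squares, Hooke--Jeeves pattern search
# ---------------------------------------------------------------------------

def _predict(theta: np.ndarray, n_cpt: int, oral: bool, with_lag: bool,
             dose: float, body_mass: float, t: np.ndarray) -> np.ndarray:
    """Model prediction from log-scale parameter vector theta."""
    p = np.exp(np.clip(theta, -20.0, 20.0))
    i = 0
    cl, vc = p[0], p[1]
    i = 2
    k12 = k21 = k13 = k31 = 0.0
    if n_cpt >= 2:
        k12, k21 = p[i], p[i + 1]
        i += 2
    if n_cpt == 3:
        k13, k31 = p[i], p[i + 1]
        i += 2
    try:
        params = DispositionParams(n_cpt, cl, vc, k12, k21, k13, k31,
                                   body_mass=body_mass)
    except InvalidParameterError:
        return np.full_like(t, np.nan)
    if oral:
        ka = p[i]
        i += 1
        tlag = p[i] if with_lag else 0.0
        spec: Bolus | FirstOrderOral = FirstOrderOral(dose, ka, tlag)
    else:
        spec = Bolus(dose)
    return simulate_disposition(params, spec, t).concentrations


def _wrss(theta: np.ndarray, obs: np.ndarray, *args) -> float:
    """Sum of (C - Chat)^2 / Chat^2 — the 1/Yhat^2 weighted residual sum."""
    try:
        with np.errstate(over="ignore", invalid="ignore"):
            pred = _predict(theta, *args)
    except (np.linalg.LinAlgError, RuntimeError, ValueError):
        return np.inf
    if not np.all(np.isfinite(pred)):
        return np.inf
    floor = max(1e-9, 1e-9 * obs.max())
    pred = np.maximum(pred, floor)
    return float(np.sum(((obs - pred) / pred) ** 2))


def _hooke_jeeves(fun, x0: np.ndarray, step: float = 0.5,
                  tol: float = 1e-6, max_evals: int = 6000):
    """Hooke & Jeeves pattern search with step halving.

    Exploratory coordinate moves followed by pattern moves; the step is
    halved when no exploratory move improves, down to ``tol`` (relative on
    the log-scale parameters).
    """
    x = x0.copy()
    fx = fun(x)
    evals = 1
    d = x.size
    base = x.copy()
    while step > tol and evals < max_evals:
        improved = False
        xe, fe = x.copy(), fx
        for j in range(d):
            for s in (step, -step):
                trial = xe.copy()
                trial[j] += s
                ft = fun(trial)
                evals += 1
                if ft < fe:
                    xe, fe = trial, ft
                    improved = True
                    break
        if improved:
            # pattern move: extrapolate along the improvement direction
            pattern = xe + (xe - base)
            fp = fun(pattern)
            evals += 1
            base = xe.copy()
            if fp < fe:
                x, fx = pattern, fp
            else:
                x, fx = xe, fe
        else:
            step *= 0.5
            base = x.copy()
    return x, fx, evals


# floor on WRSS/n in the information criteria: residuals below ~1e-7
# relative are numerical noise, so equally perfect fits tie and the
# parameter-count penalty decides
_WRSS_PER_OBS_FLOOR = 1e-14


def _information_criteria(wrss: float, n: int, p: int) -> tuple[float, float]:
    per_obs = max(wrss / n, _WRSS_PER_OBS_FLOOR)
    aic = n * math.log(per_obs) + 2 * p
    sc = n * math.log(per_obs) + p * math.log(n)
    return aic, sc


def fit_compartment_model(
    profile: ConcentrationTimeProfile,
    candidates: Iterable[int] = (1, 2, 3),
    with_lag: bool = False,
    body_mass: float = DEFAULT_BODY_MASS_KG,
    n_starts: int = 10,
    seed: int = 0,
) -> tuple[dict[int, FitReport], FitReport]:
    """Fit candidate mammillary models; return reports and the AIC-best.

    Minimizes the 1/Yhat^2-weighted residual sum with a Hooke--Jeeves
    pattern search (log-scale parameters, ``n_starts`` random multi-starts
    around a non-compartmental initial guess, each polished by Nelder--Mead).
    Oral routes co-estimate a first-order ka (plus optional lag).  The best
    model has the lowest AIC, with the Schwarz criterion as tiebreak.
    """
    obs = profile.concentrations
    t = profile.times
    if np.all(obs == 0):
        raise DegenerateDataError("all-zero concentration profile")
    mask = obs > 0
    obs_f, t_f = obs[mask], t[mask]
    oral = profile.route in (Route.oral_solution, Route.oral_tablet)

    # non-compartmental starting heuristics
    nca = compute_pk_metrics(ConcentrationTimeProfile(t_f, obs_f, profile.dose,
                                                      profile.route))
    auc = nca.auc_inf if nca.auc_inf else nca.auc_last
    cl0 = profile.dose * 1000.0 / auc  # ug basis: dose mg->ug over ug.h/L
    lamz = nca.lambda_z if nca.lambda_z else 0.15
    vc0 = cl0 / lamz / 2.0

    rng = np.random.default_rng(seed)
    reports: dict[int, FitReport] = {}
    for n_cpt in sorted(set(candidates)):
        names = ["CL", "Vc"]
        init = [cl0, vc0 / body_mass]
        if n_cpt >= 2:
            names += ["k12", "k21"]
            init += [lamz, lamz * 2]
        if n_cpt == 3:
            names += ["k13", "k31"]
            init += [lamz / 2, lamz]
        if oral:
            names.append("ka")
            init.append(max(3.0 * lamz, 1.0 / max(nca.tmax, 0.1)))
            if with_lag:
                names.append("t_lag")
                init.append(0.1)
        theta0 = np.log(np.asarray(init))
        args = (obs_f, n_cpt, oral, with_lag, profile.dose, body_mass, t_f)

        best_theta, best_f = None, np.inf
        for s in range(n_starts):
            start = theta0 if s == 0 else theta0 + rng.normal(0, 0.7, theta0.size)
            xh, fh, _ = _hooke_jeeves(lambda th: _wrss(th, *args), start)
            res = minimize(_wrss, xh, args=args, method="Nelder-Mead",
                           options={"xatol": 1e-9, "fatol": 1e-12,
                                    "maxfev": 4000})
            if res.fun < fh:
                xh, fh = res.x, float(res.fun)
            if fh < best_f:
                best_theta, best_f = xh, fh

        converged = best_theta is not None and np.isfinite(best_f)
        p = np.exp(np.clip(best_theta, -20.0, 20.0))
        i = 2
        k12 = k21 = k13 = k31 = 0.0
        if n_cpt >= 2:
            k12, k21 = p[i], p[i + 1]
            i += 2
        if n_cpt == 3:
            k13, k31 = p[i], p[i + 1]
            i += 2
        ka = float(p[i]) if oral else None
        tlag = float(p[i + 1]) if (oral and with_lag) else 0.0
        # peripheral volumes from steady-state partitioning Vp = Vc*k12/k21
        vcpk = float(p[1])
        v2 = vcpk * k12 / k21 if n_cpt >= 2 and k21 > 0 else 0.0
        v3 = vcpk * k13 / k31 if n_cpt == 3 and k31 > 0 else 0.0
        params = DispositionParams(n_cpt, float(p[0]), vcpk, k12, k21, k13,
                                   k31, v2, v3, body_mass)
        n_par = theta0.size
        aic, sc = _information_criteria(best_f, obs_f.size, n_par)
        reports[n_cpt] = FitReport(params, ka, tlag, aic, sc, best_f,
                                   converged, obs_f.size, n_par)

    best = min(reports.values(), key=lambda r: (round(r.aic, 6), r.sc))
    return reports, best
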