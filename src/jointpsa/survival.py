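"""Survival sub-model: baseline hazards, Kaplan-Meier, Weibull PH fit.

The hazard of subject ``i`` couples baseline covariates with the current
value and slope of the (error-free) PSA trajectory:

    h_i(t) = h0(t) * exp(gamma' w_i + alpha * m_i(t) + alpha_s * m_i'(t)).

Three baseline families are supported, all exposing the same contract
(``hazard``/``cumulative_hazard``/``log_hazard`` plus the derivative of the
log-hazard with respect to the family's free parameters, which the EM
M-step consumes):

* ``weibull`` — shape/scale, hazard ``(k/lam)(t/lam)^(k-1)``;
* ``piecewise_constant`` — positive heights on right-open intervals;
* ``bspline`` — cubic B-spline on the log-hazard.

The covariate vector ``w_i`` follows the usual encoding for this cohort:
hormone therapy (binary), stage III-IV vs I-II, dose band (reference
<=50 Gy), Gleason band (reference 2-5) and age.  Age is centered at 70
years so the baseline hazard refers to a typical subject; hazard ratios
per year are unaffected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import optimize

from .data import Cohort, SubjectBaseline

__all__ = [
    "SURVIVAL_TERMS",
    "AGE_CENTER",
    "survival_design_row",
    "BaselineHazard",
    "WeibullHazard",
    "PiecewiseConstantHazard",
    "BSplineLogHazard",
    "SurvivalParams",
    "subject_hazard",
    "KaplanMeierResult",
    "kaplan_meier",
    "fit_ph",
    "fit_weibull_ph",
]

SURVIVAL_TERMS = (
    "hormone_therapy",
    "stage_3_4",
    "dose_51_69",
    "dose_ge70",
    "gleason_6",
    "gleason_7",
    "gleason_8_10",
    "age",
)
AGE_CENTER = 70.0


def survival_design_row(subject: SubjectBaseline) -> np.ndarray:
    """Covariate row ``w_i`` ordered as ``SURVIVAL_TERMS`` (age centered)."""
    return np.array(
        [
            float(subject.hormone_therapy),
            1.0 if subject.stage_group == "3-4" else 0.0,
            1.0 if subject.dose_group == "51-69" else 0.0,
            1.0 if subject.dose_group == "ge70" else 0.0,
            1.0 if subject.gleason_group == "6" else 0.0,
            1.0 if subject.gleason_group == "7" else 0.0,
            1.0 if subject.gleason_group == "8-10" else 0.0,
            subject.age - AGE_CENTER,
        ]
    )


# ---------------------------------------------------------------------------
# baseline hazard families
# ---------------------------------------------------------------------------


class BaselineHazard:
    """Abstract positive baseline hazard ``h0(t)`` on ``t > 0``."""

    family: str = "abstract"

    # -- contract ------------------------------------------------------
    def log_hazard(self, t) -> np.ndarray:
        raise NotImplementedError

    def cumulative_hazard(self, t):
        """``H0(t) = int_0^t h0(s) ds``; continuous, nondecreasing, H0(0)=0."""
        raise NotImplementedError

    def hazard(self, t):
        t_arr = np.asarray(t, dtype=float)
        if np.any(t_arr <= 0):
            raise ValueError("hazard requires t > 0")
        out = np.exp(self.log_hazard(t_arr))
        return float(out) if np.ndim(t) == 0 else out

    # -- parameter-vector view used by the fitting machinery -----------
    @property
    def free_params(self) -> np.ndarray:
        raise NotImplementedError

    def with_params(self, vec) -> "BaselineHazard":
        raise NotImplementedError

    @property
    def n_params(self) -> int:
        return len(self.free_params)

    def d_log_hazard(self, t) -> np.ndarray:
        """Jacobian of ``log h0(t)`` w.r.t. ``free_params``; shape (len(t), p)."""
        raise NotImplementedError

    def quad_breakpoints(self) -> np.ndarray:
        """Interior discontinuities; quadrature splits integrals there."""
        return np.empty(0)

    def _check_time(self, t):
        t_arr = np.asarray(t, dtype=float)
        if np.any(t_arr < 0):
            raise ValueError("cumulative hazard requires t >= 0")
        return t_arr


@dataclass
class WeibullHazard(BaselineHazard):
    """Weibull baseline: ``h0(t) = (k/lam)(t/lam)^(k-1)``, ``H0 = (t/lam)^k``."""

    shape: float = 1.0
    scale: float = 1.0
    family = "weibull"

    def __post_init__(self):
        if not (self.shape > 0 and self.scale > 0):
            raise ValueError("Weibull shape and scale must be > 0")

    def log_hazard(self, t):
        t = np.asarray(t, dtype=float)
        return (
            np.log(self.shape / self.scale)
            + (self.shape - 1.0) * np.log(t / self.scale)
        )

    def cumulative_hazard(self, t):
        t_arr = self._check_time(t)
        out = (t_arr / self.scale) ** self.shape
        return float(out) if np.ndim(t) == 0 else out

    @property
    def free_params(self) -> np.ndarray:
        return np.array([np.log(self.shape), np.log(self.scale)])

    def with_params(self, vec) -> "WeibullHazard":
        return WeibullHazard(shape=float(np.exp(vec[0])), scale=float(np.exp(vec[1])))

    def d_log_hazard(self, t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        dk = 1.0 + self.shape * np.log(t / self.scale)  # d/d log k
        dl = np.full_like(t, -self.shape)  # d/d log lam
        return np.column_stack([dk, dl])


@dataclass
class PiecewiseConstantHazard(BaselineHazard):
    """Step hazard on right-open intervals ``[0,b1), [b1,b2), ..., [bm,inf)``."""

    breaks: np.ndarray
    heights: np.ndarray
    family = "piecewise_constant"

    def __post_init__(self):
        self.breaks = np.atleast_1d(np.asarray(self.breaks, dtype=float))
        self.heights = np.atleast_1d(np.asarray(self.heights, dtype=float))
        if len(self.heights) != len(self.breaks) + 1:
            raise ValueError("need len(heights) == len(breaks) + 1")
        if np.any(np.diff(self.breaks) <= 0) or np.any(self.breaks <= 0):
            raise ValueError("breaks must be positive and strictly increasing")
        if np.any(self.heights <= 0):
            raise ValueError("heights must be > 0")

    def _interval(self, t):
        return np.searchsorted(self.breaks, t, side="right")

    def log_hazard(self, t):
        t = np.asarray(t, dtype=float)
        return np.log(self.heights[self._interval(t)])

    def cumulative_hazard(self, t):
        t_arr = self._check_time(t)
        edges = np.concatenate([[0.0], self.breaks])
        # time spent in each interval, piecewise-linear in t
        upper = np.concatenate([self.breaks, [np.inf]])
        tt = np.atleast_1d(t_arr)[:, None]
        dur = np.clip(np.minimum(tt, upper[None, :]) - edges[None, :], 0.0, None)
        out = (dur * self.heights[None, :]).sum(axis=1)
        return float(out[0]) if np.ndim(t) == 0 else out.reshape(np.shape(t_arr))

    @property
    def free_params(self) -> np.ndarray:
        return np.log(self.heights)

    def with_params(self, vec) -> "PiecewiseConstantHazard":
        return PiecewiseConstantHazard(self.breaks.copy(), np.exp(np.asarray(vec)))

    def d_log_hazard(self, t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.zeros((len(t), len(self.heights)))
        out[np.arange(len(t)), self._interval(t)] = 1.0
        return out

    def quad_breakpoints(self) -> np.ndarray:
        return self.breaks.copy()


@dataclass
class BSplineLogHazard(BaselineHazard):
    """Smooth baseline: cubic B-spline for ``log h0(t)`` on ``[0, tmax]``.

    The knot vector is clamped at 0 and ``tmax``; outside the domain the
    log-hazard is extended by its boundary value.  ``H0`` has no closed
    form and is evaluated by adaptive quadrature.
    """

    internal_knots: np.ndarray
    coef: np.ndarray
    tmax: float = 10.0
    degree: int = 3
    family = "bspline"

    def __post_init__(self):
        from scipy.interpolate import BSpline

        self.internal_knots = np.atleast_1d(np.asarray(self.internal_knots, float))
        self.coef = np.atleast_1d(np.asarray(self.coef, dtype=float))
        k = self.degree
        if np.any(self.internal_knots <= 0) or np.any(self.internal_knots >= self.tmax):
            raise ValueError("internal knots must lie strictly inside (0, tmax)")
        self._knots = np.concatenate(
            [np.zeros(k + 1), np.sort(self.internal_knots), np.full(k + 1, self.tmax)]
        )
        n_basis = len(self._knots) - k - 1
        if len(self.coef) != n_basis:
            raise ValueError(f"need {n_basis} coefficients, got {len(self.coef)}")
        self._bspline = BSpline(self._knots, self.coef, k, extrapolate=False)

    def _clip(self, t):
        eps = 1e-12 * max(1.0, self.tmax)
        return np.clip(t, eps, self.tmax - eps)

    def log_hazard(self, t):
        t = np.asarray(t, dtype=float)
        return self._bspline(self._clip(t))

    def cumulative_hazard(self, t):
        from scipy.integrate import quad

        t_arr = self._check_time(t)
        flat = np.atleast_1d(t_arr).ravel()
        out = np.array(
            [
                quad(lambda s: np.exp(self._bspline(self._clip(s))), 0.0, ti,
                     epsabs=1e-12, epsrel=1e-10, limit=200)[0]
                if ti > 0 else 0.0
                for ti in flat
            ]
        )
        return float(out[0]) if np.ndim(t) == 0 else out.reshape(np.shape(t_arr))

    @property
    def free_params(self) -> np.ndarray:
        return self.coef.copy()

    def with_params(self, vec) -> "BSplineLogHazard":
        return BSplineLogHazard(
            self.internal_knots.copy(), np.asarray(vec, float), self.tmax, self.degree
        )

    def d_log_hazard(self, t) -> np.ndarray:
        from scipy.interpolate import BSpline

        t = self._clip(np.atleast_1d(np.asarray(t, dtype=float)))
        return BSpline.design_matrix(
            t, self._knots, self.degree, extrapolate=False
        ).toarray()

    def quad_breakpoints(self) -> np.ndarray:
        return np.sort(self.internal_knots)


@dataclass
class SurvivalParams:
    """Hazard sub-model parameters: covariate coefficients and baseline."""

    gamma: np.ndarray
    baseline: BaselineHazard = field(default_factory=WeibullHazard)

    def __post_init__(self):
        self.gamma = np.asarray(self.gamma, dtype=float)
        if self.gamma.shape != (len(SURVIVAL_TERMS),):
            raise ValueError(
                f"gamma must have length {len(SURVIVAL_TERMS)} ({SURVIVAL_TERMS})"
            )


def subject_hazard(joint, b_i, subject: SubjectBaseline, t):
    """Subject-specific hazard ``h0(t) exp(gamma'w + alpha m + alpha_s m')``.

    ``joint`` is a :class:`jointpsa.joint.JointParams`; defined here so the
    hazard contract lives with the baseline families.
    """
    from .longitudinal import trajectory_slope, trajectory_value

    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr <= 0):
        raise ValueError("subject_hazard requires t > 0")
    w = survival_design_row(subject)
    m = trajectory_value(joint.longitudinal, b_i, subject, t_arr, joint.fixed_spec)
    ms = trajectory_slope(joint.longitudinal, b_i, subject, t_arr, joint.fixed_spec)
    eta = joint.survival.gamma @ w + joint.alpha * m + joint.alpha_s * ms
    out = np.exp(joint.survival.baseline.log_hazard(t_arr) + eta)
    return float(out) if np.ndim(t) == 0 else out


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------


@dataclass
class KaplanMeierResult:
    """Product-limit estimate with Greenwood log-log confidence bands."""

    event_times: np.ndarray  # distinct event times, ascending
    at_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    greenwood_var: np.ndarray
    median: Optional[float]
    median_ci: tuple[Optional[float], Optional[float]]

    def survival_at(self, t) -> np.ndarray:
        """Step-function value S(t); S = 1 before the first event."""
        idx = np.searchsorted(self.event_times, np.asarray(t, float), side="right")
        s = np.concatenate([[1.0], self.survival])
        return s[idx]

    def table(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time": self.event_times,
                "at_risk": self.at_risk,
                "events": self.n_events,
                "survival": self.survival,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )


def _first_crossing(times, values, level):
    below = values <= level + 1e-15
    return float(times[np.argmax(below)]) if below.any() else None


def kaplan_meier(times, events, conf_level: float = 0.95) -> KaplanMeierResult:
    """Kaplan-Meier estimator with Greenwood variance and log-log CIs.

    The median is the earliest time at which ``S(t) <= 0.5`` (``None`` when
    never reached); its confidence limits are the crossing times of the
    lower and upper confidence bands.
    """
    from scipy import stats

    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValueError("kaplan_meier: empty input")
    if t.shape != d.shape:
        raise ValueError("times and events must have equal length")
    if np.any(t <= 0):
        raise ValueError("times must be > 0")

    uniq = np.unique(t[d == 1])
    n_at_risk = np.array([(t >= u - 1e-12).sum() for u in uniq])
    n_events = np.array([((d == 1) & (np.abs(t - u) <= 1e-12)).sum() for u in uniq])
    frac = 1.0 - n_events / n_at_risk
    surv = np.cumprod(frac)
    # Greenwood: Var(S) = S^2 * cumsum(d / (n (n - d)))
    with np.errstate(divide="ignore"):
        gw_terms = n_events / (n_at_risk * (n_at_risk - n_events))
    gw_terms[~np.isfinite(gw_terms)] = 0.0
    gw = surv**2 * np.cumsum(gw_terms)
    z = stats.norm.ppf(0.5 + conf_level / 2.0)
    # log(-log S) transformed bands: S^exp(+-z * se / (S log S))
    with np.errstate(divide="ignore", invalid="ignore"):
        se_loglog = np.sqrt(gw) / np.abs(surv * np.log(surv))
        lo = surv ** np.exp(z * se_loglog)
        hi = surv ** np.exp(-z * se_loglog)
    lo = np.where(surv <= 0.0, 0.0, np.nan_to_num(lo, nan=0.0))
    hi = np.where(surv <= 0.0, 0.0, np.nan_to_num(hi, nan=1.0))
    hi = np.where(surv >= 1.0, 1.0, hi)

    median = _first_crossing(uniq, surv, 0.5)
    median_ci = (_first_crossing(uniq, lo, 0.5), _first_crossing(uniq, hi, 0.5))
    return KaplanMeierResult(
        event_times=uniq,
        at_risk=n_at_risk,
        n_events=n_events,
        survival=surv,
        ci_low=lo,
        ci_high=hi,
        greenwood_var=gw,
        median=median,
        median_ci=median_ci,
    )


# ---------------------------------------------------------------------------
# proportional-hazards fit on baseline covariates (EM initialization)
# ---------------------------------------------------------------------------


def gl_cumulative_hazard(
    baseline: BaselineHazard, T: np.ndarray, n_nodes: int = 15
) -> np.ndarray:
    """Vectorized ``H0(T_i)`` by Gauss-Legendre, split at discontinuities."""
    T = np.atleast_1d(np.asarray(T, dtype=float))
    x, w = np.polynomial.legendre.leggauss(n_nodes)
    cuts = baseline.quad_breakpoints()
    edges_all = np.concatenate([[0.0], cuts])
    out = np.zeros_like(T)
    for j, lo in enumerate(edges_all):
        hi_edge = edges_all[j + 1] if j + 1 < len(edges_all) else np.inf
        lo_i = np.minimum(T, lo)
        hi_i = np.minimum(T, hi_edge)
        half = 0.5 * (hi_i - lo_i)
        mid = 0.5 * (hi_i + lo_i)
        nodes = mid[:, None] + half[:, None] * x[None, :]
        vals = np.where(
            half[:, None] > 0,
            np.exp(baseline.log_hazard(np.clip(nodes, 1e-300, None))),
            0.0,
        )
        out += half * (vals @ w)
    return out


def _cumhaz_for_fit(baseline: BaselineHazard, T: np.ndarray) -> np.ndarray:
    if baseline.family == "bspline":  # no closed form; adaptive quad too slow here
        return gl_cumulative_hazard(baseline, T)
    return np.asarray(baseline.cumulative_hazard(T), dtype=float)


def fit_ph(
    cohort: Cohort,
    baseline: BaselineHazard,
    max_iter: int = 500,
) -> tuple[SurvivalParams, float]:
    """Parametric PH maximum likelihood on baseline covariates only.

    ``loglik = sum_i [ d_i (log h0(T_i) + gamma'w_i) - H0(T_i) e^(gamma'w_i) ]``.
    No longitudinal term enters; the result initializes ``gamma`` and the
    baseline parameters for the joint EM.  Returns ``(params, loglik)``.
    """
    T = np.array([s.event_time for s in cohort.subjects])
    d = np.array([s.event for s in cohort.subjects], dtype=float)
    if d.sum() < 1:
        raise ValueError("fit_ph requires at least one event")
    W = np.vstack([survival_design_row(s) for s in cohort.subjects])
    q = W.shape[1]
    b0 = baseline.free_params

    def nll(theta):
        gamma = theta[:q]
        bl = baseline.with_params(theta[q:])
        try:
            with np.errstate(over="ignore"):
                eta = W @ gamma
                ll = d @ (bl.log_hazard(T) + eta) - np.exp(eta) @ _cumhaz_for_fit(
                    bl, T
                )
        except (ValueError, FloatingPointError):
            return 1e12
        return -ll if np.isfinite(ll) else 1e12

    x0 = np.concatenate([np.zeros(q), b0])
    res = optimize.minimize(
        nll, x0, method="L-BFGS-B", options={"maxiter": max_iter, "ftol": 1e-13}
    )
    if not np.isfinite(res.fun) or res.fun >= 1e12:
        raise RuntimeError(f"PH fit failed: {res.message}")
    params = SurvivalParams(gamma=res.x[:q], baseline=baseline.with_params(res.x[q:]))
    return params, -float(res.fun)


def fit_weibull_ph(cohort: Cohort, max_iter: int = 500) -> tuple[SurvivalParams, float]:
    """Weibull PH fit (shape/scale + covariates); see :func:`fit_ph`."""
    T = np.array([s.event_time for s in cohort.subjects])
    d = np.array([s.event for s in cohort.subjects], dtype=float)
    if d.sum() < 1:
        raise ValueError("fit_weibull_ph requires at least one event")
    scale0 = float(T.sum() / max(d.sum(), 1.0))  # exponential MLE start
    return fit_ph(cohort, WeibullHazard(shape=1.0, scale=scale0), max_iter=max_iter)
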