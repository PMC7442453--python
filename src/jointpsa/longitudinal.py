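"""Longitudinal sub-model: PSA trajectory as a linear mixed model.

The error-free trajectory of subject ``i`` on the transformed-PSA scale is

    m_i(t) = x_i(t)' beta + b_{i0} + b_{i1} t,

where ``x_i(t)`` is a fixed-effect design row built from baseline covariates
(hormone therapy, dose band) and polynomial time terms with
covariate-by-time interactions, and ``b_i ~ N(0, D)`` is a subject-level
random intercept and slope.  Observed values add i.i.d. Gaussian noise:
``y_ij = m_i(t_ij) + eps_ij``, ``eps ~ N(0, sigma2)``.

Because every fixed-effect term is a covariate value times a power of time,
each subject's fixed-effect mean is a polynomial in ``t``; the
decomposition ``x_i(t) = r0_i + r1_i t + r2_i t^2`` (see
:func:`design_decomposition`) is what the hazard sub-model uses to evaluate
``m_i`` and its derivative at arbitrary times.

:func:`fit_lmm` maximizes the marginal Gaussian likelihood
``y_i ~ N(X_i beta, Z_i D Z_i' + sigma2 I)`` directly (profiled GLS for
``beta``, quasi-Newton over a log-Cholesky parameterization of ``D`` and
``log sigma``); it initializes the EM algorithm of the joint model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .data import Cohort, SubjectBaseline

__all__ = [
    "FixedEffectsSpec",
    "RandomEffectsSpec",
    "LongitudinalParams",
    "build_design",
    "design_decomposition",
    "trajectory_value",
    "trajectory_slope",
    "fit_lmm",
    "lmm_marginal_loglik",
]

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class FixedEffectsSpec:
    """Fixed-effect design: baseline terms, time trend, interactions.

    Term order is fixed: intercept, hormone therapy, dose 51-69, dose >=70,
    time, [time^2 if enabled], time x hormone, time x dose 51-69,
    time x dose >=70.  The quadratic time term is opt-in.
    """

    include_quadratic_time: bool = False

    @property
    def terms(self) -> tuple[str, ...]:
        base = ["intercept", "hormone_therapy", "dose_51_69", "dose_ge70", "time"]
        if self.include_quadratic_time:
            base.append("time2")
        base += ["time_hormone", "time_dose_51_69", "time_dose_ge70"]
        return tuple(base)

    @property
    def n_terms(self) -> int:
        return len(self.terms)


@dataclass(frozen=True)
class RandomEffectsSpec:
    """Random-effect design: subject-level intercept and time slope."""

    terms: tuple[str, ...] = ("intercept", "time")

    def __post_init__(self):
        if self.terms != ("intercept", "time"):
            raise ValueError("random effects are fixed to (intercept, time)")

    @property
    def n_terms(self) -> int:
        return len(self.terms)


@dataclass
class LongitudinalParams:
    """Parameters of the longitudinal sub-model.

    beta : fixed-effect coefficients (transformed-PSA units), ordered as
        ``FixedEffectsSpec.terms``.
    D : 2x2 positive-definite covariance of the random intercept/slope.
    sigma2 : residual measurement-error variance (> 0).
    """

    beta: np.ndarray
    D: np.ndarray = field(
        default_factory=lambda: np.array([[1.0, 0.0], [0.0, 0.25]])
    )
    sigma2: float = 0.36

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float)
        self.D = np.asarray(self.D, dtype=float)
        if self.D.shape != (2, 2):
            raise ValueError("D must be 2x2")
        if not np.allclose(self.D, self.D.T):
            raise ValueError("D must be symmetric")
        np.linalg.cholesky(self.D)  # raises if not positive-definite
        if not self.sigma2 > 0:
            raise ValueError("sigma2 must be > 0")


def design_decomposition(
    subject: SubjectBaseline, spec: FixedEffectsSpec
) -> np.ndarray:
    """Rows ``(r0, r1, r2)`` with ``x_i(t) = r0 + r1 t + r2 t^2``.

    Returns an array of shape ``(3, p)``; ``r2`` is zero unless the
    quadratic time term is enabled.
    """
    h = float(subject.hormone_therapy)
    d1 = 1.0 if subject.dose_group == "51-69" else 0.0
    d2 = 1.0 if subject.dose_group == "ge70" else 0.0
    p = spec.n_terms
    rows = np.zeros((3, p))
    for j, term in enumerate(spec.terms):
        if term == "intercept":
            rows[0, j] = 1.0
        elif term == "hormone_therapy":
            rows[0, j] = h
        elif term == "dose_51_69":
            rows[0, j] = d1
        elif term == "dose_ge70":
            rows[0, j] = d2
        elif term == "time":
            rows[1, j] = 1.0
        elif term == "time2":
            rows[2, j] = 1.0
        elif term == "time_hormone":
            rows[1, j] = h
        elif term == "time_dose_51_69":
            rows[1, j] = d1
        elif term == "time_dose_ge70":
            rows[1, j] = d2
    return rows


def build_design(
    subject: SubjectBaseline,
    times,
    spec: FixedEffectsSpec = FixedEffectsSpec(),
    re_spec: RandomEffectsSpec = RandomEffectsSpec(),
) -> tuple[np.ndarray, np.ndarray]:
    """Fixed and random design matrices at the given visit times.

    ``X`` has one row per time with columns ordered as ``spec.terms``;
    ``Z`` columns are ``[1, t]``.
    """
    t = np.atleast_1d(np.asarray(times, dtype=float))
    if np.any(t < 0):
        raise ValueError("times must be >= 0")
    rows = design_decomposition(subject, spec)
    X = rows[0] + np.outer(t, rows[1]) + np.outer(t**2, rows[2])
    Z = np.column_stack([np.ones_like(t), t])
    return X, Z


def trajectory_value(
    params: LongitudinalParams,
    b_i,
    subject: SubjectBaseline,
    t,
    spec: FixedEffectsSpec = FixedEffectsSpec(),
):
    """Error-free trajectory ``m_i(t) = x_i(t)'beta + b0 + b1 t``."""
    b = np.asarray(b_i, dtype=float)
    if b.shape[-1] != 2:
        raise ValueError("b_i must have length 2 (intercept, slope)")
    tt = np.asarray(t, dtype=float)
    rows = design_decomposition(subject, spec)
    if rows.shape[1] != params.beta.shape[0]:
        raise ValueError("beta length does not match the fixed-effects spec")
    a0, a1, a2 = rows @ params.beta
    out = a0 + a1 * tt + a2 * tt**2 + b[..., 0] + b[..., 1] * tt
    return float(out) if np.ndim(out) == 0 else out


def trajectory_slope(
    params: LongitudinalParams,
    b_i,
    subject: SubjectBaseline,
    t,
    spec: FixedEffectsSpec = FixedEffectsSpec(),
):
    """Analytic time-derivative ``m_i'(t)``; constant when time is linear."""
    b = np.asarray(b_i, dtype=float)
    if b.shape[-1] != 2:
        raise ValueError("b_i must have length 2 (intercept, slope)")
    tt = np.asarray(t, dtype=float)
    rows = design_decomposition(subject, spec)
    if rows.shape[1] != params.beta.shape[0]:
        raise ValueError("beta length does not match the fixed-effects spec")
    _, a1, a2 = rows @ params.beta
    out = a1 + 2.0 * a2 * tt + b[..., 1] + 0.0 * tt
    return float(out) if np.ndim(out) == 0 else out


# ---------------------------------------------------------------------------
# marginal likelihood and fitting
# ---------------------------------------------------------------------------


def _stack_cohort(cohort: Cohort, spec: FixedEffectsSpec):
    """Stacked (y, X, Z) plus per-subject row slices, in subject order."""
    obs_by = {}
    for o in cohort.observations:
        obs_by.setdefault(o.subject_id, []).append(o)
    ys, Xs, Zs, slices = [], [], [], []
    start = 0
    for s in cohort.subjects:
        obs = sorted(obs_by[s.subject_id], key=lambda o: o.time)
        t = np.array([o.time for o in obs])
        X, Z = build_design(s, t, spec)
        ys.append(np.array([o.psa_star for o in obs]))
        Xs.append(X)
        Zs.append(Z)
        slices.append(slice(start, start + len(obs)))
        start += len(obs)
    return np.concatenate(ys), np.vstack(Xs), np.vstack(Zs), slices


def _marginal_loglik_parts(y, X, Z, slices, D, sigma2, beta=None):
    """Gaussian marginal loglik; profiles beta by GLS when beta is None."""
    XtVX = 0.0
    XtVy = 0.0
    logdet = 0.0
    solves = []
    for sl in slices:
        Zi = Z[sl]
        Vi = Zi @ D @ Zi.T + sigma2 * np.eye(sl.stop - sl.start)
        c = np.linalg.cholesky(Vi)
        logdet += 2.0 * np.sum(np.log(np.diag(c)))
        Wy = np.linalg.solve(Vi, np.column_stack([X[sl], y[sl]]))
        solves.append((sl, Wy))
        XtVX = XtVX + X[sl].T @ Wy[:, :-1]
        XtVy = XtVy + X[sl].T @ Wy[:, -1]
    if beta is None:
        beta = np.linalg.solve(XtVX, XtVy)
    quad = 0.0
    for sl, Wy in solves:
        r = y[sl] - X[sl] @ beta
        Vinv_r = Wy[:, -1] - Wy[:, :-1] @ beta
        quad += r @ Vinv_r
    n = len(y)
    loglik = -0.5 * (n * _LOG2PI + logdet + quad)
    return loglik, beta


def lmm_marginal_loglik(
    params: LongitudinalParams,
    cohort: Cohort,
    spec: FixedEffectsSpec = FixedEffectsSpec(),
) -> float:
    """Marginal loglik of the LMM at fixed parameters (matrix form)."""
    y, X, Z, slices = _stack_cohort(cohort, spec)
    ll, _ = _marginal_loglik_parts(
        y, X, Z, slices, params.D, params.sigma2, beta=params.beta
    )
    return float(ll)


def _unpack_varparams(xi):
    """(l11, l21, l22, log sigma) -> (D, sigma2) via Cholesky factor."""
    L = np.array([[np.exp(xi[0]), 0.0], [xi[1], np.exp(xi[2])]])
    return L @ L.T, float(np.exp(2.0 * xi[3]))


def fit_lmm(
    cohort: Cohort,
    spec: FixedEffectsSpec = FixedEffectsSpec(),
    re_spec: RandomEffectsSpec = RandomEffectsSpec(),
    max_iter: int = 500,
) -> tuple[LongitudinalParams, float]:
    """Maximum-likelihood fit of the linear mixed model.

    Optimizes the profiled marginal likelihood over a log-Cholesky
    parameterization of ``D`` and ``log sigma`` with L-BFGS-B; ``beta`` is
    recovered by GLS at the optimum.  Returns ``(params, loglik)``.
    """
    if cohort.n_subjects < 2:
        raise ValueError("fit_lmm needs at least 2 subjects")
    y, X, Z, slices = _stack_cohort(cohort, spec)

    # moment-based start: OLS residual variance split between RE and noise
    beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid_var = max(float(np.var(y - X @ beta0)), 1e-8)
    x0 = np.array(
        [0.5 * np.log(resid_var / 2), 0.0, 0.5 * np.log(resid_var / 4),
         0.5 * np.log(resid_var / 2)]
    )

    def nll(xi):
        D, sigma2 = _unpack_varparams(xi)
        try:
            ll, _ = _marginal_loglik_parts(y, X, Z, slices, D, sigma2)
        except np.linalg.LinAlgError:
            return 1e12
        return -ll

    bounds = [(-12.0, 8.0), (-50.0, 50.0), (-12.0, 8.0), (-12.0, 8.0)]
    res = optimize.minimize(
        nll, x0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-9},
    )
    if not np.isfinite(res.fun):
        raise RuntimeError(f"LMM fit failed to produce a finite likelihood: {res}")
    D, sigma2 = _unpack_varparams(res.x)
    ll, beta = _marginal_loglik_parts(y, X, Z, slices, D, sigma2)
    params = LongitudinalParams(beta=beta, D=D, sigma2=sigma2)
    return params, float(ll)
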