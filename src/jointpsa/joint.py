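"""Joint longitudinal-survival model: likelihood, EM fit, reporting.

The shared-random-effects joint model couples the two sub-models through
the subject-level random intercept/slope ``b_i ~ N(0, D)``:

* longitudinal:  ``y_ij = m_i(t_ij) + eps_ij``,
  ``m_i(t) = x_i(t)'beta + b_i0 + b_i1 t``;
* hazard:  ``h_i(t) = h0(t) exp(gamma'w_i + alpha m_i(t) + alpha_s m_i'(t))``.

The observed-data likelihood integrates the random effects out of the
product of the two conditional densities.  That integral has no closed
form; it is evaluated by Gauss-Hermite quadrature after standardizing the
random effects.  By default the rule is *adaptive*: nodes are recentred at
the per-subject posterior mode of ``b_i`` and rescaled by the posterior
curvature, which keeps a 9-point rule accurate even when a subject's many
measurements make the posterior much narrower than the prior.

Estimation is EM (posterior moments of ``b_i`` by quadrature reweighting;
closed-form M-step updates for ``beta``, ``sigma2`` and ``D``; Newton-type
updates for the hazard block) followed by a quasi-Newton polish of the
marginal likelihood using the analytic score obtained from Fisher's
identity (score of the marginal likelihood = posterior expectation of the
complete-data score).  The observed-data log-likelihood is monotone along
the EM trace; a step-halving safeguard enforces this against quadrature
round-off.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import optimize, stats

from .data import Cohort
from .longitudinal import (
    FixedEffectsSpec,
    LongitudinalParams,
    design_decomposition,
    fit_lmm,
    trajectory_slope,
    trajectory_value,
)
from .survival import (
    SURVIVAL_TERMS,
    BaselineHazard,
    BSplineLogHazard,
    PiecewiseConstantHazard,
    SurvivalParams,
    WeibullHazard,
    fit_ph,
    survival_design_row,
)

__all__ = [
    "JointParams",
    "QuadratureRule",
    "FitResult",
    "subject_loglik_given_b",
    "marginal_loglik",
    "em_fit",
    "standard_errors",
    "compare_baselines",
    "rr_table",
]

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class JointParams:
    """Full parameter vector of the joint model.

    ``alpha`` scales the current trajectory value (per transformed-PSA
    unit); ``alpha_s`` scales its slope (per transformed-PSA unit/year).
    ``fixed_spec`` records the fixed-effect design the trajectory uses.
    """

    longitudinal: LongitudinalParams
    survival: SurvivalParams
    alpha: float = 0.0
    alpha_s: float = 0.0
    fixed_spec: FixedEffectsSpec = field(default_factory=FixedEffectsSpec)

    def __post_init__(self):
        vals = [self.alpha, self.alpha_s, *np.ravel(self.longitudinal.beta)]
        if not np.all(np.isfinite(vals)):
            raise ValueError("joint parameters must be finite")


@dataclass(frozen=True)
class QuadratureRule:
    """Quadrature orders for the two numerical integrals.

    ``gh_nodes`` (odd) per random-effect dimension for the Gauss-Hermite
    integral over ``b_i``; ``gl_nodes`` for the Gauss-Legendre cumulative-
    hazard integral on ``[0, T_i]``.  ``adaptive`` recentres/rescales the
    GH nodes at each subject's posterior mode (recommended).
    """

    gh_nodes: int = 9
    gl_nodes: int = 15
    adaptive: bool = True

    def __post_init__(self):
        if self.gh_nodes < 1 or self.gh_nodes % 2 == 0:
            raise ValueError("gh_nodes must be a positive odd count")
        if self.gl_nodes < 2:
            raise ValueError("gl_nodes must be >= 2")

    def gh_1d(self) -> tuple[np.ndarray, np.ndarray]:
        """Nodes/weights for integrals against the standard normal."""
        x, w = np.polynomial.hermite.hermgauss(self.gh_nodes)
        return np.sqrt(2.0) * x, w / np.sqrt(np.pi)

    def gh_grid(self) -> tuple[np.ndarray, np.ndarray]:
        """Tensor-product grid ``(U, logW)`` for a 2-D standard normal."""
        x, w = self.gh_1d()
        U = np.array([[a, b] for a in x for b in x])
        logW = np.log(np.array([wa * wb for wa in w for wb in w]))
        return U, logW

    def gl_1d(self) -> tuple[np.ndarray, np.ndarray]:
        return np.polynomial.legendre.leggauss(self.gl_nodes)


@dataclass
class FitResult:
    """Outcome of a joint fit: estimates, uncertainty, diagnostics."""

    params: JointParams
    loglik: float
    n_params: int
    n_iter: int
    converged: bool
    trace: list
    se: Optional[dict] = None
    param_names: Optional[list] = None
    cov: Optional[np.ndarray] = None

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.loglik


# ---------------------------------------------------------------------------
# reference (non-vectorized) subject likelihood — also the tests' integrand
# ---------------------------------------------------------------------------


def _segment_nodes(baseline: BaselineHazard, T: float, gl_x, gl_w):
    """GL node times/weights on [0, T], split at baseline discontinuities."""
    cuts = baseline.quad_breakpoints()
    edges = np.concatenate([[0.0], cuts[cuts < T], [T]])
    s_all, w_all = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        half, mid = 0.5 * (hi - lo), 0.5 * (hi + lo)
        s_all.append(mid + half * gl_x)
        w_all.append(half * gl_w)
    return np.concatenate(s_all), np.concatenate(w_all)


def subject_loglik_given_b(
    joint: JointParams,
    subject,
    obs,
    b_i,
    rule: QuadratureRule = QuadratureRule(),
) -> float | np.ndarray:
    """Conditional log-density of one subject's data given ``b_i``.

    ``sum_j log N(y_ij; m_i(t_ij), sigma2) + d_i log h_i(T_i) - Lambda_i(T_i)``
    with the cumulative hazard by Gauss-Legendre on ``[0, T_i]`` (split at
    baseline discontinuities).  ``b_i`` may be a single vector or an
    ``(m, 2)`` batch, in which case an ``(m,)`` array is returned.
    """
    if len(obs) == 0:
        raise ValueError("subject has no observations")
    b = np.atleast_2d(np.asarray(b_i, dtype=float))
    lp = joint.longitudinal
    t_obs = np.array([o.time for o in obs])
    y = np.array([o.psa_star for o in obs])
    if np.any(t_obs > subject.event_time + 1e-12):
        raise ValueError("observation after the event/censor time")

    m_obs = np.stack(
        [trajectory_value(lp, bk, subject, t_obs, joint.fixed_spec) for bk in b]
    )
    ll_long = -0.5 * np.sum(
        _LOG2PI + np.log(lp.sigma2) + (y[None, :] - m_obs) ** 2 / lp.sigma2, axis=1
    )

    T = subject.event_time
    w_row = survival_design_row(subject)
    eta_w = float(joint.survival.gamma @ w_row)
    gl_x, gl_w = rule.gl_1d()
    s, wq = _segment_nodes(joint.survival.baseline, T, gl_x, gl_w)
    log_h0_s = joint.survival.baseline.log_hazard(s)
    ll_surv = np.empty(len(b))
    for k, bk in enumerate(b):
        m_s = trajectory_value(lp, bk, subject, s, joint.fixed_spec)
        ms_s = trajectory_slope(lp, bk, subject, s, joint.fixed_spec)
        lam = np.exp(log_h0_s + eta_w + joint.alpha * m_s + joint.alpha_s * ms_s)
        cum = float(wq @ lam)
        ev = 0.0
        if subject.event:
            m_T = trajectory_value(lp, bk, subject, T, joint.fixed_spec)
            ms_T = trajectory_slope(lp, bk, subject, T, joint.fixed_spec)
            ev = (
                float(joint.survival.baseline.log_hazard(T))
                + eta_w
                + joint.alpha * m_T
                + joint.alpha_s * ms_T
            )
        ll_surv[k] = ev - cum
    out = ll_long + ll_surv
    return float(out[0]) if np.ndim(b_i) == 1 else out


# ---------------------------------------------------------------------------
# vectorized engine
# ---------------------------------------------------------------------------


class _Engine:
    """Vectorized likelihood/score machinery for one cohort + model spec.

    Caches everything that does not depend on the parameter values:
    stacked designs, per-subject sufficient statistics of the random-effect
    design, covariate rows, and Gauss-Legendre node times on ``[0, T_i]``.
    """

    def __init__(
        self,
        cohort: Cohort,
        fixed_spec: FixedEffectsSpec,
        baseline: BaselineHazard,
        rule: QuadratureRule,
    ):
        self.cohort = cohort
        self.spec = fixed_spec
        self.rule = rule
        subs = cohort.subjects
        self.n = len(subs)
        self.T = np.array([s.event_time for s in subs])
        self.delta = np.array([float(s.event) for s in subs])
        self.W = np.vstack([survival_design_row(s) for s in subs])
        self.R = np.stack([design_decomposition(s, fixed_spec) for s in subs])
        # observations grouped contiguously in subject order
        obs_by: dict[str, list] = {}
        for o in cohort.observations:
            obs_by.setdefault(o.subject_id, []).append(o)
        y, t, idx = [], [], []
        for i, s in enumerate(subs):
            for o in sorted(obs_by[s.subject_id], key=lambda o: o.time):
                y.append(o.psa_star)
                t.append(o.time)
                idx.append(i)
        self.y = np.array(y)
        self.t_obs = np.array(t)
        self.subj_idx = np.array(idx)
        self.N = len(y)
        ones = np.ones_like(self.t_obs)
        self.X = (
            self.R[self.subj_idx, 0]
            + self.t_obs[:, None] * self.R[self.subj_idx, 1]
            + (self.t_obs**2)[:, None] * self.R[self.subj_idx, 2]
        )
        self.XtX = self.X.T @ self.X
        self.n_i = np.bincount(self.subj_idx, minlength=self.n).astype(float)
        st = np.bincount(self.subj_idx, weights=self.t_obs, minlength=self.n)
        st2 = np.bincount(self.subj_idx, weights=self.t_obs**2, minlength=self.n)
        self.S_zz = np.empty((self.n, 2, 2))
        self.S_zz[:, 0, 0] = self.n_i
        self.S_zz[:, 0, 1] = self.S_zz[:, 1, 0] = st
        self.S_zz[:, 1, 1] = st2
        # GL nodes on [0, T_i], segment-split at baseline discontinuities
        gl_x, gl_w = rule.gl_1d()
        cuts = baseline.quad_breakpoints()
        edges = np.concatenate([[0.0], cuts])
        S_list, SW_list = [], []
        for j, lo in enumerate(edges):
            hi = edges[j + 1] if j + 1 < len(edges) else np.inf
            lo_i = np.minimum(self.T, lo)
            hi_i = np.minimum(self.T, hi)
            half = 0.5 * (hi_i - lo_i)
            mid = 0.5 * (hi_i + lo_i)
            S_list.append(mid[:, None] + half[:, None] * gl_x[None, :])
            SW_list.append(half[:, None] * gl_w[None, :])
        self.S = np.concatenate(S_list, axis=1)  # (n, M) node times
        self.SW = np.concatenate(SW_list, axis=1)  # (n, M) node weights
        self.U, self.logW = rule.gh_grid()  # (K, 2), (K,)
        self.K = len(self.U)
        self.q = self.W.shape[1]
        self.p = fixed_spec.n_terms
        self.pb = baseline.n_params
        self.baseline_template = baseline

    # -- parameter packing --------------------------------------------
    def pack(self, joint: JointParams) -> np.ndarray:
        lp = joint.longitudinal
        L = np.linalg.cholesky(lp.D)
        return np.concatenate(
            [
                lp.beta,
                [0.5 * np.log(lp.sigma2)],
                [np.log(L[0, 0]), L[1, 0], np.log(L[1, 1])],
                joint.survival.gamma,
                [joint.alpha, joint.alpha_s],
                joint.survival.baseline.free_params,
            ]
        )

    def unpack(self, theta: np.ndarray) -> JointParams:
        p, q, pb = self.p, self.q, self.pb
        beta = theta[:p]
        sigma2 = float(np.exp(2.0 * theta[p]))
        L = np.array(
            [[np.exp(theta[p + 1]), 0.0], [theta[p + 2], np.exp(theta[p + 3])]]
        )
        gamma = theta[p + 4 : p + 4 + q]
        alpha, alpha_s = theta[p + 4 + q], theta[p + 5 + q]
        bl = self.baseline_template.with_params(theta[p + 6 + q : p + 6 + q + pb])
        return JointParams(
            longitudinal=LongitudinalParams(beta=beta, D=L @ L.T, sigma2=sigma2),
            survival=SurvivalParams(gamma=gamma, baseline=bl),
            alpha=float(alpha),
            alpha_s=float(alpha_s),
            fixed_spec=self.spec,
        )

    def param_names(self) -> list[str]:
        names = [f"beta_{t}" for t in self.spec.terms]
        names += ["log_sigma", "chol_11", "chol_21", "chol_22"]
        names += [f"gamma_{t}" for t in SURVIVAL_TERMS]
        names += ["alpha", "alpha_s"]
        names += [f"baseline_{j}" for j in range(self.pb)]
        return names

    # -- state at a parameter point ------------------------------------
    def _prepare(self, joint: JointParams):
        """Per-theta caches: residual stats, trajectory polys, hazards."""
        lp = joint.longitudinal
        r = self.y - self.X @ lp.beta
        S_yy = np.bincount(self.subj_idx, weights=r**2, minlength=self.n)
        S_zy = np.column_stack(
            [
                np.bincount(self.subj_idx, weights=r, minlength=self.n),
                np.bincount(self.subj_idx, weights=r * self.t_obs, minlength=self.n),
            ]
        )
        A, B, C = (self.R @ lp.beta).T  # (n,) each: m = A + B t + C t^2 + b0 + b1 t
        bl = joint.survival.baseline
        eta_w = self.W @ joint.survival.gamma
        with np.errstate(divide="ignore"):
            log_kappa = np.where(
                self.SW > 0, np.log(np.where(self.SW > 0, self.SW, 1.0)), -np.inf
            )
        log_kappa = log_kappa + bl.log_hazard(np.clip(self.S, 1e-300, None))
        log_kappa = log_kappa + eta_w[:, None]
        log_h0_T = bl.log_hazard(self.T)
        L = np.linalg.cholesky(lp.D)
        return {
            "joint": joint,
            "r": r,
            "S_yy": S_yy,
            "S_zy": S_zy,
            "A": A,
            "B": B,
            "C": C,
            "eta_w": eta_w,
            "log_kappa": log_kappa,
            "log_h0_T": log_h0_T,
            "L": L,
            "sigma2": lp.sigma2,
            "alpha": joint.alpha,
            "alpha_s": joint.alpha_s,
        }

    def _traj_at_nodes(self, st, b):
        """(m, m') at GL node times for b of shape (n, ..., 2)."""
        S = self.S
        extra = b.ndim - 2
        Se = S.reshape((self.n,) + (1,) * extra + (S.shape[1],))
        shape1 = (self.n,) + (1,) * (extra + 1)
        A = st["A"].reshape(shape1)
        B = st["B"].reshape(shape1)
        C = st["C"].reshape(shape1)
        b0 = b[..., 0][..., None]
        b1 = b[..., 1][..., None]
        m = A + (B + b1) * Se + C * Se**2 + b0
        ms = (B + b1) + 2.0 * C * Se
        return m, ms

    def _cond_loglik(self, st, b):
        """Conditional data loglik given b; b shape (n, 2) or (n, K, 2)."""
        sigma2 = st["sigma2"]
        if b.ndim == 2:
            quad = (
                st["S_yy"]
                - 2.0 * np.sum(st["S_zy"] * b, axis=-1)
                + np.einsum("ni,nij,nj->n", b, self.S_zz, b)
            )
        else:
            quad = (
                st["S_yy"][:, None]
                - 2.0 * np.einsum("nj,nkj->nk", st["S_zy"], b)
                + np.einsum("nki,nij,nkj->nk", b, self.S_zz, b)
            )
        ll_long = (
            -0.5 * self.n_i.reshape((self.n,) + (1,) * (b.ndim - 2))
            * (_LOG2PI + np.log(sigma2))
            - 0.5 * quad / sigma2
        )
        m, ms = self._traj_at_nodes(st, b)
        expo = st["log_kappa"].reshape(
            (self.n,) + (1,) * (b.ndim - 2) + (self.S.shape[1],)
        ) + st["alpha"] * m + st["alpha_s"] * ms
        with np.errstate(over="ignore"):
            Lam = np.exp(expo).sum(axis=-1)
        T = self.T.reshape((self.n,) + (1,) * (b.ndim - 2))
        m_T = (
            st["A"].reshape(T.shape)
            + (st["B"].reshape(T.shape) + b[..., 1]) * T
            + st["C"].reshape(T.shape) * T**2
            + b[..., 0]
        )
        ms_T = st["B"].reshape(T.shape) + 2.0 * st["C"].reshape(T.shape) * T + b[..., 1]
        ev = (
            st["log_h0_T"].reshape(T.shape)
            + st["eta_w"].reshape(T.shape)
            + st["alpha"] * m_T
            + st["alpha_s"] * ms_T
        )
        ll_surv = self.delta.reshape(T.shape) * ev - Lam
        return ll_long + ll_surv

    def _cond_grad_hess(self, st, b):
        """Gradient/Hessian of the conditional loglik in b; b (n, 2)."""
        sigma2 = st["sigma2"]
        grad = (st["S_zy"] - np.einsum("nij,nj->ni", self.S_zz, b)) / sigma2
        hess = -self.S_zz / sigma2
        a, a_s = st["alpha"], st["alpha_s"]
        m, ms = self._traj_at_nodes(st, b)
        with np.errstate(over="ignore"):
            lam = np.exp(st["log_kappa"] + a * m + a_s * ms)  # (n, M)
        v1 = a * self.S + a_s  # (n, M)
        g0 = a * lam.sum(axis=1)
        g1 = (lam * v1).sum(axis=1)
        grad = grad - np.column_stack([g0, g1])
        grad[:, 0] += self.delta * a
        grad[:, 1] += self.delta * (a * self.T + a_s)
        h00 = a * a * lam.sum(axis=1)
        h01 = a * (lam * v1).sum(axis=1)
        h11 = (lam * v1 * v1).sum(axis=1)
        hess = hess - np.stack(
            [np.stack([h00, h01], -1), np.stack([h01, h11], -1)], -2
        )
        return grad, hess

    # -- adaptive centring --------------------------------------------
    def _posterior_modes(self, st):
        """Vectorized Newton for the mode/curvature of g(u) per subject."""
        L = st["L"]
        u = np.zeros((self.n, 2))
        for _ in range(40):
            b = u @ L.T
            gb, hb = self._cond_grad_hess(st, b)
            gu = gb @ L - u
            hu = np.einsum("ab,nbc,cd->nad", L.T, hb, L)
            hu[:, 0, 0] -= 1.0
            hu[:, 1, 1] -= 1.0
            det = hu[:, 0, 0] * hu[:, 1, 1] - hu[:, 0, 1] * hu[:, 1, 0]
            step0 = (hu[:, 1, 1] * gu[:, 0] - hu[:, 0, 1] * gu[:, 1]) / det
            step1 = (-hu[:, 1, 0] * gu[:, 0] + hu[:, 0, 0] * gu[:, 1]) / det
            step = -np.column_stack([step0, step1])
            norm = np.linalg.norm(step, axis=1, keepdims=True)
            step = np.where(norm > 5.0, step * (5.0 / np.maximum(norm, 1e-300)), step)
            u = u + step
            if np.max(np.abs(step)) < 1e-11:
                break
        b = u @ L.T
        _, hb = self._cond_grad_hess(st, b)
        hu = np.einsum("ab,nbc,cd->nad", L.T, hb, L)
        hu[:, 0, 0] -= 1.0
        hu[:, 1, 1] -= 1.0
        M = -hu  # positive-definite curvature of -g at the mode
        r11 = np.sqrt(M[:, 0, 0])
        r21 = M[:, 1, 0] / r11
        r22 = np.sqrt(np.maximum(M[:, 1, 1] - r21**2, 1e-300))
        # C = R'^{-1} where M = R R' (lower): C C' = M^{-1}
        C = np.zeros((self.n, 2, 2))
        C[:, 0, 0] = 1.0 / r11
        C[:, 0, 1] = -r21 / (r11 * r22)
        C[:, 1, 1] = 1.0 / r22
        logdetC = -(np.log(r11) + np.log(r22))
        return u, C, logdetC

    def _nodes_and_logjoint(self, st):
        """Quadrature nodes, their b values and log joint contributions.

        Returns ``(b_nodes (n,K,2), log_contrib (n,K))`` such that
        ``loglik_i = logsumexp_k(log_contrib_ik)``.
        """
        if self.rule.adaptive:
            # substitution u = u_hat + C U (U already carries the sqrt(2)
            # scaling of the standard-normal GH rule); with raw-Hermite
            # weights restored, each node contributes
            #   log(2 pi) + log|C| + logW_k + |U_k|^2 / 2 + g(u_k)
            # where g(u) = loglik_cond(L u) + log phi_2(u).
            u_hat, C, logdetC = self._posterior_modes(st)
            u_nodes = u_hat[:, None, :] + np.einsum("nab,kb->nka", C, self.U)
            extra = (
                _LOG2PI
                + logdetC[:, None]
                + self.logW[None, :]
                + 0.5 * np.sum(self.U**2, axis=1)[None, :]
            )
            b_nodes = u_nodes @ st["L"].T
            ll_cond = self._cond_loglik(st, b_nodes)
            log_phi = -_LOG2PI - 0.5 * np.sum(u_nodes**2, axis=2)
            log_contrib = extra + ll_cond + log_phi
        else:
            # plain GH against the standard normal: the N(0, I) density is
            # absorbed into the weights
            u_nodes = np.broadcast_to(self.U[None, :, :], (self.n, self.K, 2))
            b_nodes = u_nodes @ st["L"].T
            ll_cond = self._cond_loglik(st, b_nodes)
            log_contrib = self.logW[None, :] + ll_cond
        return b_nodes, log_contrib

    def estep(self, joint: JointParams):
        """Loglik, posterior node weights and moments of b_i."""
        st = self._prepare(joint)
        b_nodes, log_contrib = self._nodes_and_logjoint(st)
        mx = log_contrib.max(axis=1, keepdims=True)
        wk = np.exp(log_contrib - mx)
        tot = wk.sum(axis=1)
        ll_i = mx[:, 0] + np.log(tot)
        P = wk / tot[:, None]
        b_mean = np.einsum("nk,nkj->nj", P, b_nodes)
        b_outer = np.einsum("nk,nki,nkj->nij", P, b_nodes, b_nodes)
        return {
            "st": st,
            "loglik": float(ll_i.sum()),
            "loglik_i": ll_i,
            "P": P,
            "b_nodes": b_nodes,
            "b_mean": b_mean,
            "b_outer": b_outer,
        }

    def loglik(self, joint: JointParams) -> float:
        st = self._prepare(joint)
        _, log_contrib = self._nodes_and_logjoint(st)
        mx = log_contrib.max(axis=1)
        ll_i = mx + np.log(np.exp(log_contrib - mx[:, None]).sum(axis=1))
        if not np.all(np.isfinite(ll_i)):
            bad = self.cohort.subjects[int(np.argmin(np.isfinite(ll_i)))].subject_id
            raise FloatingPointError(
                f"non-finite marginal likelihood for subject {bad}"
            )
        return float(ll_i.sum())

    # -- analytic score (Fisher identity) ------------------------------
    def _survival_lambda_sums(self, es):
        """Posterior-expected weighted hazard mass at GL nodes.

        Returns ``Lam_q`` (n, M): ``sum_k P_ik lam_ikq`` and the first
        moments of the node-level random effects against ``lam``.
        """
        st, P, b_nodes = es["st"], es["P"], es["b_nodes"]
        a, a_s = st["alpha"], st["alpha_s"]
        m, ms = self._traj_at_nodes(st, b_nodes)  # (n, K, M)
        with np.errstate(over="ignore"):
            lam = np.exp(st["log_kappa"][:, None, :] + a * m + a_s * ms)
        Lam_q = np.einsum("nk,nkq->nq", P, lam)
        lam_m = np.einsum("nk,nkq,nkq->nq", P, lam, m)
        lam_ms = np.einsum("nk,nkq,nkq->nq", P, lam, ms)
        return Lam_q, lam_m, lam_ms

    def score(self, es) -> np.ndarray:
        """Score of the marginal loglik at the point used for the E-step."""
        st = es["st"]
        sigma2, L = st["sigma2"], st["L"]
        a, a_s = st["alpha"], st["alpha_s"]
        b_mean, b_outer, P, b_nodes = (
            es["b_mean"],
            es["b_outer"],
            es["P"],
            es["b_nodes"],
        )
        Lam_q, lam_m, lam_ms = self._survival_lambda_sums(es)
        c0 = Lam_q.sum(axis=1)
        c1 = (Lam_q * self.S).sum(axis=1)
        c2 = (Lam_q * self.S**2).sum(axis=1)

        # beta: Gaussian part + hazard part through m and m'
        zb = b_mean[self.subj_idx, 0] + b_mean[self.subj_idx, 1] * self.t_obs
        g_beta = self.X.T @ (st["r"] - zb) / sigma2
        xT = self.R[:, 0] + self.T[:, None] * self.R[:, 1] + (self.T**2)[:, None] * self.R[:, 2]
        xdT = self.R[:, 1] + 2.0 * self.T[:, None] * self.R[:, 2]
        g_beta = g_beta + ((self.delta * a)[:, None] * xT).sum(axis=0)
        g_beta = g_beta + ((self.delta * a_s)[:, None] * xdT).sum(axis=0)
        g_beta = g_beta - a * (
            c0[:, None] * self.R[:, 0] + c1[:, None] * self.R[:, 1] + c2[:, None] * self.R[:, 2]
        ).sum(axis=0)
        g_beta = g_beta - a_s * (
            c0[:, None] * self.R[:, 1] + 2.0 * c1[:, None] * self.R[:, 2]
        ).sum(axis=0)

        # log sigma (zeta = log sigma): dl/dzeta = -N + E[rss]/sigma2
        e_rss = float(
            np.sum(st["S_yy"])
            - 2.0 * np.sum(st["S_zy"] * b_mean)
            + np.einsum("nij,nij->", self.S_zz, b_outer)
        )
        g_logsigma = -self.N + e_rss / sigma2

        # D via log-Cholesky
        Ssum = es["b_outer"].sum(axis=0)
        Dinv = np.linalg.inv(L @ L.T)
        grad_L = (Dinv @ Ssum @ Dinv - self.n * Dinv) @ L
        g_chol = np.array(
            [grad_L[0, 0] * L[0, 0], grad_L[1, 0], grad_L[1, 1] * L[1, 1]]
        )

        # gamma
        g_gamma = self.W.T @ (self.delta - c0)

        # alpha, alpha_s: E[m] at T_i and against the hazard mass
        m_T = (
            st["A"]
            + (st["B"] + b_mean[:, 1]) * self.T
            + st["C"] * self.T**2
            + b_mean[:, 0]
        )
        ms_T = st["B"] + 2.0 * st["C"] * self.T + b_mean[:, 1]
        g_alpha = float(self.delta @ m_T - lam_m.sum())
        g_alpha_s = float(self.delta @ ms_T - lam_ms.sum())

        # baseline params
        bl = es["st"]["joint"].survival.baseline
        dT = bl.d_log_hazard(self.T)  # (n, pb)
        g_base = dT.T @ self.delta
        dS = bl.d_log_hazard(self.S.ravel()).reshape(self.n, -1, self.pb)
        g_base = g_base - np.einsum("nq,nqp->p", Lam_q, dS)

        return np.concatenate(
            [g_beta, [g_logsigma], g_chol, g_gamma, [g_alpha, g_alpha_s], g_base]
        )

    # -- expected survival objective for the M-step ---------------------
    def mstep_survival(self, es, beta_new: np.ndarray, psi0: np.ndarray, maxiter=25):
        """Improve (gamma, alpha, alpha_s, baseline) on the expected loglik.

        ``psi = [gamma, alpha, alpha_s, baseline params]``; the expectation
        uses the E-step posterior node weights (held fixed), with the
        trajectory evaluated at ``beta_new``.
        """
        P, b_nodes = es["P"], es["b_nodes"]
        A, B, C = (self.R @ beta_new).T
        b0 = b_nodes[..., 0][..., None]
        b1 = b_nodes[..., 1][..., None]
        Se = self.S[:, None, :]
        m = A[:, None, None] + (B[:, None, None] + b1) * Se + C[:, None, None] * Se**2 + b0
        ms = (B[:, None, None] + b1) + 2.0 * C[:, None, None] * Se
        m_T = (
            A[:, None]
            + (B[:, None] + b_nodes[..., 1]) * self.T[:, None]
            + C[:, None] * self.T[:, None] ** 2
            + b_nodes[..., 0]
        )
        ms_T = B[:, None] + 2.0 * C[:, None] * self.T[:, None] + b_nodes[..., 1]
        with np.errstate(divide="ignore"):
            logSW = np.where(self.SW > 0, np.log(np.where(self.SW > 0, self.SW, 1.0)), -np.inf)
        q, pb = self.q, self.pb

        def neg_q_and_grad(psi):
            gamma = psi[:q]
            a, a_s = psi[q], psi[q + 1]
            bl = self.baseline_template.with_params(psi[q + 2 :])
            eta_w = self.W @ gamma
            log_h0_S = bl.log_hazard(np.clip(self.S, 1e-300, None))
            with np.errstate(over="ignore"):
                lam = np.exp(
                    (logSW + log_h0_S + eta_w[:, None])[:, None, :] + a * m + a_s * ms
                )
            if not np.all(np.isfinite(lam)):
                return 1e12, np.zeros_like(psi)
            Lam_q = np.einsum("nk,nkq->nq", P, lam)
            ev_loglin = (
                bl.log_hazard(self.T)[:, None] + eta_w[:, None] + a * m_T + a_s * ms_T
            )
            val = float(
                np.sum(self.delta[:, None] * P * ev_loglin)
                - np.einsum("nk,nkq->", P, lam)
            )
            # gradient
            c0 = Lam_q.sum(axis=1)
            g_gamma = self.W.T @ (self.delta - c0)
            e_m_T = np.einsum("nk,nk->n", P, m_T)
            e_ms_T = np.einsum("nk,nk->n", P, ms_T)
            lam_m = np.einsum("nk,nkq,nkq->", P, lam, m)
            lam_ms = np.einsum("nk,nkq,nkq->", P, lam, ms)
            g_a = float(self.delta @ e_m_T - lam_m)
            g_as = float(self.delta @ e_ms_T - lam_ms)
            dT = bl.d_log_hazard(self.T)
            dS = bl.d_log_hazard(self.S.ravel()).reshape(self.n, -1, pb)
            g_b = dT.T @ self.delta - np.einsum("nq,nqp->p", Lam_q, dS)
            grad = np.concatenate([g_gamma, [g_a, g_as], g_b])
            return -val, -grad

        res = optimize.minimize(
            neg_q_and_grad,
            psi0,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-8},
        )
        return res.x if np.isfinite(res.fun) else psi0


def _default_baseline(cohort: Cohort, family: str) -> BaselineHazard:
    """Family-specific default baseline anchored at the event-time spread."""
    T = np.array([s.event_time for s in cohort.subjects])
    d = np.array([s.event for s in cohort.subjects], dtype=bool)
    ev = np.sort(T[d])
    rate = max(d.sum(), 1) / T.sum()
    if family == "weibull":
        return WeibullHazard(shape=1.0, scale=1.0 / rate)
    if family == "piecewise_constant":
        qs = np.quantile(ev, [0.2, 0.4, 0.6, 0.8]) if len(ev) >= 5 else np.array([np.median(ev)])
        qs = np.unique(qs)
        return PiecewiseConstantHazard(qs, np.full(len(qs) + 1, rate))
    if family == "bspline":
        tmax = float(T.max() * 1.05)
        ks = np.quantile(ev, np.linspace(1, 5, 5) / 6.0) if len(ev) >= 5 else np.quantile(ev, [0.5])
        ks = np.unique(np.clip(ks, 1e-3 * tmax, 0.999 * tmax))
        n_coef = len(ks) + 4
        return BSplineLogHazard(ks, np.full(n_coef, np.log(rate)), tmax=tmax)
    raise ValueError(f"unknown baseline family {family!r}")


def marginal_loglik(
    joint: JointParams, cohort: Cohort, rule: QuadratureRule = QuadratureRule()
) -> float:
    """Observed-data log-likelihood, random effects integrated by GH."""
    eng = _Engine(cohort, joint.fixed_spec, joint.survival.baseline, rule)
    return eng.loglik(joint)


def _two_stage_init(
    cohort: Cohort, fixed_spec: FixedEffectsSpec, baseline: BaselineHazard
) -> JointParams:
    lp, _ = fit_lmm(cohort, fixed_spec)
    sp, _ = fit_ph(cohort, baseline)
    return JointParams(
        longitudinal=lp, survival=sp, alpha=0.0, alpha_s=0.0, fixed_spec=fixed_spec
    )


def em_fit(
    cohort: Cohort,
    fixed_spec: FixedEffectsSpec = FixedEffectsSpec(),
    rule: QuadratureRule = QuadratureRule(),
    baseline: Optional[BaselineHazard] = None,
    init: Optional[JointParams] = None,
    max_iter: int = 300,
    tol_loglik: float = 1e-8,
    tol_param: float = 1e-6,
    refine: bool = True,
    mstep_maxiter: int = 25,
    polish_maxiter: int = 200,
) -> FitResult:
    """Fit the joint model by EM with a quasi-Newton finishing step.

    The E-step computes per-subject posterior moments of ``b_i`` on the
    (adaptive) GH grid; the M-step updates ``D``, ``beta`` and ``sigma2``
    in closed form (``beta`` with a one-step correction for its hazard
    contribution) and improves the hazard block by L-BFGS on the expected
    complete-data loglik.  A step-halving safeguard keeps the observed
    loglik trace nondecreasing.  When ``refine`` is set the fit finishes
    with L-BFGS on the marginal likelihood itself using the analytic score
    (Fisher identity), which also rescues fits that hit ``max_iter``.

    Non-convergence is reported through ``FitResult.converged``, not as an
    exception.
    """
    if sum(s.event for s in cohort.subjects) < 1:
        raise ValueError("em_fit requires at least one event")
    if baseline is None and init is not None:
        baseline = init.survival.baseline
    if baseline is None:
        baseline = _default_baseline(cohort, "weibull")
    if init is None:
        init = _two_stage_init(cohort, fixed_spec, baseline)

    eng = _Engine(cohort, fixed_spec, baseline, rule)
    theta = eng.pack(init)
    q, p = eng.q, eng.p
    trace: list[float] = []
    es = eng.estep(eng.unpack(theta))
    trace.append(es["loglik"])
    converged = False
    n_em = 0

    for it in range(max_iter):
        n_em = it + 1
        # closed-form D
        Ssum = es["b_outer"].sum(axis=0)
        D_new = Ssum / eng.n
        try:
            np.linalg.cholesky(D_new)
        except np.linalg.LinAlgError:
            raise RuntimeError(
                f"random-effect covariance lost positive-definiteness at EM iteration {it}"
            )
        # beta: Gaussian normal equations + one-step hazard correction
        st = es["st"]
        zb = es["b_mean"][eng.subj_idx, 0] + es["b_mean"][eng.subj_idx, 1] * eng.t_obs
        beta_g = np.linalg.solve(eng.XtX, eng.X.T @ (eng.y - zb))
        full_score = eng.score(es)
        g_surv_beta = full_score[:p] - eng.X.T @ (st["r"] - zb) / st["sigma2"]
        beta_new = beta_g + st["sigma2"] * np.linalg.solve(eng.XtX, g_surv_beta)
        # sigma2 closed form at beta_new
        r_new = eng.y - eng.X @ beta_new
        S_yy = np.bincount(eng.subj_idx, weights=r_new**2, minlength=eng.n)
        S_zy = np.column_stack(
            [
                np.bincount(eng.subj_idx, weights=r_new, minlength=eng.n),
                np.bincount(eng.subj_idx, weights=r_new * eng.t_obs, minlength=eng.n),
            ]
        )
        e_rss = float(
            S_yy.sum()
            - 2.0 * np.sum(S_zy * es["b_mean"])
            + np.einsum("nij,nij->", eng.S_zz, es["b_outer"])
        )
        sigma2_new = e_rss / eng.N
        # hazard block
        psi0 = theta[p + 4 : p + 6 + q + eng.pb].copy()
        psi = eng.mstep_survival(es, beta_new, psi0, maxiter=mstep_maxiter)

        L_new = np.linalg.cholesky(D_new)
        theta_new = np.concatenate(
            [
                beta_new,
                [0.5 * np.log(sigma2_new)],
                [np.log(L_new[0, 0]), L_new[1, 0], np.log(L_new[1, 1])],
                psi,
            ]
        )
        # safeguard: halve the step until the observed loglik does not drop
        accepted = None
        step = theta_new - theta
        for _ in range(10):
            cand = theta + step
            es_new = eng.estep(eng.unpack(cand))
            if es_new["loglik"] >= trace[-1] - 1e-10:
                accepted = (cand, es_new)
                break
            step *= 0.5
        if accepted is None:
            converged = True  # cannot improve further at quadrature precision
            break
        theta_prev = theta
        theta, es = accepted
        trace.append(es["loglik"])
        rel = abs(trace[-1] - trace[-2]) / (abs(trace[-2]) + 0.1)
        if rel < tol_loglik or np.max(np.abs(theta - theta_prev)) < tol_param:
            converged = True
            break

    if refine:
        def neg(thv):
            try:
                e = eng.estep(eng.unpack(thv))
            except (np.linalg.LinAlgError, FloatingPointError, ValueError):
                return 1e12, np.zeros_like(thv)
            return -e["loglik"], -eng.score(e)

        res = optimize.minimize(
            neg,
            theta,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": polish_maxiter, "ftol": 1e-12, "gtol": 1e-6},
        )
        if np.isfinite(res.fun) and -res.fun >= trace[-1]:
            theta = res.x
            trace.append(float(-res.fun))
            converged = True

    joint = eng.unpack(theta)
    n_params = len(theta)
    return FitResult(
        params=joint,
        loglik=trace[-1],
        n_params=n_params,
        n_iter=n_em,
        converged=converged,
        trace=trace,
    )


def standard_errors(
    fit: FitResult,
    cohort: Cohort,
    rule: QuadratureRule = QuadratureRule(),
    step: float = 1e-5,
) -> FitResult:
    """Observed-information standard errors for every free parameter.

    Central finite differences of the analytic score give the Hessian of
    the marginal loglik (step ``1e-5`` relative per coordinate); standard
    errors are the square roots of the diagonal of the inverse negative
    (symmetrized) Hessian.  The result is written back onto ``fit``
    (``se``, ``cov``, ``param_names``) and returned.
    """
    joint = fit.params
    eng = _Engine(cohort, joint.fixed_spec, joint.survival.baseline, rule)
    theta = eng.pack(joint)
    names = eng.param_names()
    npar = len(theta)
    H = np.empty((npar, npar))
    for j in range(npar):
        h = step * max(1.0, abs(theta[j]))
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        gp = eng.score(eng.estep(eng.unpack(tp)))
        gm = eng.score(eng.estep(eng.unpack(tm)))
        H[:, j] = (gp - gm) / (2.0 * h)
    H = 0.5 * (H + H.T)
    negH = -H
    try:
        cov = np.linalg.inv(negH)
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(negH)
        flat = names[int(np.argmax(np.abs(V[:, np.argmin(w)])))]
        raise RuntimeError(f"singular Hessian; flattest direction near {flat!r}")
    diag = np.diag(cov)
    if np.any(diag <= 0):
        flat = names[int(np.argmin(diag))]
        raise RuntimeError(f"negative variance estimate for {flat!r}")
    fit.se = dict(zip(names, np.sqrt(diag)))
    fit.cov = cov
    fit.param_names = names
    return fit


def rr_table(fit: FitResult):
    """Relative-risk table for the hazard coefficients.

    One row per hazard-scale parameter (covariate coefficients, ``alpha``,
    ``alpha_s``): coefficient, SE, ``RR = exp(coef)``, Wald 95% CI
    ``exp(coef +- 1.96 SE)``, percent change ``100 (RR - 1)`` and two-sided
    normal p-value.  Rows without an SE are emitted flagged, without CI.
    """
    import pandas as pd

    joint = fit.params
    rows = []
    entries = [
        (f"gamma_{t}", c) for t, c in zip(SURVIVAL_TERMS, joint.survival.gamma)
    ] + [("alpha", joint.alpha), ("alpha_s", joint.alpha_s)]
    z975 = 1.959963984540054
    for name, coef in entries:
        se = fit.se.get(name) if fit.se else None
        rr = float(np.exp(coef))
        has_se = se is not None
        row = {
            "parameter": name,
            "coef": float(coef),
            "se": se if has_se else np.nan,
            "rr": rr,
            "rr_ci_low": float(np.exp(coef - z975 * se)) if has_se else np.nan,
            "rr_ci_high": float(np.exp(coef + z975 * se)) if has_se else np.nan,
            "percent_change": 100.0 * (rr - 1.0),
            "p_value": float(2.0 * stats.norm.sf(abs(coef) / se)) if has_se else np.nan,
            "se_available": has_se,
        }
        rows.append(row)
    return pd.DataFrame(rows)


def compare_baselines(
    cohort: Cohort,
    fixed_spec: FixedEffectsSpec = FixedEffectsSpec(),
    rule: QuadratureRule = QuadratureRule(),
    families: tuple[str, ...] = ("weibull", "piecewise_constant", "bspline"),
    **fit_kwargs,
):
    """Fit the joint model under each baseline family and rank by AIC.

    Returns a DataFrame with (family, loglik, n_params, aic, converged,
    error, best); ties in AIC break toward fewer parameters.  Individual
    family failures are recorded, not raised — unless every family fails.
    """
    import pandas as pd

    rows = []
    fits = {}
    for fam in families:
        try:
            bl = _default_baseline(cohort, fam)
            fit = em_fit(cohort, fixed_spec, rule, baseline=bl, **fit_kwargs)
            fits[fam] = fit
            rows.append(
                {
                    "family": fam,
                    "loglik": fit.loglik,
                    "n_params": fit.n_params,
                    "aic": fit.aic,
                    "converged": fit.converged,
                    "error": "",
                }
            )
        except Exception as exc:  # noqa: BLE001 — recorded per family
            rows.append(
                {
                    "family": fam,
                    "loglik": np.nan,
                    "n_params": np.nan,
                    "aic": np.nan,
                    "converged": False,
                    "error": str(exc),
                }
            )
    df = pd.DataFrame(rows)
    if df["aic"].isna().all():
        raise RuntimeError(
            "all baseline families failed: " + "; ".join(df["error"].tolist())
        )
    order = df.sort_values(["aic", "n_params"], na_position="last").index
    df["best"] = False
    df.loc[order[0], "best"] = True
    df.attrs["fits"] = fits
    return df
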