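"""Joint likelihood, quadrature oracles, EM estimation and reporting."""

import copy

import numpy as np
import pytest
from scipy import integrate, stats

import jointpsa.joint as joint_mod
from jointpsa.joint import (
    FitResult,
    QuadratureRule,
    _Engine,
    compare_baselines,
    em_fit,
    marginal_loglik,
    rr_table,
    standard_errors,
    subject_loglik_given_b,
)
from jointpsa.longitudinal import lmm_marginal_loglik
from jointpsa.simulate import (
    SimConfig,
    default_joint_params,
    generate_cohort,
)
from jointpsa.survival import WeibullHazard, survival_design_row

from conftest import make_cohort


def null_world(scale=0.35):
    """Generative truth with the associations switched off.

    The baseline scale is lowered so events still occur without the
    current-value boost ``alpha * m(0) ~ 1.2``.
    """
    gen = default_joint_params()
    gen = copy.deepcopy(gen)
    gen.alpha = 0.0
    gen.alpha_s = 0.0
    gen.survival.baseline = WeibullHazard(shape=1.2, scale=scale)
    return gen


def null_cohort(n, seed):
    cfg = SimConfig(n_subjects=n, seed=seed)
    cfg.generative = null_world()
    return generate_cohort(cfg)


class TestQuadratureRule:
    def test_gh_grid_integrates_polynomials_exactly(self):
        # exact to degree 2*gh_nodes - 1 against the standard normal
        U, logW = QuadratureRule(gh_nodes=5).gh_grid()
        w = np.exp(logW)
        assert np.sum(w) == pytest.approx(1.0, abs=1e-12)
        assert np.sum(w * U[:, 0] ** 2) == pytest.approx(1.0, abs=1e-10)
        assert np.sum(w * U[:, 0] ** 4) == pytest.approx(3.0, abs=1e-9)
        assert np.sum(w * U[:, 0] ** 2 * U[:, 1] ** 2) == pytest.approx(1.0, abs=1e-10)

    def test_invalid_orders_rejected(self):
        with pytest.raises(ValueError):
            QuadratureRule(gh_nodes=8)
        with pytest.raises(ValueError):
            QuadratureRule(gl_nodes=1)


class TestSubjectLoglik:
    def test_censored_exponential_closed_form(self):
        # no event, y == m exactly, null associations, h0 = 1 -> loglik is
        # the Gaussian normalizing constants minus T
        gen = null_world()
        gen.survival.baseline = WeibullHazard(shape=1.0, scale=1.0)
        gen.survival.gamma = np.zeros(8)
        sub = make_cohort(
            [{"subject_id": "A", "event_time": 2.0}], [("A", 0.0, 5.0), ("A", 1.0, 5.0)]
        )
        subject = sub.subjects[0]
        b = np.array([0.2, -0.1])
        from jointpsa.longitudinal import trajectory_value
        from jointpsa.data import LongitudinalObs

        obs = [
            LongitudinalObs("A", t, 1.0, float(trajectory_value(gen.longitudinal, b, subject, t)))
            for t in (0.0, 1.0)
        ]
        got = subject_loglik_given_b(gen, subject, obs, b)
        expected = -0.5 * 2 * np.log(2 * np.pi * gen.longitudinal.sigma2) - 2.0
        assert got == pytest.approx(expected, abs=1e-10)

    def test_event_with_constant_hazard(self):
        # event at T with subject hazard c: survival part = log c - c T
        c_haz = 0.7
        gen = null_world()
        gen.survival.baseline = WeibullHazard(shape=1.0, scale=1.0 / c_haz)
        gen.survival.gamma = np.zeros(8)
        cohort = make_cohort(
            [{"subject_id": "A", "event_time": 1.5, "event": 1}], [("A", 0.0, 5.0)]
        )
        subject = cohort.subjects[0]
        obs = cohort.observations
        b = np.zeros(2)
        got = subject_loglik_given_b(gen, subject, obs, b)
        long_part = -0.5 * (
            np.log(2 * np.pi * gen.longitudinal.sigma2)
            + (obs[0].psa_star - (gen.longitudinal.beta[0] + b[0])) ** 2
            / gen.longitudinal.sigma2
        )
        assert got - long_part == pytest.approx(np.log(c_haz) - c_haz * 1.5, abs=1e-10)

    def test_cumulative_hazard_term_matches_adaptive_quadrature(self):
        # smooth fixture (integer Weibull shape): GL15 vs scipy adaptive
        gen = default_joint_params()
        gen = copy.deepcopy(gen)
        gen.survival.baseline = WeibullHazard(shape=2.0, scale=1.5)
        cohort = generate_cohort(SimConfig(n_subjects=1, seed=15))
        subject = cohort.subjects[0]
        obs = cohort.observations
        b = np.array([0.5, -0.3])
        from jointpsa.survival import subject_hazard

        T = subject.event_time
        lam, _ = integrate.quad(
            lambda s: subject_hazard(gen, b, subject, s), 0.0, T,
            epsabs=1e-13, epsrel=1e-12, limit=200,
        )
        # recover the GL cumulative hazard from the conditional loglik at
        # b by subtracting the closed-form longitudinal + event terms
        got_with = subject_loglik_given_b(gen, subject, obs, b)
        y = np.array([o.psa_star for o in obs])
        from jointpsa.longitudinal import trajectory_value

        t_obs = np.array([o.time for o in obs])
        m = trajectory_value(gen.longitudinal, b, subject, t_obs)
        long_part = float(
            np.sum(
                -0.5 * np.log(2 * np.pi * gen.longitudinal.sigma2)
                - 0.5 * (y - m) ** 2 / gen.longitudinal.sigma2
            )
        )
        ev_part = 0.0
        if subject.event:
            ev_part = float(np.log(subject_hazard(gen, b, subject, T)))
        gl_cumhaz = -(got_with - long_part - ev_part)
        assert gl_cumhaz == pytest.approx(lam, rel=1e-8)


class TestMarginalLoglik:
    def test_matches_dense_grid_integration(self, two_subject_cohort):
        gen = default_joint_params()
        got = marginal_loglik(gen, two_subject_cohort)
        D = gen.longitudinal.D
        sd = np.sqrt(np.diag(D))
        total = 0.0
        for s in two_subject_cohort.subjects:
            obs = two_subject_cohort.observations_for(s.subject_id)
            g0 = np.linspace(-6 * sd[0], 6 * sd[0], 201)
            g1 = np.linspace(-6 * sd[1], 6 * sd[1], 201)
            B0, B1 = np.meshgrid(g0, g1, indexing="ij")
            pts = np.column_stack([B0.ravel(), B1.ravel()])
            ll = subject_loglik_given_b(gen, s, obs, pts)
            dens = stats.multivariate_normal(np.zeros(2), D).pdf(pts)
            f = (np.exp(ll) * dens).reshape(201, 201)
            total += np.log(np.trapezoid(np.trapezoid(f, g1, axis=1), g0))
        assert got == pytest.approx(total, abs=1e-4)

    def test_doubling_gh_nodes_changes_little(self, medium_sim_cohort):
        gen = default_joint_params()
        ll9 = marginal_loglik(gen, medium_sim_cohort, QuadratureRule(gh_nodes=9))
        ll15 = marginal_loglik(gen, medium_sim_cohort, QuadratureRule(gh_nodes=15))
        assert abs(ll9 - ll15) <= 1e-4

    def test_factorizes_when_associations_vanish(self):
        cohort = generate_cohort(SimConfig(n_subjects=5, seed=11))
        null = null_world(scale=2.0)
        ll_joint = marginal_loglik(null, cohort)
        ll_lmm = lmm_marginal_loglik(null.longitudinal, cohort)
        T = np.array([s.event_time for s in cohort.subjects])
        d = np.array([s.event for s in cohort.subjects], dtype=float)
        W = np.vstack([survival_design_row(s) for s in cohort.subjects])
        bl = null.survival.baseline
        eta = W @ null.survival.gamma
        ll_ph = float(d @ (bl.log_hazard(T) + eta) - np.exp(eta) @ bl.cumulative_hazard(T))
        assert ll_joint == pytest.approx(ll_lmm + ll_ph, abs=1e-4)

    def test_invariant_to_subject_relabeling_and_order(self, small_sim_cohort):
        from jointpsa.data import Cohort
        from dataclasses import replace

        gen = default_joint_params()
        base = marginal_loglik(gen, small_sim_cohort)
        rng = np.random.default_rng(0)
        order = rng.permutation(small_sim_cohort.n_subjects)
        relabel = {
            s.subject_id: f"Z{idx:03d}"
            for idx, s in zip(order, small_sim_cohort.subjects)
        }
        subjects = [
            replace(s, subject_id=relabel[s.subject_id])
            for s in reversed(small_sim_cohort.subjects)
        ]
        obs = [
            replace(o, subject_id=relabel[o.subject_id])
            for o in reversed(small_sim_cohort.observations)
        ]
        shuffled = Cohort(
            subjects=subjects, observations=obs, transform=small_sim_cohort.transform
        )
        assert marginal_loglik(gen, shuffled) == pytest.approx(base, abs=1e-10)

    def test_analytic_score_matches_finite_differences(self, small_sim_cohort):
        gen = default_joint_params()
        eng = _Engine(
            small_sim_cohort, gen.fixed_spec, gen.survival.baseline, QuadratureRule()
        )
        theta = eng.pack(gen)
        got = eng.score(eng.estep(eng.unpack(theta)))
        for j in range(0, len(theta), 3):  # subsample coordinates for speed
            h = 1e-6 * max(1.0, abs(theta[j]))
            tp, tm = theta.copy(), theta.copy()
            tp[j] += h
            tm[j] -= h
            fd = (eng.loglik(eng.unpack(tp)) - eng.loglik(eng.unpack(tm))) / (2 * h)
            assert got[j] == pytest.approx(fd, rel=2e-5, abs=1e-7)


def assert_monotone_trace(fit, tol=1e-6):
    trace = np.asarray(fit.trace)
    assert np.all(np.diff(trace) >= -tol), "EM trace decreased beyond tolerance"


@pytest.fixture(scope="module")
def null_fit():
    cohort = null_cohort(120, seed=31)
    fit = em_fit(cohort)
    fit = standard_errors(fit, cohort)
    return cohort, fit


class TestEMFit:
    def test_null_association_estimates_near_zero(self, null_fit):
        _, fit = null_fit
        assert fit.converged
        assert abs(fit.params.alpha) <= 2.0 * fit.se["alpha"]
        assert abs(fit.params.alpha_s) <= 2.0 * fit.se["alpha_s"]

    def test_loglik_trace_monotone(self, null_fit):
        _, fit = null_fit
        assert_monotone_trace(fit)

    def test_estimate_beats_random_perturbations(self, null_fit):
        cohort, fit = null_fit
        eng = _Engine(
            cohort, fit.params.fixed_spec, fit.params.survival.baseline, QuadratureRule()
        )
        theta = eng.pack(fit.params)
        base = eng.loglik(eng.unpack(theta))
        rng = np.random.default_rng(99)
        for _ in range(50):
            pert = theta + rng.uniform(-0.2, 0.2, size=len(theta))
            try:
                ll = eng.loglik(eng.unpack(pert))
            except FloatingPointError:
                continue
            assert ll <= base + 1e-6

    def test_aic_consistent_with_loglik_and_param_count(self, null_fit):
        _, fit = null_fit
        assert fit.aic == pytest.approx(2 * fit.n_params - 2 * fit.loglik, abs=1e-10)

    def test_no_event_cohort_rejected(self):
        cohort = make_cohort(
            [{"subject_id": "A"}, {"subject_id": "B"}],
            [("A", 0.0, 5.0), ("B", 0.0, 4.0)],
        )
        with pytest.raises(ValueError):
            em_fit(cohort)


class TestStandardErrors:
    def test_se_shrinks_like_root_n(self):
        # quadrupling the cohort should halve SE(alpha), up to the
        # realization noise of the event count
        ses = {}
        for n, seed in ((200, 61), (800, 62)):
            cohort = generate_cohort(SimConfig(n_subjects=n, seed=seed))
            fit = em_fit(cohort)
            fit = standard_errors(fit, cohort)
            ses[n] = fit.se["alpha"]
        ratio = ses[200] / ses[800]
        assert 1.7 <= ratio <= 2.3

    def test_all_ses_positive(self, medium_sim_cohort):
        fit = em_fit(medium_sim_cohort)
        fit = standard_errors(fit, medium_sim_cohort)
        assert all(v > 0 for v in fit.se.values())


class TestReporting:
    @staticmethod
    def _fake_fit(alpha=0.33, alpha_s=0.19, se=None):
        gen = default_joint_params()
        gen = copy.deepcopy(gen)
        gen.alpha = alpha
        gen.alpha_s = alpha_s
        fit = FitResult(
            params=gen, loglik=-1.0, n_params=24, n_iter=1, converged=True, trace=[-1.0]
        )
        fit.se = se
        return fit

    def test_reported_association_rrs(self):
        table = rr_table(self._fake_fit(se={"alpha": 0.12, "alpha_s": 0.08}))
        row_a = table.set_index("parameter").loc["alpha"]
        row_s = table.set_index("parameter").loc["alpha_s"]
        assert round(row_a["rr"], 2) == 1.39
        assert round(row_s["rr"], 2) == 1.21
        assert row_a["rr_ci_low"] < row_a["rr"] < row_a["rr_ci_high"]
        assert row_a["p_value"] == pytest.approx(
            2 * stats.norm.sf(0.33 / 0.12), rel=1e-10
        )

    def test_zero_coefficient_gives_unit_rr(self):
        table = rr_table(self._fake_fit(alpha=0.0))
        row = table.set_index("parameter").loc["alpha"]
        assert row["rr"] == 1.0
        assert row["percent_change"] == 0.0

    def test_rows_without_se_are_flagged(self):
        table = rr_table(self._fake_fit(se={"alpha": 0.12}))
        row = table.set_index("parameter").loc["alpha_s"]
        assert not row["se_available"]
        assert np.isnan(row["rr_ci_low"])


class TestCompareBaselines:
    def test_ranking_and_tie_break(self, monkeypatch, small_sim_cohort):
        def fake_em_fit(cohort, fixed_spec, rule, baseline=None, **kw):
            stats_by_family = {
                "weibull": (-100.0, 24),
                "piecewise_constant": (-100.0, 27),  # tie in loglik -> more params
                "bspline": (-120.0, 31),
            }
            ll, p = stats_by_family[baseline.family]
            gen = default_joint_params()
            return FitResult(
                params=gen, loglik=ll, n_params=p, n_iter=1, converged=True, trace=[ll]
            )

        monkeypatch.setattr(joint_mod, "em_fit", fake_em_fit)
        df = compare_baselines(small_sim_cohort)
        assert df.loc[df["best"], "family"].iloc[0] == "weibull"
        aic = df.set_index("family")["aic"]
        assert aic["weibull"] == pytest.approx(2 * 24 + 200.0)
        # identical loglik: fewer parameters ranked first
        assert aic["weibull"] < aic["piecewise_constant"]

    def test_family_failure_recorded_not_raised(self, monkeypatch, small_sim_cohort):
        def failing_em_fit(cohort, fixed_spec, rule, baseline=None, **kw):
            if baseline.family == "bspline":
                raise RuntimeError("boom")
            gen = default_joint_params()
            return FitResult(
                params=gen, loglik=-50.0, n_params=24, n_iter=1, converged=True,
                trace=[-50.0],
            )

        monkeypatch.setattr(joint_mod, "em_fit", failing_em_fit)
        df = compare_baselines(small_sim_cohort)
        bs = df.set_index("family").loc["bspline"]
        assert "boom" in bs["error"]
        assert not bs["converged"]
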