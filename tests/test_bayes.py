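"""Hierarchical model: densities, sampler correctness, and recovery."""

import warnings

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import truncnorm

from cryptdrift import (
    CloneFractionModel,
    CohortTable,
    MCMCConfig,
    SimCohortConfig,
    fit_hierarchical,
    log_posterior,
    recovery_experiment,
    trunc_student_t_logpdf,
)

LIGHT = MCMCConfig(n_chains=2, n_warmup=600, n_samples=800, seed=0)
TINY = MCMCConfig(n_chains=2, n_warmup=150, n_samples=150, seed=0)


def _quiet_fit(model, mcmc, **kw):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return model.fit(mcmc, **kw)


@pytest.fixture()
def driftless_cohort(driftless):
    return CohortTable.from_records(
        [
            (f"m{i}", 2000, k, "any_surviving", 1.0)
            for i, k in zip(range(1, 7), [70, 85, 90, 80, 75, 88])
        ]
    )


class TestTruncStudentT:
    def test_symmetry_about_location(self):
        a = trunc_student_t_logpdf(0.3, 5.0, 0.5, 0.1, 0.0, 1.0)
        b = trunc_student_t_logpdf(0.7, 5.0, 0.5, 0.1, 0.0, 1.0)
        assert a == pytest.approx(b, abs=1e-12)

    def test_outside_support(self):
        assert trunc_student_t_logpdf(1.2, 5.0, 0.5, 0.1, 0.0, 1.0) == -np.inf
        assert trunc_student_t_logpdf(-0.1, 5.0, 0.5, 0.1, 0.0, 1.0) == -np.inf

    def test_high_dof_matches_truncated_normal(self):
        loc, scale = 0.5, 0.1
        a, b = (0.0 - loc) / scale, (1.0 - loc) / scale
        for x in (0.2, 0.5, 0.8):
            ours = trunc_student_t_logpdf(x, 1e6, loc, scale, 0.0, 1.0)
            ref = truncnorm.logpdf(x, a, b, loc=loc, scale=scale)
            assert ours == pytest.approx(ref, abs=1e-4)

    def test_density_integrates_to_one(self):
        for dof, loc, scale in [(3.0, 0.3, 0.2), (20.0, 0.9, 0.5)]:
            val, _ = quad(
                lambda x: np.exp(
                    trunc_student_t_logpdf(x, dof, loc, scale, 0.0, 1.0)
                ),
                0.0,
                1.0,
                limit=200,
            )
            assert val == pytest.approx(1.0, abs=1e-8)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            trunc_student_t_logpdf(0.5, -1.0, 0.5, 0.1, 0.0, 1.0)
        with pytest.raises(ValueError):
            trunc_student_t_logpdf(0.5, 5.0, 0.5, 0.0, 0.0, 1.0)
        with pytest.raises(ValueError):
            trunc_student_t_logpdf(0.5, 5.0, 0.5, 0.1, 1.0, 0.0)


class TestLogPosterior:
    def test_row_permutation_invariance(self, colon):
        rows = [
            ("a", 900, 30, "whole_only", 30.0),
            ("b", 800, 45, "whole_only", 30.0),
            ("c", 1000, 20, "partial_only", 25.0),
        ]
        state = {
            "v": 0.4,
            "eta": 15.0,
            "sigma": 0.01,
            "R": np.array([0.035, 0.05, 0.03]),
        }
        lp1 = log_posterior(state, CohortTable.from_records(rows), colon)
        perm = [rows[2], rows[0], rows[1]]
        state2 = dict(state, R=state["R"][[2, 0, 1]])
        lp2 = log_posterior(state2, CohortTable.from_records(perm), colon)
        assert lp1 == pytest.approx(lp2, rel=1e-12)

    def test_out_of_support_states(self, colon, homogeneous_colon_cohort):
        base = {
            "v": 0.4, "eta": 15.0, "sigma": 0.01, "R": np.full(6, 0.04),
        }
        table = homogeneous_colon_cohort
        assert np.isfinite(log_posterior(base, table, colon))
        bad_R = dict(base, R=np.array([0.04] * 5 + [1.2]))
        assert log_posterior(bad_R, table, colon) == -np.inf
        assert log_posterior(dict(base, v=1.5), table, colon) == -np.inf
        assert log_posterior(dict(base, sigma=-1.0), table, colon) == -np.inf

    def test_counts_exceeding_crypts_rejected_as_data_error(self):
        with pytest.raises(ValueError, match="exceeds"):
            CohortTable.from_records([("m1", 100, 101, "whole_only", 30.0)])

    def test_chase_day_before_tau_rejected(self, colon):
        table = CohortTable.from_records([("m1", 100, 3, "whole_only", 0.5)])
        with pytest.raises(ValueError, match="tau"):
            CloneFractionModel(table, colon)

    def test_conjugate_limit_differences(self, driftless, driftless_cohort):
        """With survival = 1 and residuals pinned (R_i = v, sigma tiny)
        the posterior differs from the Beta-binomial conjugate form by a
        state-independent constant."""
        table = driftless_cohort
        kappa, C = table.clones, table.crypts

        def conjugate(v):
            return float(
                np.sum(kappa * np.log(v) + (C - kappa) * np.log1p(-v))
                + (0.5 - 1) * np.log(v)
                + (0.5 - 1) * np.log1p(-v)
            )

        def ours(v):
            state = {
                "v": v, "eta": 20.0, "sigma": 1e-3, "R": np.full(6, v),
            }
            return log_posterior(state, table, driftless)

        vs = [0.02, 0.04, 0.06, 0.2]
        diffs = [ours(v) - conjugate(v) for v in vs]
        assert np.ptp(diffs) < 1e-6


class TestFit:
    def test_recovers_simulated_truth(self, colon):
        cfg = SimCohortConfig(
            params=colon, v_true=0.30, n_mice=6, crypts_per_mouse=2000,
            sigma_true=0.005, seed=11,
        )
        from cryptdrift import simulate_cohort

        model = CloneFractionModel(simulate_cohort(cfg), colon)
        res = _quiet_fit(model, LIGHT)
        assert res.median("v") == pytest.approx(0.30, abs=0.05)

    def test_no_signal_cohort_infers_near_zero(self, colon):
        table = CohortTable.from_records(
            [(f"m{i}", 1000, 0, "whole_only", 30.0) for i in range(1, 7)]
        )
        res = _quiet_fit(CloneFractionModel(table, colon), LIGHT)
        assert res.median("v") < 0.02
        lo, _ = res.credible_interval("v")
        assert lo < 1e-3

    def test_paper_like_colon_cohort(self, colon, homogeneous_colon_cohort):
        res = _quiet_fit(
            CloneFractionModel(homogeneous_colon_cohort, colon), LIGHT
        )
        assert 0.37 <= res.median("v") <= 0.50

    def test_identical_seed_identical_draws(self, colon,
                                            homogeneous_colon_cohort):
        model = CloneFractionModel(homogeneous_colon_cohort, colon)
        a = _quiet_fit(model, TINY)
        b = _quiet_fit(model, TINY)
        for key in ("v", "eta", "sigma", "R"):
            np.testing.assert_array_equal(a.draws[key], b.draws[key])

    def test_draws_respect_support(self, colon, homogeneous_colon_cohort):
        res = _quiet_fit(
            CloneFractionModel(homogeneous_colon_cohort, colon), TINY
        )
        assert np.all((res.draws["v"] > 0) & (res.draws["v"] < 1))
        assert np.all((res.draws["R"] >= 0) & (res.draws["R"] <= 1))
        assert np.all(res.draws["eta"] >= 1.0)
        assert np.all(res.draws["sigma"] > 0)

    def test_convergence_flag_matches_diagnostics(
        self, colon, homogeneous_colon_cohort
    ):
        res = _quiet_fit(
            CloneFractionModel(homogeneous_colon_cohort, colon), TINY
        )
        sf = res.summary_frame.dropna(subset=["rhat"])
        expected = bool(
            (sf["rhat"] < res.config.rhat_threshold).all()
            and (sf["ess"] > res.config.ess_threshold).all()
        )
        assert res.converged == expected

    def test_functional_wrapper_equivalent(self, colon,
                                           homogeneous_colon_cohort):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            a = fit_hierarchical(homogeneous_colon_cohort, colon, mcmc=TINY)
        b = _quiet_fit(
            CloneFractionModel(homogeneous_colon_cohort, colon), TINY
        )
        np.testing.assert_array_equal(a.draws["v"], b.draws["v"])

    def test_unknown_fixed_parameter_rejected(self, colon,
                                              homogeneous_colon_cohort):
        model = CloneFractionModel(homogeneous_colon_cohort, colon)
        with pytest.raises(ValueError, match="unknown"):
            model.fit(TINY, fix={"nu": 3.0})

    def test_empty_table_rejected(self, colon):
        import pandas as pd

        with pytest.raises(ValueError):
            CohortTable(
                pd.DataFrame(
                    columns=[
                        "mouse_id", "crypts_scored", "clones_observed",
                        "kind", "chase_day",
                    ]
                )
            )

    def test_posterior_histogram_plot(self, colon, homogeneous_colon_cohort):
        import matplotlib

        matplotlib.use("Agg")
        res = _quiet_fit(
            CloneFractionModel(homogeneous_colon_cohort, colon), TINY
        )
        ax = res.plot_posterior("v")
        assert ax.get_xlabel() == "v"
        assert len(ax.patches) > 0

    def test_summary_text_reports_key_quantities(
        self, colon, homogeneous_colon_cohort
    ):
        res = _quiet_fit(
            CloneFractionModel(homogeneous_colon_cohort, colon), TINY
        )
        text = res.summary()
        for token in ("v", "eta", "sigma", "rhat", "ess", "95% CI"):
            assert token in text


class TestDistributionalCorrectness:
    def test_conjugate_limit_moments(self, driftless, driftless_cohort):
        """Survival pinned at 1 and sigma fixed far below the counting
        noise: the marginal posterior of v must match the analytic
        Beta(1/2 + sum kappa, 1/2 + sum(C - kappa))."""
        model = CloneFractionModel(driftless_cohort, driftless)
        res = _quiet_fit(
            model,
            MCMCConfig(n_chains=2, n_warmup=800, n_samples=2000, seed=7),
            fix={"sigma": 5e-4, "eta": 20.0},
        )
        kappa = driftless_cohort.clones.sum()
        C = driftless_cohort.crypts.sum()
        a, b = 0.5 + kappa, 0.5 + C - kappa
        exact_mean = a / (a + b)
        exact_var = a * b / ((a + b) ** 2 * (a + b + 1))
        flat = res.draws["v"].reshape(-1)
        ess = float(res.summary_frame.loc["v", "ess"])
        se_mean = np.sqrt(exact_var / ess)
        assert abs(flat.mean() - exact_mean) < 3 * se_mean
        se_var = exact_var * np.sqrt(2.0 / ess)
        assert abs(flat.var() - exact_var) < 3 * se_var + 0.1 * exact_var

    def test_prior_recovery_without_likelihood(self, driftless,
                                               driftless_cohort):
        """With the likelihood disabled the sampled v must reproduce its
        Beta(1/2, 1/2) prior moments (the mouse-level hierarchy
        integrates out of the v marginal)."""
        model = CloneFractionModel(driftless_cohort, driftless)
        res = _quiet_fit(
            model,
            MCMCConfig(n_chains=2, n_warmup=600, n_samples=2500, seed=3),
            prior_only=True,
        )
        flat = res.draws["v"].reshape(-1)
        assert flat.mean() == pytest.approx(0.5, abs=0.04)
        assert flat.var() == pytest.approx(0.125, abs=0.012)


class TestRecoveryExperiment:
    def test_single_replicate_report(self, colon):
        cfg = SimCohortConfig(
            params=colon, v_true=0.3, n_mice=4, crypts_per_mouse=400, seed=5
        )
        rep = recovery_experiment(cfg, mcmc=TINY, n_replicates=1)
        assert len(rep.table) == 1
        assert rep.n_failed == 0
        assert 0.0 <= rep.coverage <= 1.0

    def test_null_truth_recovered(self, colon):
        cfg = SimCohortConfig(
            params=colon, v_true=0.0, sigma_true=0.0, n_mice=4,
            crypts_per_mouse=500, seed=6,
        )
        rep = recovery_experiment(cfg, mcmc=TINY, n_replicates=3)
        assert (rep.table["v_median"] < 0.02).all()

    def test_replicate_errors_do_not_abort_batch(self, colon, monkeypatch):
        import cryptdrift.bayes as bayes_mod

        calls = {"n": 0}
        orig = bayes_mod.simulate_cohort

        def flaky(cfg):
            calls["n"] += 1
            if calls["n"] == 1:
                raise RuntimeError("synthetic failure")
            return orig(cfg)

        monkeypatch.setattr(bayes_mod, "simulate_cohort", flaky)
        cfg = SimCohortConfig(
            params=colon, v_true=0.3, n_mice=4, crypts_per_mouse=300, seed=1
        )
        rep = recovery_experiment(cfg, mcmc=TINY, n_replicates=3)
        assert rep.n_failed == 1
        assert rep.table["v_median"].notna().sum() == 2
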