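import math

import numpy as np
import pytest
from scipy import stats
from scipy.integrate import quad

from vigilpred import cli, ddm
from vigilpred.ddm import (
    DDMParams, FitOptions, censored_loglik, decision_cdf, decision_density,
    fit_day, rt_density, wald_density,
)


class TestWaldDensity:
    def test_unit_point_value(self):
        # exponent vanishes when a = u*t
        assert wald_density(1.0, 1.0, 1.0) == pytest.approx(1 / math.sqrt(2 * math.pi))

    def test_integrates_to_one_for_positive_drift(self):
        total, _ = quad(lambda t: wald_density(t, 2.0, 1.0), 0, np.inf)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_mean_is_a_over_v(self):
        mean, _ = quad(lambda t: t * wald_density(t, 2.0, 1.0), 0, np.inf)
        assert mean == pytest.approx(0.5, abs=1e-4)

    def test_zero_below_onset_and_boundary_validation(self):
        assert wald_density(-0.5, 1.0, 1.0) == 0.0
        assert wald_density(0.0, 1.0, 1.0) == 0.0
        with pytest.raises(ValueError):
            wald_density(1.0, 1.0, -1.0)


class TestDecisionDensity:
    def test_reduces_to_wald_at_zero_eta(self):
        t = np.linspace(0.01, 5, 200)
        np.testing.assert_allclose(decision_density(t, 1.7, 0.0, 0.9),
                                   wald_density(t, 1.7, 0.9), atol=1e-12)

    def test_unit_point_value(self):
        assert decision_density(1.0, 1.0, 1.0, 1.0) == pytest.approx(
            (4 * math.pi) ** -0.5)

    def test_defective_mass_brackets(self):
        total, _ = quad(lambda t: decision_density(t, 2.0, 1.0, 1.0), 0, np.inf,
                        limit=200)
        assert 0.95 <= total <= 1.0

    def test_cdf_matches_quadrature(self):
        for (v, eta, a, t) in [(1.5, 1.0, 1.0, 2.0), (4.0, 1.5, 1.0, 0.5),
                               (0.5, 2.0, 0.8, 1.0)]:
            num, _ = quad(lambda s: decision_density(s, v, eta, a), 0, t)
            assert decision_cdf(t, v, eta, a) == pytest.approx(num, abs=1e-8)

    def test_matches_euler_monte_carlo_histogram(self):
        """Analytic marginal density vs an independent Euler path oracle
        (bridge-corrected, 2e5 paths) on 20-bin histograms."""
        from oracles import euler_first_passage
        v, eta, a = 3.0, 1.0, 1.0
        n_paths = 200_000
        t = euler_first_passage(v, eta, a, n_paths, 1e-3, 4.0, seed=42)
        edges = np.linspace(0.02, 2.0, 20)
        cdf = decision_cdf(edges, v, eta, a)
        probs = np.append(np.diff(cdf), 1.0 - cdf[-1] + cdf[0])
        counts, _ = np.histogram(t[np.isfinite(t)], bins=edges)
        obs = np.append(counts, n_paths - counts.sum())
        exp = n_paths * probs
        chi2 = np.sum((obs - exp) ** 2 / exp)
        assert stats.chi2.sf(chi2, len(obs) - 1) > 0.01


class TestRtDensity:
    def test_degenerate_convolution_is_shift(self):
        p = DDMParams(v=3.0, eta=1.0, a=1.0, ter_s=0.3, st_s=0.0, p_c=0.0)
        t = np.array([0.4, 0.8, 2.0])
        np.testing.assert_allclose(rt_density(t, p),
                                   decision_density(t - 0.3, 3.0, 1.0, 1.0))

    def test_pure_contaminant_is_uniform(self):
        p = DDMParams(v=3.0, eta=1.0, a=1.0, ter_s=0.3, st_s=0.0, p_c=1.0)
        with pytest.raises(ValueError):
            p.validate()  # p_c above the cap is rejected outright

    def test_contaminant_mixture_level(self):
        p = DDMParams(v=3.0, eta=0.0, a=1.0, ter_s=0.3, st_s=0.0, p_c=0.1)
        # below the non-decision onset only the contaminant contributes
        assert rt_density(np.array([0.2]), p)[0] == pytest.approx(0.01)

    def test_matches_brute_force_convolution(self):
        """Gauss-Legendre convolution vs 1e5-point trapezoid oracle, on the
        region where the integrand is smooth across the non-decision window
        (above the onset kink at ter + st/2)."""
        from oracles import brute_force_uniform_convolution
        p = DDMParams(v=3.0, eta=0.0, a=1.0, ter_s=0.30, st_s=0.20, p_c=0.0)
        t = np.linspace(0.55, 3.0, 25)
        ref = brute_force_uniform_convolution(
            t, lambda s: decision_density(s, 3.0, 0.0, 1.0), 0.30, 0.20)
        np.testing.assert_allclose(rt_density(t, p), ref, atol=1e-6)

    def test_total_probability_with_censoring(self):
        p = DDMParams(v=1.0, eta=1.5, a=1.0, ter_s=0.25, st_s=0.1, p_c=0.05)
        mass, _ = quad(lambda t: rt_density(np.array([t]), p)[0], 0, 10.0,
                       limit=400)
        surv = 1.0 - ddm.response_prob(p)
        assert mass + surv == pytest.approx(1.0, abs=1e-4)

    def test_nonnegative_everywhere(self):
        p = DDMParams(v=2.0, eta=1.0, a=1.0, ter_s=0.2, st_s=0.15, p_c=0.02)
        t = np.linspace(-1, 10, 500)
        assert (rt_density(t, p) >= 0).all()


class TestCensoredLoglik:
    def test_single_trial_is_log_density(self):
        p = DDMParams(v=3.0, eta=1.0, a=1.0, ter_s=0.25, st_s=0.1, p_c=0.01)
        d = rt_density(np.array([0.6]), p)[0]
        assert censored_loglik([(0.6, False)], p) == pytest.approx(math.log(d))

    def test_timeout_adds_negative_survival_term(self):
        p = DDMParams(v=1.0, eta=1.5, a=1.0, ter_s=0.25, st_s=0.1, p_c=0.01)
        base = censored_loglik([(0.6, False)], p)
        with_to = censored_loglik([(0.6, False), (10.0, True)], p)
        assert with_to < base

    def test_impossible_data_hits_sentinel(self):
        p = DDMParams(v=3.0, eta=0.0, a=1.0, ter_s=0.4, st_s=0.0, p_c=0.0)
        # rt below the non-decision onset with no contaminant: impossible
        assert censored_loglik([(0.2, False)], p) <= -1e11

    def test_numba_kernel_matches_numpy_route(self):
        """The compiled likelihood used by the fitter equals the numpy
        reference implementation."""
        from vigilpred._fastlik import censored_loglik_kernel
        rng = np.random.default_rng(4)
        p = DDMParams(v=3.5, eta=1.2, a=1.0, ter_s=0.22, st_s=0.11, p_c=0.03)
        rts = [(float(r), False) for r in rng.uniform(0.3, 3.0, size=50)]
        rts += [(10.0, True)] * 3
        obs = np.array([r for r, to in rts if not to])
        gl_x, gl_w = np.polynomial.legendre.leggauss(11)
        fast = censored_loglik_kernel(obs, 3, p.v, p.eta, p.a, p.ter_s,
                                      p.st_s, p.p_c, 10.0, gl_x, gl_w)
        assert fast == pytest.approx(censored_loglik(rts, p), abs=1e-8)

    def test_likelihood_prefers_truth_over_perturbation_at_large_n(self):
        truth = cli.RECOVERY_TRUTH
        worse = DDMParams(v=truth.v + 1, eta=truth.eta, a=truth.a,
                          ter_s=truth.ter_s, st_s=truth.st_s, p_c=truth.p_c)
        for seed in range(3):
            rng = np.random.default_rng(seed)
            rts = cli.simulate_day_rts(truth, 10_000, rng)
            assert censored_loglik(rts, truth) > censored_loglik(rts, worse)


class TestFitDay:
    def test_too_few_trials_error_names_minimum(self):
        with pytest.raises(ValueError, match="100"):
            fit_day([(0.5, False)] * 10, FitOptions())

    def test_duplicated_data_same_estimate(self):
        rng = np.random.default_rng(8)
        rts = cli.simulate_day_rts(cli.RECOVERY_TRUTH, 150, rng)
        opts = FitOptions(restarts=2, seed=0)
        f1 = fit_day(rts, opts)
        f2 = fit_day(rts + rts, opts)
        assert f2.v == pytest.approx(f1.v, rel=1e-6)
        assert f2.loglik == pytest.approx(2 * f1.loglik, rel=1e-6)

    def test_objective_invariant_to_trial_order(self):
        rng = np.random.default_rng(9)
        rts = cli.simulate_day_rts(cli.RECOVERY_TRUTH, 150, rng)
        f1 = fit_day(rts, FitOptions(restarts=2, seed=0))
        f2 = fit_day(rts[::-1], FitOptions(restarts=2, seed=0))
        assert f1.v == pytest.approx(f2.v, rel=1e-9)

    def test_recovery_smoke(self):
        """Short recovery run: drift is recovered within a loose band."""
        errs = []
        for rep in range(5):
            rng = np.random.default_rng(300 + rep)
            rts = cli.simulate_day_rts(cli.RECOVERY_TRUTH, 270, rng)
            f = fit_day(rts, FitOptions(restarts=4, seed=rep))
            assert f.converged
            errs.append(abs(f.v - cli.RECOVERY_TRUTH.v) / cli.RECOVERY_TRUTH.v)
        assert np.median(errs) < 0.30

    def test_eta_zero_truth_recovers_small_eta(self):
        truth = DDMParams(v=4.0, eta=0.0, a=1.0, ter_s=0.28, st_s=0.12,
                          p_c=0.01)
        etas = []
        for rep in range(8):
            rng = np.random.default_rng(700 + rep)
            rts = cli.simulate_day_rts(truth, 270, rng)
            etas.append(fit_day(rts, FitOptions(restarts=4, seed=rep)).eta)
        assert np.median(etas) <= 0.5

    def test_quantile_chisq_method_smoke(self):
        rng = np.random.default_rng(21)
        rts = cli.simulate_day_rts(cli.RECOVERY_TRUTH, 400, rng)
        f = fit_day(rts, FitOptions(method="quantile_chisq", restarts=2,
                                    seed=0))
        assert 1.0 < f.v < 10.0
        assert f.ter_s - f.st_s / 2 >= 0.05 - 1e-9

    def test_free_boundary_option(self):
        rng = np.random.default_rng(22)
        rts = cli.simulate_day_rts(cli.RECOVERY_TRUTH, 300, rng)
        f = fit_day(rts, FitOptions(restarts=2, seed=0, fix_a=None))
        assert f.a > 0 and f.a != 1.0


class TestBaselineTable:
    def test_one_row_per_subject_and_flagging(self):
        """A subject whose baseline-day rows are missing is flagged, the
        rest are fitted; one row per subject either way."""
        from vigilpred import synthetic_data as sd
        study = sd.simulate_study(n_per_group=(3, 3), seed=2,
                                  day_labels=["B2", "M1_1"],
                                  session_duration_s=300.0)
        trials = study.trials
        drop = (trials["subject_id"] == "s5h_01") & (trials["day_label"] == "B2")
        tab = ddm.baseline_ddm_table(
            trials[~drop],
            options=FitOptions(restarts=1, maxiter=1500, xatol=1e-3,
                               fatol=1e-5, min_trials=50, seed=1))
        assert len(tab) == 6
        row = tab[tab["subject_id"] == "s5h_01"].iloc[0]
        assert not row["converged"] and np.isnan(row["v"])
        assert tab[tab["subject_id"] != "s5h_01"]["converged"].mean() > 0.5
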