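"""GRT-wIND: model family, probability engine, fitting, SvA curves."""

import numpy as np
import pytest
from scipy import integrate, stats

from awarekit import grt, sva
from awarekit.errors import DegenerateInputError
from conftest import make_grt_spec


class TestModelFamily:
    def test_sixteen_models(self):
        models = grt.enumerate_models()
        assert len(models) == 16
        assert len(set(models)) == 16
        assert grt.FULL_MODEL in models and grt.MOST_CONSTRAINED in models

    def test_parameter_nesting(self):
        """Every constrained template's free parameters nest in the full set."""
        full = set(grt.param_names(grt.FULL_MODEL, 6))
        for flags in grt.enumerate_models():
            names = set(grt.param_names(flags, 6))
            assert names <= full, flags

    def test_full_model_has_most_parameters(self):
        sizes = {f: len(grt.param_names(f, 6)) for f in grt.enumerate_models()}
        assert max(sizes, key=sizes.get) == grt.FULL_MODEL
        assert min(sizes, key=sizes.get) == grt.MOST_CONSTRAINED


class TestProbabilityEngine:
    def test_probs_sum_to_one(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            mx, my = rng.normal(0, 1.5, 2)
            sx, sy = np.exp(rng.normal(0, 0.4, 2))
            rho = rng.uniform(-0.9, 0.9)
            b = rng.normal(0, 1)
            c1 = rng.normal(-1, 1)
            g = np.exp(rng.normal(0, 0.5, 2))
            p = grt._cell_probs(
                mx, my, sx, sy, rho, b,
                np.array([c1, c1 + g[0], c1 + g[0] + g[1]]), rng.uniform(-1.5, 1.5)
            )
            assert p.sum() == pytest.approx(1.0, abs=1e-8)
            assert np.all(p >= 0)

    def test_identical_classes_symmetric_shape_marginal(self):
        spec = make_grt_spec(
            flags=grt.FULL_MODEL,
            means={"square": (0.4, 0.6), "diamond": (0.4, 0.6), "absent": (0.0, 0.0)},
            bounds=0.4,
        )
        for stim in ("square", "diamond"):
            p = grt.predict_response_probs(spec, 0, stim)
            assert p.sum(axis=1)[0] == pytest.approx(0.5, abs=1e-9)

    def test_extreme_cuts_put_mass_in_one_pas(self):
        spec = make_grt_spec(cuts=(8.0, 9.0, 10.0))
        p = grt.predict_response_probs(spec, 0, "square")
        assert p[:, 0].sum() == pytest.approx(1.0, abs=1e-6)  # everything PAS 1
        spec2 = make_grt_spec(cuts=(-10.0, -9.0, -8.0))
        p2 = grt.predict_response_probs(spec2, 0, "diamond")
        assert p2[:, 3].sum() == pytest.approx(1.0, abs=1e-6)  # everything PAS 4

    def test_matches_monte_carlo(self):
        """Engine vs 10^6-draw sampling for a correlated, sloped-bound spec."""
        rng = np.random.default_rng(1)
        mx, my, sx, sy, rho, b, slope = 0.5, 0.7, 1.2, 0.8, 0.45, 0.2, -0.6
        cuts = np.array([0.3, 1.1, 1.9])
        ana = grt._cell_probs(mx, my, sx, sy, rho, b, cuts, slope)
        n = 10**6
        z = rng.multivariate_normal(
            [mx, my], [[sx**2, rho * sx * sy], [rho * sx * sy, sy**2]], size=n
        )
        w = z[:, 1] - slope * z[:, 0]
        pas = 1 + np.searchsorted(cuts - slope * b, w)
        sq = z[:, 0] > b
        for r in range(2):
            for k in range(4):
                mc = np.mean((sq == (r == 0)) & (pas == k + 1))
                se = np.sqrt(max(ana[r, k] * (1 - ana[r, k]), 1e-12) / n)
                assert abs(ana[r, k] - mc) < 3 * se + 2 / n


class TestNegloglik:
    def test_empty_dataset_zero(self):
        spec = make_grt_spec(n=2)
        ds = grt.GRTDataset(counts=np.zeros((2, 3, 2, 4)))
        assert grt.negloglik(spec, ds) == 0.0

    def test_duplicated_dataset_doubles(self):
        rng = np.random.default_rng(2)
        spec = make_grt_spec(n=3)
        ds = grt.simulate_dataset(spec, np.full((3, 3), 40), rng)
        one = grt.negloglik(spec, ds)
        two = grt.negloglik(spec, grt.GRTDataset(counts=2 * ds.counts))
        assert two == pytest.approx(2 * one, rel=1e-12)

    def test_expectation_data_optimum(self):
        """At expectation data the generating spec beats 20 perturbed specs."""
        spec = make_grt_spec(n=2)
        expected = grt.predict_all(spec) * 1000.0
        ds = grt.GRTDataset(counts=expected)
        base = grt.negloglik(spec, ds)
        rng = np.random.default_rng(3)
        packing = grt._Packing(spec.flags, 2)
        theta = packing.pack(spec)
        for _ in range(20):
            pert = packing.unpack(theta + rng.normal(0, 0.05, theta.size))
            assert grt.negloglik(pert, ds) > base

    def test_participant_mismatch_rejected(self):
        spec = make_grt_spec(n=2)
        ds = grt.GRTDataset(counts=np.ones((3, 3, 2, 4)))
        with pytest.raises(ValueError):
            grt.negloglik(spec, ds)


class TestRlnaAndConditionalDprime:
    def test_identical_distributions_rlna_one(self):
        spec = make_grt_spec(
            means={"square": (0.0, 0.0), "diamond": (0.0, 0.0), "absent": (0.0, 0.0)}
        )
        grid = np.linspace(-3, 3, 21)
        np.testing.assert_allclose(sva.rlna(spec, grid), 1.0, atol=1e-12)

    def test_equal_variance_log_rlna_affine(self):
        """absent N(0,1), present N(1,1): log RLNA = 1/2 - a (slope -1)."""
        spec = make_grt_spec(
            means={"square": (0.3, 1.0), "diamond": (-0.3, 1.0), "absent": (0.0, 0.0)}
        )
        grid = np.linspace(-2, 3, 41)
        log_rlna = np.log(sva.rlna(spec, grid))
        slope, intercept = np.polyfit(grid, log_rlna, 1)
        assert slope == pytest.approx(-1.0, abs=1e-6)
        assert intercept == pytest.approx(0.5, abs=1e-6)
        assert sva.rlna(spec, 0.5) == pytest.approx(1.0, abs=1e-10)

    def test_dprime_constant_under_independence(self):
        spec = make_grt_spec(
            means={"square": (0.6, 0.9), "diamond": (-0.4, 0.9), "absent": (0.0, 0.0)}
        )
        grid = np.linspace(-3, 4, 31)
        d = sva.conditional_dprime(spec, grid)
        np.testing.assert_allclose(d, 1.0, atol=1e-12)  # delta=1.0, sd=1

    def test_identical_classes_zero_dprime(self):
        spec = make_grt_spec(
            means={"square": (0.2, 0.5), "diamond": (0.2, 0.5), "absent": (0.0, 0.0)}
        )
        np.testing.assert_allclose(
            sva.conditional_dprime(spec, np.linspace(-2, 2, 11)), 0.0, atol=1e-12
        )

    def test_correlated_case_matches_numerical_conditionals(self):
        """Conditional moments from 1-D integration of the bivariate density."""
        spec = make_grt_spec(
            flags=grt.FULL_MODEL,
            means={"square": (0.5, 0.8), "diamond": (-0.5, 0.6), "absent": (0.0, 0.0)},
            sds={"square": (1.2, 0.9), "diamond": (0.8, 1.1), "absent": (1.0, 1.0)},
            rhos={"square": 0.5, "diamond": -0.3, "absent": 0.0},
        )
        a = 0.7
        moments = {}
        for lbl in ("square", "diamond"):
            mx, my = spec.means[lbl]
            sx, sy = spec.sds[lbl]
            rho = spec.rhos[lbl]
            cov = [[sx**2, rho * sx * sy], [rho * sx * sy, sy**2]]
            pdf = stats.multivariate_normal([mx, my], cov).pdf
            fa = integrate.quad(lambda x: pdf([x, a]), -12, 12)[0]
            m1 = integrate.quad(lambda x: x * pdf([x, a]), -12, 12)[0] / fa
            m2 = integrate.quad(lambda x: x * x * pdf([x, a]), -12, 12)[0] / fa
            moments[lbl] = (m1, m2 - m1**2)
        expected = abs(moments["square"][0] - moments["diamond"][0]) / np.sqrt(
            0.5 * (moments["square"][1] + moments["diamond"][1])
        )
        assert sva.conditional_dprime(spec, a) == pytest.approx(expected, rel=1e-6)


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(10)
    true = make_grt_spec(n=10, bounds=rng.normal(0.1, 0.2, 10))
    ds = grt.simulate_dataset(true, np.array([128, 128, 64]), rng)
    fit = grt.fit_grt_wind(ds, grt.MOST_CONSTRAINED, restarts=2, rng=rng)
    return true, ds, fit


@pytest.fixture(scope="module")
def sva_fit():
    rng = np.random.default_rng(20)
    true = make_grt_spec(n=8)
    ds = grt.simulate_dataset(true, np.array([128, 128, 64]), rng)
    return grt.fit_grt_wind(ds, grt.MOST_CONSTRAINED, restarts=1, rng=rng)


class TestFitAndSelect:
    def test_recovers_present_means(self, fitted):
        true, _, fit = fitted
        for lbl in ("square", "diamond"):
            assert fit.spec.means[lbl][0] == pytest.approx(
                true.means[lbl][0], abs=0.25
            )
            assert fit.spec.means[lbl][1] == pytest.approx(
                true.means[lbl][1], abs=0.25
            )

    def test_aic_identity(self, fitted):
        _, _, fit = fitted
        assert fit.aic == pytest.approx(2 * fit.n_params - 2 * fit.loglik)
        assert 0 <= fit.pct_accounted <= 100

    def test_refit_not_worse_than_truth(self, fitted):
        true, ds, fit = fitted
        assert -fit.loglik <= grt.negloglik(true, ds) + 1e-4

    def test_nesting_constrained_nll_not_below_full(self, fitted):
        _, ds, fit = fitted
        full = grt.fit_grt_wind(
            ds, grt.FULL_MODEL, restarts=1, rng=np.random.default_rng(11)
        )
        assert -fit.loglik >= -full.loglik - 1e-4

    def test_no_catch_trials_rejected(self):
        spec = make_grt_spec(n=2)
        rng = np.random.default_rng(12)
        ds = grt.simulate_dataset(spec, np.array([[64, 64, 0]] * 2), rng)
        with pytest.raises(DegenerateInputError):
            grt.fit_grt_wind(ds, grt.MOST_CONSTRAINED, rng=rng)

    def test_select_model_tiebreaks(self, fitted):
        _, _, fit = fitted
        import dataclasses

        bigger = dataclasses.replace(fit, n_params=fit.n_params + 5,
                                     aic=fit.aic)  # same AIC, more params
        assert grt.select_model([bigger, fit]) is fit
        assert grt.select_model([fit]) is fit
        other = dataclasses.replace(fit, dataset_hash="deadbeef")
        with pytest.raises(ValueError):
            grt.select_model([fit, other])

    def test_from_trials_aggregation(self, small_cohort):
        ds = grt.GRTDataset.from_trials(small_cohort, "visibility")
        n_vis = len(small_cohort[small_cohort["block"] == "visibility"])
        assert ds.counts.sum() == n_vis
        assert ds.has_catch
        assert ds.counts[:, 2].sum() == 6 * 64  # catch trials per participant


class TestSvaCurve:
    def test_curve_matches_direct_calls(self, sva_fit):
        fit = sva_fit
        curve = sva.sva_curve(fit)
        np.testing.assert_allclose(
            curve.rlna, sva.rlna(fit.spec, curve.awareness_grid)
        )
        np.testing.assert_allclose(
            curve.d_cond, sva.conditional_dprime(fit.spec, curve.awareness_grid)
        )
        assert len(curve.awareness_grid) == 200

    def test_symmetric_ideal_criterion_is_midpoint(self):
        spec = make_grt_spec(
            means={"square": (0.4, 1.2), "diamond": (-0.4, 1.2), "absent": (0.0, 0.0)}
        )
        crit = sva.ideal_observer_criterion(spec)
        assert crit == pytest.approx(0.6, abs=1e-8)

    def test_grid_refinement_stable(self, sva_fit):
        c200 = sva.sva_curve(sva_fit, n_grid=200)
        c2000 = sva.sva_curve(sva_fit, n_grid=2000)
        assert c200.ideal_criterion == pytest.approx(
            c2000.ideal_criterion, abs=1e-3
        )

    def test_bootstrap_deterministic_and_banded(self, sva_fit):
        a = sva.bootstrap_sva(sva_fit, n_boot=5, rng=np.random.default_rng(7))
        b = sva.bootstrap_sva(sva_fit, n_boot=5, rng=np.random.default_rng(7))
        np.testing.assert_array_equal(a.ci_lower, b.ci_lower)
        np.testing.assert_array_equal(a.ci_upper, b.ci_upper)
        assert np.all(a.ci_lower <= a.ci_upper)
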