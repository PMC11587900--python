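"""Design-based estimation: reductions to iid statistics, linearized
variance against brute-force oracles, and invariance properties."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from obsmed import (SurveyDesign, SurveyLogit, fit_weighted_logistic,
                    odds_ratios, rao_scott_chisq, wald_interaction_test,
                    weighted_mean_se)
from obsmed.survey import ConvergenceError, DesignError

from conftest import simulate_logistic


def _toy_design(rng, n, n_strata=3, psu_per=3, wlo=0.5, whi=2.0):
    return SurveyDesign(rng.uniform(wlo, whi, n),
                        rng.integers(n_strata, size=n),
                        rng.integers(psu_per, size=n))


class TestSurveyDesign:
    def test_rejects_nonpositive_weights(self):
        with pytest.raises(DesignError):
            SurveyDesign(np.array([1.0, 0.0]), np.zeros(2), np.arange(2))

    def test_design_df(self, rng):
        d = SurveyDesign(np.ones(12), np.repeat([0, 1, 2], 4), np.tile([0, 0, 1, 1], 3))
        assert d.n_strata == 3 and d.n_psu == 6 and d.design_df == 3


class TestLogisticFit:
    def test_equal_weights_reduce_to_classical_mle(self, rng):
        X, y = simulate_logistic(rng, 3000, [0.8, -0.5], 0.3)
        mle = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        est = SurveyLogit().fit(X, y)
        assert np.abs(est.params_ - mle.params).max() < 1e-6

    def test_two_by_two_cross_product_ratio(self):
        # exposure-only model on 2x2 counts: 335/1110 events in the exposed
        # group, 477/2215 in the unexposed -> OR = 335*2215/(477*1110)
        df = pd.DataFrame({
            "exposed": [1] * 1445 + [0] * 2692,
            "cvd": [1] * 335 + [0] * 1110 + [1] * 477 + [0] * 2215,
        })
        fit = fit_weighted_logistic(df, "cvd ~ exposed",
                                    SurveyDesign.unclustered(len(df)))
        assert np.exp(fit.coef("exposed")) == pytest.approx(
            335 * 2215 / (477 * 1110), rel=1e-6)

    def test_duplicate_rows_halved_weights_identical(self, rng):
        X, y = simulate_logistic(rng, 500, [0.7], 0.0)
        base = SurveyLogit().fit(X, y).params_
        X2, y2 = np.vstack([X, X]), np.r_[y, y]
        d = SurveyDesign(np.full(1000, 0.5), np.zeros(1000), np.arange(1000))
        doubled = SurveyLogit().fit(X2, y2, d).params_
        assert np.allclose(base, doubled, atol=1e-8)

    def test_weight_scale_invariance(self, rng):
        X, y = simulate_logistic(rng, 800, [0.6, 0.2], -0.2)
        d1 = _toy_design(rng, 800)
        d2 = SurveyDesign(d1.weight * 7.3, d1.stratum, d1.psu)
        f1 = SurveyLogit().fit(X, y, d1).fit_
        f2 = SurveyLogit().fit(X, y, d2).fit_
        assert np.allclose(f1.params, f2.params, atol=1e-10)
        assert np.allclose(f1.cov, f2.cov, rtol=1e-8)

    def test_separation_is_flagged(self):
        X = np.r_[np.zeros(20), np.ones(20)][:, None]
        y = np.r_[np.zeros(20), np.ones(20)]
        with pytest.raises(ConvergenceError):
            SurveyLogit().fit(X, y)

    def test_rank_deficiency_names_aliased_terms(self, rng):
        X, y = simulate_logistic(rng, 200, [0.5], 0.0)
        df = pd.DataFrame({"a": X[:, 0], "b": 2.0 * X[:, 0]})
        with pytest.raises(np.linalg.LinAlgError, match=r"aliased terms: \['[ab]'\]"):
            SurveyLogit().fit(df, y)

    def test_degenerate_outcome_rejected(self, rng):
        with pytest.raises(ValueError, match="degenerate"):
            SurveyLogit().fit(rng.normal(size=(50, 1)), np.ones(50))

    def test_single_psu_stratum_errors_unless_grand_mean(self, rng):
        X, y = simulate_logistic(rng, 100, [0.5], 0.0)
        d = SurveyDesign(np.ones(100), np.r_[np.zeros(99), [1]],
                         np.r_[np.arange(99) % 4, [0]])
        with pytest.raises(DesignError, match="single PSU"):
            SurveyLogit().fit(X, y, d)
        est = SurveyLogit(single_psu="grand_mean").fit(X, y, d)
        assert np.all(np.isfinite(est.bse_))

    def test_parameter_recovery_close_to_truth(self, rng):
        # moderate-n sanity check at 3 SE; the full 200-replicate coverage
        # study lives in the acceptance suite
        beta = np.array([0.5, -0.3])
        X, y = simulate_logistic(rng, 6000, beta, 0.1)
        d = _toy_design(rng, 6000, n_strata=5, psu_per=4)
        f = SurveyLogit().fit(X, y, d).fit_
        assert np.all(np.abs(f.params[1:] - beta) < 3 * f.bse[1:])


class TestOddsRatios:
    def test_null_coefficient_gives_symmetric_unit_or(self):
        from obsmed.survey import GLMFit
        fit = GLMFit(["x"], np.array([0.0]), np.array([[0.25]]), 10, True, 0.0)
        tab = odds_ratios(fit)
        assert tab.loc["x", "OR"] == 1.0
        assert tab.loc["x", "ci_low"] * tab.loc["x", "ci_high"] == pytest.approx(1.0)

    def test_ci_matches_closed_form(self):
        from obsmed.survey import GLMFit
        coef, se = np.log(1.53), 0.14
        fit = GLMFit(["x"], np.array([coef]), np.array([[se ** 2]]), 10, True, 0.0)
        tab = odds_ratios(fit)
        assert tab.loc["x", "OR"] == pytest.approx(1.53)
        assert tab.loc["x", "ci_low"] == pytest.approx(np.exp(coef - 1.959964 * se))
        assert tab.loc["x", "ci_high"] == pytest.approx(np.exp(coef + 1.959964 * se))


class TestWeightedMean:
    def test_equal_weights_give_arithmetic_mean(self, rng):
        x = rng.normal(size=400)
        m, _ = weighted_mean_se(x, SurveyDesign.unclustered(400))
        assert m == pytest.approx(x.mean(), abs=1e-12)

    def test_constant_vector_has_zero_se(self):
        m, se = weighted_mean_se(np.full(50, 3.3), SurveyDesign.unclustered(50))
        assert (m, se) == (pytest.approx(3.3), pytest.approx(0.0, abs=1e-12))

    def test_se_matches_direct_linearization_oracle(self, rng):
        n = 300
        x = rng.normal(2.0, 1.0, n)
        d = _toy_design(rng, n, n_strata=3, psu_per=3)
        mean, se = weighted_mean_se(x, d)
        # independent direct computation of the with-replacement formula
        wsum = d.weight.sum()
        mean0 = np.sum(d.weight * x) / wsum
        u = d.weight * (x - mean0) / wsum
        var = 0.0
        for h in np.unique(d.stratum):
            zs = [u[(d.stratum == h) & (d.psu == p)].sum()
                  for p in np.unique(d.psu[d.stratum == h])]
            zs = np.asarray(zs)
            var += len(zs) / (len(zs) - 1) * np.sum((zs - zs.mean()) ** 2)
        assert mean == pytest.approx(mean0)
        assert se == pytest.approx(np.sqrt(var), rel=1e-10)

    def test_all_missing_raises(self):
        with pytest.raises(ValueError, match="missing"):
            weighted_mean_se([np.nan, np.nan], SurveyDesign.unclustered(2))


class TestRaoScott:
    def test_equal_weights_reduce_to_pearson(self, rng):
        a = rng.integers(3, size=600)
        b = rng.integers(2, size=600)
        stat, _ = rao_scott_chisq(a, b, SurveyDesign.unclustered(600))
        pearson = stats.chi2_contingency(pd.crosstab(a, b), correction=False)[0]
        assert stat == pytest.approx(pearson, abs=1e-8)

    def test_perfect_association_p_near_zero(self):
        a = np.repeat([0, 1], 100)
        _, p = rao_scott_chisq(a, a, SurveyDesign.unclustered(200))
        assert p < 1e-20

    def test_three_stratum_toy_design_matches_brute_force(self, rng):
        n = 240
        a = rng.integers(2, size=n)
        b = rng.integers(3, size=n)
        d = _toy_design(rng, n, n_strata=3, psu_per=2)
        stat, p = rao_scott_chisq(a, b, d)
        # brute-force oracle: Pearson on weighted proportions with the
        # first-order generalized-design-effect correction
        K = 6
        Z = np.zeros((n, K))
        Z[np.arange(n), a * 3 + b] = 1.0
        ph = d.weight @ Z / d.weight.sum()
        P = ph.reshape(2, 3)
        X2 = n * np.sum((P - np.outer(P.sum(1), P.sum(0))) ** 2
                        / np.outer(P.sum(1), P.sum(0)))
        U = d.weight[:, None] * (Z - ph) / d.weight.sum()
        V = np.zeros((K, K))
        for h in np.unique(d.stratum):
            zs = np.stack([U[(d.stratum == h) & (d.psu == psu)].sum(axis=0)
                           for psu in np.unique(d.psu[d.stratum == h])])
            dev = zs - zs.mean(axis=0)
            V += len(zs) / (len(zs) - 1) * dev.T @ dev
        V0 = (np.diag(ph) - np.outer(ph, ph)) / (n - 1)
        delta = np.trace(np.linalg.pinv(V0) @ V) / (K - 1)
        assert stat == pytest.approx(X2 / delta, rel=1e-10)
        assert p == pytest.approx(stats.chi2.sf(X2 / delta, 2), rel=1e-10)

    def test_weight_scale_invariance(self, rng):
        a = rng.integers(2, size=200)
        b = rng.integers(2, size=200)
        d1 = _toy_design(rng, 200)
        d2 = SurveyDesign(d1.weight * 11.0, d1.stratum, d1.psu)
        assert rao_scott_chisq(a, b, d1)[0] == pytest.approx(
            rao_scott_chisq(a, b, d2)[0], rel=1e-10)

    def test_single_level_variable_rejected(self):
        with pytest.raises(ValueError, match="two observed levels"):
            rao_scott_chisq(np.zeros(40), np.arange(40) % 2,
                            SurveyDesign.unclustered(40))


class TestWaldTest:
    def test_zero_coefficient_gives_p_one(self):
        from obsmed.survey import GLMFit
        fit = GLMFit(["x"], np.array([0.0]), np.array([[1.0]]), 10, True, 0.0)
        assert wald_interaction_test(fit, "x") == (0.0, pytest.approx(1.0))

    def test_coef_at_critical_value_gives_p_05(self):
        from obsmed.survey import GLMFit
        se = 0.2
        fit = GLMFit(["x"], np.array([1.959964 * se]), np.array([[se ** 2]]),
                     10, True, 0.0)
        _, p = wald_interaction_test(fit, "x")
        assert p == pytest.approx(0.05, abs=1e-6)

    def test_absent_term_raises(self):
        from obsmed.survey import GLMFit
        fit = GLMFit(["x"], np.array([0.0]), np.array([[1.0]]), 10, True, 0.0)
        with pytest.raises(KeyError):
            wald_interaction_test(fit, "y")

    def test_null_interaction_type_i_error(self, rng):
        # exposure and moderator with main effects but no interaction
        reps, n, rej = 1000, 600, 0
        for _ in range(reps):
            x1 = rng.integers(2, size=n).astype(float)
            x2 = rng.integers(2, size=n).astype(float)
            eta = -0.5 + 0.4 * x1 + 0.3 * x2
            y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
            df = pd.DataFrame({"x1": x1, "x2": x2, "x12": x1 * x2})
            fit = SurveyLogit().fit(df, y).fit_
            rej += wald_interaction_test(fit, "x12")[1] < 0.05
        assert 0.028 <= rej / reps <= 0.072
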