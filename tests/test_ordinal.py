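import itertools

import numpy as np
import pandas as pd
import pytest

from esbastats import counts_to_long, to_long
from esbastats.ordinal import (
    CumulativeLogitModel,
    ModelSpec,
    NonProportionalLogitModel,
    design_matrix,
    fit_nonproportional,
    fit_proportional,
    lrt_proportionality,
    pearson_gof,
    predict_probs,
    wald_ci,
)
from esbastats.simulate import GeneratorConfig, generate_cohort, \
    scenario_library


def grid_search_mle(model, lo, hi, n_points=9, refinements=2):
    """Independent oracle: dense grid over (theta1..theta3, beta), refined
    around the best point; no gradients, no reparameterization."""
    lo = np.asarray(lo, float)
    hi = np.asarray(hi, float)
    best = None
    for _ in range(refinements + 1):
        axes = [np.linspace(lo[i], hi[i], n_points) for i in range(len(lo))]
        for point in itertools.product(*axes):
            theta = np.asarray(point[:3])
            if not (theta[0] < theta[1] < theta[2]):
                continue
            val = model.negloglik(np.asarray(point))
            if best is None or val < best[1]:
                best = (np.asarray(point), val)
        width = (hi - lo) / (n_points - 1)
        lo = best[0] - width
        hi = best[0] + width
    return best[0], best[1]


class TestLikelihood:
    def test_intercept_only_closed_form(self, fixture_long):
        """Saturated marginal fit: nll at the empirical cumulative logits
        equals -sum n_j log(n_j / N)."""
        counts = fixture_long["rating"].value_counts().sort_index()
        n = counts.sum()
        model = CumulativeLogitModel(fixture_long["rating"],
                                     np.empty((len(fixture_long), 0)))
        cum = np.cumsum(counts.to_numpy())[:3] / n
        theta = np.log(cum / (1 - cum))
        expected = -np.sum(counts.to_numpy() *
                           np.log(counts.to_numpy() / n))
        assert model.negloglik(theta) == pytest.approx(expected, abs=1e-9)
        # and the MLE recovers exactly those thresholds
        res = model.fit()
        assert np.allclose(res.thresholds, theta, atol=1e-6)

    def test_half_probability_contributes_log_two(self):
        model = CumulativeLogitModel([1], np.empty((1, 0)))
        # theta_1 = 0 -> P(Y=1) = 0.5
        assert model.negloglik(np.array([0.0, 1.0, 2.0])) == \
            pytest.approx(np.log(2.0))

    def test_mle_matches_grid_search_oracle(self, fixture_long):
        """Quasi-Newton MLE equals a twice-refined dense grid search within
        1e-4 per parameter on a 4-parameter problem."""
        spec = ModelSpec(("Init.Rating",))
        y, X, names, _ = design_matrix(fixture_long, spec)
        model = CumulativeLogitModel(y, X, exog_names=names)
        res = model.fit()
        start = np.concatenate([res.thresholds, res.slopes.to_numpy()])
        point, val = grid_search_mle(model, start - 2.0, start + 2.0,
                                     n_points=11, refinements=4)
        assert np.allclose(res.params, point, atol=1e-4)
        assert -res.llf <= val + 1e-6

    def test_weighted_equals_expanded(self, fixture_long):
        spec = ModelSpec(("Phase", "Init.Rating"))
        y, X, names, _ = design_matrix(fixture_long, spec)
        expanded = CumulativeLogitModel(y, X, exog_names=names).fit()
        # collapse by hand into weighted unique rows
        df = pd.DataFrame(X, columns=names)
        df["y"] = y
        grouped = df.groupby(names + ["y"]).size().reset_index(name="w")
        weighted = CumulativeLogitModel(
            grouped["y"], grouped[names].to_numpy(), exog_names=names,
            weights=grouped["w"]).fit()
        assert np.allclose(expanded.params, weighted.params, atol=1e-8)
        assert expanded.llf == pytest.approx(weighted.llf, abs=1e-8)


class TestAgainstStatsmodels:
    def test_fixture_fit_matches_ordered_model(self, fixture_long, final_fit):
        """Independent MLE cross-check via statsmodels OrderedModel."""
        from statsmodels.miscmodels.ordinal_model import OrderedModel
        exog = fixture_long[["phase", "init_rating"]].astype(float)
        sm = OrderedModel(fixture_long["rating"], exog, distr="logit")
        sm_res = sm.fit(method="bfgs", disp=False)
        assert sm_res.llf == pytest.approx(final_fit.llf, abs=1e-5)
        assert np.allclose(sm_res.params[:2],
                           final_fit.slopes.to_numpy(), atol=1e-4)
        theta_sm = sm.transform_threshold_params(sm_res.params)[1:-1]
        assert np.allclose(theta_sm, final_fit.thresholds, atol=1e-3)
        # standard errors from the observed information agree too
        assert np.allclose(sm_res.bse[:2],
                           final_fit.bse[["Phase", "Init.Rating"]],
                           atol=1e-3)


class TestProperties:
    def test_positive_slope_shifts_mass_upward(self, final_fit):
        """Increasing a coefficient raises P(Y >= j) at positive covariate
        values, the sign convention under which positive slopes mean a
        more cooperative rating."""
        x = {"Phase": 2.0, "Init.Rating": 1.0}
        base = final_fit.predict(x)
        bumped = final_fit.params.copy()
        bumped[3] += 0.5  # Phase slope
        res2 = type(final_fit)(final_fit.model, bumped, final_fit.llf,
                               final_fit.vcov, True, False)
        shifted = res2.predict(x)
        for j in range(1, 4):
            assert shifted[j:].sum() > base[j:].sum()

    def test_predictions_on_simplex(self, final_fit):
        for phase in (1, 2, 3):
            for init in (0, 1):
                p = predict_probs(final_fit,
                                  {"Phase": phase, "Init.Rating": init})
                assert p.sum() == pytest.approx(1.0, abs=1e-12)
                assert np.all(p >= 0)

    def test_null_fit_predicts_marginals(self, fixture_long):
        res = fit_proportional(ModelSpec(()), fixture_long)
        marginal = fixture_long["rating"].value_counts(normalize=True) \
            .sort_index().to_numpy()
        assert np.allclose(res.predict([]), marginal, atol=1e-6)

    def test_thresholds_strictly_increasing(self, final_fit):
        assert np.all(np.diff(final_fit.thresholds) > 0)

    def test_analytic_hessian_matches_finite_differences(self, final_fit):
        m = final_fit.model
        Ha = m._hessian_analytic(final_fit.params)
        Hn = m._hessian(final_fit.params)
        assert np.allclose(Ha, Hn, atol=1e-5)

    def test_bic_formula(self, final_fit):
        assert final_fit.bic == pytest.approx(
            -2 * final_fit.llf + 5 * np.log(255), abs=1e-9)

    def test_useless_column_raises_bic(self, fixture_long):
        small = fit_proportional(ModelSpec(("Phase", "Init.Rating")),
                                 fixture_long)
        rng = np.random.default_rng(5)
        noisy = fixture_long.copy()
        noisy["age"] = rng.integers(7, 13, size=len(noisy)).astype(float)
        big = fit_proportional(ModelSpec(("Phase", "Init.Rating", "Age")),
                               noisy)
        assert big.llf >= small.llf - 1e-8
        if big.llf - small.llf < 0.5 * np.log(small.nobs):
            assert big.bic > small.bic


class TestWaldInference:
    def test_fixture_wald_interval_excludes_zero(self, final_fit):
        lo, hi = wald_ci(final_fit, "Init.Rating")
        assert 0 < lo < 2.48 < hi
        lo_p, hi_p = wald_ci(final_fit, "Phase")
        assert 0 < lo_p < 0.90 < hi_p

    def test_unknown_coefficient_rejected(self, final_fit):
        with pytest.raises(KeyError):
            wald_ci(final_fit, "Age")

    def test_null_predictor_coverage(self):
        """Wald 95% CI for a truly null coefficient covers zero at roughly
        the nominal rate over 500 simulated cohorts."""
        cfg = scenario_library()["paper-like"]
        spec = ModelSpec(("Phase", "Init.Rating", "Medications"))
        covered = 0
        valid = 0
        for rep in range(500):
            long_df = to_long(generate_cohort(cfg, seed=rep))
            res = fit_proportional(spec, long_df)
            if not res.converged or res.degenerate:
                continue
            lo, hi = wald_ci(res, "Medications (no)")
            valid += 1
            covered += lo <= 0.0 <= hi
        assert valid > 450
        assert 0.92 <= covered / valid <= 0.98


class TestParameterRecovery:
    def test_large_sample_recovery(self):
        """n = 2,000 children generated from known (theta, beta) recover
        the truth within 3 standard errors."""
        cfg = GeneratorConfig(n_uncoop=1060, n_coop=940,
                              thresholds=(-1.6, 1.3, 4.2),
                              slopes={"Phase": 0.9, "Init.Rating": 2.48})
        long_df = to_long(generate_cohort(cfg, seed=42))
        res = fit_proportional(ModelSpec(("Phase", "Init.Rating")), long_df)
        truth = np.array([-1.6, 1.3, 4.2, 0.9, 2.48])
        se = res.bse.to_numpy()
        assert np.all(np.abs(res.params - truth) < 3 * se)


class TestNonProportional:
    def test_nests_proportional(self, fixture_long, final_fit):
        np_res = fit_nonproportional(ModelSpec(("Phase", "Init.Rating")),
                                     fixture_long)
        assert np_res.llf >= final_fit.llf - 1e-8

    def test_intercept_only_identical(self, fixture_long):
        prop = fit_proportional(ModelSpec(()), fixture_long)
        nonprop = fit_nonproportional(ModelSpec(()), fixture_long)
        assert nonprop.llf == pytest.approx(prop.llf, abs=1e-6)
        assert np.allclose(nonprop.thresholds, prop.thresholds, atol=1e-4)

    def test_per_logit_slopes_converge_under_proportional_truth(self):
        cfg = GeneratorConfig(n_uncoop=2500, n_coop=2500,
                              thresholds=(-1.6, 1.3, 4.0),
                              slopes={"Phase": 0.9, "Init.Rating": 2.0})
        long_df = to_long(generate_cohort(cfg, seed=11))
        np_res = fit_nonproportional(ModelSpec(("Phase", "Init.Rating")),
                                     long_df)
        B = np_res.slopes
        # logit-1 slopes are noisy (bottom category is rare); spread
        # threshold reflects sampling error at this n
        assert np.all(B.max(axis=0) - B.min(axis=0) < 0.5)
        assert np.allclose(B.mean(axis=0), [0.9, 2.0], atol=0.25)

    def test_lrt_df_counting(self, fixture_long):
        spec = ModelSpec(("Phase", "Init.Rating", "Medications"))
        long_df = fixture_long.copy()
        rng = np.random.default_rng(3)
        long_df["medication"] = np.where(rng.random(len(long_df)) < 0.2,
                                         "yes", "no")
        prop = fit_proportional(spec, long_df)
        nonprop = fit_nonproportional(spec, long_df)
        stat, df, p = lrt_proportionality(prop, nonprop)
        assert df == 6  # 2 extra slope sets x 3 design columns
        assert stat >= 0

    def test_identical_fits_give_zero_statistic(self, fixture_long):
        prop = fit_proportional(ModelSpec(()), fixture_long)
        nonprop = fit_nonproportional(ModelSpec(()), fixture_long)
        stat, df, p = lrt_proportionality(prop, nonprop)
        assert stat == pytest.approx(0.0, abs=1e-4)

    def test_mismatched_fits_rejected(self, fixture_long, final_fit):
        other = fit_nonproportional(ModelSpec(("Phase",)), fixture_long)
        with pytest.raises(ValueError):
            lrt_proportionality(final_fit, other)


class TestPearsonGof:
    def test_saturated_marginal_fit_is_exact(self, fixture_long):
        res = fit_proportional(ModelSpec(()), fixture_long)
        stat, df, p = pearson_gof(res)
        assert stat == pytest.approx(0.0, abs=1e-8)

    def test_fixture_gof_consistent_with_adequate_fit(self, final_fit):
        with pytest.warns(UserWarning):
            stat, df, p = pearson_gof(final_fit)
        assert stat >= 0
        assert df == 6 * 3 - 5
        assert 0.05 < p < 0.5
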