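"""Tests of normalization, phenotype scores, and the replicate-error model."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chemotax import screen, simulate


class TestFitTrendline:
    def test_identity_relation_recovered(self):
        rng = np.random.default_rng(0)
        ctrl = rng.uniform(5, 15, 60)
        exp = ctrl + rng.normal(0, 0.2, 60)
        fit = screen.fit_trendline(exp, ctrl)
        assert fit.slope == pytest.approx(1.0, abs=0.05)
        assert fit.intercept == pytest.approx(0.0, abs=0.5)
        assert not fit.fallback

    def test_outlier_resistance(self):
        # 90 on-trend wells + 6 strong-phenotype wells at half speed:
        # the robust slope stays within 2% of the clean-subset OLS slope
        rng = np.random.default_rng(1)
        ctrl = rng.uniform(5, 15, 96)
        exp = 1.1 * ctrl + 0.5 + rng.normal(0, 0.1, 96)
        exp[:6] = 0.5 * ctrl[:6]
        fit = screen.fit_trendline(exp, ctrl)
        ols = stats.linregress(ctrl[6:], exp[6:])
        assert fit.slope == pytest.approx(ols.slope, rel=0.02)

    def test_uncorrelated_control_triggers_fallback(self):
        rng = np.random.default_rng(2)
        ctrl = rng.uniform(5, 15, 60)
        exp = rng.uniform(5, 15, 60)  # independent -> Spearman ~ 0
        fit = screen.fit_trendline(exp, ctrl)
        assert abs(fit.spearman) < 0.3
        if fit.spearman < 0.1 or fit.slope < 0:
            assert fit.fallback

    def test_constant_control_falls_back(self):
        fit = screen.fit_trendline(np.arange(10.0), np.full(10, 3.0))
        assert fit.fallback

    def test_too_few_wells_rejected(self):
        with pytest.raises(ValueError):
            screen.fit_trendline(np.arange(5.0), np.arange(5.0))


class TestNormalize:
    def test_on_trendline_scores_zero(self):
        fit = screen.TrendlineFit(2.0, 1.0, 0.9, False)
        ctrl = np.array([1.0, 2.0, 3.0])
        exp = 2.0 * ctrl + 1.0
        out = screen.normalize(exp, ctrl, fit)
        np.testing.assert_allclose(out["normalized"], 1.0)
        np.testing.assert_allclose(out["score"], 0.0)

    def test_half_expected_scores_minus_half(self):
        fit = screen.TrendlineFit(1.0, 0.0, 0.9, False)
        out = screen.normalize(np.array([5.0]), np.array([10.0]), fit)
        assert out["score"].iloc[0] == pytest.approx(-0.5)

    def test_fallback_divides_by_plate_median(self):
        exp = np.array([1.0, 2.0, 3.0, 4.0])
        out = screen.normalize(exp)  # no fit -> plate median
        np.testing.assert_allclose(out["normalized"], exp / 2.5)

    def test_nonpositive_expected_excluded(self):
        fit = screen.TrendlineFit(1.0, 0.0, 0.9, False)
        out = screen.normalize(np.array([5.0, 5.0]), np.array([-1.0, 10.0]), fit)
        assert out["excluded"].iloc[0]
        assert np.isnan(out["score"].iloc[0])
        assert not out["excluded"].iloc[1]

    def test_normalization_idempotent(self):
        rng = np.random.default_rng(3)
        ctrl = rng.uniform(5, 15, 60)
        exp = 1.2 * ctrl + rng.normal(0, 0.2, 60)
        once = screen.normalize(exp, ctrl, screen.fit_trendline(exp, ctrl))
        refit = screen.fit_trendline(once["normalized"].to_numpy(), ctrl)
        twice = screen.normalize(once["normalized"].to_numpy(), ctrl, refit)
        np.testing.assert_allclose(twice["normalized"], 1.0, atol=0.15)


class TestChemokinesisScore:
    def test_on_trendline_scores_zero(self):
        basal = np.linspace(-0.3, 0.3, 40)
        stim = 0.8 * basal + 0.05
        res = screen.chemokinesis_scores(basal, stim)
        np.testing.assert_allclose(res, 0.0, atol=1e-6)

    def test_receptor_knockdown_like_condition(self):
        # population trend ~ slope 1 through the origin; one condition with
        # basal 0 / stimulated −0.4 scores chemokinesis ~ −0.4
        rng = np.random.default_rng(4)
        basal = np.concatenate([rng.normal(0, 0.15, 60), [0.0]])
        stim = np.concatenate([basal[:60] + rng.normal(0, 0.02, 60), [-0.4]])
        res = screen.chemokinesis_scores(basal, stim)
        assert res[-1] == pytest.approx(-0.4, abs=0.05)

    def test_constant_shift_absorbed_by_intercept(self):
        rng = np.random.default_rng(5)
        basal = rng.normal(0, 0.2, 50)
        stim = 0.9 * basal + rng.normal(0, 0.05, 50)
        r1 = screen.chemokinesis_scores(basal, stim)
        r2 = screen.chemokinesis_scores(basal, stim + 0.7)
        np.testing.assert_allclose(r1, r2, atol=1e-6)

    def test_degenerate_constant_basal(self):
        stim = np.array([0.1, 0.2, 0.0, 0.1, 0.15, 0.1, 0.1, 0.1])
        res = screen.chemokinesis_scores(np.zeros(8), stim)
        assert np.isfinite(res).all()
        assert res.mean() == pytest.approx(0.0, abs=0.05)


class TestErrorModel:
    def test_single_gaussian_recovery(self):
        rng = np.random.default_rng(6)
        diffs = rng.normal(0, 0.1 * np.sqrt(2), 2000)
        model = screen.fit_error_model(diffs)
        assert model.sd == pytest.approx(0.1, rel=0.05)

    def test_two_component_recovery(self):
        rng = np.random.default_rng(7)
        true = screen.ErrorModel(0.8, 0.05, 0.2)
        x = true.rvs(5000, rng)
        y = true.rvs(5000, rng)
        model = screen.fit_error_model(x - y)
        assert model.sigma1 == pytest.approx(0.05, rel=0.15)
        assert model.sigma2 == pytest.approx(0.2, rel=0.15)

    def test_moment_identity(self):
        rng = np.random.default_rng(8)
        true = screen.ErrorModel(0.7, 0.05, 0.15)
        diffs = true.rvs(4000, rng) - true.rvs(4000, rng)
        model = screen.fit_error_model(diffs)
        # Var(X - Y) = 2 Var(X) for iid zero-mean errors
        se = np.std(diffs**2) / np.sqrt(len(diffs))
        assert np.var(diffs) == pytest.approx(2 * model.variance, abs=3 * se)

    def test_sigma_ordering_enforced(self):
        rng = np.random.default_rng(9)
        diffs = rng.normal(0, 0.1, 500)
        model = screen.fit_error_model(diffs)
        assert model.sigma1 <= model.sigma2

    def test_replicate_differences_pair_count(self):
        scores = np.arange(7.0)
        conds = ["a", "a", "a", "b", "b", "c", "d"]
        diffs = screen.replicate_differences(scores, conds)
        assert len(diffs) == 3 + 1  # C(3,2) + C(2,2)

    def test_too_few_differences_rejected(self):
        with pytest.raises(ValueError):
            screen.fit_error_model(np.ones(3))


class TestNullIntervalAndPValues:
    def test_degenerate_single_gaussian_interval(self):
        # w2 = 0, n = 3, coverage 0.98 -> bound = z_0.99 * sigma / sqrt(3)
        model = screen.ErrorModel(1.0, 0.1, 0.3)
        iv = screen.null_interval(model, n=3, coverage=0.98)
        expected = stats.norm.ppf(0.99) * 0.1 / np.sqrt(3)
        assert iv.upper == pytest.approx(expected, rel=1e-9)
        assert iv.lower == -iv.upper

    def test_simulated_null_coverage(self):
        rng = np.random.default_rng(10)
        model = screen.ErrorModel(0.8, 0.05, 0.2)
        iv = screen.null_interval(model, n=3, coverage=0.98)
        means = model.rvs(10_000 * 3, rng).reshape(10_000, 3).mean(axis=1)
        coverage = np.mean(np.abs(means) <= iv.upper)
        assert 0.97 <= coverage <= 0.99

    def test_interval_width_shrinks_with_coverage(self):
        model = screen.ErrorModel(0.8, 0.05, 0.2)
        widths = [
            screen.null_interval(model, 3, c).upper for c in (0.5, 0.9, 0.98)
        ]
        assert widths[0] < widths[1] < widths[2]
        assert screen.null_interval(model, 3, 1e-9).upper < 1e-6

    def test_p_value_basics(self):
        model = screen.ErrorModel(0.8, 0.05, 0.2)
        assert screen.p_value(0.0, model, 3) == pytest.approx(1.0)
        assert screen.p_value(0.3, model, 3) == screen.p_value(-0.3, model, 3)

    def test_p_value_at_interval_bound_is_alpha(self):
        model = screen.ErrorModel(0.75, 0.04, 0.18)
        iv = screen.null_interval(model, n=3, coverage=0.98)
        assert screen.p_value(iv.upper, model, 3) == pytest.approx(0.02, abs=1e-4)

    def test_p_value_strictly_decreasing_in_magnitude(self):
        model = screen.ErrorModel(0.8, 0.05, 0.2)
        m = np.linspace(0, 0.3, 50)
        p = screen.p_value(m, model, 3)
        assert np.all(np.diff(p) < 0)

    def test_bad_coverage_rejected(self):
        with pytest.raises(ValueError):
            screen.null_interval(screen.ErrorModel(1.0, 0.1, 0.2), 3, 1.5)


@pytest.fixture(scope="module")
def plate():
    conds = ["ctrl"] * 12 + ["slow"] * 3 + ["null"] * 3
    spec = simulate.PlateSimSpec(
        conditions=conds,
        effects={"slow": {"stimulated_speed": -0.5}},
        well_effect_sd=0.15,
        base_params=simulate.CellSimParams(n_cells=80),
    )
    return simulate.make_plate(spec, seed=5)


class TestPlateIntegration:
    def test_normalization_reduces_cv(self, plate):
        wide = plate.pivot_table(
            index=["well", "condition"], columns="population", values="stimulated_speed"
        ).reset_index()
        null_wells = wide[wide["condition"] != "slow"]
        raw_cv = null_wells["experimental"].std() / null_wells["experimental"].mean()
        fit = screen.fit_trendline(
            wide["experimental"].to_numpy(), wide["control"].to_numpy()
        )
        out = screen.normalize(
            wide["experimental"].to_numpy(), wide["control"].to_numpy(), fit
        )
        norm = out["normalized"].to_numpy()[(wide["condition"] != "slow").to_numpy()]
        norm_cv = np.std(norm) / np.mean(norm)
        assert norm_cv < raw_cv

    def test_injected_effect_recovered(self, plate):
        cond_scores, _, _ = screen.analyze_screen(plate)
        row = cond_scores[
            (cond_scores["condition"] == "slow")
            & (cond_scores["score_type"] == "stimulated_speed")
        ].iloc[0]
        assert row["mean_score"] == pytest.approx(-0.5, abs=0.05)
        assert row["outside_ci"]

    def test_null_condition_not_called(self, plate):
        cond_scores, _, _ = screen.analyze_screen(plate)
        row = cond_scores[
            (cond_scores["condition"] == "null")
            & (cond_scores["score_type"] == "stimulated_speed")
        ].iloc[0]
        assert abs(row["mean_score"]) < 0.15
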