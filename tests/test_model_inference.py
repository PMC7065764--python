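"""Gaussian GLM machinery: fits, AICc selection, averaging, partitioning."""

import math
from itertools import permutations

import numpy as np
import pandas as pd
import pytest

from fragdep.model_inference import (
    all_subsets,
    average_model,
    compare_nested_by_aic,
    confidence_set,
    fit_gaussian,
    hierarchical_partition,
    refit_excluding,
    screen_collinearity,
    select_buffer,
    standardize_predictors,
)


def _random_design(rng, n, p):
    X = pd.DataFrame(rng.standard_normal((n, p)),
                     columns=[f"x{i}" for i in range(p)])
    beta = rng.standard_normal(p)
    y = pd.Series(X.to_numpy() @ beta + rng.standard_normal(n), index=X.index)
    return y, X


class TestStandardizePredictors:
    def test_mean_zero_sd_one(self, rng):
        X = pd.DataFrame(rng.gamma(2.0, 3.0, size=(20, 3)), columns=list("abc"))
        Xs, params = standardize_predictors(X)
        assert np.allclose(Xs.mean(), 0, atol=1e-12)
        assert np.allclose(Xs.std(ddof=1), 1, atol=1e-12)

    def test_idempotent(self, rng):
        X = pd.DataFrame(rng.standard_normal((15, 2)), columns=list("ab"))
        Xs, _ = standardize_predictors(X)
        Xss, _ = standardize_predictors(Xs)
        pd.testing.assert_frame_equal(Xs, Xss)

    def test_hand_arithmetic_sample_sd(self):
        Xs, params = standardize_predictors(pd.DataFrame({"x": [1.0, 2.0, 3.0]}))
        assert Xs["x"].tolist() == pytest.approx([-1.0, 0.0, 1.0])
        assert params.loc["x", "sd"] == pytest.approx(1.0)

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            standardize_predictors(pd.DataFrame({"x": [2.0, 2.0, 2.0]}))


class TestFitGaussian:
    def test_normal_equations_hand_solution(self):
        X = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0]})
        fit = fit_gaussian([1.0, 2.0, 2.0, 4.0], X, ["x"])
        assert fit.params["x"] == pytest.approx(0.9, abs=1e-12)
        assert fit.params["Intercept"] == pytest.approx(0.0, abs=1e-12)

    def test_intercept_only_is_mean(self, rng):
        y = rng.standard_normal(10) + 3
        fit = fit_gaussian(y, pd.DataFrame(index=range(10)), [])
        assert fit.params["Intercept"] == pytest.approx(y.mean())
        assert fit.r2 == pytest.approx(0.0, abs=1e-12)

    def test_perfect_fit_flagged(self):
        X = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0, 5.0]})
        fit = fit_gaussian(2 * X["x"] + 1, X, ["x"])
        assert fit.r2 == pytest.approx(1.0)
        assert fit.aic == -math.inf and fit.loglik == math.inf

    def test_oracle_equivalence_random_designs(self):
        # coefficients must match an explicit normal-equations solve
        rng = np.random.default_rng(123)
        worst = 0.0
        for _ in range(100):
            n = int(rng.integers(8, 31))
            p = int(rng.integers(1, 6))
            y, X = _random_design(rng, n, p)
            fit = fit_gaussian(y, X)
            M = np.column_stack([np.ones(n), X.to_numpy()])
            beta = np.linalg.solve(M.T @ M, M.T @ y.to_numpy())
            worst = max(worst, np.abs(fit.params.to_numpy() - beta).max())
        assert worst < 1e-8

    def test_aicc_small_sample_correction(self, rng):
        y, X = _random_design(rng, 12, 2)
        fit = fit_gaussian(y, X)
        assert fit.k == 4  # intercept + 2 slopes + sigma^2
        assert fit.aicc == pytest.approx(fit.aic + 2 * 4 * 5 / (12 - 4 - 1))

    def test_rank_deficient_names_aliased_terms(self, rng):
        X = pd.DataFrame(rng.standard_normal((10, 1)), columns=["a"])
        X["b"] = X["a"]
        with pytest.raises(ValueError, match="aliased"):
            fit_gaussian(rng.standard_normal(10), X)

    def test_too_few_observations(self, rng):
        y, X = _random_design(rng, 4, 3)
        with pytest.raises(ValueError, match="too small"):
            fit_gaussian(y, X)


class TestCompareNested:
    def test_linear_data_prefers_linear(self, rng):
        x = np.linspace(-2, 2, 40)
        X = pd.DataFrame({"x": x, "x2": x ** 2})
        y = 1.5 * x + rng.normal(0, 0.3, 40)
        chosen, table = compare_nested_by_aic(y, X, ["x"], ["x2"])
        assert chosen.terms == ("x",)

    def test_curved_data_prefers_quadratic(self, rng):
        x = np.linspace(-2, 2, 40)
        X = pd.DataFrame({"x": x, "x2": x ** 2})
        y = x ** 2 + rng.normal(0, 0.1, 40)
        chosen, _ = compare_nested_by_aic(y, X, ["x"], ["x2"])
        assert "x2" in chosen.terms

    def test_tie_goes_to_smaller_model(self, rng):
        y, X = _random_design(rng, 20, 1)
        chosen, _ = compare_nested_by_aic(y, X, ["x0"], [])
        assert chosen.terms == ("x0",)


class TestCollinearity:
    def test_orthogonal_predictors_untouched(self):
        X = pd.DataFrame({"a": [1, -1, 1, -1, 1, -1, 1, -1.0],
                          "b": [1, 1, -1, -1, 1, 1, -1, -1.0]})
        assert X["a"] @ X["b"] == 0
        retained, report = screen_collinearity(X)
        assert retained == ["a", "b"]
        assert all(v == pytest.approx(1.0, abs=1e-9) for v in report["vif"].values())

    def test_duplicated_predictor_removed(self, rng):
        X = pd.DataFrame({"a": rng.standard_normal(20)})
        X["b"] = X["a"]
        X["c"] = rng.standard_normal(20)
        retained, report = screen_collinearity(X)
        assert len(retained) == 2 and "c" in retained
        assert report["removed"][0][1] == math.inf

    def test_near_duplicate_pair_vif_closed_form(self, rng):
        a = rng.standard_normal(200)
        X = pd.DataFrame({"a": a, "b": a + 0.1 * rng.standard_normal(200)})
        r = X.corr().loc["a", "b"]
        retained, report = screen_collinearity(X, vif_max=5.0)
        assert len(retained) == 1
        assert report["removed"][0][1] == pytest.approx(1 / (1 - r ** 2), rel=1e-6)
        assert report["flagged_pairs"]


class TestAllSubsetsAndAveraging:
    def test_enumeration_counts(self, rng):
        y, X = _random_design(rng, 30, 2)
        assert len(all_subsets(y, X).fits) == 4
        y7, X7 = _random_design(rng, 40, 7)
        assert len(all_subsets(y7, X7).fits) == 128

    def test_weights_sum_to_one_best_delta_zero(self, rng):
        y, X = _random_design(rng, 30, 4)
        ms = all_subsets(y, X)
        assert ms.weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert ms.delta[0] == 0.0

    def test_quadratic_rides_with_parent(self, rng):
        x = rng.standard_normal(40)
        X = pd.DataFrame({"x": x, "x^2": x ** 2,
                          "z": rng.standard_normal(40)})
        y = x + 0.5 * x ** 2 + rng.normal(0, 0.5, 40)
        ms = all_subsets(y, X, forced_quadratic={"x^2": "x"})
        assert len(ms.fits) == 4  # subsets over {x, z} only
        for f in ms.fits:
            assert ("x^2" in f.terms) == ("x" in f.terms)

    def test_confidence_set_rule(self, rng):
        y, X = _random_design(rng, 30, 3)
        ms = all_subsets(y, X)
        cs = confidence_set(ms, delta_max=2.0)
        assert all(d <= 2.0 + 1e-12 for d in
                   [f.aicc - ms.fits[0].aicc for f in cs.fits])
        assert cs.weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert cs.fits[0].terms == ms.fits[0].terms

    def test_singleton_set_averaging_degenerates_exactly(self, rng):
        # with one overwhelming predictor, the intercept-only rival is > 2
        # AICc behind, so the confidence set is a singleton
        x = np.linspace(0, 1, 40)
        X = pd.DataFrame({"x": x})
        y = 10 * x + rng.normal(0, 0.05, 40)
        cs = confidence_set(all_subsets(y, X))
        assert len(cs.fits) == 1
        avg = average_model(cs)
        best = cs.fits[0]
        for t in ("Intercept", *best.terms):
            assert avg.loc[t, "estimate"] == best.params[t]
            assert avg.loc[t, "se"] == best.bse[t]
            assert avg.loc[t, "ri"] == 1.0

    def test_weighted_mean_hand_value(self, rng):
        y, X = _random_design(rng, 30, 2)
        ms = all_subsets(y, X)
        cs = confidence_set(ms, delta_max=np.inf)  # keep all four models
        avg = average_model(cs)
        idx = [i for i, f in enumerate(cs.fits) if "x0" in f.terms]
        w = cs.weights[idx] / cs.weights[idx].sum()
        betas = np.array([cs.fits[i].params["x0"] for i in idx])
        assert avg.loc["x0", "estimate"] == pytest.approx(float(w @ betas))
        assert avg.loc["x0", "ri"] == pytest.approx(cs.weights[idx].sum())

    def test_term_in_every_model_ri_one(self, rng):
        y, X = _random_design(rng, 30, 2)
        cs = confidence_set(all_subsets(y, X), delta_max=np.inf)
        avg = average_model(cs)
        assert avg.loc["Intercept", "ri"] == pytest.approx(1.0)


class TestHierarchicalPartition:
    def test_single_predictor_equals_simple_r2(self, rng):
        y, X = _random_design(rng, 25, 1)
        part = hierarchical_partition(y, X)
        assert part.independent["x0"] == pytest.approx(
            fit_gaussian(y, X, ["x0"]).r2)

    def test_orthogonal_predictors_no_joint_effect(self):
        # balanced +/-1 design: exactly orthogonal columns
        a = np.array([1, 1, -1, -1, 1, 1, -1, -1.0])
        b = np.array([1, -1, 1, -1, 1, -1, 1, -1.0])
        X = pd.DataFrame({"a": a, "b": b})
        y = 2 * a + 0.5 * b + np.array([0.1, -0.1, 0.05, -0.05, 0.02, -0.02, 0.0, 0.0])
        part = hierarchical_partition(y, X)
        assert part.independent["a"] == pytest.approx(
            fit_gaussian(y, X, ["a"]).r2, abs=1e-10)
        assert abs(part.joint["a"]) < 1e-10
        assert abs(part.joint["b"]) < 1e-10

    @pytest.mark.parametrize("p", [2, 3, 4, 5, 6])
    def test_independent_effects_sum_to_full_r2(self, p):
        rng = np.random.default_rng(p)
        y, X = _random_design(rng, 30, p)
        part = hierarchical_partition(y, X)
        assert part.independent.sum() == pytest.approx(part.r2_full, abs=1e-8)

    def test_matches_permutation_average_oracle(self):
        # independent effect == mean R^2 gain over all orderings (Shapley form)
        rng = np.random.default_rng(11)
        y, X = _random_design(rng, 20, 3)
        part = hierarchical_partition(y, X)
        cols = list(X.columns)
        r2 = {}
        for perm in permutations(cols):
            for i in range(len(cols) + 1):
                key = frozenset(perm[:i])
                if key not in r2:
                    r2[key] = fit_gaussian(y, X, sorted(key)).r2 if key else 0.0
        for k in cols:
            gains = []
            for perm in permutations(cols):
                pos = perm.index(k)
                gains.append(r2[frozenset(perm[:pos + 1])] - r2[frozenset(perm[:pos])])
            assert part.independent[k] == pytest.approx(np.mean(gains), abs=1e-10)

    def test_percentages_sum_to_100(self, rng):
        y, X = _random_design(rng, 25, 3)
        part = hierarchical_partition(y, X)
        assert part.percentages.sum() == pytest.approx(100.0)


class TestBufferSelectionAndOutliers:
    def test_signal_radius_beats_noise_radius(self, rng):
        idx = pd.RangeIndex(30)
        y = pd.Series(rng.standard_normal(30), index=idx)
        candidates = {
            250: pd.Series(rng.standard_normal(30), index=idx),
            1000: y + 0.01 * pd.Series(rng.standard_normal(30), index=idx),
        }
        chosen, table = select_buffer({"resp": y}, candidates)
        assert chosen == 1000
        assert len(table) == 2

    def test_single_candidate_trivial(self, rng):
        idx = pd.RangeIndex(20)
        y = pd.Series(rng.standard_normal(20), index=idx)
        chosen, table = select_buffer(
            {"resp": y}, {500: pd.Series(rng.standard_normal(20), index=idx)})
        assert chosen == 500

    def test_table_covers_responses_by_radii(self, rng):
        idx = pd.RangeIndex(20)
        responses = {f"r{i}": pd.Series(rng.standard_normal(20), index=idx)
                     for i in range(3)}
        candidates = {r: pd.Series(rng.standard_normal(20), index=idx)
                      for r in (250, 500, 1000)}
        _, table = select_buffer(responses, candidates)
        assert len(table) == 9

    def test_refit_excluding_nothing_is_identity(self, rng):
        y, X = _random_design(rng, 20, 2)
        y.index = X.index = [f"S{i}" for i in range(20)]
        before, after, dr2 = refit_excluding(y, X, [])
        assert dr2 == 0.0
        pd.testing.assert_series_equal(before.params, after.params)

    def test_refit_excluding_planted_outlier_raises_r2(self):
        rng = np.random.default_rng(5)
        x = np.linspace(0, 1, 25)
        y = pd.Series(2 * x + rng.normal(0, 0.1, 25),
                      index=[f"S{i}" for i in range(25)])
        y.iloc[10] += 8.0  # contaminated site
        X = pd.DataFrame({"x": x}, index=y.index)
        before, after, dr2 = refit_excluding(y, X, ["S10"])
        assert dr2 > 0.2

    def test_unknown_exclusion_id_raises(self, rng):
        y, X = _random_design(rng, 10, 1)
        y.index = X.index = [f"S{i}" for i in range(10)]
        with pytest.raises(KeyError):
            refit_excluding(y, X, ["nope"])

    def test_excluding_too_many_sites_fails(self, rng):
        y, X = _random_design(rng, 6, 2)
        y.index = X.index = [f"S{i}" for i in range(6)]
        with pytest.raises(ValueError):
            refit_excluding(y, X, ["S0", "S1", "S2"])
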