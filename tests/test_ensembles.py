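import numpy as np
import pandas as pd
import pytest

import seedmenus as sm
from seedmenus.ensembles import CandidateSet
from seedmenus.metrics import CVResult, MetricSet
from seedmenus.model_space import ModelSpec


def _result(family, variables, tss, boyce=0.5, auc=0.8, aicc=100.0,
            prediction=None, importance=None, curves=None):
    spec = ModelSpec(family, tuple(variables))
    mean = MetricSet(auc=auc, tss=tss, boyce=boyce, aicc=aicc)
    if prediction is None:
        prediction = np.full((3, 3), 0.5)
    return CVResult(spec=spec, runs=pd.DataFrame(), mean=mean,
                    mean_prediction=np.asarray(prediction, dtype=float),
                    mean_importance=importance or {v: 1.0 for v in variables},
                    curves=curves or {}, n_runs=1)


class TestSelectCandidates:
    def test_weights_are_normalized_tss(self):
        results = [_result("tree_ensemble", ("SP",), 0.6),
                   _result("tree_ensemble", ("WP",), 0.4),
                   _result("tree_ensemble", ("Tmax",), -0.1, boyce=-0.2)]
        cs = sm.select_candidates(results, n_keep=10)
        assert len(cs.candidates) == 2  # negative-Boyce model filtered
        np.testing.assert_allclose(cs.weights, [0.6, 0.4])

    def test_single_survivor_gets_weight_one(self):
        cs = sm.select_candidates([_result("tree_ensemble", ("SP",), 0.5)])
        np.testing.assert_allclose(cs.weights, [1.0])

    def test_nothing_passes_filters_keeps_best_with_warning(self):
        results = [_result("tree_ensemble", ("SP",), 0.3, boyce=-0.5),
                   _result("tree_ensemble", ("WP",), 0.6, boyce=-0.1)]
        with pytest.warns(UserWarning, match="best-TSS"):
            cs = sm.select_candidates(results)
        assert cs.candidates[0].spec.variables == ("WP",)

    def test_aicc_breaks_near_ties_for_likelihood_families(self):
        results = [_result("maxent_like", ("SP",), 0.600, aicc=200.0),
                   _result("maxent_like", ("WP",), 0.595, aicc=100.0),
                   _result("maxent_like", ("Tmax",), 0.40, aicc=50.0)]
        cs = sm.select_candidates(results, n_keep=2)
        assert cs.candidates[0].spec.variables == ("WP",)  # tie -> lower AICc
        assert cs.candidates[1].spec.variables == ("SP",)

    def test_thirty_total_candidates_across_three_families(self):
        sets = []
        for fam in ("smooth_additive", "tree_ensemble", "maxent_like"):
            results = [_result(fam, (v,), 0.4 + 0.01 * i, aicc=100.0 + i)
                       for i, v in enumerate(sm.COVARIATE_CODES)]
            sets.append(sm.select_candidates(results, n_keep=10))
        assert sum(len(cs.candidates) for cs in sets) == 30
        for cs in sets:
            assert cs.weights.sum() == pytest.approx(1.0, abs=1e-9)


class TestFamilyEnsemble:
    def test_weighted_mean_hand_example(self):
        a = _result("tree_ensemble", ("SP",), 0.6,
                    prediction=np.full((2, 2), 0.8))
        b = _result("tree_ensemble", ("WP",), 0.4,
                    prediction=np.full((2, 2), 0.3))
        cs = sm.select_candidates([a, b])
        ens = sm.predict_family_ensemble(cs)
        np.testing.assert_allclose(ens, 0.6 * 0.8 + 0.4 * 0.3)

    def test_identical_candidates_reproduce_themselves(self):
        pred = np.random.default_rng(0).uniform(size=(3, 3))
        results = [_result("tree_ensemble", (v,), 0.5, prediction=pred)
                   for v in ("SP", "WP")]
        cs = sm.select_candidates(results)
        np.testing.assert_allclose(sm.predict_family_ensemble(cs), pred)

    def test_convexity(self):
        rng = np.random.default_rng(1)
        preds = [rng.uniform(size=(4, 4)) for _ in range(3)]
        results = [_result("tree_ensemble", (v,), 0.3 + 0.1 * i,
                           prediction=p)
                   for i, (v, p) in enumerate(zip(("SP", "WP", "Tmax"),
                                                  preds))]
        cs = sm.select_candidates(results)
        ens = sm.predict_family_ensemble(cs)
        lo = np.min(np.stack(preds), axis=0)
        hi = np.max(np.stack(preds), axis=0)
        assert np.all(ens >= lo - 1e-12) and np.all(ens <= hi + 1e-12)


class TestSeLayer:
    def test_identical_candidates_zero_se(self):
        pred = np.full((2, 2), 0.4)
        results = [_result("tree_ensemble", (v,), 0.5, prediction=pred)
                   for v in ("SP", "WP")]
        cs = sm.select_candidates(results)
        np.testing.assert_allclose(sm.se_layer(cs), 0.0)

    def test_two_candidate_hand_example(self):
        a = _result("tree_ensemble", ("SP",), 0.5,
                    prediction=np.full((2, 2), 0.2))
        b = _result("tree_ensemble", ("WP",), 0.5,
                    prediction=np.full((2, 2), 0.8))
        cs = sm.select_candidates([a, b])
        # SD = 0.4243 over {0.2, 0.8}; SE = SD / sqrt(2) = 0.3
        np.testing.assert_allclose(sm.se_layer(cs), 0.3, atol=1e-12)
        np.testing.assert_allclose(sm.se_layer(cs, mode="sd"),
                                   0.42426, atol=1e-4)

    def test_invariant_to_candidate_order(self):
        rng = np.random.default_rng(2)
        preds = [rng.uniform(size=(3, 3)) for _ in range(3)]
        res = [_result("tree_ensemble", (v,), 0.5, prediction=p)
               for v, p in zip(("SP", "WP", "Tmax"), preds)]
        cs1 = sm.select_candidates(res)
        cs2 = sm.select_candidates(res[::-1])
        np.testing.assert_allclose(sm.se_layer(cs1), sm.se_layer(cs2))

    def test_single_candidate_warns_and_returns_zero(self):
        cs = sm.select_candidates([_result("tree_ensemble", ("SP",), 0.5)])
        with pytest.warns(UserWarning, match="single"):
            np.testing.assert_allclose(sm.se_layer(cs), 0.0)


class TestOverallEnsemble:
    def test_mean_of_three(self):
        rasters = {"a": np.full((2, 2), 0.3), "b": np.full((2, 2), 0.6),
                   "c": np.full((2, 2), 0.9)}
        np.testing.assert_allclose(sm.overall_ensemble(rasters), 0.6)

    def test_identical_rasters_unchanged(self):
        r = np.random.default_rng(3).uniform(size=(3, 3))
        np.testing.assert_allclose(sm.overall_ensemble([r, r, r]), r,
                                   atol=1e-15)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sm.overall_ensemble([np.zeros((2, 2)), np.zeros((3, 3))])


class TestRelativeImportance:
    def test_single_family_normalization(self):
        r = _result("smooth_additive", ("SP", "WP"), 0.5,
                    importance={"SP": 2.0, "WP": 2.0})
        cs = sm.select_candidates([r])
        imp = sm.relative_importance([cs])
        assert imp["SP"] == pytest.approx(50.0)
        assert imp["WP"] == pytest.approx(50.0)

    def test_rows_sum_to_100(self):
        rng = np.random.default_rng(4)
        sets = []
        for fam in ("smooth_additive", "maxent_like"):
            res = [_result(fam, ("SP", "WP", "Tmax"), 0.5,
                           importance={c: rng.uniform(0.1, 5)
                                       for c in ("SP", "WP", "Tmax")})
                   for _ in range(3)]
            sets.append(sm.select_candidates(res))
        imp = sm.relative_importance(sets)
        assert imp.sum() == pytest.approx(100.0, abs=0.05)

    def test_codes_absent_from_family_get_zero(self):
        r = _result("maxent_like", ("SP",), 0.5, importance={"SP": 3.0})
        imp = sm.relative_importance([sm.select_candidates([r])],
                                     codes=["SP", "WP"])
        assert imp["WP"] == 0.0
        assert imp["SP"] == pytest.approx(100.0)


class TestResponseCurves:
    def _curved_result(self, family, variables, tss, curves):
        return _result(family, variables, tss, curves=curves)

    def test_flat_candidate_gives_flat_average(self):
        g = np.linspace(0, 1, 50)
        r = self._curved_result("maxent_like", ("SP",), 0.5,
                                {"SP": (g, np.full(50, 0.4))})
        out = sm.response_curves([sm.select_candidates([r])], top_k=1)
        assert np.ptp(out["SP"]["pooled"].to_numpy()) < 1e-6

    def test_averaging_two_known_curves(self):
        g = np.linspace(0, 1, 50)
        a = self._curved_result("maxent_like", ("SP",), 0.5,
                                {"SP": (g, g)})
        b = self._curved_result("maxent_like", ("SP",), 0.5,
                                {"SP": (g, 1 - g)})
        cs = sm.select_candidates([a, b])
        out = sm.response_curves([cs], top_k=1)
        np.testing.assert_allclose(out["SP"]["maxent_like"], 0.5, atol=1e-12)

    def test_monotone_generator_recovered_in_pooled_curve(self, species_data):
        """End-to-end: the pooled SP curve of a species generated with a
        positive SP coefficient trends upward."""
        from scipy import stats
        res = sm.cross_validate(ModelSpec("maxent_like", ("SP", "Tmax")),
                                species_data, n_runs=3, seed=17)
        cs = CandidateSet("maxent_like", [res], np.array([1.0]))
        out = sm.response_curves([cs], top_k=2)
        rho = stats.spearmanr(out["SP"]["value"], out["SP"]["pooled"]).statistic
        assert rho > 0.5
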