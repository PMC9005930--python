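import numpy as np
import pandas as pd
import pytest

import seedmenus as sm
from seedmenus.algorithms import (fit_maxent_like, fit_smooth_additive,
                                  fit_tree_ensemble, make_training_data)
from seedmenus.algorithms.base import TrainingData
from seedmenus.model_space import ModelSpec


def _fit_family(family, stack, presence_cells, codes, seed=1, **kw):
    spec = ModelSpec(family, tuple(codes))
    if family == "maxent_like":
        bg = sm.sample_pseudo_absences(stack, presence_cells, family,
                                       seed=seed)
        p = stack.table(cells=presence_cells, codes=list(codes))
        b = stack.table(cells=bg, codes=list(codes))
        return fit_maxent_like(spec, p, b, seed=seed, **kw), p, b
    absn = sm.sample_pseudo_absences(stack, presence_cells, family, seed=seed)
    data = make_training_data(stack, presence_cells, absn, codes,
                              balance_weights=(family == "smooth_additive"))
    fitter = {"smooth_additive": fit_smooth_additive,
              "tree_ensemble": fit_tree_ensemble}[family]
    return fitter(spec, data, seed=seed, **kw), data, None


FAMILIES = ["smooth_additive", "tree_ensemble", "maxent_like"]


@pytest.mark.filterwarnings("ignore::UserWarning")
class TestFittingContract:
    """Shared conformance battery for the three learner families."""

    @pytest.mark.parametrize("family", FAMILIES)
    def test_predictions_in_unit_interval(self, family, small_stack,
                                          presence_cells):
        kw = {"n_trees": 50} if family == "tree_ensemble" else {}
        model, *_ = _fit_family(family, small_stack, presence_cells,
                                ["SP", "Tmax"], **kw)
        preds = model.predict(small_stack.table(codes=["SP", "Tmax"]))
        assert np.all(preds >= 0) and np.all(preds <= 1)

    @pytest.mark.parametrize("family", FAMILIES)
    def test_deterministic_given_seed_and_data(self, family, small_stack,
                                               presence_cells):
        kw = {"n_trees": 50} if family == "tree_ensemble" else {}
        m1, *_ = _fit_family(family, small_stack, presence_cells,
                             ["SP", "WP"], seed=7, **kw)
        m2, *_ = _fit_family(family, small_stack, presence_cells,
                             ["SP", "WP"], seed=7, **kw)
        tbl = small_stack.table(codes=["SP", "WP"])
        np.testing.assert_array_equal(m1.predict(tbl), m2.predict(tbl))

    @pytest.mark.parametrize("family", ["smooth_additive", "tree_ensemble"])
    def test_single_class_labels_rejected(self, family, small_stack):
        spec = ModelSpec(family, ("SP",))
        tbl = small_stack.table(codes=["SP"]).head(50)
        data = TrainingData(tbl, np.ones(50), np.ones(50))
        fitter = {"smooth_additive": fit_smooth_additive,
                  "tree_ensemble": fit_tree_ensemble}[family]
        with pytest.raises(ValueError):
            fitter(spec, data, seed=0)

    @pytest.mark.parametrize("family", FAMILIES)
    def test_strong_signal_species_holdout_auc(self, family, species_data,
                                               small_stack):
        """Every family discriminates a strongly range-restricted virtual
        species (|beta| = 3, 300 records) with held-out AUC >= 0.8."""
        kw = {"n_trees": 200} if family == "tree_ensemble" else {}
        res = sm.cross_validate(ModelSpec(family, ("SP", "Tmax")),
                                species_data, n_runs=5, seed=31,
                                fit_kwargs=kw, collect_curves=False,
                                collect_prediction=False)
        assert res.mean.auc >= 0.8


@pytest.mark.filterwarnings("ignore::UserWarning")
class TestSmoothAdditive:
    def test_signal_term_has_higher_edf_than_noise(self, small_stack,
                                                   signal_species):
        """A covariate the generator actually uses keeps appreciable
        effective degrees of freedom; a pure-noise covariate in the same
        model is shrunk toward zero."""
        occ = sm.sample_occurrences(signal_species, 400, seed=21)
        pres = sm.rasterize_presences(occ, small_stack.grid)
        model, *_ = _fit_family("smooth_additive", small_stack, pres,
                                ["SP", "WP"])  # WP is noise
        assert model.term_complexity("SP") > model.term_complexity("WP")

    def test_constant_covariate_has_near_zero_edf(self, small_stack,
                                                  presence_cells):
        spec = ModelSpec("smooth_additive", ("SP", "WP"))
        absn = sm.sample_pseudo_absences(small_stack, presence_cells,
                                         "smooth_additive", seed=3)
        data = make_training_data(small_stack, presence_cells, absn,
                                  ("SP", "WP"), balance_weights=True)
        data.table["WP"] = 1.0  # degenerate term
        model = fit_smooth_additive(spec, data)
        assert model.term_complexity("WP") < 0.1

    def test_minimum_presence_floor(self, small_stack, presence_cells):
        spec = ModelSpec("smooth_additive", ("SP",))
        absn = sm.sample_pseudo_absences(small_stack, presence_cells[:5],
                                         "smooth_additive", seed=1)
        data = make_training_data(small_stack, presence_cells[:5], absn,
                                  ("SP",))
        with pytest.raises(ValueError, match="presences"):
            fit_smooth_additive(spec, data, min_presences=20)

    def test_serialization_round_trip(self, small_stack, presence_cells):
        from seedmenus.algorithms.smooth import PenalizedAdditiveModel
        model, data, _ = _fit_family("smooth_additive", small_stack,
                                     presence_cells, ["SP"])
        back = PenalizedAdditiveModel.from_dict(model.to_dict())
        np.testing.assert_allclose(back.predict(data.table),
                                   model.predict(data.table), atol=1e-12)


@pytest.mark.filterwarnings("ignore::UserWarning")
class TestTreeEnsemble:
    def test_separable_toy_data_training_auc_one(self):
        x = np.concatenate([np.zeros(30), np.ones(30)])
        tbl = pd.DataFrame({"SP": x})
        data = TrainingData(tbl, (x > 0.5).astype(int), np.ones(60))
        model = fit_tree_ensemble(ModelSpec("tree_ensemble", ("SP",)), data,
                                  n_trees=50, seed=0)
        p = model.predict(tbl)
        assert sm.auc(p[30:], p[:30]) == 1.0

    def test_label_permutation_destroys_signal(self, small_stack):
        rng = np.random.default_rng(3)
        cells = rng.choice(small_stack.valid_cells, size=500, replace=False)
        tbl = small_stack.table(cells=cells, codes=["SP"]).reset_index(drop=True)
        labels = rng.permutation(
            np.repeat([0, 1], 250))  # labels independent of covariates
        train, test = np.arange(400), np.arange(400, 500)
        data = TrainingData(tbl.iloc[train], labels[train], np.ones(400))
        model = fit_tree_ensemble(ModelSpec("tree_ensemble", ("SP",)), data,
                                  n_trees=100, seed=4)
        p = model.predict(tbl.iloc[test])
        a = sm.auc(p[labels[test] == 1], p[labels[test] == 0])
        assert abs(a - 0.5) < 0.15

    def test_invalid_tree_count(self, small_stack, presence_cells):
        with pytest.raises(ValueError):
            _fit_family("tree_ensemble", small_stack, presence_cells,
                        ["SP"], n_trees=0)


@pytest.mark.filterwarnings("ignore::UserWarning")
class TestMaxent:
    def test_raw_output_sums_to_one_over_background(self, small_stack,
                                                    presence_cells):
        model, p, b = _fit_family("maxent_like", small_stack, presence_cells,
                                  ["SP", "Tmax"])
        assert model.raw(b).sum() == pytest.approx(1.0, abs=1e-9)

    def test_uninformative_data_gives_uniform_raw(self):
        """Presences indistinguishable from background carry no signal:
        the regularized fit leaves the raw distribution near-uniform."""
        rng = np.random.default_rng(5)
        vals = rng.uniform(size=800)
        p = pd.DataFrame({"SP": vals[:100]})
        b = pd.DataFrame({"SP": vals})
        model = fit_maxent_like(ModelSpec("maxent_like", ("SP",)), p, b,
                                regularization=10.0, seed=1)
        raw = model.raw(b)
        assert raw.max() / raw.min() < 1.01

    def test_monotone_presence_selection_gives_positive_linear_term(self):
        rng = np.random.default_rng(6)
        bg_vals = rng.uniform(-1, 1, 2000)
        pres_vals = np.sort(bg_vals)[-200:]  # presences at the high end
        p = pd.DataFrame({"SP": pres_vals})
        b = pd.DataFrame({"SP": bg_vals})
        model = fit_maxent_like(ModelSpec("maxent_like", ("SP",)), p, b,
                                features=frozenset({"linear"}), seed=2)
        (idx,) = [i for i, (_, lab) in enumerate(model.feature_labels)
                  if lab == "linear:SP"]
        assert model.coef[idx] > 0

    def test_all_constant_covariates_rejected(self):
        p = pd.DataFrame({"SP": np.ones(20)})
        b = pd.DataFrame({"SP": np.ones(50)})
        with pytest.raises(ValueError, match="constant"):
            fit_maxent_like(ModelSpec("maxent_like", ("SP",)), p, b, seed=0)

    def test_parameter_count_counts_nonzero_coefficients(self, small_stack,
                                                         presence_cells):
        model, *_ = _fit_family("maxent_like", small_stack, presence_cells,
                                ["SP"])
        assert model.parameter_count() == int(
            (np.abs(model.coef) > 1e-8).sum())

    def test_serialization_round_trip(self, small_stack, presence_cells):
        import json
        from seedmenus.algorithms.maxent import MaxentModel
        model, p, b = _fit_family("maxent_like", small_stack, presence_cells,
                                  ["SP", "Tmax"])
        back = MaxentModel.from_dict(json.loads(json.dumps(model.to_dict())))
        np.testing.assert_allclose(back.predict(b), model.predict(b),
                                   atol=1e-12)
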