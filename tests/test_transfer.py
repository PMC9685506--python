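"""Transfer core: source CV fit, adaptation, refit, stacking, meta."""

import numpy as np
import pandas as pd
import pytest

from driftgbm import features, sampler, transfer
from helpers import FIXED_HP, cv_selection_oracle
from helpers import toy_matrix as as_matrix


def identity_split(columns):
    cols = tuple(columns)
    return features.FeatureSplit(
        common=cols, unique_source=(), unique_target=(),
        source_roster=cols, target_roster=cols,
    )


class TestHyperparams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"tree_depth": 1, "learning_rate": 0.05, "min_child_weight": 1},
            {"tree_depth": 3, "learning_rate": 0.5, "min_child_weight": 1},
            {"tree_depth": 3, "learning_rate": 0.05, "min_child_weight": 0},
        ],
    )
    def test_printed_ranges_enforced(self, kwargs):
        with pytest.raises(ValueError):
            transfer.GbmHyperparams(**kwargs)


class TestFitSource:
    def test_single_point_grid_selected(self, toy_xy):
        X, y = toy_xy
        model, hp, _ = transfer.fit_source(
            as_matrix(X, y), grid=[FIXED_HP], seed=0, cv=3, max_rounds=60
        )
        assert hp.tree_depth == FIXED_HP.tree_depth
        assert hp.n_trees >= 1
        assert len(model.cv_results) == 1

    def test_separable_toy_data_perfect_training_auroc(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(200, 2)), columns=["a", "b"])
        y = (X["a"] > 0).astype(int).to_numpy()
        model, _, _ = transfer.fit_source(
            as_matrix(X, y), grid=[FIXED_HP], seed=0, cv=3, max_rounds=60
        )
        assert roc_auc_score(y, model.predict(X)) == 1.0

    def test_selection_matches_exhaustive_grid_oracle(self, toy_xy):
        X, y = toy_xy
        candidates = [
            transfer.GbmHyperparams(2, 0.05, 1),
            transfer.GbmHyperparams(6, 0.1, 2),
            transfer.GbmHyperparams(4, 0.02, 8),
        ]
        model, hp, _ = transfer.fit_source(
            as_matrix(X, y), grid=candidates, seed=3, cv=4, max_rounds=60
        )
        best = cv_selection_oracle(X, y, candidates, seed=3, cv=4, max_rounds=60)
        assert (hp.tree_depth, hp.min_child_weight) == (
            candidates[best].tree_depth,
            candidates[best].min_child_weight,
        )

    def test_single_class_rejected(self, toy_xy):
        X, _ = toy_xy
        with pytest.raises(ValueError, match="both classes"):
            transfer.fit_source(as_matrix(X, np.zeros(len(X), dtype=int)), grid=[FIXED_HP])

    def test_empty_grid_rejected(self, toy_xy):
        X, y = toy_xy
        with pytest.raises(ValueError, match="grid"):
            transfer.fit_source(as_matrix(X, y), grid=[])


@pytest.fixture(scope="module")
def fitted_source(toy_xy):
    X, y = toy_xy
    model, _, _ = transfer.fit_source(
        as_matrix(X, y), grid=[FIXED_HP], seed=0, cv=3, max_rounds=60
    )
    return model


class TestAdapt:
    def test_zero_new_rounds_is_prediction_identical(self, fitted_source, toy_xy):
        X, y = toy_xy
        split = identity_split(X.columns)
        adapted = transfer.adapt_source(
            fitted_source, as_matrix(X, y), split, n_new_rounds=0
        )
        np.testing.assert_array_equal(adapted.predict(X), fitted_source.predict(X))
        assert adapted.n_source_trees == fitted_source.n_trees

    def test_adaptation_appends_trees_and_does_not_mutate_source(
        self, fitted_source, toy_xy
    ):
        X, y = toy_xy
        n_before = fitted_source.n_trees
        split = identity_split(X.columns)
        adapted = transfer.adapt_source(
            fitted_source, as_matrix(X, y), split, n_new_rounds=30, seed=1
        )
        assert fitted_source.n_trees == n_before
        assert adapted.n_trees >= n_before

    def test_all_missing_row_finite_probability(self, fitted_source, toy_xy):
        X, _ = toy_xy
        row = pd.DataFrame([[np.nan, np.nan]], columns=X.columns)
        p = fitted_source.predict(row)
        assert 0.0 < p[0] < 1.0

    def test_incompatible_input_space_rejected(self, fitted_source):
        X2 = pd.DataFrame(np.zeros((10, 1)), columns=["other"])
        split = identity_split(X2.columns)
        with pytest.raises(ValueError):
            transfer.adapt_source(
                fitted_source, as_matrix(X2, np.tile([0, 1], 5)), split, n_new_rounds=5
            )


class TestRefit:
    def test_unique_target_feature_gets_importance(self, fitted_source):
        rng = np.random.default_rng(2)
        n = 400
        X = pd.DataFrame(
            {"a": rng.normal(size=n), "b": rng.normal(size=n), "f_new": rng.normal(size=n)}
        )
        y = (X["f_new"] > 0).astype(int).to_numpy()
        split = features.FeatureSplit(
            common=("a", "b"), unique_source=(), unique_target=("f_new",),
            source_roster=("a", "b"), target_roster=("a", "b", "f_new"),
        )
        refitted = transfer.refit_target(
            as_matrix(X, y), fitted_source.hyperparams, split=split, seed=0
        )
        assert refitted.feature_importance().get("f_new", 0.0) > 0.0

    def test_determinism(self, fitted_source, toy_xy):
        X, y = toy_xy
        a = transfer.refit_target(as_matrix(X, y), FIXED_HP, seed=7)
        b = transfer.refit_target(as_matrix(X, y), FIXED_HP, seed=7)
        np.testing.assert_array_equal(a.predict(X), b.predict(X))

    def test_source_only_features_rejected(self, toy_xy):
        X, y = toy_xy
        split = features.FeatureSplit(
            common=("f1",), unique_source=("f0",), unique_target=(),
            source_roster=("f0", "f1"), target_roster=("f1",),
        )
        with pytest.raises(ValueError, match="source-only"):
            transfer.refit_target(as_matrix(X, y), FIXED_HP, split=split)


class TestStacking:
    def test_faithful_rows_are_plain_predictions(self, fitted_source, toy_xy):
        X, y = toy_xy
        split = identity_split(X.columns)
        dev = as_matrix(X, y)
        adapted = transfer.adapt_source(fitted_source, dev, split, n_new_rounds=0)
        refitted = transfer.refit_target(dev, FIXED_HP, seed=0)
        H = transfer.build_stacking_matrix(adapted, refitted, dev, mode="faithful")
        assert len(H.y) == len(y)
        np.testing.assert_allclose(H.p_adapted, adapted.predict(X), atol=1e-7)
        np.testing.assert_allclose(H.p_refitted, refitted.predict(X), atol=1e-7)
        # in-sample, a learnable problem ranks positives above negatives
        assert H.p_refitted[y == 1].mean() > H.p_refitted[y == 0].mean()

    def test_oof_row_count_and_bounds(self, fitted_source, toy_xy):
        X, y = toy_xy
        split = identity_split(X.columns)
        dev = as_matrix(X, y)
        adapted = transfer.adapt_source(fitted_source, dev, split, n_new_rounds=10, seed=0)
        refitted = transfer.refit_target(dev, FIXED_HP, seed=0)
        H = transfer.build_stacking_matrix(
            adapted, refitted, dev, mode="oof", k_folds=3, seed=0,
            source_model=fitted_source,
        )
        assert len(H.y) == len(y)
        assert np.all((H.p_adapted >= 0) & (H.p_adapted <= 1))

    def test_oof_needs_at_least_two_folds(self, fitted_source, toy_xy):
        X, y = toy_xy
        dev = as_matrix(X, y)
        split = identity_split(X.columns)
        adapted = transfer.adapt_source(fitted_source, dev, split, n_new_rounds=0)
        refitted = transfer.refit_target(dev, FIXED_HP, seed=0)
        with pytest.raises(ValueError, match="k_folds"):
            transfer.build_stacking_matrix(
                adapted, refitted, dev, mode="oof", k_folds=1, source_model=fitted_source
            )


class TestMeta:
    def test_identical_base_predictions_preserve_auroc(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(0)
        p = rng.uniform(size=500)
        y = (rng.uniform(size=500) < p).astype(int)
        H = transfer.StackingMatrix(p, p.copy(), y, mode="faithful")
        meta = transfer.fit_meta(H)
        ens = meta.predict(p, p)
        assert roc_auc_score(y, ens) == pytest.approx(roc_auc_score(y, p))

    def test_informative_column_dominates_noise(self):
        """When one base model is pure noise, the meta-learner leans on
        the informative one and the ensemble matches its AUROC."""
        from sklearn.metrics import roc_auc_score

        gaps = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 800
            signal = rng.normal(size=n)
            y = (signal + 0.7 * rng.normal(size=n) > 0).astype(int)
            p_ref = 1.0 / (1.0 + np.exp(-signal))
            p_noise = rng.uniform(size=n)
            H = transfer.StackingMatrix(p_noise, p_ref, y, mode="faithful")
            meta = transfer.fit_meta(H, seed=seed)
            assert abs(meta.coef[1]) > abs(meta.coef[0])
            ens_auc = roc_auc_score(y, meta.predict(p_noise, p_ref))
            gaps.append(ens_auc - roc_auc_score(y, p_ref))
        assert abs(np.mean(gaps)) < 0.01

    def test_separable_matrix_finite_coefficients(self):
        y = np.array([0] * 50 + [1] * 50)
        p = np.linspace(0.01, 0.99, 100)
        H = transfer.StackingMatrix(p, p.copy(), y, mode="faithful")
        meta = transfer.fit_meta(H)
        assert np.all(np.isfinite(meta.coef))

    def test_degenerate_matrix_rejected(self):
        y = np.array([0, 1] * 20)
        const = np.full(40, 0.5)
        with pytest.raises(ValueError, match="degenerate"):
            transfer.fit_meta(transfer.StackingMatrix(const, const.copy(), y, "faithful"))


class TestBundle:
    def test_serialization_round_trip_bit_identical(self, tmp_path, fitted_source, toy_xy):
        X, y = toy_xy
        split = identity_split(X.columns)
        bundle = transfer.fit_transfer(
            fitted_source, as_matrix(X, y), split, seed=0, k_folds=3
        )
        before = {
            "transfer": bundle.predict(X),
            "transported": bundle.predict_transported(X),
            "refitted": bundle.predict_refitted(X),
        }
        loaded = transfer.TransferModelBundle.load(bundle.save(tmp_path / "bundle"))
        for key, val in before.items():
            got = getattr(loaded, "predict" if key == "transfer" else f"predict_{key}")(X)
            np.testing.assert_array_equal(got, val)

    def test_probabilities_bounded_on_random_inputs(self, fitted_source, toy_xy):
        X, y = toy_xy
        split = identity_split(X.columns)
        bundle = transfer.fit_transfer(
            fitted_source, as_matrix(X, y), split, seed=0, k_folds=3
        )
        rng = np.random.default_rng(0)
        Xr = pd.DataFrame(rng.normal(scale=10, size=(1000, 2)), columns=X.columns)
        for fn in (bundle.predict, bundle.predict_transported, bundle.predict_refitted):
            p = fn(Xr)
            assert np.all((p >= 0) & (p <= 1))

    def test_transported_provenance_proves_no_target_exposure(
        self, fitted_source, toy_xy
    ):
        X, y = toy_xy
        rng = np.random.default_rng(9)
        X_t = X + rng.normal(scale=0.1, size=X.shape)
        split = identity_split(X.columns)
        bundle = transfer.fit_transfer(
            fitted_source, as_matrix(X_t, y), split, seed=0, k_folds=3
        )
        prov = bundle.provenance
        assert prov["transported_training_fingerprint"] == fitted_source.fingerprint
        assert prov["transported_training_fingerprint"] != prov["target_fingerprint"]
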