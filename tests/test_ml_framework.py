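import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from conftest import make_feature_table
from multibiodx.feature_assembly import FeatureTable
from multibiodx.ml_framework import (
    CLASSIFIERS,
    EmptySelectionError,
    Evaluation,
    FrameworkSpec,
    ModelConfig,
    UnsupportedRankingError,
    cross_validate,
    decision_scores,
    enumerate_configs,
    evaluate,
    fit_classifier,
    holdout_split,
    permutation_test,
    rank_features,
    roc_auc,
    run_framework,
    select_features,
)


class TestEnumerate:
    def test_paper_default_grid_is_280(self):
        configs = enumerate_configs(FrameworkSpec())
        assert len(configs) == 280
        blood = [c for c in configs if c.input_set == "Blood"]
        assert len(blood) == 40
        assert not any(c.fs_method in ("PCA", "RFE") for c in blood)

    def test_single_choice_grid(self):
        spec = FrameworkSpec(input_sets=("EEG",), fs_methods=("None",),
                             classifiers=("SVM",), cv_schemes=("LOO",))
        assert len(enumerate_configs(spec)) == 1

    def test_blood_only_with_all_fs_requested(self):
        spec = FrameworkSpec(input_sets=("Blood",))
        assert len(enumerate_configs(spec)) == 40

    def test_empty_component_rejected(self):
        with pytest.raises(ValueError):
            enumerate_configs(FrameworkSpec(classifiers=()))

    def test_blood_pca_config_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig("Blood", "PCA", "SVM", "LOO")


class TestHoldoutSplit:
    def test_study_sized_split(self):
        ft = make_feature_table(n_per_group=50, seed=0)
        ft.groups.iloc[:1] = ft.groups.iloc[:1]  # no-op, keep 50/50
        # emulate 49/50 by dropping one SZ subject
        keep = ft.data.index[1:]
        ft = ft.subset(keep)
        train, test = holdout_split(ft, ratio=3.0, seed=1)
        assert (test.groups == "SZ").sum() == 12
        assert (test.groups == "HC").sum() == 12
        assert train.n_subjects + test.n_subjects == 99

    def test_small_split_floor(self):
        ft = make_feature_table(n_per_group=8)
        train, test = holdout_split(ft, ratio=3.0, seed=0)
        assert test.n_subjects == 4
        assert (test.groups == "SZ").sum() == 2

    def test_seed_determinism_and_disjointness(self):
        ft = make_feature_table(n_per_group=20)
        t1 = holdout_split(ft, seed=3)
        t2 = holdout_split(ft, seed=3)
        assert list(t1[1].data.index) == list(t2[1].data.index)
        assert set(t1[0].data.index).isdisjoint(t1[1].data.index)


class TestSelectFeatures:
    def test_none_is_identity(self, rng):
        X = rng.random((20, 5))
        y = np.repeat([0, 1], 10)
        Xr, sel = select_features(X, y, "None")
        assert np.array_equal(Xr, X)
        assert sel.support.all()

    def test_anova_keeps_separating_feature(self, rng):
        n = 100
        y = np.repeat([0, 1], n // 2)
        X = np.column_stack([y * 3.0 + rng.normal(0, 0.3, n),
                             rng.standard_normal(n)])
        Xr, sel = select_features(X, y, "ANOVA")
        assert sel.support.tolist() == [True, False]
        assert Xr.shape == (n, 1)

    def test_anova_empty_selection_raises(self, rng):
        X = rng.standard_normal((30, 4))
        y = np.repeat([0, 1], 15)
        with pytest.raises(EmptySelectionError):
            select_features(X, y, "ANOVA", params={"anova_alpha": 1e-12})

    def test_pca_respects_rank(self, rng):
        base = rng.standard_normal((40, 3))
        X = base @ rng.standard_normal((3, 10))
        y = np.repeat([0, 1], 20)
        Xr, sel = select_features(X, y, "PCA")
        assert Xr.shape[1] <= 3
        assert not sel.feature_preserving

    def test_rfe_keeps_configured_fraction(self, rng):
        X = rng.standard_normal((40, 10))
        y = np.repeat([0, 1], 20)
        Xr, sel = select_features(X, y, "RFE")
        assert Xr.shape[1] == 5
        assert sel.support.sum() == 5

    def test_transform_replayable_on_new_data(self, rng):
        X = rng.standard_normal((30, 8))
        y = np.repeat([0, 1], 15)
        _, sel = select_features(X, y, "RFE")
        Xt = sel.transform(rng.standard_normal((5, 8)))
        assert Xt.shape == (5, 4)


class TestClassifiers:
    def _separable(self, rng, n=40):
        y = np.repeat([0, 1], n // 2)
        X = rng.standard_normal((n, 2)) + 10 * y[:, None]
        return X, y

    @pytest.mark.parametrize("kind", CLASSIFIERS)
    def test_separable_data_learned(self, rng, kind):
        X, y = self._separable(rng)
        model = fit_classifier(X, y, kind, params={"rf_n_estimators": 50})
        assert np.mean(model.predict(X) == y) == 1.0
        assert decision_scores(model, X).shape == (40,)

    def test_knn_one_neighbour_memorizes(self, rng):
        X = rng.standard_normal((30, 4))
        y = np.repeat([0, 1], 15)
        model = fit_classifier(X, y, "KNN", params={"knn_k": 1})
        assert np.mean(model.predict(X) == y) == 1.0

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_classifier(rng.random((10, 2)), np.zeros(10), "SVM")


class TestCrossValidate:
    def test_separable_any_scheme_is_perfect(self):
        ft = make_feature_table(n_per_group=10, n_features=4, effect=10.0, seed=1)
        for scheme in ("3fold", "5fold", "LOO"):
            cfg = ModelConfig("Blood", "None", "LDA", scheme)
            assert cross_validate(ft, cfg, seed=0) == 1.0

    def test_fold_count_exceeding_class_rejected(self):
        ft = make_feature_table(n_per_group=4)
        with pytest.raises(ValueError):
            cross_validate(ft, ModelConfig("Blood", "None", "LDA", "10fold"))

    def test_infold_selection_avoids_leakage_inflation(self, rng):
        # null data, many features: selecting on the full training set before
        # CV inflates accuracy; in-fold selection stays near chance
        n, p = 40, 300
        X = rng.standard_normal((n, p))
        y = np.repeat([0, 1], n // 2)
        idx = pd.Index([f"s{i}" for i in range(n)])
        ft = FeatureTable(pd.DataFrame(X, index=idx,
                                       columns=[f"f{i}" for i in range(p)]),
                          {f"f{i}": "EEG" for i in range(p)},
                          pd.Series(np.where(y == 1, "SZ", "HC"), index=idx))
        cfg = ModelConfig("EEG", "ANOVA", "LDA", "5fold")
        honest = cross_validate(ft, cfg, seed=0)

        # leaky variant computed by hand
        from sklearn.model_selection import StratifiedKFold
        Xs, sel = select_features(X, y, "ANOVA")
        accs = []
        for tr, va in StratifiedKFold(5, shuffle=True, random_state=0).split(Xs, y):
            m = fit_classifier(Xs[tr], y[tr], "LDA")
            accs.append(np.mean(m.predict(Xs[va]) == y[va]))
        leaky = float(np.mean(accs))
        assert leaky > honest + 0.1


class TestROC:
    def test_perfect_ranking(self):
        points, auc = roc_auc(np.array([0.1, 0.2, 0.8, 0.9]),
                              np.array([0, 0, 1, 1]))
        assert auc == 1.0
        assert tuple(points[0]) == (0.0, 0.0)
        assert tuple(points[-1]) == (1.0, 1.0)

    def test_constant_scores_are_chance(self):
        _, auc = roc_auc(np.ones(10), np.repeat([0, 1], 5))
        assert auc == 0.5

    def test_equals_mannwhitney_concordance(self, rng):
        y = rng.integers(0, 2, 60)
        y[:2] = [0, 1]
        s = rng.standard_normal(60)
        _, auc = roc_auc(s, y)
        u = mannwhitneyu(s[y == 1], s[y == 0], alternative="two-sided").statistic
        assert auc == pytest.approx(u / ((y == 1).sum() * (y == 0).sum()), abs=1e-12)

    def test_monotone_curve(self, rng):
        y = np.repeat([0, 1], 20)
        points, _ = roc_auc(rng.standard_normal(40), y)
        assert np.all(np.diff(points[:, 0]) >= 0)
        assert np.all(np.diff(points[:, 1]) >= 0)


class TestEvaluate:
    def test_perfect_and_degenerate_predictions(self):
        train = make_feature_table(n_per_group=20, effect=10.0, seed=0)
        test = make_feature_table(n_per_group=6, effect=10.0, seed=99)
        _, sel = select_features(train.data.to_numpy(), train.labels(), "None")
        model = fit_classifier(train.data.to_numpy(), train.labels(), "SVM")
        ev = evaluate(model, sel, test)
        assert ev.accuracy == ev.sensitivity == ev.specificity == 1.0

    def test_all_predicted_positive(self):
        class AlwaysSZ:
            def predict(self, X):
                return np.ones(len(X), dtype=int)

            def decision_function(self, X):
                return np.arange(len(X), dtype=float)

        test = make_feature_table(n_per_group=5)
        _, sel = select_features(test.data.to_numpy(), test.labels(), "None")
        ev = evaluate(AlwaysSZ(), sel, test)
        assert ev.sensitivity == 1.0
        assert ev.specificity == 0.0

    def test_confusion_arithmetic(self):
        ev = Evaluation(tp=11, fn=1, tn=11, fp=1,
                        roc_points=np.zeros((2, 2)), auc=0.9)
        assert ev.accuracy == pytest.approx(22 / 24)
        assert ev.sensitivity == pytest.approx(11 / 12)
        assert ev.specificity == pytest.approx(11 / 12)


class TestPermutationTest:
    def test_low_observed_accuracy_gives_large_p(self):
        ft = make_feature_table(n_per_group=16, effect=0.0, seed=3)
        cfg = ModelConfig("Blood", "None", "LDA", "3fold")
        p = permutation_test(ft, cfg, n_perm=49, seed=1, observed_accuracy=0.0)
        assert p == 1.0

    def test_unreachable_observed_accuracy_gives_zero_p(self):
        ft = make_feature_table(n_per_group=16, effect=0.0, seed=3)
        cfg = ModelConfig("Blood", "None", "LDA", "3fold")
        p = permutation_test(ft, cfg, n_perm=49, seed=1, observed_accuracy=1.01)
        assert p == 0.0

    def test_separated_groups_reach_significance(self):
        ft = make_feature_table(n_per_group=16, effect=3.0, seed=5)
        cfg = ModelConfig("Blood", "None", "LDA", "3fold")
        p = permutation_test(ft, cfg, n_perm=49, seed=2)
        assert p <= 0.05

    def test_plus_one_variant_never_zero(self):
        ft = make_feature_table(n_per_group=10, effect=0.0, seed=3)
        cfg = ModelConfig("Blood", "None", "LDA", "3fold")
        p = permutation_test(ft, cfg, n_perm=19, seed=1,
                             observed_accuracy=1.01, plus_one=True)
        assert p == pytest.approx(1 / 20)


class TestRankFeatures:
    def _fitted(self, ft, classifier="SVM", fs="None"):
        X, y = ft.data.to_numpy(), ft.labels()
        Xr, sel = select_features(X, y, fs)
        model = fit_classifier(Xr, y, classifier, params={"rf_n_estimators": 50})
        return model, sel

    def test_cardinality_of_top_five_percent(self):
        ft = make_feature_table(n_per_group=20, n_features=663, n_informative=0,
                                seed=2)
        model, sel = self._fitted(ft)
        ranking = rank_features(model, sel, ft, top_fraction=0.05)
        assert len(ranking) == 34

    def test_informative_feature_ranked_first(self):
        ft = make_feature_table(n_per_group=100, n_features=20, n_informative=1,
                                effect=3.0, seed=4)
        model, sel = self._fitted(ft, classifier="LR")
        ranking = rank_features(model, sel, ft)
        assert ranking.iloc[0]["feature"] == "f00"

    def test_pca_ranking_unsupported(self):
        ft = make_feature_table(n_per_group=20, n_features=10)
        model, sel = self._fitted(ft, fs="PCA")
        with pytest.raises(UnsupportedRankingError):
            rank_features(model, sel, ft)

    def test_ties_broken_by_name(self):
        ft = make_feature_table(n_per_group=10, n_features=6, n_informative=0)
        model, sel = self._fitted(ft)

        class Flat:
            coef_ = np.ones((1, 6))

        from sklearn.pipeline import Pipeline
        flat = Pipeline([("clf", Flat())])
        ranking = rank_features(flat, sel, ft, top_fraction=1.0)
        assert list(ranking["feature"]) == sorted(ft.data.columns)


class TestRunFramework:
    def test_restricted_grid_shape_and_columns(self):
        ft = make_feature_table(n_per_group=16, effect=1.5, seed=0)
        spec = FrameworkSpec(input_sets=("Blood",), fs_methods=("None", "ANOVA"),
                             classifiers=("LDA", "KNN"), cv_schemes=("3fold",))
        results = run_framework({"Blood": ft}, spec)
        assert len(results) == 4
        assert (results["error"] == "").all()
        assert results["auc"].between(0, 1).all()

    def test_failures_recorded_not_raised(self):
        ft = make_feature_table(n_per_group=4)
        spec = FrameworkSpec(input_sets=("Blood",), fs_methods=("None",),
                             classifiers=("LDA",), cv_schemes=("10fold",))
        results = run_framework({"Blood": ft}, spec)
        assert len(results) == 1
        assert results.iloc[0]["error"] != ""


def test_transform_depends_only_on_training_rows(rng):
    # replacing test rows by noise must leave the fitted transform unchanged
    ft = make_feature_table(n_per_group=20, n_features=15, seed=8)
    train, test = holdout_split(ft, seed=0)
    X, y = train.data.to_numpy(), train.labels()
    for method in ("ANOVA", "PCA", "RFE"):
        _, sel1 = select_features(X, y, method, seed=0)
        _, sel2 = select_features(X, y, method, seed=0)  # refit, same train
        probe = rng.standard_normal((7, 15))
        assert np.allclose(sel1.transform(probe), sel2.transform(probe))
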