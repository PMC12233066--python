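"""Drug-effect-category classifier: training sets, grouped CV, predictions."""

import numpy as np
import pandas as pd
import pytest
from pydantic import ValidationError
from morphoscreen._model import rng_from
from morphoscreen.classify import (
    DEFAULT_CATEGORIES,
    CategoryModel,
    ClassifierConfig,
    build_training_sets,
    cross_validate,
    predict_category,
    shuffle_labels_within_groups,
    train_category_model,
)
from morphoscreen.profiling import FEATURE_NAMES
from morphoscreen.synth import SyntheticSpec, synthesize_cell_table


def category_pools(length_means, n_cells=1500, seed=0):
    """Image-free cell pools with controllable separation in length."""
    pools = {}
    for i, (cat, lmean) in enumerate(length_means.items()):
        spec = SyntheticSpec(
            n_cells=n_cells, length_mean=lmean, length_sd=6.0,
            width_mean=15.0, width_sd=2.0, seed=seed + i,
        )
        pools[cat] = synthesize_cell_table(spec, condition=cat)
    return pools


def separable_six(seed=0, n_cells=1500):
    cats = list(DEFAULT_CATEGORIES)
    lengths = dict(zip(cats, (40.0, 65.0, 90.0, 115.0, 140.0, 165.0)))
    return category_pools(lengths, n_cells=n_cells, seed=seed)


@pytest.fixture(scope="module")
def small_cfg():
    return ClassifierConfig(
        n_train_bootstrap=10, train_sample_size=300, n_trees=100, seed=1
    )


@pytest.fixture(scope="module")
def six_matrix(small_cfg):
    return build_training_sets(separable_six(), small_cfg)


class TestConfig:
    def test_defaults_match_published_design(self):
        cfg = ClassifierConfig()
        assert len(cfg.categories) == 6
        assert cfg.n_train_bootstrap == 50
        assert cfg.train_sample_size == 1000

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"categories": ("only-one",)},
            {"categories": ("a", "a")},
            {"n_train_bootstrap": 1},
            {"train_sample_size": 1},
            {"cv_grouping": "bogus"},
            {"nope": 3},
        ],
    )
    def test_invalid(self, kwargs):
        with pytest.raises((ValidationError, ValueError)):
            ClassifierConfig(**kwargs)


class TestBuildTrainingSets:
    def test_two_categories_three_bootstraps(self):
        cfg = ClassifierConfig(
            categories=("a", "b"), n_train_bootstrap=3, train_sample_size=100
        )
        pools = category_pools({"a": 60.0, "b": 100.0}, n_cells=400)
        matrix = build_training_sets(pools, cfg)
        assert len(matrix) == 6
        assert sorted(set(matrix.conditions)) == ["a", "b"]

    def test_row_counts_and_sample_size(self, six_matrix, small_cfg):
        assert len(six_matrix) == 6 * small_cfg.n_train_bootstrap
        counts = pd.Series(six_matrix.conditions).value_counts()
        assert set(counts) == {small_cfg.n_train_bootstrap}
        assert set(six_matrix.meta["n_cells"]) == {small_cfg.train_sample_size}

    def test_groups_span_categories(self, six_matrix, small_cfg):
        df = six_matrix.meta
        for cat in DEFAULT_CATEGORIES:
            groups = set(df.loc[df["condition"] == cat, "group"])
            assert len(groups) == small_cfg.n_cv_groups

    def test_deterministic(self, small_cfg):
        pools = separable_six()
        a = build_training_sets(pools, small_cfg)
        b = build_training_sets(pools, small_cfg)
        np.testing.assert_array_equal(a.values, b.values)

    def test_missing_category_errors(self, small_cfg):
        pools = separable_six()
        del pools[DEFAULT_CATEGORIES[0]]
        with pytest.raises(ValueError, match="no cell pool"):
            build_training_sets(pools, small_cfg)

    def test_small_pool_warns(self, small_cfg, caplog):
        import logging

        cfg = small_cfg.model_copy(update={"train_sample_size": 1000})
        pools = separable_six(n_cells=100)
        with caplog.at_level(logging.WARNING):
            build_training_sets(pools, cfg)
        assert "highly correlated" in caplog.text


class TestTrain:
    def test_training_accuracy_at_least_oob(self, six_matrix, small_cfg):
        model = train_category_model(six_matrix, cfg=small_cfg)
        train_acc = (
            model.forest.predict(six_matrix.values) == six_matrix.conditions
        ).mean()
        assert train_acc >= model.forest.oob_score_

    def test_importances_normalized(self, six_matrix, small_cfg):
        model = train_category_model(six_matrix, cfg=small_cfg)
        assert model.importances.sum() == pytest.approx(1.0)
        assert (model.importances >= 0).all()
        assert model.feature_names == FEATURE_NAMES

    def test_single_class_errors(self, six_matrix, small_cfg):
        labels = ["same"] * len(six_matrix)
        with pytest.raises(ValueError, match="2 classes"):
            train_category_model(six_matrix, labels, small_cfg)

    def test_label_permutation_oob_near_chance(self, six_matrix, small_cfg):
        y = np.asarray(six_matrix.conditions).copy()
        rng_from(0).shuffle(y)
        model = train_category_model(six_matrix, y, small_cfg)
        n = len(y)
        p = 1.0 / 6.0
        half_width = 2.576 * np.sqrt(p * (1 - p) / n)
        assert model.forest.oob_score_ <= p + half_width + 0.05

    def test_duplicated_feature_importance_split(self):
        # impurity accounting under multicollinearity: with all features
        # considered at every split, duplicating a column cannot change the
        # chosen splits, so the copies share the original's importance.
        # (Under sqrt feature subsampling the duplicate's doubled inclusion
        # probability structurally inflates the pair by ~1.5x, so the
        # probe isolates the accounting from the sampling effect.)
        from sklearn.ensemble import RandomForestClassifier

        rng = rng_from(41)
        k, n_per = 6, 20
        X = rng.normal(0, 1, (k * n_per, 12))
        y = np.repeat([f"c{i}" for i in range(k)], n_per)
        X[:, 3] = np.repeat(np.linspace(0, 10, k), n_per) + rng.normal(
            0, 0.4, k * n_per
        )

        def forest(seed):
            return RandomForestClassifier(
                n_estimators=300, max_features=None, random_state=seed, n_jobs=1
            )

        base = forest(7).fit(X, y)
        j = int(np.argmax(base.feature_importances_))
        X13 = np.column_stack([X, X[:, j]])
        dup = forest(7).fit(X13, y)
        combined = dup.feature_importances_[j] + dup.feature_importances_[12]
        assert combined == pytest.approx(base.feature_importances_[j], rel=0.25)
        assert dup.feature_importances_.sum() == pytest.approx(1.0)

    def test_save_load_roundtrip(self, six_matrix, small_cfg, tmp_path):
        import json

        model = train_category_model(six_matrix, cfg=small_cfg)
        model.save(tmp_path / "m.pkl")
        back = CategoryModel.load(tmp_path / "m.pkl")
        np.testing.assert_array_equal(back.importances, model.importances)
        sidecar = json.loads((tmp_path / "m.pkl.json").read_text())
        assert sidecar["feature_names"] == list(FEATURE_NAMES)


class TestCrossValidate:
    def test_separable_categories_high_accuracy(self, six_matrix, small_cfg):
        result = cross_validate(six_matrix, cfg=small_cfg)
        assert result.accuracy >= 0.95

    def test_confusion_rows_normalized(self, six_matrix, small_cfg):
        result = cross_validate(six_matrix, cfg=small_cfg)
        np.testing.assert_allclose(result.confusion.sum(axis=1), 1.0, atol=1e-9)
        assert list(result.confusion.index) == sorted(DEFAULT_CATEGORIES)

    def test_permutation_null_near_chance(self, six_matrix, small_cfg):
        y = shuffle_labels_within_groups(
            six_matrix.conditions, six_matrix.groups, seed=5
        )
        result = cross_validate(six_matrix, y, cfg=small_cfg)
        n = len(y)
        p = 1.0 / 6.0
        half_width = 2.576 * np.sqrt(p * (1 - p) / n)
        assert abs(result.accuracy - p) <= half_width + 0.05

    def test_class_confined_to_one_group_errors(self, six_matrix, small_cfg):
        groups = np.asarray(six_matrix.groups).copy()
        sel = np.asarray(six_matrix.conditions) == DEFAULT_CATEGORIES[0]
        groups[sel] = "solo"
        with pytest.raises(ValueError, match="single group"):
            cross_validate(six_matrix, groups=groups, cfg=small_cfg)

    def test_deterministic(self, six_matrix, small_cfg):
        a = cross_validate(six_matrix, cfg=small_cfg)
        b = cross_validate(six_matrix, cfg=small_cfg)
        pd.testing.assert_frame_equal(a.confusion, b.confusion)
        assert a.accuracy == b.accuracy

    def test_accuracy_degrades_with_descriptor_noise(self, small_cfg):
        # per-descriptor noise scales sized to the between-category ranges
        scales = {
            "area_um2": 600.0, "perimeter_um": 120.0, "length_um": 50.0,
            "width_um": 6.0, "lw_ratio": 4.0, "compactness": 0.25,
        }
        accs = []
        for factor in (0.0, 1.0, 10.0):
            pools = separable_six(seed=3)
            rng = rng_from(17)
            for pool in pools.values():
                for col, s in scales.items():
                    noised = pool.df[col] + rng.normal(0, s * factor, len(pool))
                    pool.df[col] = np.abs(noised) + 1e-6
            matrix = build_training_sets(pools, small_cfg)
            accs.append(cross_validate(matrix, cfg=small_cfg).accuracy)
        assert accs[0] >= 0.95
        assert accs[0] + 0.02 >= accs[1] >= accs[2] - 0.02
        assert accs[2] < accs[0]

    def test_removing_top_feature_degrades_accuracy(self, small_cfg):
        # categories separated only in one synthetic feature column
        rng = rng_from(23)
        rows, labels, groups = [], [], []
        for c, center in enumerate(np.linspace(0, 10, 6)):
            for b in range(40):
                row = rng.normal(0, 1, 12)
                row[2] = center + rng.normal(0, 0.1)
                rows.append(row)
                labels.append(f"cat{c}")
                groups.append(str(b % 5))
        X = np.asarray(rows)
        cfg = small_cfg.model_copy(update={"n_trees": 300})
        full = cross_validate(X, labels, groups, cfg)
        X0 = X.copy()
        X0[:, 2] = 0.0
        ablated = cross_validate(X0, labels, groups, cfg)
        assert full.accuracy >= 0.95
        assert ablated.accuracy <= full.accuracy - 0.5


class TestPredict:
    def test_training_rows_get_their_own_labels(self, six_matrix, small_cfg):
        model = train_category_model(six_matrix, cfg=small_cfg)
        labels, proba = predict_category(model, six_matrix)
        assert (labels == six_matrix.conditions).mean() >= 0.95
        assert (proba.max(axis=1) > 1.0 / 6.0).all()

    def test_probabilities_sum_to_one(self, six_matrix, small_cfg):
        model = train_category_model(six_matrix, cfg=small_cfg)
        _, proba = predict_category(model, six_matrix)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)

    def test_feature_mismatch_lists_differences(self, six_matrix, small_cfg):
        model = train_category_model(six_matrix, cfg=small_cfg)
        bad = six_matrix.features.rename(columns={"mean_area": "total_area"})
        with pytest.raises(ValueError) as exc:
            predict_category(model, bad)
        assert "mean_area" in str(exc.value)
        assert "total_area" in str(exc.value)

    def test_uniform_shift_vs_heterogeneity_categories(self, small_cfg):
        # one drug-like response shifts means with small SDs, the other
        # inflates SDs: profiles must sort back to their generators
        rng = rng_from(31)

        def profile_row(kind):
            feats = {}
            for d in ("area", "perimeter", "length", "width", "lw_ratio",
                      "compactness"):
                if kind == "uniform-shift":
                    feats[f"mean_{d}"] = 10.0 + rng.normal(0, 0.3)
                    feats[f"sd_{d}"] = 1.0 + abs(rng.normal(0, 0.1))
                else:  # heterogeneous
                    feats[f"mean_{d}"] = 8.0 + rng.normal(0, 0.3)
                    feats[f"sd_{d}"] = 5.0 + abs(rng.normal(0, 0.5))
            return [feats[k] for k in FEATURE_NAMES]

        X, y, g = [], [], []
        for kind in ("uniform-shift", "heterogeneous"):
            for b in range(20):
                X.append(profile_row(kind))
                y.append(kind)
                g.append(str(b % 5))
        cfg = small_cfg.model_copy(update={"categories": (
            "uniform-shift", "heterogeneous")})
        result = cross_validate(np.asarray(X), y, g, cfg)
        assert result.accuracy >= 0.9


def test_shuffle_preserves_group_label_multisets():
    labels = ["a", "a", "b", "b", "c", "c"]
    groups = ["g1", "g1", "g1", "g2", "g2", "g2"]
    out = shuffle_labels_within_groups(labels, groups, seed=2)
    assert sorted(out[:3]) == ["a", "a", "b"]
    assert sorted(out[3:]) == ["b", "c", "c"]


def test_end_to_end_determinism(small_cfg):
    pools = separable_six(seed=9)
    m1 = build_training_sets(pools, small_cfg)
    m2 = build_training_sets(separable_six(seed=9), small_cfg)
    r1 = cross_validate(m1, cfg=small_cfg)
    r2 = cross_validate(m2, cfg=small_cfg)
    pd.testing.assert_frame_equal(r1.confusion, r2.confusion)
    model1 = train_category_model(m1, cfg=small_cfg)
    model2 = train_category_model(m2, cfg=small_cfg)
    np.testing.assert_array_equal(model1.importances, model2.importances)
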