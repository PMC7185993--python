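"""Donor-specificity model: confidence rule, training, CV, importances."""

import numpy as np
import pytest

from gtacore.donor import (
    DonorSpecificityModel,
    GdbtConfig,
    confidence_category,
)
from gtacore.features import FeatureDescriptor, FeatureMatrix

#: small ensemble for unit tests (the published defaults are exercised at
#: acceptance scale)
FAST = GdbtConfig(n_estimators=60, max_features=None)


def toy_matrix(rng, n_per_class=20, n_classes=3, n_features=8, shift=3.0):
    y = np.repeat(np.arange(n_classes), n_per_class)
    X = rng.normal(size=(len(y), n_features))
    for c in range(n_classes):
        X[y == c, c % n_features] += shift
    descs = [FeatureDescriptor(i + 1, "volume") for i in range(n_features)]
    labels = [f"class{c}" for c in y]
    return FeatureMatrix(X, descs, [f"s{i}" for i in range(len(y))], labels)


class TestConfidenceRule:
    @pytest.mark.parametrize(
        "probs,expected",
        [
            ((0.85, 0.05, 0.04, 0.03, 0.02, 0.01), "high"),
            ((1 / 6,) * 6, "low"),
            ((0.60, 0.20, 0.05, 0.05, 0.05, 0.05), "moderate"),
            ((0.40, 0.30, 0.10, 0.10, 0.05, 0.05), "low"),
        ],
    )
    def test_rule_examples(self, probs, expected):
        assert confidence_category(probs) == expected

    def test_exact_four_to_one_ratio_is_not_high(self):
        # p1 == 4 p2 -> excluded from high; difference 0.6 > 1/3 -> moderate
        probs = (0.8, 0.2, 0.0, 0.0, 0.0, 0.0)
        assert confidence_category(probs) == "moderate"

    def test_exact_one_third_difference_is_not_moderate(self):
        p2 = 0.125  # chosen so p1 - p2 is exactly the float 1/3; ratio < 4
        p1 = p2 + 1 / 3
        rest = (1.0 - p1 - p2) / 4
        probs = (p1, p2, rest, rest, rest, rest)
        assert p1 - p2 == 1 / 3 and p1 < 4 * p2
        assert confidence_category(probs) == "low"

    def test_partitions_the_simplex(self, rng):
        for _ in range(500):
            p = rng.dirichlet(np.ones(6))
            assert confidence_category(p) in {"high", "moderate", "low"}

    def test_invalid_vector_rejected(self):
        with pytest.raises(ValueError):
            confidence_category((0.5, 0.2, 0.1, 0.1, 0.05, 0.04))

    def test_absolute_rule_variant(self):
        probs = (0.4, 0.35, 0.15, 0.05, 0.03, 0.02)
        assert confidence_category(probs, rule="difference") == "low"
        assert confidence_category(probs, rule="absolute") == "moderate"


class TestTraining:
    def test_separable_toy_reaches_full_training_accuracy(self, rng):
        X = toy_matrix(rng, n_classes=2, shift=5.0)
        res = DonorSpecificityModel(X, config=FAST).fit()
        preds = res.estimator.predict(X.values)
        assert np.mean(preds == np.array(X.labels)) == 1.0

    def test_training_reproducible_for_fixed_config(self, rng):
        X = toy_matrix(rng)
        r1 = DonorSpecificityModel(X, config=FAST).fit()
        r2 = DonorSpecificityModel(X, config=FAST).fit()
        assert np.array_equal(
            r1.estimator.predict_proba(X.values), r2.estimator.predict_proba(X.values)
        )

    def test_single_class_rejected(self, rng):
        X = toy_matrix(rng, n_classes=1)
        with pytest.raises(ValueError):
            DonorSpecificityModel(X)

    def test_default_config_is_the_published_one(self):
        cfg = GdbtConfig()
        est = cfg.to_sklearn()
        assert est.n_estimators == 1600 and est.random_state == 10


class TestCrossValidation:
    def test_perfect_features_give_near_perfect_accuracy(self, rng):
        X = toy_matrix(rng, shift=6.0)
        cv = DonorSpecificityModel(X, config=FAST).cross_validate(k=5, seed=0)
        assert cv.accuracy >= 0.95
        assert cv.confusion.to_numpy().sum() == len(X.sequence_ids)

    def test_shuffled_labels_give_chance_accuracy(self, rng):
        from scipy.stats import binomtest

        accs = []
        n = 0
        for seed in range(2):
            y = np.repeat(np.arange(6), 20)
            X = rng.normal(size=(120, 10))
            labels = [f"c{v}" for v in rng.permutation(y)]
            m = FeatureMatrix(
                X,
                [FeatureDescriptor(i + 1, "asa") for i in range(10)],
                [f"s{i}" for i in range(120)],
                labels,
            )
            cv = DonorSpecificityModel(m, config=FAST).cross_validate(k=5, seed=seed)
            accs.append(cv.accuracy)
            n = len(labels)
        # pooled correct count indistinguishable from 1/6 at alpha = 0.01
        correct = int(round(np.mean(accs) * n))
        assert binomtest(correct, n, 1 / 6).pvalue > 0.01

    def test_small_class_triggers_fold_reduction_warning(self, rng):
        X = toy_matrix(rng, n_per_class=4, n_classes=2)
        with pytest.warns(UserWarning, match="reducing folds"):
            cv = DonorSpecificityModel(X, config=FAST).cross_validate(k=10, seed=0)
        assert cv.n_folds == 4


class TestPredictions:
    def test_resubstitution_recovers_labels_on_separable_data(self, rng):
        X = toy_matrix(rng, shift=5.0)
        res = DonorSpecificityModel(X, config=FAST).fit()
        preds = res.predict_with_confidence(X)
        agree = np.mean([p.predicted_class == l for p, l in zip(preds, X.labels)])
        assert agree >= 0.95
        for p in preds:
            assert p.class_probabilities.sum() == pytest.approx(1.0, abs=1e-9)
            assert p.predicted_class == res.classes_[np.argmax(p.class_probabilities)]

    def test_descriptor_mismatch_lists_missing_features(self, rng):
        X = toy_matrix(rng)
        res = DonorSpecificityModel(X, config=FAST).fit()
        other = FeatureMatrix(
            X.values[:, :4],
            X.descriptors[:4],
            X.sequence_ids,
            X.labels,
        )
        with pytest.raises(ValueError, match="missing"):
            res.predict_with_confidence(other)

    def test_degenerate_constant_row_yields_valid_probabilities(self, rng):
        X = toy_matrix(rng)
        res = DonorSpecificityModel(X, config=FAST).fit()
        flat = FeatureMatrix(
            np.tile(X.values.mean(axis=0), (1, 1)),
            X.descriptors,
            ["flat"],
        )
        pred = res.predict_with_confidence(flat)[0]
        assert pred.class_probabilities.sum() == pytest.approx(1.0, abs=1e-9)
        assert pred.confidence in {"high", "moderate", "low"}


class TestImportances:
    def test_dominant_feature_ranks_first_with_majority_share(self, rng):
        y = np.repeat(np.arange(2), 40)
        X = rng.normal(size=(80, 6)) * 0.1
        X[:, 3] = y * 4.0  # single dominant feature
        m = FeatureMatrix(
            X,
            [FeatureDescriptor(i + 1, "charge") for i in range(6)],
            [f"s{i}" for i in range(80)],
            [f"c{v}" for v in y],
        )
        imp = DonorSpecificityModel(m, config=FAST).fit().feature_importances()
        assert imp.iloc[0]["column_id"] == 4
        assert imp.iloc[0]["importance"] > 0.5
        assert imp["importance"].sum() == pytest.approx(1.0, abs=1e-9)
        assert list(imp.head(10)["band"]) == ["high"] * min(10, len(imp))

    def test_pure_noise_importances_stay_diffuse(self, rng):
        y = np.repeat(np.arange(2), 40)
        X = rng.normal(size=(80, 30))
        m = FeatureMatrix(
            X,
            [FeatureDescriptor(i + 1, "asa") for i in range(30)],
            [f"s{i}" for i in range(80)],
            [f"c{v}" for v in y],
        )
        imp = DonorSpecificityModel(m, config=FAST).fit().feature_importances()
        assert imp["importance"].mean() < 2 / 30

    def test_per_donor_importance_isolates_class_specific_column(self, rng):
        # class A determined solely by feature/column 7; class B by column 2
        y = np.repeat(["A", "B", "C"], 30)
        X = rng.normal(size=(90, 10)) * 0.2
        X[y == "A", 6] += 4.0
        X[y == "B", 1] += 4.0
        m = FeatureMatrix(
            X,
            [FeatureDescriptor(i + 1, "volume") for i in range(10)],
            [f"s{i}" for i in range(90)],
            list(y),
        )
        model = DonorSpecificityModel(m, config=FAST)
        imp_a = model.per_donor_importance("A")
        assert imp_a.iloc[0]["column_id"] == 7
        assert imp_a["importance"].sum() == pytest.approx(1.0, abs=1e-9)
        imp_b = model.per_donor_importance("B")
        assert imp_b.iloc[0]["column_id"] == 2

    def test_missing_class_rejected(self, rng):
        X = toy_matrix(rng)
        with pytest.raises(ValueError, match="absent"):
            DonorSpecificityModel(X, config=FAST).per_donor_importance("Xyl")

    def test_importance_comparison_joins_full_and_per_class_ranks(self, rng):
        X = toy_matrix(rng, n_classes=2, n_per_class=15)
        df = DonorSpecificityModel(X, config=FAST).importance_comparison()
        assert {"full_rank", "class0_rank", "class1_rank"} <= set(df.columns)
        assert len(df) == X.n_features


class TestRfBaseline:
    def test_empty_subset_rejected(self, rng):
        X = toy_matrix(rng)
        with pytest.raises(ValueError):
            DonorSpecificityModel(X).rf_baseline(feature_subset=[])

    def test_subset_restriction_hurts_when_signal_is_split(self, rng):
        # half the class signal on "site" features, half off-site
        y = np.repeat(np.arange(3), 30)
        X = rng.normal(size=(90, 12)) * 1.0
        site = [0, 1, 2]
        offsite = [6, 7, 8]
        for c in range(3):
            X[y == c, site[c]] += 1.2
            X[y == c, offsite[c]] += 1.2
        descs = [FeatureDescriptor(i + 1, "polarity") for i in range(12)]
        m = FeatureMatrix(X, descs, [f"s{i}" for i in range(90)], [f"c{v}" for v in y])
        model = DonorSpecificityModel(m)
        _, acc_full = model.rf_baseline(n_trees=100, k=5, seed=0)
        _, acc_site = model.rf_baseline(
            n_trees=100, k=5, seed=0, feature_subset=[descs[i] for i in site]
        )
        assert acc_full - acc_site >= 0.05

    def test_single_tree_weaker_than_forest_on_noisy_data(self, rng):
        y = np.repeat(np.arange(2), 60)
        X = rng.normal(size=(120, 10))
        X[:, 0] += y * 1.0  # weak signal
        m = FeatureMatrix(
            X,
            [FeatureDescriptor(i + 1, "charge") for i in range(10)],
            [f"s{i}" for i in range(120)],
            [f"c{v}" for v in y],
        )
        model = DonorSpecificityModel(m)
        _, acc1 = model.rf_baseline(n_trees=1, k=5, seed=0)
        _, acc300 = model.rf_baseline(n_trees=300, k=5, seed=0)
        assert acc1 <= acc300
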