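"""Shadow-feature screening, the forest classifier, CV machinery and ROC."""

import numpy as np
import pandas as pd
import pytest

from epiforest import (
    ImmunogenicityClassifier,
    ModelBundle,
    ShadowFeatureSelector,
    categorize,
    repeated_cv,
    roc_auc,
    roc_points,
)
from epiforest.model import (
    BundleSchemaError,
    NEGATIVE_HIGH,
    POSITIVE_HIGH,
    POSITIVE_LOW,
)


def brute_force_auc(scores, labels):
    """Pairwise oracle: (concordant + half-ties) / (n_pos * n_neg)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_ties(self):
        assert roc_auc([0.5] * 10, [1, 0] * 5) == 0.5

    def test_matches_pairwise_oracle_with_ties(self, rng):
        """Rank-sum AUC equals brute-force pair counting on 200 instances."""
        for _ in range(200):
            n = int(rng.integers(10, 50))
            # quantized scores inject ties
            scores = np.round(rng.uniform(0, 1, size=n), 1)
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                labels[0], labels[-1] = 0, 1
            assert roc_auc(scores, labels) == pytest.approx(
                brute_force_auc(scores, labels), abs=1e-12
            )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([0.1, 0.9], [1, 1])

    def test_string_labels_accepted(self):
        assert roc_auc([0.9, 0.1], ["immunogenic", "nonimmunogenic"]) == 1.0

    def test_curve_points_shape(self):
        pts = roc_points([0.9, 0.4, 0.2], [1, 0, 0])
        assert list(pts.columns) == ["fpr", "tpr", "threshold"]
        assert pts["tpr"].iloc[-1] == 1.0


class TestCategorize:
    @pytest.mark.parametrize(
        "score,expected",
        [
            (0.60, POSITIVE_HIGH),
            (0.45, POSITIVE_LOW),
            (0.30, NEGATIVE_HIGH),
            (0.50, POSITIVE_LOW),   # boundary: closed into the middle band
            (0.40, POSITIVE_LOW),   # boundary: closed into the middle band
            (0.0, NEGATIVE_HIGH),
            (1.0, POSITIVE_HIGH),
        ],
    )
    def test_score_bands(self, score, expected):
        assert categorize([score])[0] == expected

    def test_bands_partition_unit_interval(self):
        grid = np.linspace(0, 1, 1001)
        cats = categorize(grid)
        assert set(cats) == {NEGATIVE_HIGH, POSITIVE_LOW, POSITIVE_HIGH}
        # monotone: once the band steps up it never steps back
        order = {NEGATIVE_HIGH: 0, POSITIVE_LOW: 1, POSITIVE_HIGH: 2}
        steps = np.array([order[c] for c in cats])
        assert (np.diff(steps) >= 0).all()


class TestShadowSelector:
    def test_perfect_separator_confirmed_noise_rejected(self, rng):
        n = 300
        y = rng.integers(0, 2, size=n)
        X = pd.DataFrame(
            {
                "signal": y + rng.normal(0, 0.05, n),
                "noise1": rng.normal(size=n),
                "noise2": rng.normal(size=n),
                "noise3": rng.normal(size=n),
            }
        )
        sel = ShadowFeatureSelector(max_iter=20, n_trees=50, random_state=0).fit(X, y)
        assert sel.result_.status["signal"] == "confirmed"
        assert sel.result_.status["noise1"] == "rejected"
        assert sel.get_support(indices=True).tolist() == [0]

    def test_label_permuted_data_confirms_nothing(self, rng):
        """Null behavior: screened against shadows, shuffled labels confirm 0
        features in >= 95% of seeds."""
        confirmed = 0
        for seed in range(20):
            local = np.random.default_rng(seed)
            X = pd.DataFrame(local.normal(size=(150, 6)),
                             columns=[f"f{i}" for i in range(6)])
            y = local.integers(0, 2, size=150)
            sel = ShadowFeatureSelector(
                max_iter=12, n_trees=30, random_state=seed
            ).fit(X, y)
            confirmed += bool(sel.result_.confirmed)
        assert confirmed <= 1

    def test_single_class_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 3)))
        with pytest.raises(ValueError, match="two classes"):
            ShadowFeatureSelector().fit(X, np.zeros(30))

    def test_deterministic_under_fixed_seed(self, strong_features):
        X, y = strong_features
        r1 = ShadowFeatureSelector(max_iter=5, n_trees=30, random_state=3).fit(X, y)
        r2 = ShadowFeatureSelector(max_iter=5, n_trees=30, random_state=3).fit(X, y)
        assert (r1.status_ == r2.status_).all()
        pd.testing.assert_frame_equal(
            r1.result_.importance_history, r2.result_.importance_history
        )

    def test_every_feature_gets_a_final_status(self, strong_features):
        X, y = strong_features
        sel = ShadowFeatureSelector(max_iter=5, n_trees=30, random_state=1).fit(X, y)
        assert set(sel.status_.index) == set(X.columns)
        assert set(sel.status_.unique()) <= {"confirmed", "rejected", "tentative"}


class TestClassifierAndCV:
    def test_scores_in_unit_interval_and_schema_check(self, strong_features):
        X, y = strong_features
        clf = ImmunogenicityClassifier(n_trees=50, random_state=0).fit(X, y)
        scores = clf.predict_score(X)
        assert ((scores >= 0) & (scores <= 1)).all()
        with pytest.raises(ValueError, match="schema mismatch"):
            clf.predict_score(X.rename(columns={"C1": "Z1"}))

    def test_mtry_defaults_capped(self, strong_features):
        X, y = strong_features
        clf = ImmunogenicityClassifier(mode="antigen", n_trees=10, random_state=0)
        clf.fit(X, y)
        assert clf.mtry_ == 15
        clf2 = ImmunogenicityClassifier(mode="neoantigen", n_trees=10, random_state=0)
        clf2.fit(X.iloc[:, :10], y)
        assert clf2.mtry_ == 10  # capped at available features

    def test_cv_partitions_each_repeat(self, strong_features):
        X, y = strong_features
        cv = repeated_cv(
            ImmunogenicityClassifier(n_trees=20, random_state=0),
            X, y, n_repeats=2, random_state=0,
        )
        for _, grp in cv.oof.groupby("repeat"):
            assert sorted(grp["id"]) == sorted(X.index)
        assert len(cv.fold_aucs) == 10
        assert 0 <= cv.sensitivity <= 1 and 0 <= cv.specificity <= 1

    def test_cv_deterministic_under_fixed_seed(self, strong_features):
        X, y = strong_features
        make = lambda: repeated_cv(
            ImmunogenicityClassifier(n_trees=20, random_state=5),
            X, y, n_repeats=1, random_state=5,
        )
        a, b = make(), make()
        pd.testing.assert_frame_equal(a.oof, b.oof)
        assert a.auc == b.auc

    def test_too_small_dataset_rejected(self, strong_features):
        X, y = strong_features
        with pytest.raises(ValueError, match="too small"):
            repeated_cv(ImmunogenicityClassifier(), X.iloc[:8], y[:8])


class TestModelBundle:
    def test_save_load_predict_round_trip(self, tmp_path, strong_features, strong_dataset):
        from epiforest import train
        from epiforest.features import EpitopeFeaturizer

        X, y = strong_features
        fz = EpitopeFeaturizer().fit(strong_dataset)
        bundle, cv = train(X, y, mode="antigen", frequency_model=fz.frequency_model_,
                           n_trees=30, seed=1, n_repeats=1)
        before = bundle.predict(X)
        bundle.save(tmp_path / "model")
        loaded = ModelBundle.load(tmp_path / "model")
        after = loaded.predict(X)
        pd.testing.assert_frame_equal(before, after)
        assert loaded.mode == "antigen"
        assert loaded.metadata["data_fingerprint"] == bundle.metadata["data_fingerprint"]

    def test_schema_version_mismatch_refused(self, tmp_path, strong_features, strong_dataset):
        import json

        from epiforest import train
        from epiforest.features import EpitopeFeaturizer

        X, y = strong_features
        fz = EpitopeFeaturizer().fit(strong_dataset)
        bundle, _ = train(X, y, mode="antigen", frequency_model=fz.frequency_model_,
                          n_trees=10, seed=1, n_repeats=1)
        path = bundle.save(tmp_path / "model")
        meta = json.loads((path / "bundle.json").read_text())
        meta["schema_version"] = 99
        (path / "bundle.json").write_text(json.dumps(meta))
        with pytest.raises(BundleSchemaError):
            ModelBundle.load(path)

    def test_feature_schema_mismatch_lists_features(self, strong_features, strong_dataset):
        from epiforest import train
        from epiforest.features import EpitopeFeaturizer

        X, y = strong_features
        fz = EpitopeFeaturizer().fit(strong_dataset)
        bundle, _ = train(X, y, mode="antigen", frequency_model=fz.frequency_model_,
                          n_trees=10, seed=1, n_repeats=1)
        with pytest.raises(ValueError, match="C24"):
            bundle.predict(X.drop(columns=["C24"]))
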