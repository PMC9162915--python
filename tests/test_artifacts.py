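"""Artifact-filter contracts: region features, classifier, AUC, exclusion."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tmaquant.artifacts import (
    SpotMeasurement,
    apply_exclusion,
    auc_score,
    discordance_score,
    evaluate_auc,
    extract_regions,
    label_regions_with_truth,
    nonspecific_fraction,
    region_feature_matrix,
    stratified_patient_split,
    train_artifact_classifier,
)
from tmaquant.segmentation import SpotImage


def _empty_cells():
    return pd.DataFrame(
        {
            "spot_id": pd.Series(dtype=str),
            "clone": pd.Series(dtype=str),
            "y_px": pd.Series(dtype=float),
            "x_px": pd.Series(dtype=float),
            "positive": pd.Series(dtype=bool),
            "membrane_score": pd.Series(dtype=float),
            "region_id": pd.array([], dtype="Int64"),
        }
    )


def _stain_image(stain):
    return SpotImage(np.zeros_like(stain), stain, 1.0, "fx", "cloneA")


class TestRegionFeatures:
    def test_disc_region_is_nearly_circular(self, params):
        stain = np.zeros((120, 120), dtype=np.float32)
        rr, cc = np.ogrid[:120, :120]
        stain[(rr - 60) ** 2 + (cc - 60) ** 2 <= 30**2] = 0.5
        _, feats = extract_regions(_stain_image(stain), _empty_cells(), params)
        assert len(feats) == 1
        assert abs(feats[0].circularity - 1.0) < 0.05
        assert feats[0].stained_fraction > 0.9

    def test_elongated_region_has_low_circularity(self, params):
        stain = np.zeros((60, 220), dtype=np.float32)
        stain[28:33, 10:210] = 0.5  # 5 x 200 px bar
        _, feats = extract_regions(_stain_image(stain), _empty_cells(), params)
        assert len(feats) == 1
        assert feats[0].circularity < 0.2

    def test_blank_image_has_no_regions(self, params):
        stain = np.zeros((80, 80), dtype=np.float32)
        _, feats = extract_regions(_stain_image(stain), _empty_cells(), params)
        assert feats == []

    def test_cells_assigned_to_their_region(self, params):
        stain = np.zeros((120, 120), dtype=np.float32)
        rr, cc = np.ogrid[:120, :120]
        stain[(rr - 40) ** 2 + (cc - 40) ** 2 <= 20**2] = 0.5
        cells = pd.DataFrame(
            {
                "spot_id": ["s", "s"],
                "clone": ["cloneA"] * 2,
                "y_px": [40.0, 100.0],
                "x_px": [40.0, 100.0],
                "positive": [True, True],
                "membrane_score": [0.3, 0.9],
                "region_id": pd.array([None, None], dtype="Int64"),
            }
        )
        labels, feats = extract_regions(_stain_image(stain), cells, params)
        assert feats[0].cell_count == 1
        assert feats[0].mean_membrane_score == pytest.approx(0.3)
        assert cells.loc[0, "region_id"] == feats[0].region_id
        assert pd.isna(cells.loc[1, "region_id"])

    def test_truth_labels_follow_mask_overlap(self, params):
        stain = np.zeros((120, 120), dtype=np.float32)
        rr, cc = np.ogrid[:120, :120]
        stain[(rr - 40) ** 2 + (cc - 40) ** 2 <= 15**2] = 0.5
        stain[(rr - 90) ** 2 + (cc - 90) ** 2 <= 15**2] = 0.5
        labels, feats = extract_regions(_stain_image(stain), _empty_cells(), params)
        mask = np.zeros((120, 120), dtype=bool)
        mask[60:, 60:] = True  # covers only the second disc
        flags = label_regions_with_truth(labels, feats, mask)
        assert sorted(flags) == [False, True]


class TestAuc:
    def test_perfect_separation(self):
        assert auc_score([0.1, 0.2, 0.8, 0.9], [False, False, True, True]) == 1.0

    def test_all_ties_give_half(self):
        assert auc_score([0.5] * 6, [True, False, True, False, True, False]) == 0.5

    def test_hand_computed_pairwise_value(self):
        # pairs: (.5>.4)+(.5<.6)+(.7>.4)+(.7>.6) = 3 of 4
        assert auc_score([0.4, 0.6, 0.5, 0.7], [False, False, True, True]) == 0.75

    def test_missing_class_rejected(self):
        with pytest.raises(ValueError, match="no negative"):
            auc_score([0.1, 0.2], [True, True])
        with pytest.raises(ValueError, match="no positive"):
            auc_score([0.1, 0.2], [False, False])

    def test_matches_sklearn_on_random_instances(self, rng):
        from sklearn.metrics import roc_auc_score

        for _ in range(50):
            n = rng.integers(4, 60)
            scores = rng.choice([0.1, 0.25, 0.5, 0.8], size=n)  # force ties
            labels = rng.uniform(size=n) < 0.5
            if labels.all() or not labels.any():
                continue
            assert auc_score(scores, labels) == pytest.approx(
                roc_auc_score(labels, scores), abs=1e-12
            )


class TestClassifier:
    @staticmethod
    def _feature_table(n_per_entity=20, entities=("e1", "e2"), seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for entity in entities:
            for i in range(n_per_entity):
                pid = f"{entity}_{i}"
                specific = i % 2 == 0
                rows.append(
                    {
                        "patient_id": pid,
                        "entity": entity,
                        "spot_id": pid,
                        "clone": "cloneA",
                        "region_id": 1,
                        "area_um2": 10 ** rng.normal(2.3 if specific else 5.0, 0.1),
                        "circularity": 0.9 if specific else 0.7,
                        "mean_membrane_score": rng.normal(
                            0.9 if specific else 0.3, 0.02
                        ),
                        "stained_fraction": 0.3 if specific else 1.0,
                        "cell_count": 1 if specific else 200,
                        "truth_nonspecific": not specific,
                    }
                )
        return pd.DataFrame(rows)

    def test_stratified_split_rounds_half_up_per_entity(self):
        patients = pd.DataFrame(
            {
                "patient_id": [f"e1_{i}" for i in range(100)]
                + [f"e2_{i}" for i in range(10)],
                "entity": ["e1"] * 100 + ["e2"] * 10,
            }
        )
        train, val = stratified_patient_split(patients, 0.75, seed=0)
        e1_train = [p for p in train if p.startswith("e1")]
        e2_train = [p for p in train if p.startswith("e2")]
        assert len(e1_train) == 75  # 75% of 100
        assert len(e2_train) == 8  # 7.5 rounds half up
        assert set(train).isdisjoint(val)

    def test_split_is_deterministic(self):
        patients = pd.DataFrame(
            {"patient_id": [f"p{i}" for i in range(40)], "entity": ["e"] * 40}
        )
        assert stratified_patient_split(patients, 0.75, 7) == stratified_patient_split(
            patients, 0.75, 7
        )

    def test_separable_features_learned_perfectly(self):
        table = self._feature_table()
        clf = train_artifact_classifier(table, 0.75, seed=1)
        X = region_feature_matrix(table)
        acc = (clf.predict(X) == table["truth_nonspecific"].to_numpy()).mean()
        assert acc == 1.0
        val = table[table["patient_id"].isin(clf.validation_patients)]
        assert evaluate_auc(clf, val) == 1.0

    def test_training_is_deterministic(self):
        table = self._feature_table()
        c1 = train_artifact_classifier(table, 0.75, seed=3)
        c2 = train_artifact_classifier(table, 0.75, seed=3)
        assert np.array_equal(c1.weights, c2.weights)
        assert c1.train_patients == c2.train_patients

    def test_single_class_training_set_rejected(self):
        table = self._feature_table()
        table["truth_nonspecific"] = False
        with pytest.raises(ValueError, match="non-specific"):
            train_artifact_classifier(table, 0.75, seed=0)

    def test_classifier_json_roundtrip(self):
        from tmaquant.artifacts import ArtifactClassifier

        clf = train_artifact_classifier(self._feature_table(), 0.75, seed=1)
        again = ArtifactClassifier.from_json(clf.to_json())
        X = region_feature_matrix(self._feature_table())
        assert np.allclose(clf.score(X), again.score(X))


class TestFractionAndExclusion:
    @staticmethod
    def _cells(n, n_bad):
        return pd.DataFrame(
            {
                "spot_id": ["s"] * n,
                "clone": ["cloneA"] * n,
                "y_px": np.zeros(n),
                "x_px": np.zeros(n),
                "positive": [True] * n,
                "membrane_score": np.zeros(n),
                "region_id": pd.array(
                    [1] * n_bad + [None] * (n - n_bad), dtype="Int64"
                ),
            }
        )

    def test_fraction_arithmetic(self):
        assert nonspecific_fraction(self._cells(200, 0), {1}) == 0.0
        assert nonspecific_fraction(self._cells(200, 10), {1}) == pytest.approx(0.05)
        assert nonspecific_fraction(self._cells(0, 0), {1}) == 0.0

    def test_fraction_exact_against_generator_truth(self, cross_config):
        """With perfect region labels the fraction equals the planted one."""
        from tmaquant.synthetic import iter_cohort

        checked = 0
        for rec in iter_cohort(cross_config):
            for gt in rec.ground_truths:
                cls = gt.cell_class
                n = len(cls)
                if n == 0:
                    continue
                cells = pd.DataFrame(
                    {
                        "spot_id": ["s"] * n,
                        "clone": ["c"] * n,
                        "positive": [True] * n,
                        "membrane_score": np.zeros(n),
                        "region_id": pd.array(
                            [1 if c == "crossreactive_cell" else None for c in cls],
                            dtype="Int64",
                        ),
                    }
                )
                f = nonspecific_fraction(cells, {1})
                assert f == pytest.approx(gt.true_nonspecific_fraction, abs=1e-12)
                checked += 1
        assert checked > 0

    @staticmethod
    def _measurement(f):
        return SpotMeasurement(
            spot_id="s", clone_name="cloneA", positive_count=10, total_count=100,
            area_mm2=0.28, density=35.7, nonspecific_fraction=f,
        )

    def test_exclusion_boundary_is_closed_at_threshold(self):
        assert apply_exclusion(self._measurement(0.05), 0.05).excluded
        assert not apply_exclusion(self._measurement(0.04), 0.05).excluded
        assert not apply_exclusion(self._measurement(0.0), 0.05).excluded

    def test_exclusion_monotone_in_threshold(self):
        fractions = [0.0, 0.01, 0.04, 0.05, 0.2, 0.6, 1.0]
        counts = []
        for thr in (0.01, 0.05, 0.1, 0.5, 1.0):
            counts.append(
                sum(apply_exclusion(self._measurement(f), thr).excluded for f in fractions)
            )
        assert counts == sorted(counts, reverse=True)


class TestDiscordance:
    def test_examples(self):
        assert discordance_score(500, 500) == 0.0
        assert discordance_score(1000, 0) == 1.0
        assert discordance_score(300, 100) == pytest.approx(0.5)
        assert discordance_score(0, 0) == 0.0

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            discordance_score(-1, 5)

    @given(
        a=st.floats(min_value=0, max_value=1e6),
        b=st.floats(min_value=0, max_value=1e6),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_bounded_and_symmetric(self, a, b):
        s = discordance_score(a, b)
        assert 0.0 <= s <= 1.0
        assert s == discordance_score(b, a)
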