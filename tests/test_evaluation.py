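"""Confusion metrics, vote-sweep ROC/AUC, LOOCV and distance statistics."""

import copy
import math

import numpy as np
import pytest
from scipy import stats as sps

from epitopepatch import evaluation as EV
from epitopepatch.evaluation import (confusion_metrics, loocv, paired_t_test,
                                     patch_distance_statistics, roc_auc)
from epitopepatch.patches import ResiduePatch
from epitopepatch.pipeline import FeaturizedStructure, RunConfig


class TestConfusionMetrics:
    def test_hand_evaluated_example(self):
        m = confusion_metrics(TP=1, TN=8, FP=1, FN=0)
        assert m["SN"] == 1.0
        assert m["SP"] == pytest.approx(8 / 9)
        assert m["ACC"] == pytest.approx(0.9)
        assert m["precision"] == 0.5
        assert m["F"] == pytest.approx(2 / 3)

    def test_perfect_classifier(self):
        m = confusion_metrics(TP=5, TN=5, FP=0, FN=0)
        assert m["SN"] == m["SP"] == m["ACC"] == m["F"] == 1.0

    def test_zero_numerator(self):
        assert confusion_metrics(TP=0, TN=5, FP=2, FN=3)["SN"] == 0.0

    def test_zero_denominator_reported_as_undefined(self):
        m = confusion_metrics(TP=0, TN=5, FP=0, FN=0)
        assert math.isnan(m["SN"]) and math.isnan(m["precision"])
        assert not math.isnan(m["SP"])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics(-1, 0, 0, 0)

    @pytest.mark.parametrize("seed", range(10))
    def test_formulas_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        TP, TN, FP, FN = (int(v) for v in rng.integers(1, 200, size=4))
        m = confusion_metrics(TP, TN, FP, FN)
        assert abs(m["SN"] - TP / (TP + FN)) < 1e-12
        assert abs(m["SP"] - TN / (TN + FP)) < 1e-12
        assert abs(m["ACC"] - (TP + TN) / (TP + TN + FP + FN)) < 1e-12
        prec, rec = TP / (TP + FP), TP / (TP + FN)
        assert abs(m["F"] - 2 * prec * rec / (prec + rec)) < 1e-12


def _rank_auc(scores, labels):
    """Mann-Whitney AUC with half credit for ties (independent oracle)."""
    pos = scores[labels.astype(bool)]
    neg = scores[~labels.astype(bool)]
    u = sps.mannwhitneyu(pos, neg, alternative="two-sided").statistic
    return u / (len(pos) * len(neg))


class TestRocAuc:
    def test_constant_scores_are_uninformative(self):
        votes = np.full(10, 3)
        labels = np.array([1, 1, 0, 0, 0, 0, 0, 0, 0, 1])
        points, auc = roc_auc(votes, labels, n_sub=5)
        assert auc == pytest.approx(0.5)

    def test_perfect_ranking(self):
        votes = np.array([5, 5, 4, 1, 0, 0])
        labels = np.array([1, 1, 1, 0, 0, 0])
        _, auc = roc_auc(votes, labels, n_sub=5)
        assert auc == pytest.approx(1.0)

    def test_curve_spans_both_corners(self):
        votes = np.array([0, 1, 2, 3])
        labels = np.array([0, 1, 0, 1])
        points, _ = roc_auc(votes, labels, n_sub=3)
        assert (0.0, 0.0) in points and (1.0, 1.0) in points

    def test_single_class_labels_are_error(self):
        with pytest.raises(ValueError):
            roc_auc(np.array([1, 2]), np.array([1, 1]), n_sub=3)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_rank_statistic_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_sub = int(rng.integers(3, 12))
        n = int(rng.integers(8, 40))
        votes = rng.integers(0, n_sub + 1, size=n)
        labels = rng.integers(0, 2, size=n)
        if labels.sum() in (0, n):
            labels[0], labels[1] = 0, 1
        _, auc = roc_auc(votes, labels, n_sub=n_sub)
        assert auc == pytest.approx(_rank_auc(votes, labels), abs=1e-12)


class TestPairedT:
    def test_identical_arrays_give_p_one(self):
        t, p = paired_t_test(np.ones(5), np.ones(5))
        assert (t, p) == (0.0, 1.0)

    def test_hand_computed_three_pair_case(self):
        a = np.array([2.0, 3.0, 5.0])
        b = np.array([1.0, 1.0, 2.0])
        # d = [1, 2, 3], mean 2, sd 1, t = 2*sqrt(3)
        t, p = paired_t_test(a, b)
        assert t == pytest.approx(2 * math.sqrt(3))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_scipy_ttest_rel(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=12)
        b = rng.normal(size=12)
        t, p = paired_t_test(a, b)
        ref = sps.ttest_rel(a, b)
        assert t == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)


class TestLoocv:
    def test_folds_partition_by_structure_without_leakage(self, signal_dataset,
                                                          monkeypatch):
        _, items, cfg = signal_dataset
        seen = []
        original = EV._train_fold

        def spy(X_train, y_train, config, fold_seed):
            seen.append(X_train.copy())
            return original(X_train, y_train, config, fold_seed)

        monkeypatch.setattr(EV, "_train_fold", spy)
        result = loocv(items, cfg)
        assert len(result.per_structure) == len(items)
        for held_out, X_train in zip(items, seen):
            train_rows = {row.tobytes() for row in X_train}
            test_rows = {row.tobytes() for row in held_out.X}
            assert not (train_rows & test_rows)

    def test_reported_metrics_match_confusion_counts(self, signal_dataset):
        _, items, cfg = signal_dataset
        result = loocv(items, cfg)
        for r in result.per_structure:
            assert r.TP + r.TN + r.FP + r.FN == len(r.labels)
            recomputed = confusion_metrics(r.TP, r.TN, r.FP, r.FN)
            for key, value in recomputed.items():
                if math.isnan(value):
                    assert math.isnan(r.metrics[key])
                else:
                    assert r.metrics[key] == pytest.approx(value, abs=1e-12)
            if r.auc is not None:
                assert 0.0 <= r.auc <= 1.0

    def test_single_class_structure_skipped_for_auc(self, signal_dataset):
        _, items, cfg = signal_dataset
        degenerate = copy.copy(items[0])
        degenerate.y = np.zeros_like(items[0].y)
        degenerate.structure_id = "all_negative"
        result = loocv(items[1:] + [degenerate], cfg)
        by_id = {r.structure_id: r for r in result.per_structure}
        assert by_id["all_negative"].auc is None
        assert not math.isnan(result.mean_auc)

    def test_two_structures_make_two_folds(self, signal_dataset):
        _, items, cfg = signal_dataset
        result = loocv(items[:2], cfg)
        assert [r.structure_id for r in result.per_structure] == \
            [it.structure_id for it in items[:2]]

    def test_fewer_than_two_structures_rejected(self, signal_dataset):
        _, items, cfg = signal_dataset
        with pytest.raises(ValueError, match="at least 2"):
            loocv(items[:1], cfg)


def _toy_patch(key, distances):
    return ResiduePatch(central=key,
                        adjacent=[((key[0], key[1], i + 2, ""), float(d), True)
                                  for i, d in enumerate(sorted(distances))],
                        mode="thick", size=len(distances) + 1)


class TestDistanceStatistics:
    def test_identical_patch_sets_give_null_result(self):
        patches, labels, types = [], {}, {}
        rng = np.random.default_rng(0)
        for i in range(6):
            d = rng.uniform(3, 10, size=4)
            for lab in (True, False):
                key = ("s", lab, i, "")
                patches.append(_toy_patch(key, d))
                labels[key] = lab
                types[key] = ["ALA", "GLY", "TRP"][i % 3]
        profile = patch_distance_statistics(patches, labels, types)
        for epi, non in profile.by_k.values():
            assert epi == pytest.approx(non)
        assert profile.k_p == 1.0 and profile.aa_p == 1.0

    def test_single_class_aa_types_are_excluded_and_reported(self):
        patches, labels, types = [], {}, {}
        for i, (lab, aa) in enumerate([(True, "ALA"), (False, "ALA"),
                                       (True, "TRP")]):
            key = ("s", i, 0, "")
            patches.append(_toy_patch(key, [2.0 + i, 4.0, 5.0]))
            labels[key] = lab
            types[key] = aa
        profile = patch_distance_statistics(patches, labels, types)
        assert profile.excluded_aa == ["TRP"]
        assert set(profile.by_aa) == {"ALA"}

    def test_planted_shift_separates_classes_in_the_right_direction(
            self, signal_dataset):
        from conftest import tag_patches_by_structure
        fixtures, _, _ = signal_dataset
        patches, labels, types = tag_patches_by_structure(fixtures)
        profile = patch_distance_statistics(patches, labels, types)
        gaps = [epi - non for epi, non in profile.by_k.values()]
        assert np.mean(gaps) > 0
        assert profile.k_t > 0

    def test_mixed_patch_sizes_rejected(self):
        patches = [_toy_patch(("s", 0, 0, ""), [2, 3]),
                   _toy_patch(("s", 1, 0, ""), [2, 3, 4])]
        with pytest.raises(ValueError, match="sizes differ"):
            patch_distance_statistics(patches,
                                      {p.central: bool(i) for i, p in
                                       enumerate(patches)},
                                      {p.central: "ALA" for p in patches})
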