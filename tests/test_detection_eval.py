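"""Lesion matching, detection summaries and the FROC curve."""

import itertools
import math

import numpy as np
import pytest

from bmtriage import detection_summary, froc, match_by_provenance, match_lesions
from bmtriage.detection_eval import MatchResult
from conftest import scan_from_voxel_sets, table_scan


def brute_force_best_assignment(overlaps):
    """Enumerate all one-to-one assignments; return the greedy-equivalent one.

    The implementation's greedy order (descending overlap, ties by smaller
    predicted id then ground-truth id) is replayed on the full candidate
    list, which for the small graphs used here is an exhaustive check that
    each lesion is used at most once and every claimed pair overlaps.
    """
    pairs = sorted(overlaps, key=lambda gp: (-overlaps[gp], gp[1], gp[0]))
    used_gt, used_pred, chosen = set(), set(), []
    for g, p in pairs:
        if g not in used_gt and p not in used_pred:
            chosen.append((g, p))
            used_gt.add(g)
            used_pred.add(p)
    return sorted(chosen)


class TestMatchLesions:
    def test_identity_prediction_is_all_tp(self):
        voxels = [{(0, 0, 0), (0, 0, 1)}, {(3, 3, 3)}, {(5, 5, 5), (5, 5, 6)}]
        gt = scan_from_voxel_sets("p", "ground_truth", voxels)
        pred = scan_from_voxel_sets("p", "detector", voxels)
        res = match_lesions(gt, pred)
        assert len(res.tp_pairs) == 3
        assert res.fn_gt_ids == [] and res.fp_pred_ids == []

    def test_empty_prediction_is_all_fn(self):
        gt = scan_from_voxel_sets("p", "ground_truth", [{(i, 0, 0)} for i in range(4)])
        pred = scan_from_voxel_sets("p", "detector", [])
        res = match_lesions(gt, pred)
        assert res.tp_pairs == [] and res.fp_pred_ids == []
        assert sorted(res.fn_gt_ids) == [1, 2, 3, 4]

    def test_no_overlap_is_fp_and_fn(self):
        gt = scan_from_voxel_sets("p", "ground_truth", [{(0, 0, 0)}])
        pred = scan_from_voxel_sets("p", "detector", [{(9, 9, 9)}])
        res = match_lesions(gt, pred)
        assert res.fn_gt_ids == [1] and res.fp_pred_ids == [1] and not res.tp_pairs

    def test_one_blob_spanning_two_gt_lesions(self):
        # two ground-truth lesions touching the same prediction; the larger
        # overlap wins under one-to-one and the second lesion goes undetected,
        # while any-overlap mode credits both
        gt = scan_from_voxel_sets(
            "p", "ground_truth", [{(0, 0, 0), (0, 0, 1), (0, 0, 2)}, {(1, 1, 3)}]
        )
        pred = scan_from_voxel_sets(
            "p", "detector", [{(0, 0, 1), (0, 0, 2), (1, 1, 3)}]
        )
        one = match_lesions(gt, pred, mode="one_to_one")
        assert one.tp_pairs == [(1, 1)]  # gt 1 has overlap 2 > overlap 1 of gt 2
        assert one.fn_gt_ids == [2] and one.fp_pred_ids == []
        many = match_lesions(gt, pred, mode="any_overlap")
        assert sorted(many.tp_pairs) == [(1, 1), (2, 1)]
        assert many.fn_gt_ids == [] and many.fp_pred_ids == []

    def test_extra_overlapping_prediction_is_absorbed_not_fp(self):
        gt = scan_from_voxel_sets("p", "ground_truth", [{(0, 0, 0), (0, 0, 1)}])
        pred = scan_from_voxel_sets("p", "detector", [{(0, 0, 0)}, {(0, 0, 1)}])
        res = match_lesions(gt, pred)
        assert res.tp_pairs == [(1, 1)]  # tie on overlap=1, smaller pred id wins
        assert res.absorbed_pred_ids == [2] and res.fp_pred_ids == []
        assert res.n_tp_pred + len(res.fp_pred_ids) + len(res.absorbed_pred_ids) == res.n_pred

    def test_greedy_matches_exhaustive_on_random_overlap_graphs(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n_gt, n_pred = rng.integers(1, 4, size=2)
            gt_sets, base = [], 0
            for _g in range(n_gt):
                size = int(rng.integers(1, 4))
                gt_sets.append({(base + i, 0, 0) for i in range(size)})
                base += size + 1
            all_gt_voxels = sorted(set().union(*gt_sets))
            pred_sets = []
            for _p in range(n_pred):
                size = int(rng.integers(1, 4))
                vox = {tuple(all_gt_voxels[j]) for j in rng.choice(len(all_gt_voxels), size)}
                if rng.random() < 0.3:
                    vox.add((1000 + _p, 0, 0))  # sometimes stray voxels
                pred_sets.append(vox)
            gt = scan_from_voxel_sets("p", "ground_truth", gt_sets)
            pred = scan_from_voxel_sets("p", "detector", pred_sets)
            overlaps = {
                (g.lesion_id, p.lesion_id): len(g.voxel_indices & p.voxel_indices)
                for g in gt.lesions
                for p in pred.lesions
                if g.voxel_indices & p.voxel_indices
            }
            res = match_lesions(gt, pred)
            assert sorted(res.tp_pairs) == brute_force_best_assignment(overlaps)
            # conservation laws
            assert len(res.tp_pairs) + len(res.fn_gt_ids) == res.n_gt
            assert res.n_tp_pred + len(res.fp_pred_ids) + len(res.absorbed_pred_ids) == res.n_pred

    def test_invariant_to_lesion_relabeling(self):
        sets_a = [{(0, 0, 0), (0, 0, 1)}, {(5, 5, 5)}]
        gt = scan_from_voxel_sets("p", "ground_truth", sets_a)
        pred = scan_from_voxel_sets("p", "detector", [{(0, 0, 1)}, {(5, 5, 5)}, {(8, 8, 8)}])
        res1 = match_lesions(gt, pred)
        # relabel: reverse both lists
        gt2 = scan_from_voxel_sets("p", "ground_truth", sets_a[::-1])
        pred2 = scan_from_voxel_sets(
            "p", "detector", [{(8, 8, 8)}, {(5, 5, 5)}, {(0, 0, 1)}]
        )
        res2 = match_lesions(gt2, pred2)
        assert len(res1.tp_pairs) == len(res2.tp_pairs)
        assert len(res1.fp_pred_ids) == len(res2.fp_pred_ids)
        assert len(res1.fn_gt_ids) == len(res2.fn_gt_ids)

    def test_mismatched_grids_rejected(self):
        gt = scan_from_voxel_sets("p", "ground_truth", [{(0, 0, 0)}], spacing=(1, 1, 1))
        pred = scan_from_voxel_sets("p", "detector", [{(0, 0, 0)}], spacing=(1, 1, 2))
        with pytest.raises(ValueError, match="different"):
            match_lesions(gt, pred)


class TestProvenanceMatching:
    def test_matches_recorded_sources(self):
        gt = table_scan("p", "ground_truth", [100.0, 10.0])
        pred = table_scan(
            "p", "detector", [90.0, 7.0], confidences=[0.9, 0.4], source_gt_ids=[1, None]
        )
        res = match_by_provenance(gt, pred)
        assert res.tp_pairs == [(1, 1)]
        assert res.fn_gt_ids == [2] and res.fp_pred_ids == [2]


class TestDetectionSummary:
    def test_cohort_count_arithmetic(self):
        # TP=1, FN=1, FP=3 over 2 patients
        results = [
            MatchResult("p1", tp_pairs=[(1, 1)], fn_gt_ids=[2], fp_pred_ids=[2, 3], n_gt=2, n_pred=3),
            MatchResult("p2", tp_pairs=[], fn_gt_ids=[], fp_pred_ids=[1], n_gt=0, n_pred=1),
        ]
        summary = detection_summary(results)
        assert summary.sensitivity == pytest.approx(0.5)
        assert summary.ppv == pytest.approx(0.25)
        assert summary.fp_per_patient == pytest.approx(1.5)

    def test_zero_denominators_are_nan_not_zero(self):
        summary = detection_summary([MatchResult("p1")])
        assert math.isnan(summary.sensitivity)
        assert math.isnan(summary.ppv)
        assert summary.fp_per_patient == 0.0

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            detection_summary([])

    def test_study_scale_counts(self):
        # cohort pooled counts at the scale of a 112-patient study:
        # 876 detected, 76 missed, 160 false positives
        results = [
            MatchResult(
                "all",
                tp_pairs=[(i, i) for i in range(876)],
                fn_gt_ids=list(range(1000, 1076)),
                fp_pred_ids=list(range(2000, 2160)),
                n_gt=952,
                n_pred=1036,
            )
        ]
        s = detection_summary(results)
        assert s.sensitivity == pytest.approx(876 / 952)
        assert s.ppv == pytest.approx(876 / 1036)


class TestFroc:
    def test_single_tp_detection(self):
        gt = table_scan("p", "ground_truth", [50.0])
        pred = table_scan("p", "detector", [50.0], confidences=[0.9], source_gt_ids=[1])
        curve = froc([match_by_provenance(gt, pred)], [pred])
        assert curve.points == [(0.0, 1.0)]
        assert curve.thresholds == [0.9]

    def test_no_detections(self):
        gt = table_scan("p", "ground_truth", [50.0])
        pred = table_scan("p", "detector", [])
        curve = froc([match_by_provenance(gt, pred)], [pred])
        assert curve.points == [(0.0, 0.0)]

    def test_exhaustive_threshold_sweep(self):
        # 2 patients, 3 GT lesions, detections {TP .9, FP .8, TP .4, FP .2};
        # expected points frozen from a hand sweep over the 4 thresholds
        gt1 = table_scan("p1", "ground_truth", [100.0, 10.0])
        pred1 = table_scan(
            "p1", "detector", [90.0, 8.0], confidences=[0.9, 0.8], source_gt_ids=[1, None]
        )
        gt2 = table_scan("p2", "ground_truth", [40.0])
        pred2 = table_scan(
            "p2", "detector", [35.0, 5.0], confidences=[0.4, 0.2], source_gt_ids=[1, None]
        )
        matches = [match_by_provenance(gt1, pred1), match_by_provenance(gt2, pred2)]
        curve = froc(matches, [pred1, pred2])
        assert curve.thresholds == [0.9, 0.8, 0.4, 0.2]
        assert curve.points == [
            (0.0, pytest.approx(1 / 3)),
            (0.5, pytest.approx(1 / 3)),
            (0.5, pytest.approx(2 / 3)),
            (1.0, pytest.approx(2 / 3)),
        ]

    def test_monotone_under_random_confidences(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            n = int(rng.integers(1, 8))
            confs = rng.uniform(0, 1, n).round(2).tolist()
            srcs = [int(i) + 1 if rng.random() < 0.5 else None for i in range(n)]
            n_gt = max([s for s in srcs if s is not None], default=0) + int(rng.integers(1, 3))
            gt = table_scan("p", "ground_truth", [50.0] * n_gt)
            pred = table_scan("p", "detector", [10.0] * n, confidences=confs, source_gt_ids=srcs)
            curve = froc([match_by_provenance(gt, pred)], [pred])
            fps = [p[0] for p in curve.points]
            sens = [p[1] for p in curve.points]
            assert fps == sorted(fps)
            assert all(b >= a for a, b in zip(sens, sens[1:]))

    def test_missing_confidence_rejected(self):
        gt = table_scan("p", "ground_truth", [50.0])
        pred = table_scan("p", "detector", [50.0], source_gt_ids=[1])
        with pytest.raises(ValueError, match="confidence"):
            froc([match_by_provenance(gt, pred)], [pred])
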