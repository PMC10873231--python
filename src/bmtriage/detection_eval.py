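"""Lesion-wise detection evaluation.

A detected lesion is a candidate match for a ground-truth lesion when the
two share at least one voxel.  The default matching mode resolves the
candidate graph one-to-one, greedily by descending overlap size; an
any-overlap mode follows the literal ">= 1 voxel" reading in which a
single prediction may account for several ground-truth lesions.  Extra
predictions that overlap an already-matched ground-truth lesion are
"absorbed" into that detection: they count neither as true nor as false
positives.  Predictions overlapping nothing are false positives; unmatched
ground-truth lesions are false negatives.

Cohort summaries are lesion-level sensitivity TP/(TP+FN), positive
predictive value TP/(TP+FP), the mean false-positive count per patient,
and the FROC curve obtained by sweeping the detector confidence
threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .lesion_io import PatientScan

__all__ = [
    "MatchResult",
    "DetectionSummary",
    "FrocCurve",
    "match_lesions",
    "match_by_provenance",
    "detection_summary",
    "froc",
    "write_match_table",
]


@dataclass
class MatchResult:
    """Per-patient lesion match labels.

    Invariants: |tp_pairs| + |fn_gt_ids| = n_gt (one-to-one mode), and
    |tp_pairs distinct preds| + |fp_pred_ids| + |absorbed_pred_ids| = n_pred.
    """

    patient_id: str
    tp_pairs: list[tuple[int, int]] = field(default_factory=list)  # (gt_id, pred_id)
    fn_gt_ids: list[int] = field(default_factory=list)
    fp_pred_ids: list[int] = field(default_factory=list)
    absorbed_pred_ids: list[int] = field(default_factory=list)
    n_gt: int = 0
    n_pred: int = 0

    @property
    def n_tp_gt(self) -> int:
        """Ground-truth lesions detected (the sensitivity numerator)."""
        return len({gt for gt, _ in self.tp_pairs})

    @property
    def n_tp_pred(self) -> int:
        """Predicted lesions that are true positives (the PPV numerator)."""
        return len({p for _, p in self.tp_pairs})


@dataclass
class DetectionSummary:
    sensitivity: float
    ppv: float
    fp_per_patient: float
    tp: int
    fn: int
    fp: int
    n_patients: int


@dataclass
class FrocCurve:
    """FROC points ordered from the strictest to the loosest threshold."""

    points: list[tuple[float, float]]  # (fp_per_patient, sensitivity)
    thresholds: list[float]

    def __post_init__(self) -> None:
        if len(self.points) != len(self.thresholds):
            raise ValueError("points and thresholds must have matching lengths")
        fps = [p[0] for p in self.points]
        sens = [p[1] for p in self.points]
        if any(b < a - 1e-12 for a, b in zip(fps, fps[1:])) or any(
            b < a - 1e-12 for a, b in zip(sens, sens[1:])
        ):
            raise ValueError("FROC must be monotone as the threshold decreases")


def _overlap_counts(gt: PatientScan, pred: PatientScan) -> dict[tuple[int, int], int]:
    for scan in (gt, pred):
        for les in scan.lesions:
            if les.voxel_indices is None:
                raise ValueError(
                    f"patient {scan.patient_id}: lesion {les.lesion_id} has no voxel set; "
                    "voxel-overlap matching needs mask-derived lesions"
                )
    overlaps = {}
    for g in gt.lesions:
        for p in pred.lesions:
            n = len(g.voxel_indices & p.voxel_indices)
            if n:
                overlaps[(g.lesion_id, p.lesion_id)] = n
    return overlaps


def match_lesions(gt: PatientScan, pred: PatientScan, mode: str = "one_to_one") -> MatchResult:
    """Match predicted lesions to ground-truth lesions by voxel overlap.

    mode="one_to_one" (default): candidate pairs sorted by descending
    overlap-voxel count (ties by smaller predicted id, then smaller
    ground-truth id) and assigned greedily, each lesion used at most once.
    mode="any_overlap": every overlapped ground-truth lesion is detected
    and is paired with its largest-overlap prediction.
    """
    if mode not in ("one_to_one", "any_overlap"):
        raise ValueError(f"unknown matching mode {mode!r}")
    if tuple(gt.spacing) != tuple(pred.spacing):
        raise ValueError(
            f"patient {gt.patient_id}: ground truth and prediction are on different "
            f"grids (spacing {gt.spacing} vs {pred.spacing})"
        )
    overlaps = _overlap_counts(gt, pred)
    result = MatchResult(patient_id=gt.patient_id, n_gt=gt.n_lesions, n_pred=pred.n_lesions)

    candidates = sorted(overlaps.items(), key=lambda kv: (-kv[1], kv[0][1], kv[0][0]))
    matched_gt: set[int] = set()
    matched_pred: set[int] = set()
    if mode == "one_to_one":
        for (g_id, p_id), _n in candidates:
            if g_id in matched_gt or p_id in matched_pred:
                continue
            result.tp_pairs.append((g_id, p_id))
            matched_gt.add(g_id)
            matched_pred.add(p_id)
    else:
        for (g_id, p_id), _n in candidates:
            if g_id in matched_gt:
                continue
            result.tp_pairs.append((g_id, p_id))
            matched_gt.add(g_id)
            matched_pred.add(p_id)

    overlapping_preds = {p for (_g, p) in overlaps}
    for p in pred.lesions:
        if p.lesion_id in matched_pred:
            continue
        if p.lesion_id in overlapping_preds:
            result.absorbed_pred_ids.append(p.lesion_id)
        else:
            result.fp_pred_ids.append(p.lesion_id)
    result.fn_gt_ids = [g.lesion_id for g in gt.lesions if g.lesion_id not in matched_gt]
    result.tp_pairs.sort()
    return result


def match_by_provenance(gt: PatientScan, pred: PatientScan) -> MatchResult:
    """Match simulated detections to their recorded source lesions.

    Table-based simulated cohorts carry no voxel sets; instead each
    detection records the ground-truth lesion it originated from
    (``source_gt_id``, None for simulated false positives).  This yields
    the same one-to-one labels voxel matching would produce for
    detections rendered overlapping their source.
    """
    result = MatchResult(patient_id=gt.patient_id, n_gt=gt.n_lesions, n_pred=pred.n_lesions)
    gt_ids = {g.lesion_id for g in gt.lesions}
    matched_gt: set[int] = set()
    for p in sorted(pred.lesions, key=lambda l: l.lesion_id):
        src = p.source_gt_id
        if src is None:
            result.fp_pred_ids.append(p.lesion_id)
        elif src in gt_ids and src not in matched_gt:
            result.tp_pairs.append((src, p.lesion_id))
            matched_gt.add(src)
        elif src in gt_ids:
            result.absorbed_pred_ids.append(p.lesion_id)
        else:
            raise ValueError(
                f"patient {pred.patient_id}: detection {p.lesion_id} references "
                f"unknown ground-truth lesion {src}"
            )
    result.fn_gt_ids = sorted(gt_ids - matched_gt)
    result.tp_pairs.sort()
    return result


def detection_summary(results: Sequence[MatchResult]) -> DetectionSummary:
    """Pool per-patient match labels into cohort detection statistics.

    Ratios with a zero denominator are reported as NaN, never as 0.
    ``fp_per_patient`` divides by the number of patients, so patients with
    no lesions still count in its denominator.
    """
    if not results:
        raise ValueError("detection_summary needs at least one patient")
    tp_gt = sum(r.n_tp_gt for r in results)
    tp_pred = sum(r.n_tp_pred for r in results)
    fn = sum(len(r.fn_gt_ids) for r in results)
    fp = sum(len(r.fp_pred_ids) for r in results)
    n_patients = len(results)
    sens = tp_gt / (tp_gt + fn) if (tp_gt + fn) else math.nan
    ppv = tp_pred / (tp_pred + fp) if (tp_pred + fp) else math.nan
    return DetectionSummary(
        sensitivity=sens,
        ppv=ppv,
        fp_per_patient=fp / n_patients,
        tp=tp_gt,
        fn=fn,
        fp=fp,
        n_patients=n_patients,
    )


def froc(results: Sequence[MatchResult], pred_scans: Sequence[PatientScan]) -> FrocCurve:
    """FROC curve: sensitivity vs mean FP per patient over confidence cutoffs.

    Match labels are fixed by the overlap rule; thresholding only removes
    low-confidence detections.  One point is produced per distinct
    confidence value (threshold = that value, detections kept when
    confidence >= threshold), ordered strictest first.
    """
    if not results:
        raise ValueError("froc needs at least one patient")
    by_id = {s.patient_id: s for s in pred_scans}
    detections: list[tuple[float, bool]] = []  # (confidence, is_tp)
    n_gt = 0
    for r in results:
        n_gt += r.n_gt
        scan = by_id.get(r.patient_id)
        if scan is None:
            raise ValueError(f"no prediction scan for patient {r.patient_id}")
        conf = {}
        for les in scan.lesions:
            if les.confidence is None:
                raise ValueError(
                    f"patient {r.patient_id}: lesion {les.lesion_id} has no confidence"
                )
            conf[les.lesion_id] = les.confidence
        detections.extend((conf[p], True) for _g, p in r.tp_pairs)
        detections.extend((conf[p], False) for p in r.fp_pred_ids)
    n_patients = len(results)
    if not detections:
        return FrocCurve(points=[(0.0, 0.0)], thresholds=[math.inf])
    thresholds = sorted({c for c, _ in detections}, reverse=True)
    points = []
    for t in thresholds:
        tp = sum(1 for c, is_tp in detections if is_tp and c >= t)
        fp = sum(1 for c, is_tp in detections if not is_tp and c >= t)
        sens = tp / n_gt if n_gt else math.nan
        points.append((fp / n_patients, sens))
    return FrocCurve(points=points, thresholds=thresholds)


def write_match_table(results: Sequence[MatchResult], path) -> None:
    """Per-lesion match statuses as CSV (status in {TP, FN, FP, absorbed})."""
    rows = []
    for r in results:
        for g, p in r.tp_pairs:
            rows.append({"patient_id": r.patient_id, "lesion_id": g, "status": "TP", "matched_id": p})
        for g in r.fn_gt_ids:
            rows.append({"patient_id": r.patient_id, "lesion_id": g, "status": "FN", "matched_id": None})
        for p in r.fp_pred_ids:
            rows.append({"patient_id": r.patient_id, "lesion_id": p, "status": "FP", "matched_id": None})
        for p in r.absorbed_pred_ids:
            rows.append({"patient_id": r.patient_id, "lesion_id": p, "status": "absorbed", "matched_id": None})
    pd.DataFrame(rows, columns=["patient_id", "lesion_id", "status", "matched_id"]).to_csv(
        path, index=False
    )
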