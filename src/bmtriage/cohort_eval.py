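"""Cohort-level concordance evaluation and the end-to-end pipeline.

Per-patient triage suggestions are compared with reference groups derived
from the treatments actually given, through a 3x3 confusion matrix (rows
= actual group, columns = suggested group) and its summary statistics:
overall accuracy (trace/total), accuracy modified by the targeted-agent
override, per-group sensitivity, high-risk (B+C vs A) sensitivity and
specificity, weighted kappa, plus detection statistics, count/volume
ICCs and the FROC curve for the detector-vs-ground-truth comparison.

``run_pipeline`` orchestrates all of it and emits a deterministic,
JSON-serializable report with an embedded config snapshot.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .agreement_stats import IccResult, KappaResult, icc_consistency, weighted_kappa
from .detection_eval import (
    DetectionSummary,
    FrocCurve,
    MatchResult,
    detection_summary,
    froc,
    match_by_provenance,
    match_lesions,
)
from .lesion_io import ClinicalRecord, PatientScan
from .triage import (
    GROUPS,
    TriageAssignment,
    TriageConfig,
    apply_targeted_agent_rule,
    assign_group,
    dichotomize,
    map_treatment_to_group,
)

__all__ = [
    "ConfusionMatrix3",
    "CohortReport",
    "confusion_matrix",
    "overall_accuracy",
    "modified_accuracy",
    "per_group_sensitivity",
    "high_risk_metrics",
    "group_summaries",
    "run_pipeline",
]

_GROUP_INDEX = {g: i for i, g in enumerate(GROUPS)}


@dataclass
class ConfusionMatrix3:
    """3x3 patient counts; rows = actual group, columns = suggested group."""

    counts: np.ndarray
    labels: tuple[str, str, str] = GROUPS

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        if counts.shape != (3, 3) or (counts < 0).any():
            raise ValueError("counts must be a 3x3 array of non-negative integers")
        self.counts = counts

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=[f"actual_{g}" for g in self.labels],
            columns=[f"suggested_{g}" for g in self.labels],
        )


def confusion_matrix(actual: Sequence[str], suggested: Sequence[str]) -> ConfusionMatrix3:
    """Tally per-patient (actual, suggested) group pairs."""
    if len(actual) != len(suggested):
        raise ValueError(f"length mismatch: {len(actual)} actual vs {len(suggested)} suggested")
    counts = np.zeros((3, 3), dtype=int)
    for a, s in zip(actual, suggested):
        if a not in _GROUP_INDEX or s not in _GROUP_INDEX:
            raise ValueError(f"labels must be in {GROUPS}, got ({a!r}, {s!r})")
        counts[_GROUP_INDEX[a], _GROUP_INDEX[s]] += 1
    return ConfusionMatrix3(counts=counts)


def overall_accuracy(cm: ConfusionMatrix3) -> float:
    """Percentage of patients whose suggested group equals the actual group."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return 100.0 * float(np.trace(cm.counts)) / cm.total


def modified_accuracy(cm: ConfusionMatrix3, overrides: Sequence[tuple[str, str]]) -> float:
    """Accuracy after re-classifying overridden discordant patients as correct.

    ``overrides`` lists (actual_group, suggested_group) pairs of patients
    the targeted-agent rule accepts; each must sit off-diagonal and no
    cell may be overridden more often than it has patients.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    per_cell: dict[tuple[str, str], int] = {}
    for a, s in overrides:
        if a == s:
            raise ValueError(f"override ({a}, {s}) targets a concordant (diagonal) cell")
        per_cell[(a, s)] = per_cell.get((a, s), 0) + 1
    for (a, s), n in per_cell.items():
        cell = int(cm.counts[_GROUP_INDEX[a], _GROUP_INDEX[s]])
        if n > cell:
            raise ValueError(
                f"{n} overrides for cell (actual {a}, suggested {s}) but only {cell} patients"
            )
    return 100.0 * (float(np.trace(cm.counts)) + len(overrides)) / cm.total


def per_group_sensitivity(cm: ConfusionMatrix3) -> dict[str, float]:
    """Diagonal over row total per actual group, in percent (NaN if empty row)."""
    out = {}
    for g, i in _GROUP_INDEX.items():
        row = int(cm.counts[i].sum())
        out[g] = 100.0 * float(cm.counts[i, i]) / row if row else math.nan
    return out


def high_risk_metrics(actual_risk: Sequence[str], suggested_risk: Sequence[str]) -> tuple[float, float]:
    """(sensitivity %, specificity %) for flagging high-risk patients.

    Sensitivity = suggested-high among actual-high; specificity =
    suggested-low among actual-low.  A side with no patients yields NaN.
    """
    if len(actual_risk) != len(suggested_risk):
        raise ValueError("length mismatch between actual and suggested risk labels")
    for lab in list(actual_risk) + list(suggested_risk):
        if lab not in ("low", "high"):
            raise ValueError(f"risk labels must be 'low' or 'high', got {lab!r}")
    tp = sum(1 for a, s in zip(actual_risk, suggested_risk) if a == "high" and s == "high")
    fn = sum(1 for a, s in zip(actual_risk, suggested_risk) if a == "high" and s == "low")
    tn = sum(1 for a, s in zip(actual_risk, suggested_risk) if a == "low" and s == "low")
    fp = sum(1 for a, s in zip(actual_risk, suggested_risk) if a == "low" and s == "high")
    sens = 100.0 * tp / (tp + fn) if (tp + fn) else math.nan
    spec = 100.0 * tn / (tn + fp) if (tn + fp) else math.nan
    return sens, spec


def group_summaries(assignments: Sequence[TriageAssignment]) -> list[dict]:
    """Per-group patient counts and lesion count/volume means and ranges."""
    out = []
    for g in GROUPS:
        sub = [a for a in assignments if a.group == g]
        if sub:
            counts = [a.n_lesions for a in sub]
            vols = [a.total_volume_mm3 for a in sub]
            out.append(
                {
                    "group": g,
                    "n_patients": len(sub),
                    "mean_n_lesions": float(np.mean(counts)),
                    "min_n_lesions": int(min(counts)),
                    "max_n_lesions": int(max(counts)),
                    "mean_total_volume_mm3": float(np.mean(vols)),
                    "min_total_volume_mm3": float(min(vols)),
                    "max_total_volume_mm3": float(max(vols)),
                }
            )
        else:
            out.append({"group": g, "n_patients": 0})
    return out


@dataclass
class CohortReport:
    """Everything the pipeline measures for one cohort, JSON-serializable."""

    n_patients: int
    accuracy_pct: float
    modified_accuracy_pct: float
    n_overrides: int
    per_group_sensitivity_pct: dict[str, float]
    high_risk_sensitivity_pct: float
    high_risk_specificity_pct: float
    kappa: KappaResult
    icc_counts: Optional[IccResult]
    icc_volumes: Optional[IccResult]
    detection: Optional[DetectionSummary]
    froc: Optional[FrocCurve]
    confusion_actual_vs_dls: ConfusionMatrix3
    gt_vs_dls_concordance_pct: float
    confusion_gt_vs_dls: ConfusionMatrix3
    group_summaries: list[dict]
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def _clean(x):
            if isinstance(x, float):
                return None if math.isnan(x) else round(x, 6)
            if isinstance(x, np.ndarray):
                return x.tolist()
            if isinstance(x, dict):
                return {k: _clean(v) for k, v in x.items()}
            if isinstance(x, (list, tuple)):
                return [_clean(v) for v in x]
            return x

        d = asdict(self)
        return _clean(d)

    def to_json(self, path=None, indent: int = 2) -> str:
        text = json.dumps(self.to_dict(), indent=indent, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _match_cohort(
    gt_scans: Sequence[PatientScan],
    pred_scans: Sequence[PatientScan],
    mode: str,
) -> list[MatchResult]:
    results = []
    for gt, pred in zip(gt_scans, pred_scans):
        has_voxels = all(l.voxel_indices is not None for l in gt.lesions) and all(
            l.voxel_indices is not None for l in pred.lesions
        )
        if has_voxels and (gt.lesions or pred.lesions):
            results.append(match_lesions(gt, pred, mode=mode))
        elif all(l.source_gt_id is not None or l.confidence is not None for l in pred.lesions):
            results.append(match_by_provenance(gt, pred))
        else:
            raise ValueError(
                f"patient {gt.patient_id}: lesions carry neither voxel sets nor "
                "detection provenance; cannot match"
            )
    return results


def run_pipeline(
    gt_scans: Sequence[PatientScan],
    pred_scans: Sequence[PatientScan],
    records: Sequence[ClinicalRecord],
    config: Optional[TriageConfig] = None,
    match_mode: str = "one_to_one",
    kappa_weights: str = "linear",
    seed: Optional[int] = None,
) -> CohortReport:
    """Run the full post-detection analysis for one cohort.

    All three inputs must cover the same patients; the report is a pure
    function of the inputs and configuration.
    """
    config = config or TriageConfig()
    gt_by_id = {s.patient_id: s for s in gt_scans}
    pred_by_id = {s.patient_id: s for s in pred_scans}
    rec_by_id = {r.patient_id: r for r in records}
    ids = sorted(gt_by_id)
    missing = sorted((set(ids) ^ set(pred_by_id)) | (set(ids) ^ set(rec_by_id)))
    if len(gt_by_id) != len(gt_scans) or missing:
        raise ValueError(f"patient ids do not align across inputs; offending ids: {missing}")

    gt_sorted = [gt_by_id[i] for i in ids]
    pred_sorted = [pred_by_id[i] for i in ids]
    rec_sorted = [rec_by_id[i] for i in ids]

    dls_triage = [assign_group(s, config) for s in pred_sorted]
    gt_triage = [assign_group(s, config) for s in gt_sorted]
    dls_groups = [t.group for t in dls_triage]
    gt_groups = [t.group for t in gt_triage]
    actual_groups = [map_treatment_to_group(r) for r in rec_sorted]

    cm = confusion_matrix(actual_groups, dls_groups)
    overrides = [
        (a, d)
        for a, d, r in zip(actual_groups, dls_groups, rec_sorted)
        if a != d and apply_targeted_agent_rule(d, r)
    ]
    acc = overall_accuracy(cm)
    mod_acc = modified_accuracy(cm, overrides)
    sens_by_group = per_group_sensitivity(cm)
    hr_sens, hr_spec = high_risk_metrics(
        [dichotomize(g).risk for g in actual_groups],
        [dichotomize(g).risk for g in dls_groups],
    )
    kappa = weighted_kappa(actual_groups, dls_groups, weights=kappa_weights, categories=GROUPS)

    try:
        icc_counts = icc_consistency(
            [s.n_lesions for s in gt_sorted], [s.n_lesions for s in pred_sorted]
        )
    except ValueError:
        icc_counts = None
    try:
        icc_volumes = icc_consistency(
            [s.total_volume_mm3 for s in gt_sorted], [s.total_volume_mm3 for s in pred_sorted]
        )
    except ValueError:
        icc_volumes = None

    matches = _match_cohort(gt_sorted, pred_sorted, match_mode)
    detection = detection_summary(matches)
    froc_curve: Optional[FrocCurve]
    if all(l.confidence is not None for s in pred_sorted for l in s.lesions):
        froc_curve = froc(matches, pred_sorted)
    else:
        froc_curve = None

    cm_gt = confusion_matrix(gt_groups, dls_groups)
    gt_concordance = overall_accuracy(cm_gt)

    return CohortReport(
        n_patients=len(ids),
        accuracy_pct=acc,
        modified_accuracy_pct=mod_acc,
        n_overrides=len(overrides),
        per_group_sensitivity_pct=sens_by_group,
        high_risk_sensitivity_pct=hr_sens,
        high_risk_specificity_pct=hr_spec,
        kappa=kappa,
        icc_counts=icc_counts,
        icc_volumes=icc_volumes,
        detection=detection,
        froc=froc_curve,
        confusion_actual_vs_dls=cm,
        gt_vs_dls_concordance_pct=gt_concordance,
        confusion_gt_vs_dls=cm_gt,
        group_summaries=group_summaries(dls_triage),
        config={**asdict(config), "match_mode": match_mode, "kappa_weights": kappa_weights,
                "seed": seed},
    )
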