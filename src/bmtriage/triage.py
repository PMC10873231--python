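"""Count/volume-based treatment triage for newly diagnosed brain metastases.

Patients are assigned to one of three treatment-suggestion groups from
the number n and volume V (mm^3) of their detected lesions, following
current neuro-oncology practice guidance:

* group A — short-term imaging follow-up without treatment: at most 2
  lesions with a cumulative volume of at most 65 mm^3 (the volume of a
  5 mm sphere, the RANO-BM measurability cutoff);
* group B — limited disease, surgery or stereotactic radiosurgery: not A,
  but at most 10 lesions with a cumulative volume of at most 15 mL
  (15,000 mm^3);
* group C — extensive disease, whole-brain radiotherapy or systemic
  chemotherapy: everything else.

The three branches partition the (n, V) plane.  A strict per-lesion mode
applies the 65 mm^3 cap to the largest lesion instead of the total
(see ``volume_mode``).

The module also maps actual treatments to reference groups, applies the
targeted-agent concordance override (EGFR/ALK-mutant, asymptomatic
patients triaged B who received upfront chemotherapy count as
concordant), and dichotomizes groups into low risk (A) versus high risk
(B or C).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from typing import Optional

import yaml

from .lesion_io import ClinicalRecord, PatientScan

__all__ = [
    "GROUPS",
    "TriageConfig",
    "TriageAssignment",
    "RiskLabel",
    "assign_group",
    "assign_group_from_counts",
    "map_treatment_to_group",
    "apply_targeted_agent_rule",
    "dichotomize",
]

logger = logging.getLogger(__name__)

GROUPS = ("A", "B", "C")

_TREATMENT_TO_GROUP = {
    "follow_up": "A",
    "surgery": "B",
    "srs": "B",
    "wbrt": "C",
    "chemo": "C",
}


@dataclass(frozen=True)
class TriageConfig:
    """Thresholds of the triage algorithm (all configurable, never inlined).

    ``volume_mode`` selects whether the group-A volume cap applies to the
    cumulative volume ("total", default) or to each lesion ("per_lesion").
    """

    max_count_A: int = 2
    max_volume_A: float = 65.0  # mm^3; 5 mm sphere
    max_count_B: int = 10
    max_volume_B: float = 15000.0  # mm^3 = 15 mL
    volume_mode: str = "total"

    def __post_init__(self) -> None:
        if not (0 < self.max_count_A < self.max_count_B):
            raise ValueError("need 0 < max_count_A < max_count_B")
        if not (0 < self.max_volume_A < self.max_volume_B):
            raise ValueError("need 0 < max_volume_A < max_volume_B")
        if self.volume_mode not in ("total", "per_lesion"):
            raise ValueError(f"volume_mode must be 'total' or 'per_lesion', got {self.volume_mode!r}")

    @classmethod
    def from_yaml(cls, path) -> "TriageConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class TriageAssignment:
    patient_id: str
    group: str
    n_lesions: int
    total_volume_mm3: float
    rule_fired: str


@dataclass
class RiskLabel:
    patient_id: str
    risk: str  # "low" | "high"


def assign_group_from_counts(
    n_lesions: int,
    total_volume_mm3: float,
    config: Optional[TriageConfig] = None,
    max_lesion_volume_mm3: Optional[float] = None,
    patient_id: str = "",
) -> TriageAssignment:
    """Assign a triage group from a lesion count and volume summary.

    In per-lesion mode ``max_lesion_volume_mm3`` (largest single lesion)
    is tested against the group-A cap; it defaults to the total, which
    reduces to total mode for single-lesion patients.
    """
    config = config or TriageConfig()
    if n_lesions < 0:
        raise ValueError(f"negative lesion count {n_lesions}")
    if total_volume_mm3 < 0:
        raise ValueError(f"negative total volume {total_volume_mm3}")
    if config.volume_mode == "per_lesion":
        vol_a = total_volume_mm3 if max_lesion_volume_mm3 is None else max_lesion_volume_mm3
        vol_desc = "max lesion volume"
    else:
        vol_a = total_volume_mm3
        vol_desc = "total volume"
    if n_lesions <= config.max_count_A and vol_a <= config.max_volume_A:
        group = "A"
        rule = (
            f"A: count {n_lesions} <= {config.max_count_A} and "
            f"{vol_desc} {vol_a:g} mm^3 <= {config.max_volume_A:g} mm^3"
        )
    elif n_lesions <= config.max_count_B and total_volume_mm3 <= config.max_volume_B:
        group = "B"
        rule = (
            f"B: not A, count {n_lesions} <= {config.max_count_B} and "
            f"total volume {total_volume_mm3:g} mm^3 <= {config.max_volume_B:g} mm^3"
        )
    else:
        group = "C"
        rule = (
            f"C: count {n_lesions} > {config.max_count_B} or "
            f"total volume {total_volume_mm3:g} mm^3 > {config.max_volume_B:g} mm^3"
        )
    return TriageAssignment(
        patient_id=patient_id,
        group=group,
        n_lesions=n_lesions,
        total_volume_mm3=float(total_volume_mm3),
        rule_fired=rule,
    )


def assign_group(scan: PatientScan, config: Optional[TriageConfig] = None) -> TriageAssignment:
    """Triage one patient from their lesion scan.

    A scan with zero detected lesions is group A (follow-up), the only
    coherent default when nothing requiring treatment was found.
    """
    return assign_group_from_counts(
        n_lesions=scan.n_lesions,
        total_volume_mm3=scan.total_volume_mm3,
        config=config,
        max_lesion_volume_mm3=scan.max_lesion_volume_mm3,
        patient_id=scan.patient_id,
    )


def map_treatment_to_group(record: ClinicalRecord) -> str:
    """Reference-standard group implied by the treatment actually given."""
    try:
        return _TREATMENT_TO_GROUP[record.actual_treatment]
    except KeyError:
        raise ValueError(
            f"patient {record.patient_id}: unknown treatment {record.actual_treatment!r}"
        ) from None


def apply_targeted_agent_rule(dls_group: str, record: ClinicalRecord) -> bool:
    """Whether a discordant patient counts as concordant under targeted therapy.

    For EGFR/ALK-mutant NSCLC without lesion-related symptoms, upfront
    targeted chemotherapy replaces local therapy as first-line treatment,
    so a patient triaged B whose actual treatment was chemotherapy is
    regarded as correctly suggested.
    """
    if dls_group not in GROUPS:
        raise ValueError(f"unknown group {dls_group!r}")
    mutant = record.egfr_alk_mutant
    symptomatic = record.symptomatic
    if mutant is None or symptomatic is None:  # pragma: no cover - dataclass defaults
        logger.warning(
            "patient %s: missing mutation/symptom flag, treated as False", record.patient_id
        )
        mutant = bool(mutant)
        symptomatic = bool(symptomatic)
    return (
        dls_group == "B"
        and record.actual_treatment == "chemo"
        and mutant
        and not symptomatic
    )


def dichotomize(group: str, patient_id: str = "") -> RiskLabel:
    """Low risk (follow-up, group A) versus high risk (treatment, B or C)."""
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    return RiskLabel(patient_id=patient_id, risk="low" if group == "A" else "high")
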