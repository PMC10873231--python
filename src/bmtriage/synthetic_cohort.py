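"""Synthetic brain-metastasis cohorts: ground truth, detector, decisions.

The generator emulates a clinical cohort of patients newly diagnosed with
brain metastases together with an imperfect voxel-wise detector, so that
every downstream stage (extraction, matching, triage, agreement, report)
is testable end to end without patient data.

Ground truth
    Per-patient lesion counts follow a zero-truncated negative binomial
    (over-dispersion is required: the cohort the defaults emulate has
    mean 8.5 lesions/patient with SD 12.22).  Per-lesion volumes are
    lognormal, with the two parameters solved in closed form so that the
    fraction of lesions below 65 mm^3 is 72.6% and the mean per-patient
    total volume is 1814.5 mm^3.  Optionally, lesions are rendered as
    non-overlapping digital spheres inside an ellipsoidal brain mask.

Detector
    Each true lesion is detected with probability expit(s * (ln V - ln
    m50)) — small lesions are missed more often — with the midpoint m50
    solved by quadrature so the expected lesion-wise sensitivity equals a
    target (default 876/952).  Detected volumes get multiplicative
    lognormal noise; false positives arrive as a per-patient Poisson
    count with their own (smaller) lognormal volumes; confidences are
    Beta-distributed, higher for true detections than for false ones.

Clinical decisions
    Each patient's actual treatment is drawn from the treatment set of
    their ground-truth triage group with probability 1 - epsilon, else
    from an adjacent group's set; a configurable subset of group-B
    patients is flagged EGFR/ALK-mutant and assigned upfront
    chemotherapy, the scenario the targeted-agent override addresses.

All generators are pure functions of (params, seed); per-patient
substreams are keyed by patient index so cohorts extend without
reshuffling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq, root
from scipy.special import expit
from scipy.stats import norm

from .lesion_io import ClinicalRecord, Lesion, PatientScan, VoxelGrid, equivalent_diameter
from .triage import TriageAssignment

__all__ = [
    "CohortParams",
    "DetectorParams",
    "simulate_ground_truth",
    "simulate_detector",
    "simulate_clinical_decisions",
]


@dataclass(frozen=True)
class CohortParams:
    """Ground-truth cohort parameters (defaults emulate the study cohort)."""

    n_patients: int = 112
    count_mean: float = 8.5  # lesions/patient, zero-truncated mean
    count_sd: float = 12.22
    frac_below_65: float = 0.726  # fraction of lesions with V < 65 mm^3
    frac_gt10: float = 0.223  # fraction of patients with > 10 lesions (descriptive)
    mean_total_volume_mm3: float = 1814.5  # mean per-patient total volume
    small_volume_cut_mm3: float = 65.0
    volume_log_mu: Optional[float] = None  # solved from the two constraints if None
    volume_log_sigma: Optional[float] = None
    grid_shape: tuple[int, int, int] = (96, 96, 96)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_below_65", "frac_gt10"):
            val = getattr(self, name)
            if not (0.0 <= val <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {val}")
        if self.count_mean <= 0 or self.count_sd <= 0:
            raise ValueError("count_mean and count_sd must be positive")
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")

    def volume_law(self) -> tuple[float, float]:
        """(mu, sigma) of the per-lesion lognormal volume distribution."""
        if self.volume_log_mu is not None and self.volume_log_sigma is not None:
            return self.volume_log_mu, self.volume_log_sigma
        mean_per_lesion = self.mean_total_volume_mm3 / self.count_mean
        return _solve_volume_lognormal(
            self.frac_below_65, mean_per_lesion, self.small_volume_cut_mm3
        )


@dataclass(frozen=True)
class DetectorParams:
    """Simulated-detector parameters (defaults calibrated to the study)."""

    sensitivity_target: float = 876.0 / 952.0
    miss_slope: float = 1.5  # logistic slope per log-volume unit
    miss_midpoint_mm3: Optional[float] = None  # solved from target if None
    fp_rate_per_patient: float = 160.0 / 112.0  # Poisson mean
    fp_volume_log_mu: float = math.log(30.0)  # FPs are small vessel-like mimics
    fp_volume_log_sigma: float = 1.0
    volume_noise_sigma: float = 0.2  # multiplicative, log scale
    tp_confidence_beta: tuple[float, float] = (6.0, 2.0)
    fp_confidence_beta: tuple[float, float] = (2.0, 5.0)
    seed: int = 1

    def __post_init__(self) -> None:
        if not (0.0 < self.sensitivity_target <= 1.0):
            raise ValueError("sensitivity_target must be in (0, 1]")
        if self.fp_rate_per_patient < 0:
            raise ValueError("fp_rate_per_patient must be non-negative")
        if self.volume_noise_sigma < 0:
            raise ValueError("volume_noise_sigma must be non-negative")


# ---------------------------------------------------------------------------
# Calibration solvers


@lru_cache(maxsize=None)
def _solve_volume_lognormal(frac_below: float, mean_mm3: float, cut_mm3: float) -> tuple[float, float]:
    """Lognormal (mu, sigma) with P(V < cut) = frac_below and E[V] = mean.

    With z = Phi^-1(frac_below), mu = ln(cut) - z*sigma, and
    E[V] = exp(mu + sigma^2/2) gives the quadratic
    sigma^2/2 - z*sigma - (ln mean - ln cut) = 0, whose positive root is
    sigma = z + sqrt(z^2 + 2 (ln mean - ln cut)).
    """
    z = float(norm.ppf(frac_below))
    c = math.log(mean_mm3) - math.log(cut_mm3)
    disc = z * z + 2.0 * c
    if disc <= 0:
        raise ValueError("volume constraints are infeasible for a lognormal law")
    sigma = z + math.sqrt(disc)
    mu = math.log(cut_mm3) - z * sigma
    return mu, sigma


@lru_cache(maxsize=None)
def _solve_ztnb(mean: float, sd: float) -> tuple[float, float]:
    """(mu, r) of the untruncated NB whose zero-truncation has given mean/SD."""
    target_m1 = mean
    target_m2 = sd * sd + mean * mean

    def eqs(theta):
        mu, r = np.exp(theta)
        p0 = (r / (r + mu)) ** r
        m1 = mu / (1.0 - p0)
        m2 = (mu + mu * mu / r + mu * mu) / (1.0 - p0)
        return [m1 - target_m1, m2 - target_m2]

    for r0 in (1.0, 0.1, 10.0, 100.0):
        sol = root(eqs, x0=np.log([mean, r0]))
        if sol.success and np.max(np.abs(sol.fun)) < 1e-6:
            mu, r = np.exp(sol.x)
            return float(mu), float(r)
    raise RuntimeError(
        f"zero-truncated NB calibration failed for mean={mean}, sd={sd}: {sol.message}"
    )


@lru_cache(maxsize=None)
def _count_law(mean: float, sd: float) -> tuple[str, float, float]:
    """Resolve the per-patient lesion-count law.

    Over-dispersed targets get the zero-truncated negative binomial; when
    the requested SD is below what that family reaches, the law falls back
    to a zero-truncated Poisson matched on the mean alone, and a mean at
    the lower bound of 1 degenerates to exactly one lesion per patient.
    """
    if mean <= 1.0 + 1e-9:
        return ("one", 0.0, 0.0)
    try:
        mu, r = _solve_ztnb(mean, sd)
        return ("ztnb", mu, r)
    except RuntimeError:
        mu = float(brentq(lambda m: m / (1.0 - math.exp(-m)) - mean, 1e-9, 1e3))
        return ("ztpoisson", mu, 0.0)


@lru_cache(maxsize=None)
def _solve_miss_midpoint(
    slope: float, vol_mu: float, vol_sigma: float, target_sensitivity: float
) -> float:
    """ln(m50) such that E[expit(slope*(lnV - ln m50))] = target sensitivity.

    The expectation over the lognormal volume law is evaluated with
    Gauss-Hermite quadrature; the midpoint is found by bisection.
    """
    nodes, weights = np.polynomial.hermite_e.hermegauss(96)
    weights = weights / math.sqrt(2.0 * math.pi)

    def expected_sensitivity(log_m50: float) -> float:
        logv = vol_mu + vol_sigma * nodes
        return float(np.sum(weights * expit(slope * (logv - log_m50))))

    lo = vol_mu - 12.0 * vol_sigma
    hi = vol_mu + 12.0 * vol_sigma
    return float(brentq(lambda m: expected_sensitivity(m) - target_sensitivity, lo, hi, xtol=1e-10))


# ---------------------------------------------------------------------------
# Ground truth


def _sample_counts(rng: np.random.Generator, law: tuple[str, float, float], size: int) -> np.ndarray:
    kind, mu, r = law
    if kind == "one":
        return np.ones(size, dtype=int)
    out = np.zeros(size, dtype=int)
    todo = np.ones(size, dtype=bool)
    while todo.any():
        n = int(todo.sum())
        if kind == "ztnb":
            out[todo] = rng.negative_binomial(r, r / (r + mu), size=n)
        else:
            out[todo] = rng.poisson(mu, size=n)
        todo = out == 0
    return out


def _patient_rng(seed: int, stream: int, index: int) -> np.random.Generator:
    return np.random.default_rng([seed, stream, index])


def _scan_from_volumes(
    patient_id: str, source: str, volumes: np.ndarray, spacing
) -> PatientScan:
    order = np.argsort(-volumes, kind="stable")
    lesions = [
        Lesion(
            lesion_id=i + 1,
            volume_mm3=float(volumes[j]),
            equivalent_diameter_mm=equivalent_diameter(float(volumes[j])),
        )
        for i, j in enumerate(order)
    ]
    return PatientScan(patient_id=patient_id, source=source, lesions=lesions, spacing=tuple(spacing))


def simulate_ground_truth(
    params: CohortParams, render_masks: bool = False
) -> list[PatientScan] | tuple[list[PatientScan], dict[str, VoxelGrid]]:
    """Draw a ground-truth cohort; optionally render label masks.

    Returns the list of scans, or (scans, {patient_id: VoxelGrid}) when
    ``render_masks`` is set.  Rendered lesions are digital spheres placed
    without overlap inside an ellipsoidal brain mask; scans then carry
    voxel sets and voxel-exact volumes.
    """
    count_law = _count_law(params.count_mean, params.count_sd)
    vol_mu, vol_sigma = params.volume_law()
    scans: list[PatientScan] = []
    grids: dict[str, VoxelGrid] = {}
    for i in range(params.n_patients):
        rng = _patient_rng(params.seed, 0, i)
        pid = f"P{i:04d}"
        n = int(_sample_counts(rng, count_law, 1)[0])
        volumes = np.exp(rng.normal(vol_mu, vol_sigma, size=n))
        if render_masks:
            scan, grid = _render_patient(pid, "ground_truth", volumes, params, rng)
            grids[pid] = grid
        else:
            scan = _scan_from_volumes(pid, "ground_truth", volumes, params.spacing)
        scans.append(scan)
    if render_masks:
        return scans, grids
    return scans


# ---------------------------------------------------------------------------
# Mask rendering


def _sphere_offsets(radius_mm: float, spacing) -> np.ndarray:
    """Voxel offsets whose centers fall within radius_mm of the origin."""
    spacing = np.asarray(spacing, dtype=float)
    half = np.maximum(np.floor(radius_mm / spacing).astype(int), 0)
    axes = [np.arange(-h, h + 1) for h in half]
    ii, jj, kk = np.meshgrid(*axes, indexing="ij")
    dist2 = (ii * spacing[0]) ** 2 + (jj * spacing[1]) ** 2 + (kk * spacing[2]) ** 2
    keep = dist2 <= radius_mm**2
    return np.column_stack([ii[keep], jj[keep], kk[keep]])


def _render_patient(
    pid: str, source: str, volumes: np.ndarray, params: CohortParams, rng: np.random.Generator
) -> tuple[PatientScan, VoxelGrid]:
    shape = np.asarray(params.grid_shape)
    spacing = np.asarray(params.spacing, dtype=float)
    values = np.zeros(tuple(shape), dtype=np.int16)
    center = (shape - 1) / 2.0
    semi = (shape - 1) / 2.0 - 1.0  # ellipsoid semi-axes in voxels
    placed: list[tuple[np.ndarray, float]] = []  # (center voxel, radius mm)
    lesions: list[Lesion] = []
    order = np.argsort(-volumes, kind="stable")
    for lab, j in enumerate(np.asarray(order), start=1):
        vol = float(volumes[j])
        radius = equivalent_diameter(vol) / 2.0
        offsets = _sphere_offsets(radius, spacing)
        ok = False
        for _try in range(300):
            cand = np.array([rng.uniform(0, s - 1) for s in shape])
            rel = (cand - center) / np.maximum(semi, 1e-9)
            margin = radius / float(spacing.min())
            if np.sum(rel**2) > (1.0 - margin / float(semi.min())) ** 2:
                continue
            cand_round = np.round(cand).astype(int)
            too_close = any(
                np.linalg.norm((cand_round - c0) * spacing) <= radius + r0 + float(spacing.max())
                for c0, r0 in placed
            )
            if too_close:
                continue
            vox = cand_round + offsets
            inside = np.all((vox >= 0) & (vox < shape), axis=1)
            vox = vox[inside]
            if vox.shape[0] == 0:
                continue
            values[vox[:, 0], vox[:, 1], vox[:, 2]] = lab
            placed.append((cand_round, radius))
            vvol = vox.shape[0] * float(np.prod(spacing))
            centroid = tuple(float(c) for c in (vox.mean(axis=0) * spacing))
            lesions.append(
                Lesion(
                    lesion_id=lab,
                    volume_mm3=vvol,
                    equivalent_diameter_mm=equivalent_diameter(vvol),
                    centroid_mm=centroid,
                    voxel_indices=frozenset(map(tuple, vox.tolist())),
                )
            )
            ok = True
            break
        if not ok:
            raise RuntimeError(
                f"patient {pid}: could not place lesion of {vol:.0f} mm^3 "
                f"in grid {tuple(shape)} without overlap"
            )
    scan = PatientScan(patient_id=pid, source=source, lesions=lesions, spacing=tuple(spacing))
    return scan, VoxelGrid(values=values, spacing=tuple(spacing))


# ---------------------------------------------------------------------------
# Detector


def simulate_detector(
    gt_scans: Sequence[PatientScan],
    params: DetectorParams,
    cohort_params: Optional[CohortParams] = None,
    masks: Optional[dict[str, VoxelGrid]] = None,
) -> list[PatientScan] | tuple[list[PatientScan], dict[str, VoxelGrid]]:
    """Simulate an imperfect detector over a ground-truth cohort.

    Each detection records its source lesion id, so table-based cohorts
    can be matched by provenance; when ``masks`` are supplied, detections
    are rendered as spheres centered on their source lesion (guaranteeing
    >= 1 voxel overlap) and false positives away from all true lesions,
    and (scans, mask dict) is returned.
    """
    cohort_params = cohort_params or CohortParams()
    if params.miss_midpoint_mm3 is not None:
        log_m50 = math.log(params.miss_midpoint_mm3)
    elif params.sensitivity_target >= 1.0:
        log_m50 = -math.inf  # perfect detector: every lesion detected
    else:
        vol_mu, vol_sigma = cohort_params.volume_law()
        log_m50 = _solve_miss_midpoint(
            params.miss_slope, vol_mu, vol_sigma, params.sensitivity_target
        )
    out: list[PatientScan] = []
    out_grids: dict[str, VoxelGrid] = {}
    for i, gt in enumerate(gt_scans):
        rng = _patient_rng(params.seed, 1, i)
        detections: list[tuple[float, float, Optional[int]]] = []  # (volume, conf, src)
        for les in gt.lesions:
            p_detect = float(expit(params.miss_slope * (math.log(les.volume_mm3) - log_m50)))
            if rng.uniform() >= p_detect:
                continue
            if params.volume_noise_sigma > 0:
                vol = les.volume_mm3 * math.exp(rng.normal(0.0, params.volume_noise_sigma))
            else:
                vol = les.volume_mm3
            conf = float(rng.beta(*params.tp_confidence_beta))
            detections.append((vol, conf, les.lesion_id))
        n_fp = int(rng.poisson(params.fp_rate_per_patient))
        for _ in range(n_fp):
            vol = float(np.exp(rng.normal(params.fp_volume_log_mu, params.fp_volume_log_sigma)))
            conf = float(rng.beta(*params.fp_confidence_beta))
            detections.append((vol, conf, None))
        detections.sort(key=lambda d: (-d[0], d[1]))
        if masks is not None:
            scan, grid = _render_detections(gt, detections, masks[gt.patient_id], rng)
            out_grids[gt.patient_id] = grid
        else:
            lesions = [
                Lesion(
                    lesion_id=k + 1,
                    volume_mm3=vol,
                    equivalent_diameter_mm=equivalent_diameter(vol),
                    confidence=conf,
                    source_gt_id=src,
                )
                for k, (vol, conf, src) in enumerate(detections)
            ]
            scan = PatientScan(
                patient_id=gt.patient_id, source="detector", lesions=lesions, spacing=gt.spacing
            )
        out.append(scan)
    if masks is not None:
        return out, out_grids
    return out


def _render_detections(
    gt: PatientScan,
    detections: list[tuple[float, float, Optional[int]]],
    gt_grid: VoxelGrid,
    rng: np.random.Generator,
) -> tuple[PatientScan, VoxelGrid]:
    spacing = np.asarray(gt_grid.spacing, dtype=float)
    shape = np.asarray(gt_grid.shape)
    values = np.zeros(tuple(shape), dtype=np.int16)
    gt_by_id = {l.lesion_id: l for l in gt.lesions}
    lesions: list[Lesion] = []
    lab = 0
    occupied = gt_grid.values > 0
    for vol, conf, src in detections:
        radius = equivalent_diameter(vol) / 2.0
        offsets = _sphere_offsets(radius, spacing)
        if src is not None:
            center = np.round(np.asarray(gt_by_id[src].centroid_mm) / spacing).astype(int)
        else:
            center = None
            for _try in range(300):
                cand = np.array([rng.integers(0, s) for s in shape])
                vox = cand + offsets
                inside = np.all((vox >= 0) & (vox < shape), axis=1)
                if not inside.all() or np.any(occupied[tuple(vox.T)]):
                    continue
                center = cand
                break
            if center is None:
                continue  # skip unplaceable FP rather than fail the cohort
        vox = center + offsets
        inside = np.all((vox >= 0) & (vox < shape), axis=1)
        vox = vox[inside]
        if vox.shape[0] == 0:
            continue
        lab += 1
        values[vox[:, 0], vox[:, 1], vox[:, 2]] = lab
        vvol = vox.shape[0] * float(np.prod(spacing))
        lesions.append(
            Lesion(
                lesion_id=lab,
                volume_mm3=vvol,
                equivalent_diameter_mm=equivalent_diameter(vvol),
                centroid_mm=tuple(float(c) for c in (vox.mean(axis=0) * spacing)),
                confidence=conf,
                voxel_indices=frozenset(map(tuple, vox.tolist())),
                source_gt_id=src,
            )
        )
    scan = PatientScan(
        patient_id=gt.patient_id, source="detector", lesions=lesions, spacing=tuple(gt_grid.spacing)
    )
    return scan, VoxelGrid(values=values, spacing=gt_grid.spacing)


# ---------------------------------------------------------------------------
# Clinical decisions

_GROUP_TREATMENTS = {
    # treatment sets per triage group, with draw weights reflecting the
    # treatment mix of the emulated cohort (SRS dominates group B; systemic
    # chemotherapy is more common than WBRT in group C)
    "A": (("follow_up",), (1.0,)),
    "B": (("srs", "surgery"), (56.0 / 57.0, 1.0 / 57.0)),
    "C": (("chemo", "wbrt"), (21.0 / 32.0, 11.0 / 32.0)),
}

_ADJACENT = {"A": ("B",), "B": ("A", "C"), "C": ("B",)}


def simulate_clinical_decisions(
    gt_triage: Sequence[TriageAssignment],
    epsilon: float = 0.11,
    mutant_b_fraction: float = 5.0 / 60.0,
    n_mutant_chemo: Optional[int] = None,
    seed: int = 2,
) -> list[ClinicalRecord]:
    """Draw actual treatments consistent with ground-truth triage groups.

    With probability ``epsilon`` a patient's treatment comes from an
    adjacent group's set (clinical discretion); otherwise from their own
    group's set.  Among group-B patients whose drawn treatment was local
    therapy, a fraction ``mutant_b_fraction`` (or exactly
    ``n_mutant_chemo`` patients, when given) is flagged EGFR/ALK-mutant,
    asymptomatic, and switched to upfront chemotherapy — the patients
    the targeted-agent override re-classifies as concordant.
    """
    if not (0.0 <= epsilon <= 1.0):
        raise ValueError("epsilon must be in [0, 1]")
    records: list[ClinicalRecord] = []
    eligible: list[int] = []  # indices of concordant local-therapy B patients
    for i, assignment in enumerate(gt_triage):
        rng = _patient_rng(seed, 2, i)
        group = assignment.group
        if epsilon > 0 and rng.uniform() < epsilon:
            group = str(rng.choice(_ADJACENT[group]))
        treatments, weights = _GROUP_TREATMENTS[group]
        treatment = str(rng.choice(treatments, p=weights))
        if assignment.group == "B" and group == "B" and treatment in ("srs", "surgery"):
            eligible.append(i)
        records.append(
            ClinicalRecord(
                patient_id=assignment.patient_id,
                actual_treatment=treatment,
                egfr_alk_mutant=False,
                symptomatic=False,
                primary_site="lung_nsclc",
            )
        )
    cohort_rng = np.random.default_rng([seed, 3, 0])
    if n_mutant_chemo is not None:
        n_pick = min(n_mutant_chemo, len(eligible))
        picked = cohort_rng.choice(len(eligible), size=n_pick, replace=False) if n_pick else []
        chosen = {eligible[int(j)] for j in np.atleast_1d(picked)}
    else:
        chosen = {i for i in eligible if cohort_rng.uniform() < mutant_b_fraction}
    for i in chosen:
        records[i] = replace(records[i], actual_treatment="chemo", egfr_alk_mutant=True)
    return records
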