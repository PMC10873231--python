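import numpy as np
import pytest

from bmtriage import (
    CohortParams,
    DetectorParams,
    Lesion,
    PatientScan,
    equivalent_diameter,
)


def scan_from_voxel_sets(patient_id, source, voxel_sets, spacing=(1.0, 1.0, 1.0), confidences=None):
    """Build a PatientScan directly from explicit voxel sets (test helper)."""
    lesions = []
    voxvol = float(np.prod(spacing))
    for i, vox in enumerate(voxel_sets, start=1):
        vol = len(vox) * voxvol
        lesions.append(
            Lesion(
                lesion_id=i,
                volume_mm3=vol,
                equivalent_diameter_mm=equivalent_diameter(vol),
                voxel_indices=frozenset(vox),
                confidence=None if confidences is None else confidences[i - 1],
            )
        )
    return PatientScan(patient_id=patient_id, source=source, lesions=lesions, spacing=spacing)


def table_scan(patient_id, source, volumes, confidences=None, source_gt_ids=None):
    """Build a table-style PatientScan (no voxel sets) from volumes."""
    lesions = []
    for i, vol in enumerate(volumes, start=1):
        lesions.append(
            Lesion(
                lesion_id=i,
                volume_mm3=float(vol),
                equivalent_diameter_mm=equivalent_diameter(float(vol)),
                confidence=None if confidences is None else confidences[i - 1],
                source_gt_id=None if source_gt_ids is None else source_gt_ids[i - 1],
            )
        )
    return PatientScan(patient_id=patient_id, source=source, lesions=lesions)


@pytest.fixture(scope="session")
def small_render_params():
    """Cohort parameters small enough to render masks quickly."""
    return CohortParams(
        n_patients=3,
        count_mean=3.0,
        count_sd=2.0,
        volume_log_mu=float(np.log(60.0)),
        volume_log_sigma=0.7,
        grid_shape=(48, 48, 48),
        spacing=(1.0, 1.0, 1.0),
        seed=11,
    )


@pytest.fixture(scope="session")
def perfect_detector_params():
    return DetectorParams(
        sensitivity_target=1.0,
        fp_rate_per_patient=0.0,
        volume_noise_sigma=0.0,
        seed=3,
    )
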