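"""Ground-truth extravasation activity from static PET volumes.

Total excess activity near the injection site, I_TOT, is measured with a
dual volume-of-interest (VOI) approach: a VOI over the injection-arm tissue
and a matched VOI on the contralateral (reference) arm.  The reference sum,
scaled by the VOI volume ratio, estimates what the injection VOI would
contain under normal physiological uptake alone, and is subtracted:

    I_TOT = V_V * [ sum_i m_I,i x_i  -  (V_I / V_R) * sum_i m_R,i x_i ]

where ``x`` is the PET image in Bq/ml, ``V_V`` the voxel volume, ``m_I`` /
``m_R`` the binary injection/reference masks, and ``V_I`` / ``V_R`` their
volumes.  Both masks are refined from the hand-drawn VOIs by an SUV >= 0.2
threshold to suppress noisy background voxels.

I_TOT, normalized by the decay-compensated injected dose A_INJ, is the
severity statistic I_TOT / A_INJ used throughout the classifier.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from .tac import F18_HALF_LIFE_MIN

SUV_THRESHOLD_DEFAULT = 0.2


class PetValidationError(ValueError):
    """Raised for inconsistent PET volumes, masks, or metadata."""


@dataclass
class PetStudy:
    """A static PET volume with injection/reference VOIs and dose metadata.

    ``volume`` holds voxel values in Bq/ml at ``scan_start_time`` (seconds
    after injection).  ``injected_activity`` is A_INJ in MBq at injection
    time; ``voxel_volume`` is in ml.  Masks are boolean arrays on the same
    grid and must be disjoint and nonempty.
    """

    volume: np.ndarray
    voxel_volume: float
    injection_voi: np.ndarray
    reference_voi: np.ndarray
    injected_activity: float  # MBq at injection time
    body_weight: float  # kg
    scan_start_time: float  # s after injection
    subject_id: str = ""
    half_life: float = F18_HALF_LIFE_MIN  # minutes

    def __post_init__(self) -> None:
        self.volume = np.asarray(self.volume, dtype=float)
        self.injection_voi = np.asarray(self.injection_voi).astype(bool)
        self.reference_voi = np.asarray(self.reference_voi).astype(bool)
        if self.injection_voi.shape != self.volume.shape or (
            self.reference_voi.shape != self.volume.shape
        ):
            raise PetValidationError(
                f"mask/volume grid mismatch: volume {self.volume.shape}, "
                f"injection {self.injection_voi.shape}, reference {self.reference_voi.shape}"
            )
        if self.voxel_volume <= 0:
            raise PetValidationError("voxel_volume must be positive")
        if np.any(self.injection_voi & self.reference_voi):
            raise PetValidationError("injection and reference VOIs overlap")
        if not self.injection_voi.any() or not self.reference_voi.any():
            raise PetValidationError("both VOIs must be nonempty")


@dataclass(frozen=True)
class ActivityEstimate:
    """Total excess injection-site activity and its dose-normalized form.

    ``i_tot`` is in MBq, decay-referenced to injection time.  ``fraction``
    is max(i_tot, 0) / A_INJ — negative estimates (possible under image
    noise) are preserved in ``i_tot`` but floored before classification,
    since severity classes are defined on nonnegative fractions.
    ``source`` is ``"pet_image"`` or ``"detector_calibrated"``.
    """

    i_tot: float
    fraction: float
    source: str = "pet_image"


def decayed_dose_bq(study: PetStudy, at_scan: bool = True) -> float:
    """Injected dose in Bq, optionally decayed to scan start."""
    dose = study.injected_activity * 1e6
    if at_scan:
        dose *= np.exp2(-study.scan_start_time / (study.half_life * 60.0))
    return float(dose)


def suv_volume(study: PetStudy, dose_at_scan: bool = True) -> np.ndarray:
    """Standardized uptake value per voxel.

    SUV_i = x_i [Bq/ml] * body weight [g] / dose [Bq], with the dose decayed
    to scan start by default (the usual SUV convention; set
    ``dose_at_scan=False`` to normalize by the dose at injection instead).
    Assumes 1 g/ml tissue density.
    """
    if not np.isfinite(study.body_weight) or study.body_weight <= 0:
        raise PetValidationError("body_weight must be positive for SUV")
    if not np.isfinite(study.injected_activity) or study.injected_activity <= 0:
        raise PetValidationError("injected_activity must be positive for SUV")
    weight_g = study.body_weight * 1000.0
    return study.volume * weight_g / decayed_dose_bq(study, at_scan=dose_at_scan)


def refine_mask(
    voi: np.ndarray, suv: np.ndarray, threshold: float = SUV_THRESHOLD_DEFAULT
) -> np.ndarray:
    """Restrict a VOI to voxels with SUV >= threshold.

    Suppresses noisy background voxels inside the generously drawn VOIs.
    Idempotent and anti-extensive; the result may be empty.
    """
    voi = np.asarray(voi).astype(bool)
    if voi.shape != np.asarray(suv).shape:
        raise PetValidationError("VOI and SUV volume shapes differ")
    return voi & (np.asarray(suv) >= threshold)


def total_extravasation_activity(
    study: PetStudy,
    suv_threshold: float = SUV_THRESHOLD_DEFAULT,
    refine: bool = True,
) -> ActivityEstimate:
    """Dual-VOI total excess activity I_TOT and the fraction I_TOT / A_INJ.

    The voxel sums run over the SUV-refined masks; the reference-arm sum is
    scaled by the refined-volume ratio V_I / V_R before subtraction, so any
    shared physiological background cancels.  The Bq result (valid at scan
    start) is decay-referenced to injection time and converted to MBq, so
    the fraction shares A_INJ's reference frame.
    """
    if refine:
        suv = suv_volume(study)
        m_i = refine_mask(study.injection_voi, suv, suv_threshold)
        m_r = refine_mask(study.reference_voi, suv, suv_threshold)
    else:
        m_i = study.injection_voi
        m_r = study.reference_voi
    n_r = int(np.count_nonzero(m_r))
    if n_r == 0:
        raise PetValidationError(
            "refined reference mask is empty; cannot normalize background"
        )
    n_i = int(np.count_nonzero(m_i))
    x = study.volume
    i_tot_bq = study.voxel_volume * (
        float(x[m_i].sum()) - (n_i / n_r) * float(x[m_r].sum())
    )
    # refer to injection time so the fraction uses one decay frame
    i_tot_mbq = i_tot_bq * np.exp2(study.scan_start_time / (study.half_life * 60.0)) / 1e6
    fraction = max(i_tot_mbq, 0.0) / study.injected_activity
    return ActivityEstimate(i_tot=float(i_tot_mbq), fraction=float(fraction), source="pet_image")


def read_pet_nifti(
    volume_path: str | Path,
    injection_voi_path: str | Path,
    reference_voi_path: str | Path,
    meta: str | Path | dict,
) -> PetStudy:
    """Load a PET study from NIfTI files plus a subject metadata mapping.

    ``meta`` (dict or JSON path) must provide ``injected_activity_mbq``,
    ``body_weight_kg`` and ``pet_start_s``; ``subject_id`` and
    ``half_life_min`` are optional.  The voxel volume is computed from the
    header spacing (e.g. 4.1 x 4.1 x 5.0 mm -> 0.084 ml).  All three images
    must share the same grid.
    """
    if not isinstance(meta, dict):
        meta = json.loads(Path(meta).read_text())
    vol_img = nib.load(str(volume_path))
    inj_img = nib.load(str(injection_voi_path))
    ref_img = nib.load(str(reference_voi_path))
    shapes = {vol_img.shape, inj_img.shape, ref_img.shape}
    if len(shapes) != 1:
        raise PetValidationError(
            f"grid mismatch: volume {vol_img.shape}, injection VOI "
            f"{inj_img.shape}, reference VOI {ref_img.shape}"
        )
    zooms = vol_img.header.get_zooms()[:3]
    voxel_volume_ml = float(np.prod(zooms)) / 1000.0  # mm^3 -> ml
    return PetStudy(
        volume=np.asarray(vol_img.get_fdata(), dtype=float),
        voxel_volume=voxel_volume_ml,
        injection_voi=np.asarray(inj_img.get_fdata()) > 0.5,
        reference_voi=np.asarray(ref_img.get_fdata()) > 0.5,
        injected_activity=float(meta["injected_activity_mbq"]),
        body_weight=float(meta["body_weight_kg"]),
        scan_start_time=float(meta["pet_start_s"]),
        subject_id=str(meta.get("subject_id", "")),
        half_life=float(meta.get("half_life_min", F18_HALF_LIFE_MIN)),
    )


def write_pet_nifti(study: PetStudy, out_dir: str | Path, spacing_mm=(4.1, 4.1, 5.0)) -> dict:
    """Write a study's volume and VOIs as NIfTI files; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(spacing_mm) + [1.0])
    paths = {}
    for name, data in (
        ("pet", study.volume),
        ("injection_voi", study.injection_voi.astype(np.uint8)),
        ("reference_voi", study.reference_voi.astype(np.uint8)),
    ):
        img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)
        img.header.set_zooms(spacing_mm)
        path = out_dir / f"{study.subject_id or 'subject'}_{name}.nii.gz"
        nib.save(img, str(path))
        paths[name] = path
    return paths
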