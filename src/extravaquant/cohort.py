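"""Synthetic patient-cohort simulator.

Generates mutually consistent per-subject records — paired detector TACs,
voxelized two-arm PET phantoms, and exact ground truth — with the
statistical structure the pipeline assumes, so every stage and the full
evaluation run with no external data:

* 1 Hz paired TACs with Poisson counting noise on the physical (decayed)
  rate, a shared body-background rise-to-plateau in both arms, an injection
  bolus transient on the injection detector, exponential biological
  resolution of the extravasation, and occasional baseline-shift artifacts;
* two-arm phantoms on a PET-like grid (4.1 x 4.1 x 5.0 mm voxels) with
  equal physiological uptake in both arm cylinders and a 3-D Gaussian
  insert in the injection arm whose voxel-summed activity equals the truth
  exactly by construction;
* detector response modeled as a single multiplicative geometry factor per
  subject, with lognormal scatter, tied to the configured log-log
  calibration truth (b0*, b1*) so the cohort-level relation between PET
  activity and adjusted detector difference is known.

Cohort-level distributions default to the study conditions: injected
activity 320 +/- 86 MBq, uptake time 68.0 +/- 13.7 min, and a roughly
half-extravasated cohort with severity fractions log-uniform on
[0.001, 0.5] of the injected dose.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .classify import SeverityClass, classify_severity
from .pet import PetStudy
from .tac import F18_HALF_LIFE_MIN, F18_POSITRON_FRACTION, Tac, TacPair


class CohortConfigError(ValueError):
    """Raised when a cohort configuration is invalid."""


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition parameters for the simulator.

    Activities in MBq, times in the stated units.  ``calibration_truth``
    are (b0*, b1*) of the generating log-log relation between PET activity
    (Bq, injection-referenced) and the positron-fraction-adjusted detector
    difference (cps); ``geometry_sigma_log`` is the lognormal scatter of
    the per-subject detector geometry factor about that relation.
    """

    n_subjects: int = 24
    injected_activity_mean: float = 320.0  # MBq
    injected_activity_sd: float = 86.0
    injected_activity_min: float = 50.0  # truncation, keeps draws physical
    uptake_time_mean: float = 68.0  # min
    uptake_time_sd: float = 13.7
    uptake_time_min: float = 35.0  # truncation
    pet_gap_s: float = 900.0  # detector removal to PET start
    extravasated_fraction_of_cohort: float = 0.75
    fraction_low: float = 0.001  # log-uniform severity fraction bounds
    fraction_high: float = 0.5
    clearance_halflife_median_min: float = 45.0
    clearance_halflife_sigma_log: float = 0.5
    clearance_halflife_bounds_min: tuple[float, float] = (10.0, 240.0)
    calibration_truth: tuple[float, float] = (8.0, 1.2)  # (b0*, b1*)
    geometry_sigma_log: float = 0.3
    background_plateau_median_cps: float = 1000.0
    background_plateau_sigma_log: float = 0.3
    background_rise_tau_bounds_s: tuple[float, float] = (60.0, 180.0)
    spike_prob: float = 1.0
    spike_amp_median_cps: float = 20000.0
    spike_amp_sigma_log: float = 0.5
    spike_tau_s: float = 30.0
    baseline_shift_prob: float = 0.1
    baseline_shift_mag_bounds_cps: tuple[float, float] = (100.0, 500.0)
    baseline_shift_window_s: tuple[float, float] | None = None  # default: [600, end-60]
    poisson_noise: bool = True
    body_weight_mean_kg: float = 80.0
    body_weight_sd_kg: float = 15.0
    body_weight_bounds_kg: tuple[float, float] = (45.0, 140.0)
    phantom_shape: tuple[int, int, int] = (40, 40, 20)
    phantom_spacing_mm: tuple[float, float, float] = (4.1, 4.1, 5.0)
    arm_radius_mm: float = 18.0
    arm_suv: float = 0.5
    insert_sigma_mm: float = 6.0
    voi_margin_voxels: int = 3
    pet_noise_sigma_bqml: float = 50.0
    half_life: float = F18_HALF_LIFE_MIN
    positron_fraction: float = F18_POSITRON_FRACTION

    def __post_init__(self) -> None:
        problems = []
        for name in (
            "injected_activity_mean", "injected_activity_sd", "uptake_time_mean",
            "uptake_time_sd", "pet_gap_s", "clearance_halflife_median_min",
            "background_plateau_median_cps", "arm_radius_mm", "insert_sigma_mm",
            "body_weight_mean_kg",
        ):
            if getattr(self, name) <= 0:
                problems.append(f"{name} must be > 0")
        for name in ("extravasated_fraction_of_cohort", "spike_prob", "baseline_shift_prob"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                problems.append(f"{name} must be in [0, 1]")
        if not (0 < self.fraction_low < self.fraction_high <= 1.0):
            problems.append("need 0 < fraction_low < fraction_high <= 1")
        if self.n_subjects < 1:
            problems.append("n_subjects must be >= 1")
        if problems:
            raise CohortConfigError("; ".join(problems))

    def noiseless(self) -> "CohortConfig":
        """Copy with every stochastic corruption disabled (the generating
        model itself stays random across subjects)."""
        return replace(
            self,
            geometry_sigma_log=0.0,
            poisson_noise=False,
            baseline_shift_prob=0.0,
            pet_noise_sigma_bqml=0.0,
        )


@dataclass(frozen=True)
class SubjectTruth:
    """Exact ground truth for one simulated subject.

    ``activity_mbq`` is the extravasation activity at PET start,
    decay-referenced to injection time (so ``fraction =
    activity_mbq / injected_activity``); ``d_hat_cps`` is the raw
    (decay-corrected, not positron-adjusted) detector difference the
    injection arm carries at PET start.
    """

    subject_id: str
    injected_activity: float  # MBq at injection
    body_weight: float  # kg
    uptake_time_s: float  # PET start, s after injection
    detector_removal_s: float
    activity_mbq: float
    fraction: float
    severity: SeverityClass
    d_hat_cps: float
    clearance_rate_per_min: float
    baseline_shift: bool


def _truncated_normal(rng, mean, sd, low, high=np.inf):
    while True:
        x = rng.normal(mean, sd)
        if low <= x <= high:
            return float(x)


def _draw_subject_params(rng: np.random.Generator, config: CohortConfig, sid: str):
    """All per-subject random draws, in a fixed order for reproducibility."""
    a_inj = _truncated_normal(
        rng, config.injected_activity_mean, config.injected_activity_sd,
        config.injected_activity_min,
    )
    uptake_min = _truncated_normal(
        rng, config.uptake_time_mean, config.uptake_time_sd, config.uptake_time_min
    )
    weight = _truncated_normal(
        rng, config.body_weight_mean_kg, config.body_weight_sd_kg,
        *config.body_weight_bounds_kg,
    )
    extravasated = rng.random() < config.extravasated_fraction_of_cohort
    if extravasated:
        log_f = rng.uniform(np.log(config.fraction_low), np.log(config.fraction_high))
        fraction = float(np.exp(log_f))
    else:
        fraction = 0.0
    bio_half = float(
        np.clip(
            config.clearance_halflife_median_min
            * np.exp(rng.normal(0.0, config.clearance_halflife_sigma_log)),
            *config.clearance_halflife_bounds_min,
        )
    )
    geom_eps = rng.normal(0.0, config.geometry_sigma_log) if config.geometry_sigma_log > 0 else 0.0
    plateau = config.background_plateau_median_cps * float(
        np.exp(rng.normal(0.0, config.background_plateau_sigma_log))
    )
    rise_tau = rng.uniform(*config.background_rise_tau_bounds_s)
    spike = rng.random() < config.spike_prob
    spike_amp = config.spike_amp_median_cps * float(
        np.exp(rng.normal(0.0, config.spike_amp_sigma_log))
    )
    shift = rng.random() < config.baseline_shift_prob
    shift_mag = float(
        rng.uniform(*config.baseline_shift_mag_bounds_cps) * rng.choice([-1.0, 1.0])
    )
    shift_frac = rng.random()  # position within the allowed window

    pet_start = uptake_min * 60.0
    removal = pet_start - config.pet_gap_s
    activity_mbq = fraction * a_inj
    b0, b1 = config.calibration_truth
    if activity_mbq > 0:
        d_adj = float(np.exp((np.log(activity_mbq * 1e6) - b0) / b1 + geom_eps))
        d_raw = d_adj * config.positron_fraction
    else:
        d_raw = 0.0
    truth = SubjectTruth(
        subject_id=sid,
        injected_activity=a_inj,
        body_weight=weight,
        uptake_time_s=pet_start,
        detector_removal_s=removal,
        activity_mbq=activity_mbq,
        fraction=fraction,
        severity=classify_severity(fraction),
        d_hat_cps=d_raw,
        clearance_rate_per_min=float(np.log(2) / bio_half),
        baseline_shift=shift,
    )
    extras = dict(
        plateau=plateau, rise_tau=rise_tau,
        spike=spike, spike_amp=spike_amp,
        shift_mag=shift_mag, shift_frac=shift_frac,
    )
    return truth, extras


def generate_tac_pair(
    truth: SubjectTruth,
    config: CohortConfig,
    rng: np.random.Generator,
    extras: dict | None = None,
) -> TacPair:
    """Simulate the paired 1 Hz detector record for one subject.

    Both arms share a rise-to-plateau body background B(t); the injection
    arm adds g * A_ex(t) with A_ex the decay-corrected extravasation
    activity resolving exponentially, g fixed by ``truth.d_hat_cps`` at PET
    start.  Counts are drawn Poisson per 1 s bin on the physical (decayed)
    rate; raw (uncorrected) TACs are returned.  The optional injection
    bolus transient and baseline-shift step act on the injection detector.
    """
    if extras is None:
        extras = dict(
            plateau=config.background_plateau_median_cps,
            rise_tau=float(np.mean(config.background_rise_tau_bounds_s)),
            spike=config.spike_prob >= 1.0,
            spike_amp=config.spike_amp_median_cps,
            shift_mag=0.0,
            shift_frac=0.5,
        )
    t = np.arange(0.0, max(truth.detector_removal_s, 120.0) + 1.0)
    bg = extras["plateau"] * (1.0 - np.exp(-t / extras["rise_tau"]))

    k_bio = truth.clearance_rate_per_min / 60.0  # per second
    if truth.activity_mbq > 0:
        # geometry factor from the required difference at PET start
        a_ex_pet = truth.activity_mbq  # MBq, injection-referenced
        g = truth.d_hat_cps / a_ex_pet
        a_ex = truth.activity_mbq * np.exp(k_bio * (truth.uptake_time_s - t))
        excess = g * a_ex
    else:
        excess = np.zeros_like(t)

    inj = bg + excess
    if extras["spike"]:
        inj = inj + extras["spike_amp"] * np.exp(-t / config.spike_tau_s)
    if truth.baseline_shift:
        window = config.baseline_shift_window_s or (600.0, max(t[-1] - 60.0, 660.0))
        t_shift = window[0] + extras["shift_frac"] * (window[1] - window[0])
        inj = inj + extras["shift_mag"] * (t >= t_shift)

    decay = np.exp2(-t / (config.half_life * 60.0))
    inj_phys = np.clip(inj, 0.0, None) * decay
    ref_phys = bg * decay
    if config.poisson_noise:
        inj_rate = rng.poisson(inj_phys).astype(float)
        ref_rate = rng.poisson(ref_phys).astype(float)
    else:
        inj_rate, ref_rate = inj_phys, ref_phys
    return TacPair(
        injection=Tac(t, inj_rate),
        reference=Tac(t, ref_rate),
        subject_id=truth.subject_id,
        injected_activity=truth.injected_activity,
        detector_removal_time=truth.detector_removal_s,
        pet_start_time=truth.uptake_time_s,
        half_life=config.half_life,
    )


def generate_pet_phantom(
    truth: SubjectTruth, config: CohortConfig, rng: np.random.Generator
) -> PetStudy:
    """Voxelized two-arm phantom with a known injection-arm insert.

    Two parallel arm cylinders (along z) carry equal physiological uptake
    at SUV ``arm_suv``; the injection arm additionally holds a 3-D Gaussian
    insert normalized on the voxel grid so its summed activity equals the
    truth activity at scan start exactly, then optional Gaussian voxel
    noise is added.  Box VOIs exceed both arms and the insert.
    """
    nx, ny, nz = config.phantom_shape
    sx, sy, sz = config.phantom_spacing_mm
    voxel_ml = sx * sy * sz / 1000.0
    x = (np.arange(nx) + 0.5) * sx
    y = (np.arange(ny) + 0.5) * sy
    z = (np.arange(nz) + 0.5) * sz
    xx, yy, zz = np.meshgrid(x, y, z, indexing="ij")

    inj_center = np.array([nx * sx * 0.25, ny * sy * 0.5])
    ref_center = np.array([nx * sx * 0.75, ny * sy * 0.5])
    r_inj = np.hypot(xx - inj_center[0], yy - inj_center[1])
    r_ref = np.hypot(xx - ref_center[0], yy - ref_center[1])
    inj_arm = r_inj <= config.arm_radius_mm
    ref_arm = r_ref <= config.arm_radius_mm

    dose_scan_bq = truth.injected_activity * 1e6 * np.exp2(
        -truth.uptake_time_s / (config.half_life * 60.0)
    )
    bg_conc = config.arm_suv * dose_scan_bq / (truth.body_weight * 1000.0)  # Bq/ml
    volume = np.zeros(config.phantom_shape)
    volume[inj_arm] = bg_conc
    volume[ref_arm] = bg_conc

    insert_bq_scan = truth.activity_mbq * 1e6 * np.exp2(
        -truth.uptake_time_s / (config.half_life * 60.0)
    )
    if insert_bq_scan > 0:
        c = np.array([inj_center[0], inj_center[1], nz * sz * 0.5])
        sig = config.insert_sigma_mm
        if (
            c[0] < 3 * sig or c[1] < 3 * sig or c[2] < 3 * sig
            or nx * sx - c[0] < 3 * sig or ny * sy - c[1] < 3 * sig or nz * sz - c[2] < 3 * sig
        ):
            raise CohortConfigError("insert spills outside the phantom grid")
        shape_fn = np.exp(
            -((xx - c[0]) ** 2 + (yy - c[1]) ** 2 + (zz - c[2]) ** 2) / (2 * sig**2)
        )
        # normalize on the grid: voxel sum * V_V equals the truth exactly
        shape_fn *= insert_bq_scan / (shape_fn.sum() * voxel_ml)
        volume += shape_fn

    if config.pet_noise_sigma_bqml > 0:
        volume = volume + rng.normal(0.0, config.pet_noise_sigma_bqml, size=volume.shape)

    def box(mask_arm: np.ndarray) -> np.ndarray:
        idx = np.nonzero(mask_arm)
        m = config.voi_margin_voxels
        out = np.zeros(config.phantom_shape, dtype=bool)
        out[
            max(idx[0].min() - m, 0) : idx[0].max() + m + 1,
            max(idx[1].min() - m, 0) : idx[1].max() + m + 1,
            :,
        ] = True
        return out

    return PetStudy(
        volume=volume,
        voxel_volume=voxel_ml,
        injection_voi=box(inj_arm),
        reference_voi=box(ref_arm),
        injected_activity=truth.injected_activity,
        body_weight=truth.body_weight,
        scan_start_time=truth.uptake_time_s,
        subject_id=truth.subject_id,
        half_life=config.half_life,
    )


def generate_cohort(
    config: CohortConfig | None = None,
    seed: int = 0,
    phantoms: bool = True,
) -> tuple[list[TacPair], list[PetStudy], list[SubjectTruth]]:
    """Generate a full synthetic cohort, reproducibly from ``seed``.

    Each subject draws from its own child stream of a single seed
    sequence, so subjects are independently reproducible and the cohort is
    bit-identical across runs with the same seed.  Set ``phantoms=False``
    to skip PET volume synthesis when only TACs and truths are needed.
    """
    config = config or CohortConfig()
    children = np.random.SeedSequence(seed).spawn(config.n_subjects)
    pairs: list[TacPair] = []
    studies: list[PetStudy] = []
    truths: list[SubjectTruth] = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        sid = f"S{i + 1:03d}"
        truth, extras = _draw_subject_params(rng, config, sid)
        pairs.append(generate_tac_pair(truth, config, rng, extras))
        if phantoms:
            studies.append(generate_pet_phantom(truth, config, rng))
        truths.append(truth)
    return pairs, studies, truths
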