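"""Time-activity curves (TACs) from paired topical gamma detectors.

Two uncollimated 511 keV detectors are taped to the patient's arms during
radiotracer uptake: one proximal to the injection site, one at the matched
location on the contralateral (reference) arm.  Each outputs a photon count
rate (cps) at nominally 1 Hz.  Because the body background seen by the two
detectors is comparable, the injection-minus-reference difference isolates
excess activity retained near the injection site (an extravasation).

This module holds the TAC data model, CSV round-trip I/O, physical-decay
correction, alignment/differencing of the two arms, and the windowed median
used as ground truth when validating extrapolation.

Conventions
-----------
* Time origin is the recorded injection start; all times are seconds.
* Decay correction refers rates to ``reference_time`` (default 0, i.e. the
  injection instant), so detector readings and PET activities share one
  reference frame.
* F-18 half-life defaults to 109.771 min.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

F18_HALF_LIFE_MIN = 109.771
"""Physical half-life of fluorine-18 in minutes."""

F18_POSITRON_FRACTION = 0.9686
"""Branching fraction of F-18 decays that emit a positron."""


class TacValidationError(ValueError):
    """Raised when a TAC or TAC pair violates its structural invariants."""


class TacParseError(ValueError):
    """Raised when a TAC CSV file cannot be parsed."""


@dataclass(frozen=True)
class Tac:
    """A single detector time-activity curve.

    Parameters
    ----------
    times
        Sample times in seconds since injection start, strictly increasing.
        Nominally 1 Hz; gaps are tolerated and never interpolated.
    rates
        Count rates in cps.  Raw rates must be nonnegative; difference TACs
        (decay corrected) may be negative.
    decay_corrected
        Whether ``rates`` have been corrected for physical tracer decay.
    reference_time
        The instant (seconds) to which decay correction refers; only
        meaningful when ``decay_corrected`` is true.
    """

    times: np.ndarray
    rates: np.ndarray
    decay_corrected: bool = False
    reference_time: float = 0.0

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        rates = np.asarray(self.rates, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "rates", rates)
        if times.ndim != 1 or rates.ndim != 1:
            raise TacValidationError("times and rates must be 1-D arrays")
        if times.size != rates.size:
            raise TacValidationError(
                f"times ({times.size}) and rates ({rates.size}) differ in length"
            )
        if times.size < 2:
            raise TacValidationError("a TAC needs at least 2 samples")
        if not np.all(np.isfinite(times)):
            raise TacValidationError("times contain non-finite values")
        if not np.all(np.isfinite(rates)):
            raise TacValidationError("rates contain non-finite values")
        if np.any(np.diff(times) <= 0):
            bad = int(np.argmax(np.diff(times) <= 0))
            raise TacValidationError(
                f"times must be strictly increasing (violated after index {bad})"
            )
        if not self.decay_corrected and np.any(rates < 0):
            raise TacValidationError("raw (non-decay-corrected) rates must be >= 0")

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def start(self) -> float:
        return float(self.times[0])

    @property
    def end(self) -> float:
        return float(self.times[-1])


@dataclass(frozen=True)
class TacPair:
    """Paired injection/reference detector TACs plus acquisition metadata.

    ``injected_activity`` is the administered activity A_INJ in MBq at
    injection time (before decay compensation).  ``detector_removal_time``
    equals the last TAC sample time in routine use; ``pet_start_time`` is
    when the static PET acquisition begins (seconds after injection).
    The two arms should overlap on a common window of several minutes for
    extrapolation to be possible; that requirement is enforced by the
    extrapolation stage, not here, so that short test records stay loadable.
    """

    injection: Tac
    reference: Tac
    subject_id: str = ""
    injected_activity: float = float("nan")  # MBq at injection time
    injection_time: float = 0.0
    detector_removal_time: float = float("nan")
    pet_start_time: float = float("nan")
    half_life: float = F18_HALF_LIFE_MIN  # minutes

    def __post_init__(self) -> None:
        if (
            np.isfinite(self.pet_start_time)
            and np.isfinite(self.detector_removal_time)
            and self.pet_start_time <= self.detector_removal_time
        ):
            raise TacValidationError(
                "pet_start_time must be after detector_removal_time"
            )
        if self.half_life <= 0:
            raise TacValidationError("half_life must be positive")


def read_tac_csv(path: str | Path, meta: str | Path | dict | None = None) -> TacPair:
    """Read a per-subject paired TAC CSV (columns time_s, injection_cps,
    reference_cps), optionally attaching subject metadata.

    ``meta`` may be a dict or a path to a JSON file with keys
    ``subject_id, injected_activity_mbq, detector_removal_s, pet_start_s``
    (others are ignored here).  Rates are returned raw (not decay corrected);
    gaps in the 1 Hz sampling are preserved, never interpolated.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # malformed beyond recovery
        raise TacParseError(f"{path}: {exc}") from exc
    required = ["time_s", "injection_cps", "reference_cps"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise TacParseError(f"{path}: missing columns {missing}")
    for col in required:
        values = pd.to_numeric(frame[col], errors="coerce")
        bad = np.nonzero(values.isna().to_numpy() & frame[col].notna().to_numpy())[0]
        if bad.size or values.isna().any():
            first = int(np.nonzero(values.isna().to_numpy())[0][0])
            # +2: header line plus 1-origin numbering
            raise TacParseError(
                f"{path}: malformed value in column {col!r} at line {first + 2}"
            )
        frame[col] = values
    times = frame["time_s"].to_numpy(dtype=float)
    if np.any(np.diff(times) <= 0):
        bad = int(np.argmax(np.diff(times) <= 0)) + 1
        raise TacValidationError(
            f"{path}: time_s not strictly increasing at line {bad + 2}"
        )

    kwargs: dict = {}
    if meta is not None:
        if not isinstance(meta, dict):
            meta = json.loads(Path(meta).read_text())
        kwargs["subject_id"] = str(meta.get("subject_id", ""))
        if "injected_activity_mbq" in meta:
            kwargs["injected_activity"] = float(meta["injected_activity_mbq"])
        if "detector_removal_s" in meta:
            kwargs["detector_removal_time"] = float(meta["detector_removal_s"])
        if "pet_start_s" in meta:
            kwargs["pet_start_time"] = float(meta["pet_start_s"])
        if "half_life_min" in meta:
            kwargs["half_life"] = float(meta["half_life_min"])
    return TacPair(
        injection=Tac(times, frame["injection_cps"].to_numpy(dtype=float)),
        reference=Tac(times, frame["reference_cps"].to_numpy(dtype=float)),
        **kwargs,
    )


def write_tac_csv(pair: TacPair, path: str | Path) -> None:
    """Write a TacPair to CSV with full float round-trip precision.

    The two arms must share identical timestamps (as produced by the
    simulator and by ``read_tac_csv``).
    """
    if not np.array_equal(pair.injection.times, pair.reference.times):
        raise TacValidationError("write_tac_csv requires arms on a shared time grid")
    frame = pd.DataFrame(
        {
            "time_s": pair.injection.times,
            "injection_cps": pair.injection.rates,
            "reference_cps": pair.reference.rates,
        }
    )
    frame.to_csv(path, index=False, float_format="%.17g")


def decay_correct(
    tac: Tac, reference_time: float = 0.0, half_life: float = F18_HALF_LIFE_MIN
) -> Tac:
    """Correct a TAC for physical tracer decay.

    Each rate is multiplied by ``2**((t - reference_time) / half_life_s)``,
    referring all samples to the activity they would show at
    ``reference_time``.  Sample times are untouched.  Correcting an already
    corrected TAC is an error (re-reference by constructing from the raw
    series instead).
    """
    if tac.decay_corrected:
        raise TacValidationError("TAC is already decay corrected")
    if half_life <= 0:
        raise ValueError("half_life must be positive")
    half_life_s = half_life * 60.0
    factor = np.exp2((tac.times - reference_time) / half_life_s)
    return Tac(
        tac.times,
        tac.rates * factor,
        decay_corrected=True,
        reference_time=reference_time,
    )


def rereference(tac: Tac, new_reference_time: float, half_life: float = F18_HALF_LIFE_MIN) -> Tac:
    """Move a decay-corrected TAC to a different reference instant."""
    if not tac.decay_corrected:
        raise TacValidationError("rereference requires a decay-corrected TAC")
    shift = np.exp2((tac.reference_time - new_reference_time) / (half_life * 60.0))
    return Tac(
        tac.times,
        tac.rates * shift,
        decay_corrected=True,
        reference_time=new_reference_time,
    )


def difference_tac(pair: TacPair) -> Tac:
    """Injection-minus-reference difference on the common timestamps.

    Both arms must already be decay corrected to the same reference time.
    The result isolates excess injection-arm activity and may be negative.
    """
    inj, ref = pair.injection, pair.reference
    if not (inj.decay_corrected and ref.decay_corrected):
        raise TacValidationError("both arms must be decay corrected before differencing")
    if inj.reference_time != ref.reference_time:
        raise TacValidationError(
            "arms decay corrected to different reference times "
            f"({inj.reference_time} vs {ref.reference_time})"
        )
    common, idx_i, idx_r = np.intersect1d(
        inj.times, ref.times, assume_unique=True, return_indices=True
    )
    if common.size < 2:
        raise TacValidationError("injection and reference share fewer than 2 timestamps")
    return Tac(
        common,
        inj.rates[idx_i] - ref.rates[idx_r],
        decay_corrected=True,
        reference_time=inj.reference_time,
    )


def corrected_difference(pair: TacPair, reference_time: float = 0.0) -> Tac:
    """Decay-correct both arms of a raw pair and difference them."""
    inj = pair.injection
    ref = pair.reference
    if not inj.decay_corrected:
        inj = decay_correct(inj, reference_time, pair.half_life)
    if not ref.decay_corrected:
        ref = decay_correct(ref, reference_time, pair.half_life)
    return difference_tac(replace(pair, injection=inj, reference=ref))


def median_window_rate(tac: Tac, window_end: float, width: float = 180.0) -> float:
    """Median rate over the closed window ``[window_end - width, window_end]``.

    Used as the ground-truth count rate when validating extrapolation
    against the clipped-away tail of a long TAC.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    mask = (tac.times >= window_end - width) & (tac.times <= window_end)
    if not np.any(mask):
        raise TacValidationError(
            f"window [{window_end - width}, {window_end}] contains no samples"
        )
    return float(np.median(tac.rates[mask]))
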