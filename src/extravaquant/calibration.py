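"""Calibration of topical detector readings against PET ground truth.

The extrapolated, decay- and positron-fraction-adjusted detector count-rate
difference D-hat is regressed against the PET-derived extravasation
activity I_TOT with two model forms:

* linear, through the origin:      I_hat = b1 * D
* log-log:                 ln(I_hat) = b0 + b1 * ln(D)

Both are ordinary least squares.  The linear fit is heteroscedastic on real
cohorts (residual spread grows with activity); the log fit corrects this
and is the one used — with leave-one-out cross-validation — to produce the
activity estimates consumed by the severity classifier.

The fits are unit-agnostic: they regress whatever numbers the calibration
points carry.  The pipeline fits I_TOT in Bq against D-hat in cps, the
scale on which the log-fit intercept is conventionally reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pet import ActivityEstimate
from .tac import F18_POSITRON_FRACTION


class CalibrationError(ValueError):
    """Raised when a calibration fit is infeasible."""


@dataclass(frozen=True)
class CalibrationPoint:
    """One subject's (D-hat, I_TOT) pair.

    ``d_hat`` in cps (decay- and positron-fraction-adjusted); ``i_tot`` the
    PET ground-truth activity (Bq in the pipeline; any consistent unit
    works).  Points with d_hat <= 0 cannot enter log-model fitting and are
    excluded there explicitly, never silently.
    """

    subject_id: str
    d_hat: float
    i_tot: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.d_hat):
            raise CalibrationError(f"subject {self.subject_id!r}: d_hat not finite")


@dataclass(frozen=True)
class CalibrationModel:
    """Fitted calibration parameters.

    ``kind`` is "linear" (through-origin; b0 is identically 0) or "log"
    (b0, b1 in log-log space).  ``r2`` is on the original scale for the
    linear model and in log space for the log model.  ``se_b0``/``se_b1``
    are OLS standard errors (se_b0 is NaN for the linear model).
    ``excluded`` lists subjects dropped from a log fit for d_hat <= 0 or
    i_tot <= 0.
    """

    kind: str
    b0: float
    b1: float
    n_fit: int
    r2: float
    se_b0: float = float("nan")
    se_b1: float = float("nan")
    r2_ci: tuple[float, float] | None = None
    excluded: tuple[str, ...] = ()


def adjust_d_hat(raw_d_hat: float, positron_fraction: float = F18_POSITRON_FRACTION) -> float:
    """Convert a decay-corrected count-rate difference to positron-emission
    terms by dividing out the positron branching fraction.

    The constant cancels into the calibration slope but keeps the
    dimensional bookkeeping honest (detected annihilation photons per
    decay < 1 for F-18).
    """
    if not (0.0 < positron_fraction <= 1.0):
        raise ValueError("positron_fraction must be in (0, 1]")
    return raw_d_hat / positron_fraction


def fit_linear(points: list[CalibrationPoint]) -> CalibrationModel:
    """Through-origin OLS: slope b1 = sum(d*i) / sum(d^2).

    r2 is 1 - SSE/SST with SST about the mean of i_tot (conventions for
    through-origin r2 differ; this choice keeps it comparable with the log
    fit's and is documented).
    """
    if len(points) < 2:
        raise CalibrationError("need >= 2 points for the linear fit")
    d = np.array([p.d_hat for p in points])
    i = np.array([p.i_tot for p in points])
    ss_d = float(np.sum(d * d))
    if ss_d == 0:
        raise CalibrationError("all d_hat are 0; slope undefined")
    b1 = float(np.sum(d * i) / ss_d)
    resid = i - b1 * d
    sse = float(np.sum(resid**2))
    sst = float(np.sum((i - i.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    dof = len(points) - 1
    se_b1 = float(np.sqrt(sse / dof / ss_d)) if dof > 0 else float("nan")
    return CalibrationModel(kind="linear", b0=0.0, b1=b1, n_fit=len(points), r2=r2, se_b1=se_b1)


def fit_log(points: list[CalibrationPoint]) -> CalibrationModel:
    """OLS of ln(i_tot) on ln(d_hat): ln(I_hat) = b0 + b1 ln(D).

    Only points with d_hat > 0 and i_tot > 0 can enter; excluded subjects
    are recorded on the model.  r2 is in log space.
    """
    usable = [p for p in points if p.d_hat > 0 and p.i_tot > 0]
    excluded = tuple(p.subject_id for p in points if p not in usable)
    if len(usable) < 3:
        raise CalibrationError(
            f"need >= 3 positive points for the log fit; excluded: {list(excluded)}"
        )
    ld = np.log(np.array([p.d_hat for p in usable]))
    li = np.log(np.array([p.i_tot for p in usable]))
    n = len(usable)
    sxx = float(np.sum((ld - ld.mean()) ** 2))
    if sxx == 0:
        raise CalibrationError("all positive d_hat identical; slope undefined")
    b1 = float(np.sum((ld - ld.mean()) * (li - li.mean())) / sxx)
    b0 = float(li.mean() - b1 * ld.mean())
    resid = li - (b0 + b1 * ld)
    sse = float(np.sum(resid**2))
    sst = float(np.sum((li - li.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    dof = n - 2
    if dof > 0:
        s2 = sse / dof
        se_b1 = float(np.sqrt(s2 / sxx))
        se_b0 = float(np.sqrt(s2 * (1.0 / n + ld.mean() ** 2 / sxx)))
    else:
        se_b0 = se_b1 = float("nan")
    return CalibrationModel(
        kind="log", b0=b0, b1=b1, n_fit=n, r2=r2, se_b0=se_b0, se_b1=se_b1, excluded=excluded
    )


def predict_activity(model: CalibrationModel, d_hat: float) -> ActivityEstimate:
    """Estimated extravasation activity from a detector reading alone.

    Linear: b1 * d.  Log: exp(b0 + b1 ln d) for d > 0; a nonpositive d maps
    to 0 activity (class "none") since the log model cannot represent it.
    The returned estimate carries the activity in the model's units and no
    fraction (the caller normalizes by A_INJ).
    """
    if model.kind == "linear":
        value = model.b1 * d_hat
    elif model.kind == "log":
        value = float(np.exp(model.b0 + model.b1 * np.log(d_hat))) if d_hat > 0 else 0.0
    else:
        raise CalibrationError(f"unknown model kind {model.kind!r}")
    return ActivityEstimate(i_tot=float(value), fraction=float("nan"), source="detector_calibrated")


def loo_predictions(points: list[CalibrationPoint]) -> list[ActivityEstimate]:
    """Leave-one-out cross-validated log-model activity estimates.

    For each subject the log fit is re-estimated on the other n-1 points
    and evaluated at the held-out d_hat; each fold must retain >= 3
    positive points.  Output order matches the input.
    """
    if len(points) < 4:
        raise CalibrationError("need >= 4 points for leave-one-out")
    out = []
    for held in range(len(points)):
        fold = [p for j, p in enumerate(points) if j != held]
        model = fit_log(fold)
        out.append(predict_activity(model, points[held].d_hat))
    return out


def bootstrap_r2_ci(
    points: list[CalibrationPoint],
    n_boot: int = 10_000,
    seed: int | np.random.Generator = 0,
    kind: str = "log",
) -> tuple[float, float]:
    """Percentile-bootstrap 95% CI of the coefficient of determination.

    Subjects are resampled with replacement ``n_boot`` times; the model is
    refitted on each replicate and its r2 collected; the 2.5th/97.5th
    percentiles are returned.  Degenerate replicates (e.g. all-identical
    d_hat, or too few positive points for a log fit) are skipped and
    counted against n_boot.  Deterministic for a given seed.
    """
    if len(points) < 3:
        raise CalibrationError("need >= 3 points for a bootstrap CI")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fitter = fit_log if kind == "log" else fit_linear
    n = len(points)
    r2s = np.empty(n_boot)
    got = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            r2s[got] = fitter([points[j] for j in idx]).r2
        except CalibrationError:
            continue
        got += 1
    if got == 0:
        raise CalibrationError("every bootstrap replicate was degenerate")
    lo, hi = np.percentile(r2s[:got], [2.5, 97.5])
    return float(lo), float(hi)
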