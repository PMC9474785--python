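"""Extravasation severity classification and diagnostic evaluation.

Severity is graded from the dose-normalized extravasation activity
f = I_hat_TOT / A_INJ into four classes with lower-inclusive bins:

    none     f < 1%
    minor    1%  <= f < 5%
    moderate 5%  <= f < 20%
    severe   20% <= f

The 5% and 20% cut points follow the QIBA profile for quantitative PET in
therapy-response studies; 5% is also the binary positive/negative boundary
(equivalently, classes moderate and severe are positives).

The evaluation suite provides multiclass and binary confusion matrices,
the standard diagnostic rates plus the Matthews correlation coefficient
(MCC), an exhaustive optimal-threshold search maximizing MCC, delete-one
jackknife standard errors, and a t-test comparing two classifiers' MCCs.

``run_pipeline`` chains the whole method for a cohort: decay-correct and
difference the detector TACs, extrapolate to PET start, quantify PET ground
truth, calibrate (leave-one-out log fit), classify, and evaluate.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
from scipy import stats

from . import calibration as cal
from .extrapolation import ExtrapolationConfig, extrapolate_pair
from .pet import PetStudy, total_extravasation_activity
from .tac import F18_POSITRON_FRACTION, TacPair

logger = logging.getLogger("extravaquant")

QIBA_BINARY_THRESHOLD = 0.05
SEVERITY_EDGES = (0.01, 0.05, 0.20)  # none|minor, minor|moderate, moderate|severe


class SeverityClass(IntEnum):
    """Ordered extravasation severity grades."""

    NONE = 0
    MINOR = 1
    MODERATE = 2
    SEVERE = 3

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name.lower()


class EvaluationError(ValueError):
    """Raised for infeasible evaluation requests."""


def classify_severity(fraction: float) -> SeverityClass:
    """Grade a nonnegative activity fraction I_hat_TOT / A_INJ.

    Bins are lower-inclusive: e.g. exactly 5% is moderate, exactly 20% is
    severe.  Negative estimates must be floored to 0 upstream.
    """
    if not np.isfinite(fraction):
        raise EvaluationError(f"fraction must be finite, got {fraction}")
    if fraction < 0:
        raise EvaluationError("fraction must be >= 0 (floor negative estimates upstream)")
    if fraction < SEVERITY_EDGES[0]:
        return SeverityClass.NONE
    if fraction < SEVERITY_EDGES[1]:
        return SeverityClass.MINOR
    if fraction < SEVERITY_EDGES[2]:
        return SeverityClass.MODERATE
    return SeverityClass.SEVERE


def binarize(fraction: float, threshold: float = QIBA_BINARY_THRESHOLD) -> bool:
    """Positive (clinically significant extravasation) iff fraction >= threshold.

    At the default 5% threshold this equals grouping the moderate and
    severe classes as positives.
    """
    if threshold <= 0:
        raise EvaluationError("threshold must be positive")
    return bool(fraction >= threshold)


@dataclass(frozen=True)
class ConfusionMatrix2x2:
    """Binary confusion counts (positives = significant extravasation)."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise EvaluationError("confusion counts must be nonnegative")

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_labels(cls, pred: np.ndarray, truth: np.ndarray) -> "ConfusionMatrix2x2":
        pred = np.asarray(pred, dtype=bool)
        truth = np.asarray(truth, dtype=bool)
        if pred.shape != truth.shape:
            raise EvaluationError("pred and truth lengths differ")
        return cls(
            tp=int(np.sum(pred & truth)),
            tn=int(np.sum(~pred & ~truth)),
            fp=int(np.sum(pred & ~truth)),
            fn=int(np.sum(~pred & truth)),
        )


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Standard binary diagnostic rates (percent) plus MCC.

    Rates with a zero denominator are NaN with the affected names listed in
    ``undefined``; MCC with any zero marginal is 0 by convention.
    """

    sensitivity: float
    specificity: float
    accuracy: float
    ppv: float
    npv: float
    mcc: float
    mcc_se: float = float("nan")
    undefined: tuple[str, ...] = ()


def mcc_from_counts(tp: int, tn: int, fp: int, fn: int) -> float:
    """Matthews correlation coefficient; 0 when any marginal is empty."""
    denom_sq = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom_sq == 0:
        return 0.0
    return float((tp * tn - fp * fn) / np.sqrt(denom_sq))


def diagnostic_metrics(cm: ConfusionMatrix2x2) -> DiagnosticMetrics:
    """Sensitivity/specificity/accuracy/PPV/NPV (percent) and MCC."""
    if cm.n < 1:
        raise EvaluationError("empty confusion matrix")
    undefined = []

    def rate(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return float("nan")
        return 100.0 * num / den

    return DiagnosticMetrics(
        sensitivity=rate(cm.tp, cm.tp + cm.fn, "sensitivity"),
        specificity=rate(cm.tn, cm.tn + cm.fp, "specificity"),
        accuracy=100.0 * (cm.tp + cm.tn) / cm.n,
        ppv=rate(cm.tp, cm.tp + cm.fp, "ppv"),
        npv=rate(cm.tn, cm.tn + cm.fn, "npv"),
        mcc=mcc_from_counts(cm.tp, cm.tn, cm.fp, cm.fn),
        undefined=tuple(undefined),
    )


CLASS_ORDER = tuple(SeverityClass)


def multiclass_confusion(pred, truth) -> np.ndarray:
    """4x4 confusion matrix indexed [predicted, truth] in severity order."""
    pred = list(pred)
    truth = list(truth)
    if len(pred) != len(truth):
        raise EvaluationError(f"length mismatch: {len(pred)} predictions vs {len(truth)} truths")
    out = np.zeros((4, 4), dtype=int)
    for p, t in zip(pred, truth):
        out[int(p), int(t)] += 1
    return out


def collapse_to_binary(cm4: np.ndarray) -> ConfusionMatrix2x2:
    """Collapse a 4x4 severity matrix by the moderate/severe-positive rule."""
    cm4 = np.asarray(cm4)
    pos = slice(2, 4)
    neg = slice(0, 2)
    return ConfusionMatrix2x2(
        tp=int(cm4[pos, pos].sum()),
        tn=int(cm4[neg, neg].sum()),
        fp=int(cm4[pos, neg].sum()),
        fn=int(cm4[neg, pos].sum()),
    )


@dataclass(frozen=True)
class ThresholdSearchResult:
    """Open interval of thresholds attaining the maximal MCC.

    ``(lo, hi)`` are bounding data values: every threshold strictly between
    them yields the same, maximal MCC.  ``lo`` may be -inf (any threshold
    below the smallest fraction) and ``hi`` +inf.
    """

    lo: float
    hi: float
    mcc: float


def optimal_threshold(fractions, truth_positive) -> ThresholdSearchResult:
    """Exhaustive MCC-maximizing threshold search.

    MCC is piecewise constant in the threshold, changing only at the
    observed fractions; each midpoint between consecutive sorted unique
    values (plus one below the minimum and one above the maximum) is
    evaluated.  Among maximal candidates, the widest contiguous open
    interval of thresholds is returned, expressed by its bounding data
    values (ties broken toward the lowest interval).  Deterministic.
    """
    f = np.asarray(fractions, dtype=float)
    y = np.asarray(truth_positive, dtype=bool)
    if f.shape != y.shape:
        raise EvaluationError("fractions and truth lengths differ")
    if y.all() or not y.any():
        raise EvaluationError("truth must contain both classes")
    uniq = np.unique(f)
    # candidate thresholds: one per constant-MCC interval
    bounds = np.concatenate(([-np.inf], uniq, [np.inf]))
    mccs = np.empty(uniq.size + 1)
    for j in range(uniq.size + 1):
        lo, hi = bounds[j], bounds[j + 1]
        if np.isinf(lo):
            thr = hi - 1.0
        elif np.isinf(hi):
            thr = lo + 1.0
        else:
            thr = 0.5 * (lo + hi)
        pred = f >= thr
        cm = ConfusionMatrix2x2.from_labels(pred, y)
        mccs[j] = mcc_from_counts(cm.tp, cm.tn, cm.fp, cm.fn)
    best = float(np.max(mccs))
    at_best = np.isclose(mccs, best)
    # widest contiguous run of maximal intervals
    best_lo = best_hi = None
    best_width = -np.inf
    j = 0
    while j <= uniq.size:
        if at_best[j]:
            j0 = j
            while j + 1 <= uniq.size and at_best[j + 1]:
                j += 1
            lo, hi = float(bounds[j0]), float(bounds[j + 1])
            width = hi - lo
            if width > best_width:
                best_width, best_lo, best_hi = width, lo, hi
        j += 1
    return ThresholdSearchResult(lo=best_lo, hi=best_hi, mcc=best)


def jackknife_se(pred, truth, statistic=None) -> float:
    """Delete-one jackknife standard error of a binary-classification
    statistic (default MCC).

    SE = sqrt((n-1)/n * sum((theta_(i) - theta_bar)^2)).  Replicates whose
    statistic is undefined fall back on the MCC=0 convention inside
    ``mcc_from_counts``.
    """
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    n = pred.size
    if n < 3:
        raise EvaluationError("need >= 3 subjects for a jackknife SE")
    if pred.shape != truth.shape:
        raise EvaluationError("pred and truth lengths differ")
    if statistic is None:
        def statistic(p, t):
            cm = ConfusionMatrix2x2.from_labels(p, t)
            return mcc_from_counts(cm.tp, cm.tn, cm.fp, cm.fn)
    keep = np.ones(n, dtype=bool)
    reps = np.empty(n)
    for i in range(n):
        keep[i] = False
        reps[i] = statistic(pred[keep], truth[keep])
        keep[i] = True
    return float(np.sqrt((n - 1) / n * np.sum((reps - reps.mean()) ** 2)))


def compare_mcc(mcc_a: float, se_a: float, mcc_b: float, se_b: float, n: int) -> float:
    """Two-sided t-test p-value for a difference in MCC between two
    classifiers evaluated on the same n subjects.

    t = (mcc_a - mcc_b) / sqrt(se_a^2 + se_b^2) with n-1 degrees of
    freedom, treating the two jackknife SEs as independent (a conservative,
    unpaired construction; see the methods note).
    """
    if se_a < 0 or se_b < 0:
        raise EvaluationError("standard errors must be >= 0")
    denom = np.hypot(se_a, se_b)
    if denom == 0:
        return 1.0 if mcc_a == mcc_b else 0.0
    t = (mcc_a - mcc_b) / denom
    return float(2.0 * stats.t.sf(abs(t), df=n - 1))


# ---------------------------------------------------------------------------
# End-to-end cohort pipeline
# ---------------------------------------------------------------------------


@dataclass
class SubjectResult:
    """Per-subject pipeline outputs (activities in MBq, d_hat in cps)."""

    subject_id: str
    d_hat_raw: float
    d_hat_adjusted: float
    i_tot_pet: float
    truth_fraction: float
    truth_class: SeverityClass
    predicted_i_tot: float
    predicted_fraction: float
    predicted_class: SeverityClass


@dataclass
class CohortResult:
    """Full pipeline output for a cohort.

    Holds per-subject results, the all-data log calibration, the 4x4 and
    binary (QIBA-threshold) confusion matrices with diagnostic metrics, the
    MCC-optimal threshold interval, and a reproducibility manifest.
    """

    subjects: list[SubjectResult]
    model: cal.CalibrationModel
    confusion4: np.ndarray
    binary_cm: ConfusionMatrix2x2
    metrics: DiagnosticMetrics
    optimal: ThresholdSearchResult | None
    excluded: dict[str, str] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.subjects)


def run_pipeline(
    pairs: list[TacPair],
    studies: list[PetStudy] | None = None,
    i_tot_mbq: dict[str, float] | None = None,
    config: ExtrapolationConfig | None = None,
    positron_fraction: float = F18_POSITRON_FRACTION,
    binary_threshold: float = QIBA_BINARY_THRESHOLD,
    d_hat_floor_cps: float = 10.0,
    i_tot_floor_mbq: float = 0.01,
) -> CohortResult:
    """Run the complete method on a cohort.

    PET ground truth comes either from ``studies`` (matched to ``pairs`` by
    position) or from precomputed activities ``i_tot_mbq`` keyed by subject
    id.  Subjects failing any stage are excluded with a logged reason; the
    run aborts if fewer than 4 subjects survive.  Predicted activities come
    from leave-one-out log fits so no subject is scored by a model trained
    on itself.

    Detection floors: subjects whose adjusted D-hat falls below
    ``d_hat_floor_cps`` or whose PET activity falls below
    ``i_tot_floor_mbq`` carry no calibration information (both quantities
    sit below their counting/image noise) and cannot enter a log-log fit
    meaningfully; they are excluded from model FITTING (recorded on the
    model) but are still predicted and classified — a sub-floor or
    nonpositive D-hat maps to near-zero activity, class "none".  Set both
    floors to 0 to fit every positive point.
    """
    config = config or ExtrapolationConfig()
    if (studies is None) == (i_tot_mbq is None):
        raise EvaluationError("provide exactly one of studies or i_tot_mbq")

    rows: list[dict] = []
    excluded: dict[str, str] = {}
    for idx, pair in enumerate(pairs):
        sid = pair.subject_id or f"subject-{idx}"
        try:
            fit, _ = extrapolate_pair(pair, config)
            d_raw = fit.d_hat
            if studies is not None:
                est = total_extravasation_activity(studies[idx])
                i_tot = est.i_tot
            else:
                i_tot = float(i_tot_mbq[sid])
            rows.append(
                dict(
                    subject_id=sid,
                    d_raw=float(d_raw),
                    d_adj=cal.adjust_d_hat(d_raw, positron_fraction),
                    i_tot=i_tot,
                    a_inj=pair.injected_activity,
                )
            )
        except Exception as exc:
            logger.warning("subject %r excluded: %s", sid, exc)
            excluded[sid] = str(exc)
    if len(rows) < 4:
        raise EvaluationError(
            f"only {len(rows)} subjects survived preprocessing; need >= 4"
        )

    points = [
        cal.CalibrationPoint(r["subject_id"], r["d_adj"], r["i_tot"] * 1e6)  # MBq -> Bq
        for r in rows
    ]
    eligible = [
        j
        for j, r in enumerate(rows)
        if r["d_adj"] >= d_hat_floor_cps and r["i_tot"] >= i_tot_floor_mbq
    ]
    if len(eligible) < 4:
        raise EvaluationError(
            f"only {len(eligible)} subjects above the detection floors; need >= 4 to calibrate"
        )
    fit_points = [points[j] for j in eligible]
    model = cal.fit_log(fit_points)
    loo_eligible = cal.loo_predictions(fit_points)
    # eligible subjects get their leave-one-out prediction; sub-floor
    # subjects never influence the fit, so the all-data model scores them
    loo: list = [None] * len(rows)
    for j, est in zip(eligible, loo_eligible):
        loo[j] = est
    for j in range(len(rows)):
        if loo[j] is None:
            loo[j] = cal.predict_activity(model, points[j].d_hat)

    subjects: list[SubjectResult] = []
    for r, est in zip(rows, loo):
        truth_fraction = max(r["i_tot"], 0.0) / r["a_inj"]
        pred_mbq = est.i_tot / 1e6
        pred_fraction = max(pred_mbq, 0.0) / r["a_inj"]
        subjects.append(
            SubjectResult(
                subject_id=r["subject_id"],
                d_hat_raw=r["d_raw"],
                d_hat_adjusted=r["d_adj"],
                i_tot_pet=r["i_tot"],
                truth_fraction=truth_fraction,
                truth_class=classify_severity(truth_fraction),
                predicted_i_tot=pred_mbq,
                predicted_fraction=pred_fraction,
                predicted_class=classify_severity(pred_fraction),
            )
        )

    pred_classes = [s.predicted_class for s in subjects]
    truth_classes = [s.truth_class for s in subjects]
    cm4 = multiclass_confusion(pred_classes, truth_classes)
    pred_pos = np.array([binarize(s.predicted_fraction, binary_threshold) for s in subjects])
    truth_pos = np.array([binarize(s.truth_fraction, binary_threshold) for s in subjects])
    cm2 = ConfusionMatrix2x2.from_labels(pred_pos, truth_pos)
    metrics = diagnostic_metrics(cm2)
    try:
        se = jackknife_se(pred_pos, truth_pos)
    except EvaluationError:
        se = float("nan")
    metrics = DiagnosticMetrics(
        sensitivity=metrics.sensitivity, specificity=metrics.specificity,
        accuracy=metrics.accuracy, ppv=metrics.ppv, npv=metrics.npv,
        mcc=metrics.mcc, mcc_se=se, undefined=metrics.undefined,
    )
    try:
        optimal = optimal_threshold(
            np.array([s.predicted_fraction for s in subjects]), truth_pos
        )
    except EvaluationError:
        optimal = None

    manifest = dict(
        n_input=len(pairs),
        n_analyzed=len(subjects),
        binary_threshold=binary_threshold,
        positron_fraction=positron_fraction,
        d_hat_floor_cps=d_hat_floor_cps,
        i_tot_floor_mbq=i_tot_floor_mbq,
        n_calibration_fit=len(eligible),
        below_floor_subjects=[rows[j]["subject_id"] for j in range(len(rows)) if j not in eligible],
        extrapolation_config=dataclasses.asdict(config),
        calibration=dict(kind=model.kind, b0=model.b0, b1=model.b1, r2=model.r2),
    )
    return CohortResult(
        subjects=subjects, model=model, confusion4=cm4, binary_cm=cm2,
        metrics=metrics, optimal=optimal, excluded=excluded, manifest=manifest,
    )
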