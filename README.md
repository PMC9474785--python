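# extravaquant

Quantification and severity grading of radiotracer **extravasation** — the
unintended leakage of an injected PET tracer (e.g. [18F]FDG) into the
tissue around the injection site — from a pair of topical gamma detectors,
calibrated against static PET images.

Extravasations occur in a substantial fraction of FDG PET/CT injections,
bias SUV quantification, and often resolve before the scan, which makes
radiological assessment from the static image unreliable.  Two small
uncollimated 511 keV detectors, one taped proximal to the injection site
and one at the matched spot on the contralateral arm, record count-rate
time-activity curves (TACs) at 1 Hz throughout tracer uptake.  Since both
detectors see a comparable body background, the injection-minus-reference
difference isolates the excess activity retained at the injection site.

## Method

1. **TAC processing** — decay-correct both arms to injection time and
   difference them on their common timestamps.
2. **Extrapolation** — detectors are removed ~15 min before PET (voiding,
   positioning), so the difference is extrapolated to PET start: a
   gradient-based heuristic advances the fit start past baseline
   transitions, then a time-shifted decaying exponential
   `f(t) = A·exp(−k·(t − t_s))`, `k ≥ 0`, is fitted by iteratively
   reweighted least squares with Tukey bisquare robust weights multiplied
   by recency weights `W_i = t_i − t_s + 1`.  The value at PET start is the
   count-rate difference `D̂` (cps), adjusted for the F-18 positron
   fraction.
3. **PET ground truth** — total excess injection-site activity from a
   static PET volume via a dual volume-of-interest estimate

   `I_TOT = V_V · [ Σ_i m_I,i x_i − (V_I/V_R) Σ_i m_R,i x_i ]`

   with both VOIs refined by an SUV ≥ 0.2 threshold, so shared
   physiological background cancels.
4. **Calibration** — ordinary least squares of `ln(I_TOT)` on `ln(D̂)`
   (`ln Î_TOT = b0 + b1·ln D̂`), cross-validated leave-one-out; a
   through-origin linear variant (`Î_TOT = b1·D̂`) is provided for
   comparison but is heteroscedastic on realistic cohorts.
5. **Classification** — the dose-normalized estimate `f = Î_TOT / A_INJ`
   is graded *none* (< 1%), *minor* (1–5%), *moderate* (5–20%), *severe*
   (≥ 20%); the 5%/20% cut points follow the QIBA profile, and `f ≥ 5%` is
   the binary "significant extravasation" rule.
6. **Evaluation** — multiclass and binary confusion matrices, sensitivity/
   specificity/accuracy/PPV/NPV, Matthews correlation coefficient (MCC)
   with delete-one jackknife standard errors, an exhaustive MCC-optimal
   threshold search, percentile-bootstrap confidence intervals for R², and
   a t-test comparing two classifiers' MCCs.

Because clinical detector/PET records are not redistributable, the package
ships a first-class synthetic cohort simulator (`extravaquant.cohort`)
producing paired Poisson-noise TACs, voxelized two-arm PET phantoms with
exactly known inserted activity, and ground-truth records, all
reproducible from a seed.

## Worked example

```python
import extravaquant as eq

pairs, studies, truths = eq.generate_cohort(eq.CohortConfig(), seed=1)
res = eq.run_pipeline(pairs, studies=studies)
print("log fit: b0=%.2f b1=%.2f r2=%.2f" % (res.model.b0, res.model.b1, res.model.r2))
m = res.metrics
print("sens %.1f spec %.1f acc %.1f mcc %.2f" %
      (m.sensitivity, m.specificity, m.accuracy, m.mcc))
print(res.confusion4)
print("optimal: %.3f < f < %.3f at MCC %.2f" %
      (res.optimal.lo, res.optimal.hi, res.optimal.mcc))
```

prints, for this seed:

```
log fit: b0=8.37 b1=1.13 r2=0.97
sens 100.0 spec 100.0 acc 100.0 mcc 1.00
[[10  1  0  0]
 [ 0  6  0  0]
 [ 0  0  3  1]
 [ 0  0  0  3]]
optimal: 0.040 < f < 0.060 at MCC 1.00
```

The 24-subject cohort was generated with a true calibration of
(b0, b1) = (8.0, 1.2) in Bq-vs-cps units and lognormal detector-geometry
scatter σ = 0.3; the fitted (8.37, 1.13) recovers it within sampling
error.  The 4×4 matrix is predicted class (rows) against PET-derived truth
(columns): 22/24 subjects land in their true class, all binary calls at
the 5 % threshold are correct (MCC 1.00), and any threshold strictly
between 4.0 % and 6.0 % would have performed equally well on this cohort.

A command-line interface mirrors the stages:

```
extravaquant simulate --out-dir cohort/ --seed 7
extravaquant extrapolate --tac cohort/S001_tac.csv --meta cohort/S001_meta.json --out fit.json
extravaquant quantify-pet --pet vol.nii.gz --inj-voi a.nii.gz --ref-voi b.nii.gz \
    --meta subject.json --out activity.json
extravaquant calibrate --points points.csv --model log --boot 10000 --seed 7 --out model.json
extravaquant classify --activities activities.csv --out classes.json
extravaquant evaluate --pred pred.csv --truth truth.csv --out metrics.json
```

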