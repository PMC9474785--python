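# Methods

This note documents the models, conventions, numerical choices and known
limitations behind `extravaquant`.  Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`.

## Reference frames and constants

All times are seconds since the recorded injection start.  Decay
correction multiplies a rate by `2^((t − t_ref)/T½)` with `t_ref = 0`
(injection) by default, so detector readings and PET activities share one
reference frame; any consistent choice of reference instant cancels into
the calibration slope, and this one keeps `I_TOT / A_INJ` a ratio of
same-frame quantities.  The F-18 half-life is fixed at 109.771 min and the
positron branching fraction at 0.9686; both are configurable.  Gaps in the
nominal 1 Hz sampling are tolerated and never interpolated — every
downstream fit operates on the samples that exist.

## Detector difference and extrapolation

The injection-minus-reference difference is computed on the exact
intersection of timestamps of the two decay-corrected arms, and may be
negative (it is a difference of noisy rates).

**Model form.**  The extrapolation model is a two-parameter time-shifted
decaying exponential `f(t) = A·exp(−k(t − t_s))` with `k ∈ [0, k_max]`,
`k_max = 0.01 s⁻¹` by default.  No additive offset is fitted by default:
an offset is poorly identifiable from an 8–20 min window, and the
decay-corrected difference of a resolving extravasation tends to the
(near-zero) background asymmetry between arms.  An offset variant is
available behind `ExtrapolationConfig(fit_offset=True)`.  The upper bound
`k_max` encodes that biological clearance of an extravasation cannot
plausibly be faster than a ~70 s half-time; without it, pure-noise
differences (no extravasation) can fit arbitrarily steep decays whose
extrapolation underflows to meaningless positive values.

**Fit-start selection.**  Early TAC segments contain the injection bolus
and occasional baseline steps (patient motion relocating high-uptake
structures relative to the uncollimated detector).  The selector smooths
the difference with a 31 s moving median, takes a central-difference
gradient over a 60 s lag, and scores each sample by the change of that
gradient across a further 60 s lag — a discrete curvature that is near
zero for a smooth exponential but large at a step.  A sample is a
transition when its score exceeds `5 ×` a robust noise scale (1.4826 ×
MAD of the scores over the final 5 min, floored at 0.6 cps/s so that
noiseless smooth records are never flagged).  The fit starts after the
last transition (plus a 30 s buffer) within the candidate window
`[t_end − 20 min, t_end]`, never later than `t_end − 8 min`; if
transitions persist into the minimum window, the minimum start is used
and the result flagged.  This detector is a heuristic of this package's
own design; every constant sits in `ExtrapolationConfig`.

**Robust regression.**  Within the window, iteratively reweighted least
squares alternates (a) a bounded nonlinear least-squares solve
(`scipy.optimize.least_squares`, trust-region reflective) under fixed
per-sample weights and (b) a bisquare weight update from the residuals
(tuning constant 4.685, the conventional 95 %-Gaussian-efficiency value;
residual scale 1.4826 × MAD).  The total weight of a sample is the
bisquare weight times the recency weight `W_i = t_i − t_s + 1` with times
in seconds — later samples, closest to the extrapolation target, dominate.
Initialization is deterministic: `A₀` from the median of the final 60 s
(referred back to `t_s` with `k₀`), `k₀` from a log-linear fit of the
positive samples clamped to `[0, k_max]`.  Convergence is a relative
parameter change below 1e−8 within 50 iterations; non-convergence returns
the fit flagged rather than raising.  If every sample in the window is
≤ 0 the fit degenerates to the recency-weighted mean with `k = 0`; a
nonpositive `D̂` is a legal output meaning "no measurable excess".

**Validation protocol.**  Long difference TACs (≥ 40 min) are clipped by
15 min, extrapolated across the gap, and compared with the ground-truth
median over the final 3 min of the unclipped record; the report carries
per-subject paired differences, their mean, SD, 1.96 SD agreement limits,
and 1.5 × IQR box-plot outlier flags.  Note an inherent protocol bias:
the extrapolation targets the end time while the 3 min median is centred
~90 s earlier, so a decaying difference makes the paired difference
slightly negative in proportion to `k · 90 s · f(t_end)`; on the default
synthetic conditions this stays well inside the ±0.1 kcps scale of the
mean bias.

## PET quantification

The dual-VOI estimate subtracts, from the injection-VOI sum, the
reference-VOI sum scaled by the refined-volume ratio `V_I/V_R` — i.e. what
the injection VOI would contain under normal physiological uptake alone —
and multiplies by the voxel volume.  Both hand-drawn VOIs (inputs; mask
files or programmatic boxes) are refined by an SUV ≥ 0.2 threshold.  SUV
assumes 1 g/ml tissue density and, by default, the injected dose decayed
to scan start (the usual SUV convention; `dose_at_scan=False` switches to
the dose at injection).  The Bq result, valid at scan start, is
decay-referenced to injection time before normalizing by `A_INJ`, so the
severity fraction is a same-frame ratio.  Negative estimates (possible
under image noise) are preserved in reports but floored to zero before
classification, because the severity classes are defined on nonnegative
fractions.

## Calibration

The log model `ln Î_TOT = b0 + b1 ln D̂` is plain OLS in log space; the
through-origin linear model `Î_TOT = b1 D̂` uses the closed-form slope
`Σdi/Σd²`.  `r²` for the linear model is `1 − SSE/SST` with SST about the
mean (through-origin conventions differ; this one keeps the two models
comparable).  Both fits are unit-agnostic; the pipeline fits Bq against
cps, the scale on which the log intercept is conventionally reported.
Points with `D̂ ≤ 0` or `I_TOT ≤ 0` cannot enter a log fit and are
recorded on the model, never silently dropped; at prediction time a
nonpositive `D̂` maps to zero activity (class *none*).  Leave-one-out
predictions refit the log model on the other n−1 points per subject.  The
percentile bootstrap (default 10,000 replicates, seedable) resamples
subjects with replacement and reports the 2.5th/97.5th percentiles of the
refitted `r²`, skipping and counting degenerate replicates.

**Detection floors (pipeline only).**  `run_pipeline` excludes from
calibration *fitting* any subject with adjusted `D̂` below 10 cps or
`|I_TOT|` below 0.01 MBq.  Both quantities are then below their own noise
(counting noise on a ~1 kcps background; image noise over a ~1000-voxel
VOI), so such points carry no information about the log-log relation but
enormous leverage in log space.  Sub-floor subjects are still predicted
(via the model fitted without them) and classified; the floors and the
excluded ids are recorded in the run manifest.  Set both floors to zero
to fit every positive point.

## Classification and evaluation

Severity bins are lower-inclusive exactly as defined: *none* < 1 % ≤
*minor* < 5 % ≤ *moderate* < 20 % ≤ *severe*; the binary rule `f ≥ 5 %`
coincides with grouping moderate and severe as positives.  MCC with any
zero marginal is defined as 0.  Rates with a zero denominator are NaN and
flagged.  The optimal-threshold search exploits that MCC is piecewise
constant in the threshold: one candidate per interval between consecutive
sorted unique fractions (plus below-min and above-max) is evaluated, and
the widest contiguous open interval attaining the maximal MCC is returned,
expressed by its bounding data values; when several disjoint intervals tie
on MCC, the widest (then lowest) is reported.  The jackknife SE uses
delete-one replicates with `SE = sqrt((n−1)/n · Σ(θ_(i) − θ̄)²)`.  The MCC
comparison uses `t = Δmcc / sqrt(se_a² + se_b²)` with n−1 degrees of
freedom, treating the two jackknife SEs as independent — a conservative,
unpaired construction chosen because the exact pairing of such a test is
not uniquely defined; interpret borderline p-values accordingly.

## Synthetic cohorts

The simulator emulates the study conditions: injected activity
N(320, 86²) MBq truncated above 50, uptake time N(68.0, 13.7²) min
truncated above 35, detectors removed 15 min before PET start, body
weight N(80, 15²) kg.  75 % of subjects carry an extravasation with
severity fraction log-uniform on [0.001, 0.5] of the injected dose (the
remainder have exactly zero), which puts roughly half the cohort in class
*none* and a quarter above the 5 % binary threshold — the truth marginals
of the motivating comparison study.  Extravasations resolve exponentially
with a biological half-time lognormal about 45 min (σ_log = 0.5, clipped
to [10, 240] min).

The detector response is a single multiplicative geometry factor per
subject rather than a photon-transport model: the factor is chosen so the
cohort-level relation between PET activity (Bq) and *adjusted* detector
difference (cps) follows a configurable log-log truth, default
(b0*, b1*) = (8.0, 1.2), with lognormal scatter σ = 0.3.  This reproduces
the log-log linear structure with heteroscedastic linear-scale residuals
that the calibration assumes, at desk scale.  Both arms share a
two-compartment rise-to-plateau background (plateau lognormal about
1 kcps); the injection arm adds the scaled extravasation curve, an
injection-bolus transient (default ~20 kcps, 30 s time constant), and with
probability 0.1 a ±100–500 cps baseline step.  Counts are Poisson per 1 s
bin on the physical (decayed) rate.  PET phantoms are two equal-uptake arm
cylinders (SUV 0.5) on a 40×40×20 grid of 4.1×4.1×5.0 mm voxels; the
injection arm holds a 3-D Gaussian insert (σ = 6 mm) normalized on the
voxel grid so its summed activity equals the truth exactly, plus optional
Gaussian voxel noise (default σ = 50 Bq/ml); box VOIs exceed both arms.
One seed sequence per cohort spawns one child stream per subject, so
subjects are independently reproducible.

**What passing does and does not show.**  The simulator realizes exactly
the structural assumptions the method makes (shared background, single
multiplicative detector response, exponential resolution, exact log-log
calibration truth).  Passing therefore demonstrates correctness and
calibration of the *algorithms* under their own model; it does not
establish clinical performance, which depends on solid-angle and
attenuation effects, heterogeneous extravasation geometry, asymmetric
physiological uptake and patient motion that the simulator only caricatures
(geometry scatter, baseline steps).

## Degenerate inputs and tie-breaks

Monotonicity, length, finiteness and mask-consistency violations raise
typed errors naming the offending location.  A TAC shorter than the
minimum fit window cannot be extrapolated; in cohort runs such subjects
are excluded with a logged reason and the run aborts below 4 survivors.
An empty refined reference mask is an error (background cannot be
normalized); an empty refined injection mask is legal and yields a
negative estimate.  Equal-MCC threshold intervals and even-length medians
follow the conventions stated above and in the docstrings.

## Problem sizes

Defaults keep the whole suite and the acceptance script at desk scale:
24-subject cohorts (~3,000 TAC samples/subject, 32,000-voxel phantoms),
23 long records for the clipped-TAC protocol, 200 replicates for noisy
calibration recovery, reduced bootstrap replicate counts in unit tests
(the operation default remains 10,000), and 30 cohort replicates for the
noisy classifier regression guard.
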