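# Methods

## Scope and data model

The package operates on quiet-stance center-of-pressure (CoP) recordings:
uniformly sampled time plus medial-lateral (X) and anterior-posterior (Y)
displacement, in inches, with (0, 0) at the subject's balance origin.
The reference protocol is 30 s trials at 100 Hz under four conditions —
T1 firm surface, T2 foam, T3 firm with eyes closed, T4 foam with eyes
closed — for two athlete groups ("elite", "expert").  Recordings are
plain CSV/TSV with a manifest mapping files to subject, group, condition
and standing height; no device-specific formats and no resampling or
filtering are applied.

Four descriptor series feed the analysis: the raw channels COPX and COPY,
the radial excursion `COPLen = sqrt(x² + y²)`, and the tilt angle
`cos⁻¹(COPLen / (0.55·height))` in degrees, which places the center of
mass at 55 % of standing height.  The arccos form is the package default;
note it reads ≈ 90° for a perfectly quiet stance and *decreases* with
excursion.  An `arcsin` variant (0° when quiet — the natural
"inclination from vertical" reading) is available via `mode="arcsin"`,
and a per-trial mean-centering option exists for platforms whose origin
is not the balance point.  Both are off by default.  The argument of the
inverse trig function is clamped to [−1, 1].

## Empirical mode decomposition

Sifting subtracts the mean of the cubic-spline envelopes through the
local maxima and minima until the normalized squared change between
successive candidates, `SD = Σ(h_prev − h)² / Σ h_prev²`, falls below a
threshold **and** the candidate satisfies the IMF count property
(|#extrema − #zero-crossings| ≤ 1).  Requiring the count property on top
of the classic SD rule guarantees every emitted mode is a valid IMF
without materially changing the decomposition.  Defaults: SD threshold
0.2 (the classic sifting criterion), ≤ 100 sifts per mode, ≤ 10 modes (a
3000-sample series supports no more dyadic scales).

Numerical conventions:

* **Extrema.** Strict local extrema; a plateau of equal values counts
  once at its floor-midpoint index.
* **Envelope boundaries.** The two extrema nearest each endpoint are
  mirrored about it before fitting (the standard guard against edge
  swings); `CubicSpline` with the not-a-knot condition, linear fallback
  when fewer than four knots exist.
* **Sifting stops** on a residual with fewer than two maxima or two
  minima; decomposition stops when the residual is monotone.
* **Completeness.** The residual is maintained by exact subtraction, so
  `Σ IMFs + residual` rebuilds the input to float bookkeeping (~1e-16
  relative; the test bound is 1e-9).

Mode truncation retains IMFs holding at least 1 % of the total IMF
energy (`Σ imf²`).  Truncation intentionally breaks completeness for the
retained subset; source and residual are kept unchanged.  If nothing
survives, the single highest-energy mode is kept.  Only the energy rule
is implemented; no frequency-band relevance filter.

## Analytic signal and sample entropy

Each retained IMF's analytic signal comes from the one-sided-spectrum
(frequency-domain Hilbert) method; amplitude is the modulus, phase the
argument wrapped to (−π, π].  An all-zero mode maps to zero amplitude
and zero phase by convention.

Sample entropy follows the Richman–Moorman convention: `N − m` templates,
Chebyshev distance, inclusive tolerance `r`, self-matches excluded, with
both the length-`m` and length-`m+1` match counts taken over the same
template start positions; `SE = −ln(A/B)`.  Defaults `m = 2`,
`r = 0.2·σ`, where σ is the *population* standard deviation of the series
being measured (the amplitude's own σ for amplitude entropy, the wrapped
phase's own σ for phase entropy) — so SE is affine-invariant.  Edge
cases:

* a constant series returns SE = 0 (maximally regular);
* a series whose total variation sits at float-rounding level
  (peak-to-peak ≤ 1e-10 of its magnitude) is treated as constant —
  because SE is scale-free it would otherwise quantify rounding noise,
  as the analytic amplitude of a pure tone demonstrates;
* if no template pair matches at either length, SE is undefined (NaN)
  and propagates.

The optimized counting kernel (numba, with a chunked numpy fallback)
returns counts identical to a naive O(N²) double loop; the test suite
asserts bitwise equality of (A, B).

Phase entropy uses the **wrapped** phase: the unwrapped phase of any
oscillatory mode is near-monotone, which would pin its entropy at ~0
regardless of the signal.  An instantaneous-frequency alternative
(`phase_mode="ifreq"`) is provided but non-default.

## The complexity index

Per retained IMF, total complexity is the weighted sum
`TCᵢ = ω_a·SE(aᵢ) + ω_φ·SE(φᵢ)` with equal weights (½, ½) by default;
the index is the mean of `TCᵢ` over retained IMFs.  "Multiscale" refers
to the IMF scales — no Costa-style coarse-graining is involved.  IMFs
with undefined entropy are skipped from the average while at least one
defined term remains; otherwise the index is undefined with a
diagnostic.  The index is deterministic, scale-invariant (EMD is
scale-equivariant and `r` tracks σ), and rises with broadband noise
content.

## Feature tables

One row per (subject, condition); never pooled across conditions.  The
`time_domain` set yields mean, SD (n−1), moment skewness `m₃/m₂^{3/2}`
and Pearson kurtosis `m₄/m₂²` (normal → 3, *not* excess) per descriptor;
the `cmci` set yields one index per descriptor.  Constant series flag
skewness/kurtosis as undefined.  No feature screening and no scaling
happen here — classifier-side z-scoring is fit on training folds only.

## Classifier bench and evaluation

The Ranking Forest is implemented as bagging of 50 CART trees (Gini,
unlimited depth, min leaf 1, √p features per split, bootstrap resampling)
whose averaged positive-class vote is the ranking score; with trees grown
to purity this equals the fraction of trees voting positive.  Baselines:
Gaussian Naive Bayes (variance floor via 1e-9 smoothing), L2 logistic
regression (C = 1), RBF soft-margin SVM (C = 1, γ = 1/(p·var)); all
baselines see z-scored features with scaling statistics from the
training part only.  Splitting is stratified 70/30 (per-class shuffle,
per-class train count `round(0.7·n_class)` with banker's rounding — 13 +
12 subjects split 9 + 8 / 4 + 4) and stratified 10-fold CV.

ROC curves are built from integer (FP, TP) counts at every distinct
score threshold, so the trapezoidal AUC equals the Mann–Whitney
pairwise-ordering statistic (ties = ½) *bitwise* — this is why the ROC
is not delegated to a library routine.  Sensitivity/specificity are
reported at the Youden point (max TPR − FPR; ties resolved toward the
lower threshold).  Cross-validated results carry per-fold AUC/SEN/SPC
and their means (the headline numbers); the aggregate ROC shown is the
pooled out-of-fold score curve, which for decision-value scorers (SVM) is
a display convenience, as raw decision values are not calibrated across
folds.  No hyperparameter search, no calibration, no multiple-testing
correction across models.

## Group statistics

Per descriptor and condition: Lilliefors-corrected KS normality per group
(the plain KS test with estimated parameters is anti-conservative); if
both groups pass at α = 0.05, Welch's t-test (unequal variances),
otherwise the Mann–Whitney U — exact null distribution when the combined
n ≤ 25 and no ties are present, tie-corrected normal approximation
otherwise.  Groups smaller than 4 cannot enter the Lilliefors table and
route to the rank test.  The per-descriptor AUC fits a 1-D linear
soft-margin SVM on the pooled values; a 1-D linear scorer is monotone, so
this equals the rank-based AUC up to orientation, and the larger
orientation is reported (0.5 for a degenerate zero-weight fit).  Under
the null (both groups the same normal, 13 vs 12), the gated procedure
rejects at ≈ 5 %, which the test suite verifies over 2000 simulations.

## Synthetic cohorts

The generator emulates the study conditions end to end: 13 elite + 12
expert subjects by default, 30 s at 100 Hz, four conditions.  Each
channel is a sum of 2–4 sway oscillators (0.1–1.5 Hz, random phases,
amplitudes weighted toward low frequency) plus 1/f^β Gaussian noise at
35 % of the oscillator RMS, mean-removed and rescaled to the condition's
target RMS (0.25 in on the firm surface; multipliers 1.0/1.4/1.2/1.8 for
T1/T2/T3/T4, so RMS orders T4 > T2 > T3 > T1).  Heights are drawn near
68.8 ± 1.3 in.  All randomness flows from one seed through per-subject
substreams spawned by counter; cohorts are bit-reproducible.

The between-group difference is injected into *irregularity*, not
magnitude.  Both groups carry the same noise fraction, but the expert
group's noise exponent is flattened from the elite β = 2 toward white in
proportion to the complexity gap (β = 2 − 2·gap; pure white at gap 1),
and its oscillators acquire mild phase jitter.  Two properties motivated
this design, and both were verified before the defaults were frozen:

* a Gaussian noise marginal does not depend on its colour, so
  mean/SD/skewness/kurtosis of every descriptor stay distributionally
  matched between groups — moment features hover near chance while the
  complexity index separates strongly (Cohen's d ≈ 7–9 at gap 0.8,
  n = 30/group);
* a steep elite exponent is needed because β = 1 noise is already
  near-maximally irregular at the m = 2 / 100 Hz template scale, leaving
  no headroom for a regularity contrast; β = 2 also matches the steep
  high-frequency rolloff of real quiet-stance CoP spectra.

At gap 0 the two groups' generative laws coincide draw for draw.  The
knob saturates as the noise approaches white, so monotonicity of mean
CMCI in the gap is probed over gaps 0–0.8.

What the generator does *not* emulate: inverted-pendulum dynamics,
intermittent postural corrections, non-stationarity across a trial,
fatigue or learning effects, or the actual athletes' descriptor values.
Passing the pipeline tests therefore shows the machinery recovers a
planted, magnitude-matched irregularity difference at realistic sample
sizes — not that real elite/expert athletes differ this way.

## Problem sizes in the validation suite

Signal-level checks run at the native trial size (N = 3000).  The
cohort-level checks use one condition with 30 subjects per group over 5
seeds for both the gap-recovery and null benches; the generator's
distribution-level self-checks (gap-0 KS, knob monotonicity) run at 10 s
trials, where the entropy estimates are already stable.  The acceptance
script reproduces the full 13 + 12 × four-condition study design.

## Known limitations

* EMD has no uniqueness guarantee; mode mixing can shift entropy between
  adjacent IMFs, and the count of retained modes varies between
  realizations, which is the dominant within-group variance source of
  the index.
* The index averages over however many modes survive truncation, so
  signals decomposing into different mode counts are compared on
  slightly different supports.
* Sample entropy at m = 2 on 100 Hz data probes ~20–30 ms structure;
  slow amplitude/phase modulation is largely invisible to it.
* The exact Mann–Whitney branch requires tie-free data; tied small
  samples fall back to the tie-corrected approximation.
* Sensitivity/specificity at the Youden point are optimistic relative to
  a pre-registered threshold.
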