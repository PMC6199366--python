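# Methods

This note documents the models, conventions and numerical choices behind
`tcdmorph`, and what the synthetic cohort does and does not demonstrate.

## Signal model and pipeline

The raw input is a cerebral blood-flow-velocity (CBFV) envelope in cm/s,
sampled at 125 Hz (the reference rate), recorded for 30 s per insonation
depth and hemisphere. Per recording the pipeline is:

1. **Beat detection** (`beats.detect_beats`). The envelope is detrended
   with a 2 s moving average (high-pass near 0.5 Hz) and lightly
   smoothed; systolic peaks are found by prominence ≥ 25% of the signal
   inter-quartile range with a refractory distance derived from an
   autocorrelation period estimate (the estimate checks integer
   subdivisions of the autocorrelation argmax so that reflected/dicrotic
   humps or period-doubled maxima do not masquerade as the beat period).
   Onsets are placed at the diastolic minimum between consecutive peaks,
   then re-anchored in a second pass: a median beat template is built
   over all first-pass beats, its foot is localized on the (much less
   noisy) template, and each beat is aligned to the template by
   cross-correlation. The second pass exists because the pre-systolic
   foot of a pulse waveform is nearly flat, so a per-beat argmin wanders
   under envelope noise; correlation against the ensemble template is
   well conditioned. Beats whose duration falls outside a 35–180 bpm
   window are flagged rather than silently kept. Everything is
   deterministic: no RNG anywhere in detection, rejection or averaging.
2. **Outlier rejection** (`beats.reject_outlier_beats`), replacing the
   manual beat editing of an interactive acquisition workflow with two
   automated rules: a beat is rejected iff its Pearson correlation with
   the mean of all other beats (resampled to the median beat length)
   falls below 0.9, or its mean velocity deviates from the median beat
   mean by more than 3 robust SDs (1.4826·MAD, floored at a tiny epsilon
   so identical beats are never rejected). Both thresholds are exposed.
3. **Averaging** (`beats.average_beats`): accepted beats are resampled
   by linear interpolation to the median accepted length, aligned at
   onset only (no time warping), and averaged pointwise.
4. **Pair selection** (`beats.select_bilateral_pair`): per hemisphere
   the average beat with the highest mean velocity across depths is
   kept, since Doppler velocity scales with the cosine of the
   beam-vessel angle and the fastest reading is closest to truth. Ties
   break to the shallower depth, then to recording order. A hemisphere
   with no usable recording of ≥ 15 accepted beats makes the exam
   incomplete; such subjects are reported as skipped, not errors.

## VCI and VAI conventions

Curvature is evaluated on the smoothed beat as
`k_i = |x_{i+1} − 2x_i + x_{i−1}| / (1 + (x_i − x_{i−1})²)^{3/2}`.
Differences are taken **per sample index** with velocity in cm/s — no
division by the sampling interval. The magnitude of VCI is therefore
tied to the sampling rate; 125 Hz is declared the reference rate and
the convention is pinned rather than inferred. Boundary samples get
k = 0 (they sit far below the canopy threshold in any real beat, and it
keeps the canopy sum total). The canopy is kept as a literal set — it
may be non-contiguous — and its landmarks (diastolic minimum, systolic
maximum) are recomputed on the smoothed beat, since that is the signal
curvature sees.

The smoothing kernel is a raised cosine whose nonzero tap count is the
nearest odd integer to `window_ms · fs / 1000`, floored at 3 taps so the
operation always smooths: at 125 Hz the 9 ms default gives the minimal
kernel [0.25, 0.5, 0.25], and the kernel widens proportionally if data
arrive at a higher rate. Edges are handled by reflection. A literal
"9 ms at 125 Hz" is about one sample — an identity — so the floor is an
interpretation, chosen so the smoothing step never degenerates.

VAI uses the unsmoothed average beats of the selected pair; means are
over the averaged beat, not the raw 30 s envelope. VCI of a pair is the
minimum across hemispheres (the occluded side is the informative one);
VAI is min/max of the hemispheric means, so it is symmetric, bounded in
[0, 1], and equals 1 only for exactly symmetric flow.

Note that VCI is *not* monotone under arbitrary smoothing or widening:
blunting lowers per-sample curvature but also widens the canopy, and
for extreme widening the larger canopy wins. The blunting-monotonicity
checks therefore widen the systolic pulse over the moderate range
(width factors 1–2) where the physiologic effect — lower curvature —
dominates.

## Threshold fitting and the tree

`J_α = α·TPR − (1−α)·FPR` is maximized exhaustively over candidate cut
points: midpoints between consecutive distinct sorted values plus ±∞
sentinels. Ties in `J_α` break toward higher specificity (the candidate
classifying fewest subjects positive); this makes α = 1 return the
*least* aggressive threshold that still reaches training sensitivity 1.
Predictions use strict inequalities; equality at any threshold falls to
the control side. The tree fits VCI_MIN on all training data, VCI_MAX
on the sub-threshold remainder (candidates restricted to ≥ VCI_MIN, so
the ordering invariant holds by construction), and VAI_CRIT on what is
left. A stage whose training subset is single-class gets a pass-through
sentinel (±∞) and is recorded in fit metadata — degenerate LOOCV folds
therefore never abort a sweep. The same α is applied to all three
thresholds, matching a one-parameter sensitivity dial.

LOOCV refits the chosen classifier n times and pools the n held-out
predictions into one confusion matrix. The α sweep runs LOOCV at each α
in 0.5…1.0 (step 0.01, 51 points) and reports both cross-validated and
in-sample SEN/SPE/ACC; in-sample sensitivity is provably non-decreasing
in α for single-feature classifiers under the tie-break above.

## Statistics

Group differences use the two-sided Mann-Whitney U test: exact
enumeration when `n₁·n₂ ≤ 400` and the data are tie-free, otherwise the
normal approximation with tie and continuity corrections. The U
statistic divided by `n₁·n₂` is the common-language effect size and
equals the trapezoidal ROC-AUC with ties half-counted; both routes are
computed (the ROC via scikit-learn) and agree to 1e−12, which the tests
pin. AUCs are oriented so that values above 0.5 mean the feature is
higher in controls, the direction both VCI and VAI take. Confidence
intervals on group means are percentile bootstrap intervals (10,000
resamples, 2.5th/97.5th percentiles, seeded generator). p-values are
reported to 3 significant figures, with values below 10⁻³ rendered as
"p < 0.001".

## Synthetic cohort

No waveform data are distributed, so `synth` generates them. Beats are
a three-pulse additive surrogate: a diastolic floor plus systolic,
reflected and dicrotic pulses, each a two-sided Gaussian with separate
rise/fall widths (the dicrotic fall doubling as diastolic runoff).
Two parameter sets are shipped: a sharp "normal" morphology and a
blunted occlusion morphology with a wider, flatter systolic complex.
Per subject, widths and amplitudes get ~10% log-normal jitter.

Study conditions follow the clinical cohort the package emulates:
33 LVO / 33 in-hospital controls; 30 s recordings at 125 Hz; four
depths (45–60 mm) per hemisphere with a cosine-of-angle amplitude
factor peaking at a subject-level optimal depth; heart rates drawn
N(87.9, 22.2) bpm for LVO and N(71.2, 11) for controls (clipped to
45–140 bpm); 3% beat-period jitter, 4% amplitude jitter, 0.6 cm/s
additive Gaussian noise, and 3% corrupted (flat-dropout) beats. Every
beat is normalized to its hemisphere's mean-velocity level, so
hemispheric scale ratios translate exactly into VAI: LVO subjects get
an ipsilateral scale drawn around 0.65 and controls a log-normal
asymmetry with SD 0.12, targeting group mean VAI ≈ 0.65 and ≈ 0.89.
The morphology parameters were calibrated once so that the *pipeline*
group VCI means land near 2.7 (LVO) and 5.0 (controls); these are
calibration targets mirroring the published group means, not claims of
physiological fidelity. The generator records ground truth (true
onsets, corrupt spans, ipsilateral side, scales) for validation, and
all generation is reproducible from (spec, seed) with per-subject
counter-derived substreams, so a subject's data do not depend on cohort
size.

`generate_feature_cohort` bypasses waveforms entirely and draws
(VCI, VAI) pairs from truncated normal distributions through a Gaussian
copula (default correlation 0.3 — a free parameter, since the true
within-group correlation structure is unknown). Default means match
the clinical group means; default SDs are inferred from the published
bootstrap CIs of those means (CI half-width ≈ 1.96·SD/√33).

**What passing tests show — and don't.** The synthetic cohort is
cleaner than clinical data: noise is white, morphology variation is
parametric, and the two groups differ exactly along the dimensions the
metrics measure. Separability on it (AUCs ≈ 0.96) is therefore an
upper bound, not a reproduction of clinical performance; the tests
establish correctness of the computations and the qualitative ordering
(controls above LVO in both features, tree at least as sensitive as
VCI alone), not clinical effect sizes.

## Numerical choices and degenerate inputs

- Flat beats (no diastolic-systolic range) raise a degenerate-beat
  error everywhere a range is needed; VAI only requires positive means.
- Robust SD in outlier rejection is floored at max(1e−12, 1e−9·|median|)
  so identical beats never self-reject.
- Candidate thresholds at value midpoints make fits invariant to scale
  and independent of label order; the ±∞ sentinels make "predict all" /
  "predict none" available to the optimizer.
- Envelope CSV floats are written with shortest-exact repr and read
  back with round-trip precision, so write→read is bit-identical.
- Seeds: one integer seeds a cohort; subject streams are derived as
  `default_rng([seed, counter])`.

## Known limitations

- The beat detector is validated only against the synthetic generator's
  ground truth (≥95% of onsets within ±3 samples at default noise); no
  claim is made about hardware-specific envelope artifacts.
- Velocity means are taken over the averaged beat, not the full
  envelope; with strong beat-length asymmetry between hemispheres the
  two definitions can differ slightly.
- The problem sizes used by the test suite and the acceptance script
  (a 66-subject waveform cohort, 500-row planted cohorts, 10,000
  bootstrap resamples, 51-point α sweeps) were chosen to exercise every
  code path at the study's own scale; they complete in seconds.
- No probabilistic outputs: the classifiers emit hard LVO/control
  labels only, and pulsatility index is deliberately not part of the
  decision rule.
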