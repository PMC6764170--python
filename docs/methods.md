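# Methods

This note documents the models, conventions and design choices behind
`vfforecast`, in the spirit of a methods appendix: what is computed,
under which assumptions, and where the genuinely open choices were made.

## Analysis windows

A VF-prone record must carry an onset marker at least 150 s into the
recording; its feature window is `[onset − 150 s, onset − 30 s)`. The
final 30 s before onset (the forecast gap) is never used, so a deployed
predictor would have that much warning time. Control records use a
120-s window starting at a configurable offset (default 0 s, i.e. the
first 120 s — the choice is arbitrary for stationary recordings and is
therefore deterministic and exposed as `control_offset_s`). Windows are
half-open `[start, end)` on 0-based sample indices; a beat at exactly
the window end is excluded, a beat at the start is kept. Records whose
window does not fit are excluded (with their ids reported), not
silently dropped. Windowing is idempotent: a trimmed record trims to
itself.

Beat annotations are trusted verbatim; no ectopic-beat filtering is
applied. An RR series requires at least 3 in-window beats.

## HRV features

With `RR` the N intervals in ms and `D` the N−1 successive differences:

| feature | definition | convention notes |
|---|---|---|
| Mean NN | ΣRR/N | |
| SDNN | √(Σ(RR−MeanNN)²/N) | population (1/N) form |
| RMSSD | √(ΣD²/(N−1)) | averaged over the differences |
| pNN50 | 100·#{|D|>50 ms}/N | denominator is the number of **intervals**; `per_differences=True` selects the N−1 convention |
| VLF, LF, HF | PSD bin sums over (0, 0.04], (0.04, 0.15], (0.15, 0.4] Hz | ms²; see below |
| LF/HF | LF/HF | NaN when HF ≤ 10⁻⁹ ms² (flagged, never infinite) |
| SD1 | √(Var(RRᵢ−RRᵢ₊₁)/2) | population variance over the N−1 differences |
| SD2 | √(max(2·SDNN²−SD1², 0)) | see below |
| SD1/SD2 | ratio | NaN when SD2 = 0 |

The pNN50 interval-count denominator is unusual (most toolkits divide
by N−1); it is kept as the package's primary convention with a switch,
because the two differ by a factor (N−1)/N that matters at these window
lengths (~150 beats) only in the third digit.

**SD2 and the Poincaré identity.** SD2 is defined through the standard
identity SD2² = 2·SDNN² − SD1², so SD1² + SD2² = 2·SDNN² holds exactly
— *except* when SD1² exceeds 2·SDNN², which can happen for short,
almost purely alternating series because SD1 averages over N−1
differences while SDNN averages over N intervals. The radicand is then
clamped at 0 and SD2 reported as 0 (a pure alternation genuinely has no
spread along the line of identity). Property tests assert the identity
up to this documented clamp.

**Spectral estimation.** The tachogram RR(t) (interval value at its
end time) is resampled with a cubic spline onto a 4-Hz grid — the
conventional HRV choice, and it makes one 256-point Welch window equal
64 s, so a 120-s record yields two 50 %-overlapping Hann windows —
linearly detrended, and passed to Welch's periodogram. Band powers are
Riemann sums of PSD bins with half-open band edges (lo, hi], which
makes VLF+LF+HF exactly additive and assigns each bin to one band. The
DC bin is removed by detrending, so "0–0.04 Hz" is effectively
(0, 0.04]. VLF from 120-s windows is a noisy quantity (fewer than five
cycles of a 0.04-Hz component fit) and should be interpreted with care.

## QRS-shape features

R peaks: annotated positions are used verbatim when present; otherwise
a band-pass (5–15 Hz) → differentiate → square → 150-ms
moving-average detector with an adaptive threshold and 250-ms
refractory period locates beats, refined to the local
absolute-amplitude extremum of the raw signal within ±100 ms. On
noise-free synthetic records at 250 Hz this refinement recovers ≥ 99 %
of beats to within one sample.

Per beat, the QRS window runs from the PQ junction to the J point,
found by scanning outward from R for the first point where the slope
magnitude falls below 5 % of the local peak slope *after* the scan has
crossed the steep QRS limb; if no such point exists within ±120 ms the
window falls back to fixed ±60 ms offsets. The baseline is the mean of
the 40-ms segment ending at the PQ junction (a local PR-segment
estimate, robust to slow drift). Beats whose window would cross the
record edge are skipped and logged.

The signed area is the uniform-weight, baseline-corrected sum of
samples across the window (a weight-kernel hook exists for alternative
weightings), in µV·samples by default; `area_in_uv_ms=True` rescales by
1000/fs for cross-sampling-rate comparability. The sign is preserved
per beat; the *aggregates* take the absolute value first:
QRSaM/QRSaSD are the population mean/SD of |area|, RPampM/RPampSD the
population mean/SD of the (signed) per-beat maximum above baseline.

## Classifier

The network is `x ∈ ℝⁿ → h = ReLU(W₁x + b₁) ∈ ℝ⁶ → p = σ(w₂·h + b₂)`,
n = 11 (HRV), 4 (QRS) or 15 (combined); six hidden units. Biases enter
before the activation; a `literal_bias` forward mode implements the
post-activation variant `f(Wx) + b` (clipping the output into [0, 1])
for comparison — post-activation output bias breaks the probability
interpretation, which is why it is not the default. Training minimizes
mean binary cross-entropy with Adam (learning rate 0.001, β₁ = 0.9,
β₂ = 0.999, batch size 8, 200 epochs, seeded small-uniform init in
[−0.2, 0.2]); these are standard Adam defaults, generous for a 55-row
dataset, and the gradient code is verified against central finite
differences at 10⁻⁴ relative tolerance. Decision threshold 0.5, ties
classified as VF.

Features are z-scored with training-set means and population SDs;
zero-variance features raise an error naming the feature. The scaler is
fit on the nine training folds only (default); `scaler_scope="global"`
scales the full dataset before splitting, which leaks test-fold
statistics and exists only to mirror the simpler protocol some analyses
use.

Comparison classifiers are scikit-learn with default hyperparameters
(recorded in the run manifest): `SVC` wrapped in
`CalibratedClassifierCV` so it exposes probabilities,
`KNeighborsClassifier`, `RandomForestClassifier` (seeded), `GaussianNB`.

## Evaluation

Stratified shuffled 10-fold cross-validation repeated 10 times (seeds
advance per repeat; each repeat is a valid partition with fold sizes
differing by ≤ 1; 55 records give folds of 5 and 6). Sensitivity
(VF positive), specificity and accuracy are computed per held-out fold
and aggregated as mean ± SD over the 100 repeat × fold cells; AUC is
computed by trapezoidal integration of the ROC over the pooled held-out
scores of each repeat and averaged over repeats, because a per-fold ROC
on 5–6 points is too coarse. The trapezoidal AUC is tested to agree
with the rank-based (Mann–Whitney) statistic to 10⁻¹².

Feature and accuracy comparisons use Welch's unequal-variance
two-tailed t-test (group SDs of these features differ by large
factors); a pooled-variance option exists. Degenerate inputs follow
fixed conventions: identical constant groups → (t, p) = (0, 1);
distinct constant groups → (±∞, 0). The five-algorithm comparison is a
one-way ANOVA over the 100 accuracy replicates per algorithm with Tukey
HSD post-hoc pairs; replicates within an algorithm share folds, so the
independence assumption is approximate — the same caveat applies to any
repeated-CV ANOVA.

## Synthetic data model

Per record, RR intervals follow
`RR(tᵢ) = mean_rr + A_LF·sin(2π f_LF tᵢ) + A_HF·sin(2π f_HF tᵢ) + ε`,
ε ~ N(0, σ_RR²), floored at 200 ms; f_LF must lie in (0.04, 0.15) Hz
and f_HF in (0.15, 0.4) Hz so the modulations land in the intended
bands. The ECG places a sum-of-Gaussians P–QRS–T template at each beat:
R amplitude `a·(1 + d·sin(2π f_LF tᵢ))` (slow amplitude modulation, the
mechanism the shape features detect), Q/S amplitudes fixed fractions of
the R amplitude, per-beat QRS width jittered by N(0, σ_w²), white
measurement noise added per sample. Ground truth (exact beat times,
per-beat analytic amplitude, discrete QRS signed area) is carried
alongside every record.

Cohorts fan one master seed out to independent per-record child seeds
(`numpy` `SeedSequence.spawn`), so regeneration is bit-identical and
records are independent. VF-group records get an onset marker uniform
in [150 s, duration − 1 s]; any placement there is equivalent for
feature extraction. Between-subject heterogeneity is modeled by
lognormal multipliers (median 1) on the RR-variability parameters
(CV `subject_cv_rr`, a third of it on `mean_rr`) and on the QRS
parameters (CV `subject_cv_qrs`) — without it, all records in a group
are statistically identical and every feature set separates the groups
trivially.

**Default conditions (`table2` preset).** 27 VF-prone and 28 control
records at 128 Hz, 170 s. Control: mean RR 760 ms, LF/HF modulation
12/10 ms, RR noise 20 ms, R amplitude 800 µV with 5 % modulation depth,
QRS width 80 ms, 3 % width jitter. VF-prone: mean RR 800 ms, modulation
28/22 ms, RR noise 48 ms, R amplitude 1600 µV with 22 % depth, width
85 ms, 12 % jitter. Between-subject CVs are 0.45 (RR side) and 0.15
(QRS side). The contrasts were set from the group-separation
arithmetic: on the log scale a 2–2.5× ratio under CV 0.45 gives d′ ≈ 2
(strongly significant in a 27-vs-28 t-test but overlapping enough that
classification stays imperfect), while 2–10× ratios under CV 0.15 give
d′ ≳ 4.5 (near-perfect separation) — producing the intended ordering:
QRS-feature classification ≈ perfect, HRV-feature classification good
but visibly worse, and VF > control in SDNN, RMSSD, pNN50, SD1, SD2,
QRSaSD, RPampM, RPampSD at p < 0.05 in essentially every cohort. The
`separable` preset shrinks the between-subject CVs (both families
nearly noise-free separators); the `null` preset draws both groups from
the control distribution.

**What the generator does and does not emulate.** It reproduces the
statistical structure the pipeline consumes: RR-variability contrasts
with band-limited modulation, QRS amplitude/area dispersion contrasts,
annotation/truth consistency, and onset geometry. It does not attempt
physiological realism: no fibrillatory waveform after onset (only the
pre-onset window is consumed), no ectopy, artifacts, baseline wander or
non-stationarity, and the pre-onset amplitude/area modulation is a
generic stand-in mechanism, not a claim about arrhythmogenesis. Passing
tests therefore validate the *machinery* (formulas, windowing,
training, evaluation) and the *internal consistency* of the analysis,
not clinical performance on real recordings.

## Problem sizes and tolerances in the test suite

Formula oracles run 100 random series against naive loop
implementations at 10⁻⁹ relative tolerance. The end-to-end structural
check uses 50 seeded cohorts (27/28 records each) with 2-repeat 10-fold
CV per cohort — enough repeats to rank the two feature sets stably
while keeping the suite's total runtime in minutes; the acceptance
script uses 10-repeat CV for its headline numbers and 20 cohorts for
the pattern-stability fractions. Monte-Carlo checks (RR noise SD,
permutation null, type-I error) use fixed seeds and the bands stated in
their assertions.

## Known limitations

- WFDB support covers single-channel reading of formats 16 and 212 and
  beat/onset annotations — enough for the databases this analysis
  targets, not a general WFDB implementation.
- The QRS boundary search assumes a dominant upright R wave (as the
  synthetic template has); heavily fragmented or inverted complexes
  will fall back to fixed ±60-ms windows.
- Area units of µV·samples depend on sampling rate; mixing sampling
  rates in one cohort without `area_in_uv_ms=True` conflates gain and
  rate (a deliberate default, flagged here, since single-rate cohorts
  are the normal case).
- With 55 records, per-fold test sets hold 5–6 records; fold-level
  sensitivity/specificity are coarse (0/20/40…%), which is why
  aggregates are reported with SDs.
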