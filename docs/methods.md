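# Methods

This note documents the models, defaults and numerical choices behind
`glvchoice`, and what the synthetic-data benchmarks do and do not show
about real data.

## Imaging chain

### Acquisition model

The default geometry is a 10 s recording at 4 Hz (40 frames): 2 s
pre-stimulus, 2 s odor pulse, 6 s post-stimulus, on 344 × 260 px frames
with 2.5 µm pixels (4-fold binned CCD). All frame indexing is 0-based;
times are seconds from recording start. The stimulus onset frame is
`round(pre_s · rate)` = 8.

### Correction pipeline

The order is fixed and logged: **background → bleach → motion → median →
ΔF/F**. Rerunning on identical input is bit-identical.

* **Background.** A single scalar camera/tissue offset, estimated as the
  1st percentile of the *temporal-mean* image and subtracted with
  clipping at 0. Taking the percentile of the time-averaged image rather
  than of raw frames matters: averaging shrinks sensor noise by √T, so
  the estimate tracks the true dark level instead of sitting ~2.3 noise
  SD below it in the dark-pixel noise tail. The estimator assumes the
  field of view contains some off-tissue (dark) pixels, which the
  wide-field AL preparation provides.
* **Bleaching.** A global model b(t) = a·e^(−t/τ) + c is fitted
  (`scipy.optimize.curve_fit`, non-negative bounds) to the whole-frame
  mean trace, excluding the response window (stimulus onset → onset +
  4 s by default) so the odor response is not flattened; every frame is
  divided by b(t)/b(0). A global multiplicative model is appropriate for
  bath-applied dyes; per-pixel fits are noise-dominated at this SNR. On
  fit failure a linear detrend is applied with a warning (`strict=True`
  raises instead, naming the fallback). Note that a response decaying
  slower than the excluded window leaks into the fit and biases
  recovered amplitudes by ~1–2 % at full frame size; the exclusion
  window is a parameter when this matters.
* **Motion.** Per-frame rigid *integer* translation against a reference
  frame (default frame 0), estimated by FFT cross-correlation of
  mean-subtracted images with the maximum restricted to ±10 px; frames
  are shifted back with edge-value fill. Estimates at the search bound
  trigger a warning. No rotation, warping or subpixel refinement: the
  preparation is restrained and subpixel gains are below the 5-px median
  filter scale.
* **Median filter.** Per-frame 5 × 5 square median (edge-repeating
  reflection). "5 pixels" is interpreted as the window side.
* **ΔF/F.** f0 is the per-pixel mean over the 8 pre-stimulus frames;
  dff = (F − f0)/f0. Pixels with f0 ≤ 10⁻⁶ counts have undefined ΔF/F
  and are masked (NaN) or, on request, raise an error naming the
  affected pixel count. Off-tissue pixels are legitimately masked after
  scalar background subtraction.

### Response statistics

ROIs are 60 × 60 µm squares (24 px at default pixel size) centered on
activity spots. Traces are the ROI-mean ΔF/F per frame, smoothed by a
centered 3-frame moving mean (window shrinking at the ends). The
response amplitude is the post-onset maximum (earliest frame on ties,
for determinism) averaged with its existing neighbours. Amplitudes are
normalized per animal across all stimuli of a session — so exactly one
response per animal is 100 % — and a stimulus is included if any of its
ROIs reaches ≥ 30 % of the animal maximum. Activation maps average ΔF/F
over the stimulus frames plus the following second (frames 8–19 at
defaults); pattern similarity is the Pearson correlation over masked
pixels (Spearman behind a flag). Comparisons should be restricted to an
AL-outline mask: the low-baseline rim of the preparation otherwise
contributes a shared artifact that inflates correlations between
unrelated patterns. The ROI activation ratio (Z)-3-specific /
(E)-2-specific uses the same negative-reciprocal display transform as
the chemistry (below); 1 marks equal activation.

## Synthetic AL movies

The generator renders
`F(t) = offset + bleach(t) · baseline · tissue · (1 + Σ spot·dff(t))`,
rigidly shifted per frame, plus additive Gaussian noise, clipped at 0
(Gaussian noise keeps closed-form checks simple; it stands in for photon
noise). The scene is a soft-edged bright disk (the AL) on a dark
surround with a constant camera offset — the dark surround is what makes
a percentile background estimator meaningful. Glomeruli are Gaussian
spots (default σ = 25 µm) with per-odor peak ΔF/F; the default
four-spot layout mirrors the observed response organization: one
unspecific region, one aldehyde/alcohol region with stronger (E)-2
responses, and one (Z)-3- and one (E)-2-hexenyl-acetate-specific region.
The response time course is a linear ramp over the 2 s stimulus to peak
followed by exponential decay (τ = 2 s) — a stand-in shape chosen to
match published transients qualitatively; real calcium kinetics are not
calibrated against deposited traces. `bleach(t) = (1−f) + f·e^(−t/τ)`
with defaults f = 0.2, τ = 20 s; movies serialize as 16-bit TIFF with a
JSON ground-truth sidecar.

Ground truth for recovery scoring is the *noiseless ROI trace*: the
spatial mean of the spot profile over the ROI times the response course,
with no bleach, shift or noise. This is the quantity the extraction
chain estimates; comparing to the center-pixel peak instead would
conflate estimator definition with corruption recovery.

**Benchmark conditions** (`glvchoice.benchmarks`): 20 movies at full
geometry, bleach τ drawn from 10–40 s, integer shifts up to ±5 px, noise
SD 5 % of baseline; scored on ROIs with true amplitude ≥ 0.01 ΔF/F
(below that, single-ROI relative error is dominated by the noise floor).
Measured: median relative amplitude error ≈ 6–8 %, 100 % of shifts
recovered exactly, pure-bleach baselines flattened to ≪ 0.1 % residual
slope per frame. These movies do not emulate non-rigid tissue motion,
dye-kinetics nonlinearity, or spatially structured noise, so passing
benchmarks bound algorithmic error, not biological variability.

## GLV chemistry

### Quantification

SIM peaks are integrated trapezoidally above a straight baseline drawn
between the window endpoints (±12 s around the registry retention time),
clipped at 0 — the simplest defensible baseline for well-separated SIM
peaks. Analyte areas are normalized to the tetralin internal standard
(laboratory SuperQ traps: 320 ng; field charcoal traps: 240 ng; a
sample spiked differently from the calibration standards is rescaled to
the curve's spike reference). Calibration is ordinary least squares of
normalized area on standard mass at levels 33, 10, 5, 1, 0.5, 0.1 ng
(three replicates), intercept retained for generality
(`force_origin=True` available). Back-calculated amounts below the
lowest level carry the `bld` (below detection limit) flag; the synthetic
generator flags amounts under 0.001 units the same way. Emission rates
divide by leaf fresh mass (g) or leaf area (cm²) over the 2 h trapping
window; 50 cm² ≈ 1 g FM for cross-basis comparison. Molar masses ship
in the registry (hexenal 98.14, hexenol 100.16, hexenyl acetate 142.20,
hexenyl butyrate 170.25 g/mol), overridable. The registry's quantifier
ions are m/z 83 (hexenals) and m/z 82 (hexenols, acetates); the
butyrates are assigned m/z 82 as a stand-in since the study's SIM list
does not cover them, and tetralin's synthetic retention time (20.0 min)
is a placeholder beyond the GLV elution window.

### Ratios

The default ratio statistic is **per-sample**: r = (Z)-3 / (E)-2 within
each sample, then summarized (median). Samples whose (E)-2 denominator
is bld or non-positive are excluded with a logged count — never imputed
as zero, which would be a division hazard. The ratio of group means is a
separate, explicitly named helper (`ratio_of_means`): the two estimators
genuinely disagree and must not be silently interchanged. Display values
use T(r) = r if r ≥ 1 else −1/r; the image never enters (−1, 1), the
sign encodes which isomer dominates and |T| = max(r, 1/r).

### Synthetic emissions

Per sample, each family's (Z)-3 and (E)-2 amounts are drawn lognormally
(median = configured mean, σ = 0.4 on the log scale) around day-time
(Z)-3-dominant base levels; under the herbivory-mimic treatment a
fraction c (default 0.6) of the drawn (Z)-3 amount moves to the paired
(E)-2 compound — mass-conserving, before measurement noise. Because the
converted ratio is a monotone map of the lognormal ratio, its median has
the closed form (1−c)/(m_E/m_Z + c), which the recovery benchmark checks
(measured relative error < 1 % at n = 2000). The generator does not
model between-plant covariance, diurnal drift within a block, or
adsorbent breakthrough.

## Nonparametric tests

All tests are rank-based and therefore invariant under strictly monotone
transforms. Two-sided exact p-values double the smaller tail mass,
capped at 1.

* **Mann–Whitney U**: exact by enumerating all C(n+m, n) labelings of
  the pooled *observed* values when n + m ≤ 12 (a permutation null,
  exact under ties); otherwise tie-corrected normal approximation with
  continuity correction. Exact and approximate p agree within 0.02 at
  the boundary on tie-free data.
* **Wilcoxon signed-rank**: zero differences dropped before ranking
  (the classical rule, matching contemporaneous software defaults);
  exact by enumerating 2ⁿ sign patterns of the observed absolute ranks
  for n ≤ 15; the reported W is the smaller rank sum. Supports a
  hypothesized center µ (e.g. activation ratios vs 1).
* **Kruskal–Wallis**: tie-corrected H, χ² with k−1 df.
* **Dunn post-hoc**: pairwise z from pooled mean ranks with the tie
  correction Σ(t³−t)/(12(N−1)), Bonferroni-adjusted over all pairs (the
  common default for "Dunn's multiple comparison test"), plus a greedy
  compact-letter display.

Exactness is verified against an independent enumeration oracle
(scipy's exact modes) in the test suite; scipy is never the
implementation path.

## Paired-choice behavior

The response variable is d = eggs_A − eggs_B per plant. Plants with zero
eggs on both sides are excluded before testing (they carry no preference
information; the exclusion provably cannot change the signed-rank
statistic, since d = 0 pairs are dropped by the test anyway — the
exclusion count is still reported because it changes the effective n).
Side-switching across nights is assumed resolved in the input labeling:
the table stores treatment identity, not physical side. Eggs of both
hawkmoth species are pooled.

**Calibration.** On null synthetic data (independent Poisson counts,
mean 1.0 per side — the field-scale (Z)-3 mean with preference ratio 1 —
n = 15 plants, 2000 seeded runs) the exact signed-rank rejects at 4.0 %
at nominal α = 5 %. The slight conservatism is the expected effect of
discreteness and heavy ties in small Poisson differences, not an
implementation artifact. Power at the field effect size (means 1.0 vs
0.5) increases with n, verified at n = 15 vs 60.

## Orchestration

A single JSON-serializable config drives end-to-end demo runs
(synthetic movies → preprocessing → amplitudes/correlations; emissions →
ratios → U tests; egg counts → signed-rank), writing numeric tables, the
resolved config and a stage manifest; stage failures abort with the
stage name. Runs are deterministic given the seed. The CLI is a thin
layer over these functions (exit codes: 0 ok, 1 usage, 2 stage failure).

## Problem sizes

The shipped benchmarks use 20 full-geometry movies for the imaging
recovery suite, 5 movies for bleach flatness, 200 instances for oracle
agreement, 2000 runs for type-I calibration, 2000 samples for ratio
recovery and 3 repeats × 2 scenes for the pattern-similarity study —
sizes at which every reported metric is stable to well within its
decision margin.

## Known limitations

* Rigid integer motion only; non-rigid or sub-pixel drift is out of
  scope.
* The global bleach model cannot capture spatially inhomogeneous
  bleaching.
* Exact enumeration limits (n + m ≤ 12, n ≤ 15) are conservative;
  beyond them the normal approximation is used even when enumeration
  would still be feasible on fast machines.
* Chromatogram simulation uses single Gaussian peaks per compound; no
  co-elution deconvolution or retention-index calibration.
* Whether field ratio statistics should use net (control-subtracted) or
  raw amounts is left to the caller: both pathways exist
  (`subtract_paired_control` before `ratio_table`), neither is asserted
  as canonical.
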