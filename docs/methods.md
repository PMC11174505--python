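# Methods

This note documents the models and procedures implemented in `ficss`, the
parameters that matter, the synthetic data the package is validated
against, and the design decisions that were genuinely open.

## Data model and preprocessing

A `SpectralDataset` couples an absorbance matrix (n_samples × n_channels,
A = log₁₀(1/R), unitless) on a strictly increasing wavenumber axis (cm⁻¹)
to a per-sample concentration matrix (n_samples × n_analytes, in the
user's concentration units — the examples use % dry mass).  Preprocessing
is Savitzky–Golay smoothing along the wavelength axis; defaults are
window 11, polynomial order 2, which at 4 cm⁻¹ channel spacing smooths
over ~44 cm⁻¹ — narrow relative to the ~100 cm⁻¹ bandwidths typical of
NIR overtone bands.  Edge windows use the filter's polynomial
interpolation mode, so the output keeps full length and channel indices
stay aligned through the pipeline.  The calibration/prediction split is a
seeded uniform shuffle assigning round(ratio·n) samples (default ratio
2/3) to calibration.

## PLS2

The PLS model centers X and Y and extracts components whose X-weights are
the dominant left singular vector of X_deflatedᵀY — the fixed point of the
classical NIPALS inner iteration, computed directly by SVD.  This is
~60× faster than an iterative NIPALS on wide matrices (the interval
search below fits thousands of PLS models) and agrees with scikit-learn's
`PLSRegression` to within its convergence tolerance; a test asserts that
agreement.  The component count for the stand-alone PLS baseline is chosen
by 5-fold cross-validation, capped at 15.  At full rank the model
reproduces ordinary least squares (tested against the normal equations).

## Extreme learning machine

One ELM with m output neurons predicts all analytes simultaneously.
Input weights and biases are uniform on [−1, 1] and frozen; the output
weights solve min ‖Hβ − C‖ by SVD pseudoinverse with
rcond = eps·max(dim) (the exact-math generalized inverse needs a floating
point cutoff).  Inputs are centered per channel and scaled by a single
global standard deviation times √p (p = number of input channels).  Two
reasons for this instead of a per-channel z-score: per-channel scaling
inflates near-dead channels, which carry only instrument noise, to the
same variance as real bands and so poisons the random projections; and
the √p factor keeps ω·x of order one, inside the sigmoid's responsive
range, for any input dimension.  The scaling mode is a keyword argument
(`"global"`, `"per-channel"`, `"none"`).

Hidden-node selection follows the repeated-restart protocol: candidates
4–40 in steps of 2, each evaluated as the mean 5-fold CV RMSE over
`repeats` random input layers (default 50 stand-alone; 10 inside the
benchmark protocol, which is the problem size used by the acceptance
tests); the candidate with the smallest mean wins, and the restart with
the lowest CV RMSE at that size becomes the final model — random input
layers make a single draw unstable, so the lowest-RMSE structure is kept.

## Metrics

RMSE = √(Σ(ŷ−y)²/n); R² = 1 − SSres/SStot with SStot about the mean of
the measured values; RPD = 1/√(1−R²).  The square-root form of RPD is the
one every published (R², RPD) pair in the motivating tables satisfies to
two decimals (e.g. 0.91→3.33, 0.97→5.77), and equals SD/SEP for a
bias-free predictor; the test suite asserts all 24 pairs.  Selection
shape: NFW (selected channel count), NWI (maximal contiguous runs),
AWIW = NFW/NWI.  Internal math is full precision; rounding half-even
happens only at display time.

## FIC-SS

*Partitioning.* p equal-width contiguous intervals (default 20); when p
does not divide the channel count, leading intervals get one extra
channel.

*Screening.* Thresholds and interval scores are k-fold cross-validation
statistics on the calibration set only — the prediction set never enters
the search.  An interval survives when, for at least one analyte, its
RMSE is at or below the global RMSE **and** its R² at or above the global
R²; comparisons are inclusive so boundary intervals survive.  A shared
(multi-analyte) selection is produced because the calibration model is
multi-output; a per-analyte variant is exposed through the
`analytes=` argument of the segmentation stage.

*The screener.* The default screener is a cross-validated ELM of fixed
size (20 hidden nodes, 2 random restarts averaged, all seeds derived from
one configuration seed — deterministic end to end).  This was a
genuinely open design point, and the deciding observation is structural:
interval screening only functions if the full-spectrum screener pays a
real price for carrying redundant channels.  An ELM does — its random
projections mix in every channel, so its full-spectrum CV score reflects
the dilution — whereas a cross-validated PLS projects irrelevant channels
out so effectively that its full-spectrum score dominates every
75-channel local model and the screen eliminates everything.  A PLS
screener remains available (`PLSScreener`) and is the right choice when
scoring small channel subsets deterministically.

*Combination.* All 2^q − 1 non-empty unions of survivors are scored
exhaustively; the aggregate is the mean of per-analyte RMSEs, each scaled
by the analyte's calibration standard deviation so analytes with very
different concentration ranges weigh equally.  Ties (at 10⁻¹²) break to
fewer channels, then lower interval ids, so the output is deterministic.
If q exceeds `q_cap` (default 12, i.e. at most 4095 candidate unions),
the q_cap best survivors by their own scaled RMSE are kept first.

*Sensitivity segmentation.*  Pure-component spectra are not measured, so
each analyte's unit-content absorbance is estimated by channel-wise
non-negative least squares of absorbance on the concentration matrix.
A non-negative intercept column is included by default: without it any
additive baseline leaks into every analyte's estimate (positive-mean
concentrations can mimic a constant), leaving no channel flagged as
non-absorbing and making the pruning stage inert.  The no-offset
behavior is retained as `include_offset=False` and its bias is
documented by a test.  Sensitivity factors α are the unit spectra
normalized across analytes per channel (Σα = 1 wherever anything
absorbs; flagged zero otherwise).  Within each interval of the winning
combination a channel is kept when at least one target analyte's α
reaches that analyte's interval mean (ties keep).  With all analytes as
targets this provably keeps every absorbing channel (if every α were
below its mean the per-channel sum 1 would be below the means' sum ≤ 1),
so in the shared mode pruning removes exactly the channels with no
estimated analyte absorbance — the "mistakenly selected" ones; with a
target subset it also removes channels dominated by non-target
interferents.

## Baseline selectors

**CARS** — 100 Monte-Carlo runs; each run fits PLS on a random 90% sample
subset, weighs channels by summed |coefficient| across sd-scaled
analytes, retains the count dictated by a two-point exponentially
decreasing function (all channels at run 1, 2 at run 100), applies
adaptive reweighted sampling among the retained, and logs the
cross-validated RMSE of the current subset; the subset with the global
minimum wins.  The 90% sampling ratio was chosen after observing that
80% produced noticeably more diffuse, noise-heavy subsets on these data.

**MC-UVE** — the calibration matrix is augmented with an equal number of
Gaussian noise channels; over 500 (default) random 80% subsamples the
per-channel PLS coefficients are collected, stability = mean/std, and a
real channel is retained when its maximal |stability| across analytes
exceeds the 99th percentile of the noise channels' stabilities.

**SPA** — deterministic successive projections from 20 evenly spaced
start columns: each step adds the channel with the largest component
orthogonal to the span of the chosen ones (ties to the lowest index);
every chain prefix is scored by cross-validated MLR and the global
minimum wins.

Both stochastic selectors are reproducible under a fixed seed; their
across-seed variability can be quantified with `jaccard_stability`.

## Synthetic data

The generator draws correlated truncated-Gaussian concentrations,
mixes Gaussian bands per unit content (Beer–Lambert), and adds, in
order: a saturating concentration response
c_eff = c / (1 + κ·c/mean), an optional channel-wise quadratic
distortion, optional per-sample multiplicative scatter, optional
interferent species with independent random levels, a fixed gentle
quadratic baseline, and iid Gaussian noise.  `scenario.noiseless()`
switches every distortion off, restoring exact linear mixing for
round-trip tests.  Channels where the summed unit-content absorbance
exceeds 1% of its maximum count as informative ground truth.

The reference scenario (105 samples, 1500 channels) mimics the
four-catechin problem: EC and ECG have overlapping dominant bands at
5650/5950 cm⁻¹, EGC and EGCG at 6550/6850 cm⁻¹, and all four contribute
to a nearly coincident band cluster at ~8600 cm⁻¹ — severe overlap:
collectively strong signal that no analyte can be resolved from alone.
Concentration means (0.40, 2.5, 3.0, 8.0) with ~40% relative spread and
positive correlations except one near-zero pair (r = 0.098) echo the
descriptive statistics of catechin content across tea samples.  The
saturation strength (κ = 2.2) and noise (0.003 AU) jointly place
full-spectrum PLS prediction R² at ≈ 0.7–0.85 per analyte — a realistic
mid-quality linear calibration with visible headroom — while leaving the
nonlinear inverse map learnable by an ELM.

What the generator does **not** emulate: instrument physics (detector
nonlinearity, wavelength jitter, dark current), scattering that would
call for MSC/SNV correction (absent by default because the modeled
pipeline smooths but does not scatter-correct), non-Gaussian band shapes,
and reference-method (HPLC) measurement error.  Passing tests therefore
show that the algorithms behave as specified under controlled overlap,
redundancy and nonlinearity — not that any particular real spectrometer
dataset will reach the same numbers.

## Problem sizes used by the validation suite

The acceptance tests run the full pipeline at the study scale — 1500
channels, 105 samples, 2:1 split, 10 seeds — with the benchmark protocol
sizes (ELM node search with 10 restarts per candidate, MC-UVE with 100
Monte-Carlo runs); stand-alone defaults are larger (50 restarts, 500
runs).  Recovery is summarized as the median over seeds of the fraction
of informative channels selected (≥ 80% required) and the fraction of
non-informative channels selected (≤ 10%); the comparative pattern is
the median prediction R² ordering FIC-SS-ELM ≥ full-spectrum ELM ≥
full-spectrum PLS per analyte, with every selector-ELM above
full-spectrum PLS.

## Known limitations

- The exhaustive combination stage is exponential in the survivor count;
  `q_cap` bounds it, at the cost of discarding the weakest survivors.
- The unit-spectrum estimate behind the sensitivity factors is a
  classical-least-squares approximation; under strong response
  nonlinearity it recovers band *shapes* faithfully but per-analyte
  scales only approximately.  The segmentation stage uses only
  within-interval comparisons of α, which are insensitive to per-analyte
  rescaling, so the selection is robust to this.
- With the shared multi-analyte segmentation rule, pruning is
  conservative (only non-absorbing channels are removed); aggressive
  per-analyte pruning requires the `analytes=` argument.
- CARS and MC-UVE outcomes vary across seeds (by design of those
  methods); only their seeded behavior is deterministic.
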