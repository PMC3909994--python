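# Methods

## Scope and data model

The pipeline operates on two containers: a voxel-level dataset (voxels ×
timepoints with one network label per voxel) and a region-level dataset
(named ROIs × timepoints). Time indexing is 0-based throughout and all
segments are half-open `[start, end)`. The pre-infusion segment is
`[0, onset)` and the post-infusion segment `[onset + duration, T)`: the
infusion minute itself is treated as a pharmacological transition and
excluded from both, since neither segment can be assumed stationary across
it. Inputs are assumed preprocessed (no motion correction, registration or
nuisance regression is performed).

## Synchrony estimators

The notion of "intrinsic synchrony" admits two natural operationalizations,
and the package implements both, selected by `mode`:

* **phase** — each voxel series is linearly detrended, band-pass filtered
  (Butterworth order 2, zero-phase `sosfiltfilt`, default band
  0.01–0.1 Hz, the conventional resting-BOLD band), and its instantaneous
  phase taken from the analytic signal. Synchrony is the Kuramoto order
  parameter R(t) of the voxel phases. The first and last `trim_len = 10`
  samples (30 s at TR 3 s) are marked invalid to absorb filter and Hilbert
  edge transients; the constant is configurable.
* **amplitude** — voxels are z-scored over the full scan (sample sd, n−1)
  and synchrony at t is the across-voxel standard deviation of the
  z-scores, i.e. dispersion around the network mean (higher = less
  synchronous). No trimming is needed.

Metastability is the unbiased (n−1) temporal variance of the synchrony
trace within a segment. Neither estimator is claimed to replicate the
original study's unpublished implementation numerically; the amplitude
estimator matches its verbal definition (deviation of voxels from the
network's mean signal), while the phase estimator follows the coordination-
dynamics literature the concept comes from. Group results can be reported
for both; the cohort-level significance claims in the analysis drivers use
the amplitude estimator, which has substantially lower per-subject sampling
variance at 240 timepoints (the phase order parameter of ~16 voxels is
itself a noisy quantity, and the variance of its variance over ~100-sample
segments is too large for a 15-subject percent-change t-test to clear a
Bonferroni bar; the phase-mode effect is still positive in expectation and
is validated as such).

## Entropy of binned synchrony

A synchrony trace is discretized into `n_bins = 10` equal-width bins
(~24 samples/bin at 240 timepoints); bins are right-open except the last.
For pre/post comparison the edges are built once over the pooled pre+post
range ("pooled" strategy), so both distributions share a support and
ΔH = H_post − H_pre is well defined; comparing distributions with different
edges raises an error. "Equal sized bins" is read as equal *width* (a
"centered" strategy, with bins symmetric about the pooled mean — bins as
distance from the mean — is provided as an alternative reading; quantile
binning is not offered because it forces near-uniform occupancy and
destroys the quantity of interest). Entropy is the plug-in estimator in
bits, 0·log 0 = 0; base 2 keeps values interpretable against the log2 64
motif ceiling. An optional Miller–Madow small-sample correction
((K−1)/(2n ln 2)) is available but off by default, matching the plug-in
description of the original analyses. A degenerate (constant) trace yields
a single occupied bin with a warning, not an error.

## Connectivity motifs

Time-resolved connectivity uses sliding-window Pearson correlation,
default `window_len = 20` samples (60 s at TR 3 s, balancing correlation
stability against temporal resolution) advancing by `step = 1`. Windows
containing a constant region are dropped and counted. Matrices are
thresholded at 0.5 on signed correlations by default (`use_absolute`
switches to magnitude); the analysis driver sweeps {0.3, 0.4, 0.5, 0.6} to
show threshold robustness. A binary graph on k labeled nodes is encoded by
assigning bit b to node pair b in lexicographic order — (0,1),(0,2),(0,3),
(1,2),(1,3),(2,3) for k = 4 — giving a bijection with the integers
[0, 2^(k(k−1)/2)); the 64-motif space for 4 nodes includes the empty graph.
Motif-sequence entropy order 0 (plug-in entropy of motif frequencies) is
the headline statistic, by analogy with word-frequency entropy of speech;
order 1 (conditional entropy of transitions) is supplementary. Entropy
comparisons between conditions are made at matched sequence lengths.

## Group inference

Per-network percent changes are tested with the classical one-sample
two-tailed t (df = n−1); the family of 9 networks uses the Bonferroni
threshold 0.05/9 (stored at full precision, displayed as 0.006; similarly
0.05/23 displays as 0.002 in the rating analysis). The drug-vs-placebo
entropy contrast is a paired t-test on per-subject differences, paired
because the design is within-subject. A constant sample exactly at the
null (e.g. identical paired change vectors) is reported as t = 0, p = 1;
a constant sample off the null raises a degenerate-sample error. Percent
change of a variance is a ratio statistic whose null expectation is
slightly positive (E[post/pre] > 1 at finite segment length); the
two-tailed test absorbs most of this (upper-tail inflation is offset by
lower-tail deflation), and the empirical familywise false-positive rate of
the full placebo pipeline sits within binomial 95% bounds of the nominal
0.05 over 500 replicates (see `analysis/05_null_calibration.py`).

## Synthetic data generator

The generator emulates the study conditions so the pipeline can be
validated against known ground truth; its defaults are the design
constants: 9 networks (5 sensory-like, 4 association-like, named after the
canonical resting-state parcellation), 240 timepoints at TR 3 s (12 min),
infusion onset 120 and duration 20 (60 s beginning midway), 15 subjects,
both conditions per subject. The repetition time is not stated by the
design being emulated; 3 s is a typical value and is configurable.

**Voxel model.** Network n has a unit-variance AR(1) latent signal
(coefficient 0.8, giving a low-frequency BOLD-like spectrum; hemodynamic
convolution is deliberately omitted since the latent is already
band-limited). Voxel v emits w_v(t)·s_n(t) + ε with white noise sd 0.5.
Coupling weights are constant per voxel (drawn N(1, 0.1), clipped at 0)
except in association networks post-infusion under the drug-like
condition, where an AR(1) drift (coefficient 0.9, stationary sd
`coupling_sd_post` = 0.5, started at 0 at the onset, clipped total at 0)
is added. The drift variance is split evenly between a **network-shared**
component — the whole network transiently decouples and recouples, which
is what moves the phase order parameter — and a **voxel-specific**
component, which spreads voxels around the network mean and moves the
amplitude dispersion. A purely voxel-independent drift would leave the
cross-voxel coupling distribution nearly constant in time and barely
change phase metastability; the shared component is therefore a modeling
requirement of the planted signature, not a tuning knob.

**ROI model.** The 4 ROIs (bilateral hippocampus + bilateral ACC analogs)
follow a hidden-regime model: a Markov chain over distinct binary coupling
patterns (strong edges at target correlation 0.85; each pattern's matrix
is eigenvalue-clipped to the nearest positive-definite correlation
matrix). Regional innovations are drawn through the active regime's
Cholesky factor and AR(1)-smoothed (coefficient 0.5), plus small
measurement noise (`roi_noise_sd` = 0.05 — kept far below the signal scale
so windowed correlations track the regime pattern; the voxel-level
noise_sd would swamp a 4-channel correlation structure). Baseline dynamics
(2 regimes, switch probability 0.05/step) apply pre-infusion and
throughout placebo; the drug-like condition switches to 8 regimes at
0.2/step post-onset. The true regime sequence is returned for validation.
Note that with finite windows the sample correlation fluctuates around the
regime pattern, so even a single static regime yields a few spurious
motifs at the default 20-sample window; the "single regime → repertoire 1"
property holds in the limit of vanishing noise *and* long windows, and is
tested there.

**Randomness.** A root seed is expanded via `numpy.random.SeedSequence`
spawn keys into named substreams (latent / weights / noise / coupling;
patterns / markov / innovations / noise) and per-subject seeds (< 2^31).
A subject's placebo and drug arms share the subject seed, so they are
bit-identical until the infusion onset and diverge only through the
condition flag — sensory networks are bit-identical across the entire
scan, which is why their paired contrasts are exactly zero. Fixed seeds
give bit-identical output on a given platform; across platforms agreement
is to ordinary float64 arithmetic (~1e-15 relative).

**What the generator does not emulate.** Hemodynamic response shape,
physiological noise and motion, spatial structure within networks,
between-network correlations at the voxel level, and any receptor-level
pharmacology. Passing tests therefore demonstrate that the *pipeline*
recovers planted effects of the assumed form and controls its error rate
under the assumed null — not that real drug data contain such effects.

## Problem sizes

The validation suites run at desk scale, chosen as the package's own
defaults: 15-subject cohorts with 16 voxels/network for effect recovery;
500 root seeds for null calibration (binomial 95% half-width ±0.019 around
0.05); 200 seeds per point for the regime-count monotonicity curve; long
(2000-sample) series with 400-sample windows for the noise-free repertoire
limit.

## Known limitations

* The phase-mode percent-change test is underpowered at n = 15 for
  effect sizes the generator plants; it is validated directionally, not at
  the Bonferroni threshold.
* Plug-in entropy is biased low at small sample counts; pre/post
  differences at matched segment lengths cancel most of the bias, and the
  Miller–Madow flag exists for users who want the correction.
* The NIfTI reader loads the full 4D image into memory; very large images
  should be masked upstream.
* No voxelwise statistical maps, GLM-based connectivity, or spectral (MEG)
  analyses are provided.
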