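# neuroentropy

Entropy-based analysis of brain-network dynamics for within-subject
placebo vs drug infusion designs, with a synthetic BOLD-like data generator
that makes every stage verifiable end to end.

## The problem

Resting-state fMRI studies of psychedelics report that high-level
association networks become less stable after drug infusion: the variance
of each network's *intrinsic synchrony* over time (its **metastability**)
increases, the Shannon entropy of the binned synchrony distribution rises,
and the repertoire of transient 4-region connectivity motifs widens. This
package implements those three analyses as a tested, reusable pipeline for
voxel-level data (networks of labeled voxels) and small ROI sets, plus the
group inference used to report them. Because the original raw data were
never deposited, the package ships a generator that emulates the design —
nine canonical resting-state networks, a 12-min scan with a 60-s infusion
beginning midway, 15 subjects scanned under both conditions — so the
pipeline's operating characteristics can be demonstrated on data whose
ground truth is known.

## The statistics

For a network of voxels with instantaneous phases θ_v(t) (detrended,
band-passed 0.01–0.1 Hz, analytic signal), synchrony is the Kuramoto order
parameter

    R(t) = | (1/N) Σ_v exp(i θ_v(t)) |  ∈ [0, 1],

and metastability is Var_t[R(t)] over a segment (phase mode). In amplitude
mode, synchrony is instead the per-timepoint dispersion of z-scored voxels
around the network mean — the estimator matching the verbal definition
"if voxels deviate little from the network's mean signal, variance is low".
Pre/post comparison uses percent change (post − pre)/pre × 100, tested
against zero per network (one-sample two-tailed t, Bonferroni 0.05/9,
displayed threshold 0.006).

Entropy of synchrony: the trace is discretized into 10 equal-width bins
over the pooled pre+post range and H = −Σ p_i log2 p_i (bits) is compared
pre vs post, then drug vs placebo (paired t, Bonferroni 0.05/9).

Motifs: sliding-window Pearson correlations over 4 ROIs are thresholded
(default 0.5) into binary graphs; with 4 nodes there are 2^6 = 64 possible
motifs, encoded as integers bit-per-pair. Reported per sequence: distinct
motif repertoire, motifs exclusive to one condition, and motif-sequence
entropy (order 0 = plug-in entropy of motif frequencies; order 1 =
conditional entropy of the next motif given the current).

## Worked example

The numbered drivers under `analysis/` reproduce the study-analog findings
on the synthetic 15-subject cohort (root seed 1). For example:

```bash
python analysis/02_network_metastability.py
```

prints (abridged):

```
[amplitude] drug % change vs 0, Bonferroni p < 0.0056 (displayed 0.006):
    visual-medial          mean     -7.5%  t= -1.46  p=1.66e-01
    ...
  * default-mode           mean    111.3%  t=  8.27  p=9.28e-07
  * executive-control      mean    163.6%  t=  5.68  p=5.71e-05
  * frontoparietal-left    mean    128.2%  t=  8.37  p=8.08e-07
  * frontoparietal-right   mean    151.2%  t=  8.18  p=1.06e-06
  significant: default-mode, executive-control, frontoparietal-left, frontoparietal-right
```

i.e. exactly the planted dissociation: metastability rises significantly in
the four association networks where the generator makes voxel–network
coupling temporally variable post-infusion, and in none of the five
sensory/motor networks. `analysis/03_synchrony_entropy.py` shows the
matching entropy result (ΔH ≈ +0.5 bits more under drug than placebo in
those networks), `analysis/04_motif_repertoire.py` the motif repertoire
widening (≈13.4 vs ≈9.5 distinct motifs post-infusion, threshold-robust),
`analysis/05_null_calibration.py` the familywise false-positive rate of the
whole pipeline under placebo (0.056 over 500 replicates, nominal 0.05), and
`analysis/06_rating_correlations.py` the 23-item Bonferroni-corrected
rating-correlation design (displayed threshold 0.002).

The same pipeline is scriptable from a config file:

```bash
neuroentropy run configs/demo.yml -o results/demo
```

which writes tidy TSVs (`metastability.tsv`, `entropy.tsv`, `motifs.tsv`,
test tables) and a `manifest.json` recording the config snapshot, seed and
package version; re-running a manifest reproduces every number. Real data
enter through `neuroentropy.io` as delimited matrix + label-sidecar bundles
or as 4D NIfTI-1 images with an integer network-label volume.

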