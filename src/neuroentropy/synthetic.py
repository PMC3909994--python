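"""Synthetic BOLD-like datasets for the placebo/drug infusion design.

The generator produces data with exactly the statistical structure the
analyses assume, so every stage of the pipeline can be validated end to end
without access to raw fMRI.

Voxel-level model
-----------------
Each network n carries a latent band-limited signal s_n(t): unit-variance
first-order autoregressive noise (AR(1), coefficient 0.8), giving the slow,
low-frequency character of resting BOLD. Voxel v in network n emits

    x_v(t) = w_v(t) * s_n(t) + noise_sd * eps_v(t),   eps white Gaussian.

Pre-infusion, and at all times in the placebo-like condition, the coupling
weight w_v(t) is a constant drawn once per voxel near 1. In the drug-like
condition, association networks' weights become a slowly drifting AR(1)
process post-infusion (stationary sd = ``coupling_sd_post``, clipped at 0),
split evenly between a network-shared component g_n(t) — the whole network
transiently decouples and recouples, which drives variance of the phase
order parameter — and a voxel-specific component u_v(t), which spreads
voxels around the network mean and drives variance of the amplitude
dispersion. Sensory-like networks keep constant weights in both conditions.

ROI-level model
---------------
The n_rois regional signals follow a hidden-regime model: a Markov chain
selects among ``n_regimes`` distinct binary coupling patterns (each pattern
a set of strong pairwise couplings, realised as a PSD-repaired correlation
matrix with strong edges at rho 0.85); regional innovations are drawn from
the active regime's Cholesky factor and smoothed by an AR(1) (coefficient
0.5). The drug-like condition switches to a larger regime set and a faster
switch rate post-infusion, which widens the downstream motif repertoire and
raises motif-sequence entropy. The true regime sequence is returned for
validation.

Randomness
----------
A single root seed is expanded via ``numpy.random.SeedSequence`` spawn keys
into named substreams (latent / weights / noise / coupling for voxels;
patterns / markov / innovations / noise for ROIs) and, in cohort generation,
into per-subject seeds. Matched placebo/drug datasets of one subject share
the subject seed, so they are sample-identical up to the infusion and
diverge only through the condition flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from scipy import signal as sps

from .config import GeneratorConfig
from .exceptions import ConfigurationError
from .io import RegionTimeSeries, VoxelTimeSeriesSet

__all__ = [
    "generate_voxel_dataset",
    "generate_roi_dataset",
    "generate_condition_pair",
    "RoiDataset",
    "SubjectPair",
    "ConditionArm",
]

LATENT_AR = 0.8  # AR(1) coefficient of network latent signals
WEIGHT_AR = 0.9  # AR(1) coefficient of the drifting coupling weight
ROI_AR = 0.5  # AR(1) coefficient of regional innovations
WEIGHT_BASE_SD = 0.1  # spread of the constant per-voxel baseline weight
WEIGHT_SHARED_FRAC = 0.5  # share of coupling variance common to the network
REGIME_RHO = 0.85  # target correlation of a "strong" coupling edge
_BURN_IN = 50


def _rng(config: GeneratorConfig, *key: int) -> np.random.Generator:
    """Deterministic substream: root seed + named spawn key."""
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=key))


def _ar1(rng: np.random.Generator, shape: Tuple[int, int], coeff: float) -> np.ndarray:
    """Stationary unit-variance AR(1) rows (burn-in discarded)."""
    n, t = shape
    white = rng.standard_normal((n, t + _BURN_IN)) * np.sqrt(1 - coeff**2)
    out = sps.lfilter([1.0], [1.0, -coeff], white, axis=1)
    return out[:, _BURN_IN:]


# ---------------------------------------------------------------------------
# voxel-level generator
# ---------------------------------------------------------------------------

def _coupling_weights(config: GeneratorConfig) -> np.ndarray:
    """(n_voxels, n_timepoints) coupling weights w_v(t).

    Constant per voxel everywhere except association networks post-onset in
    the drug-like condition, where an AR(1) drift (started at 0 at the
    infusion onset, stationary sd ``coupling_sd_post``, split between a
    network-shared and a voxel-specific component) is added and the total
    clipped at 0.
    """
    labels = config.network_labels()
    v, t = config.n_networks * config.voxels_per_network, config.n_timepoints
    base = 1.0 + WEIGHT_BASE_SD * _rng(config, 1).standard_normal(v)
    base = np.clip(base, 0.0, None)
    weights = np.repeat(base[:, None], t, axis=1)
    if config.condition == "drug_like" and config.coupling_sd_post > 0:
        sensory = set(config.sensory_labels())
        onset = config.infusion_onset
        drift_rng = _rng(config, 3)
        n_post = t - onset
        sd_shared = config.coupling_sd_post * np.sqrt(WEIGHT_SHARED_FRAC)
        sd_voxel = config.coupling_sd_post * np.sqrt(1 - WEIGHT_SHARED_FRAC)
        scale = np.sqrt(1 - WEIGHT_AR**2)
        for i, label in enumerate(labels):
            lo = i * config.voxels_per_network
            hi = lo + config.voxels_per_network
            # one stream per network keeps sensory/association draws aligned
            innov = drift_rng.standard_normal((config.voxels_per_network + 1, n_post))
            if label in sensory:
                continue
            u = np.zeros((config.voxels_per_network + 1, n_post))
            for s in range(1, n_post):
                u[:, s] = WEIGHT_AR * u[:, s - 1] + scale * innov[:, s]
            drift = sd_shared * u[0][None, :] + sd_voxel * u[1:]
            weights[lo:hi, onset:] = np.clip(base[lo:hi, None] + drift, 0.0, None)
    return weights


def generate_voxel_dataset(config: GeneratorConfig) -> VoxelTimeSeriesSet:
    """Generate a labeled voxel x timepoint dataset under ``config``."""
    config.validate()
    labels = config.network_labels()
    s = _ar1(_rng(config, 0), (config.n_networks, config.n_timepoints), LATENT_AR)
    latent_per_voxel = np.repeat(s, config.voxels_per_network, axis=0)
    weights = _coupling_weights(config)
    noise = config.noise_sd * _rng(config, 2).standard_normal(latent_per_voxel.shape)
    data = weights * latent_per_voxel + noise
    return VoxelTimeSeriesSet(
        data=data,
        network_labels=np.repeat(np.array(labels), config.voxels_per_network),
        sampling_interval=config.sampling_interval,
        infusion_onset=config.infusion_onset,
        infusion_duration=config.infusion_duration,
        condition=config.condition,
    )


# ---------------------------------------------------------------------------
# ROI-level generator
# ---------------------------------------------------------------------------

@dataclass
class RoiDataset:
    """ROI signals plus the hidden regime sequence that generated them."""

    series: RegionTimeSeries
    regimes: np.ndarray  # (n_timepoints,) regime index at each sample
    regime_patterns: np.ndarray  # (n_total_regimes, k, k) binary edge patterns


def _psd_correlation(pattern: np.ndarray, rho: float = REGIME_RHO) -> np.ndarray:
    """Correlation matrix with ``rho`` on pattern edges, repaired to PSD."""
    c = np.eye(pattern.shape[0]) + rho * pattern
    vals, vecs = np.linalg.eigh(c)
    vals = np.clip(vals, 0.01, None)
    c = vecs @ np.diag(vals) @ vecs.T
    d = np.sqrt(np.diag(c))
    return c / np.outer(d, d)


def _regime_patterns(config: GeneratorConfig) -> np.ndarray:
    """Distinct binary edge patterns shared by both conditions.

    The first ``n_regimes_baseline`` patterns form the baseline set; the
    drug-like post-infusion set is the first ``n_regimes``.
    """
    from .motifs import count_possible_motifs, decode_motif

    k = config.n_rois
    total = max(config.n_regimes, config.n_regimes_baseline)
    n_codes = count_possible_motifs(k)
    if total > n_codes:
        raise ConfigurationError(
            f"n_regimes {total} exceeds the {n_codes} distinct patterns for k={k}"
        )
    rng = _rng(config, 10)
    codes = rng.choice(n_codes, size=total, replace=False)
    return np.array([decode_motif(int(c), k) for c in codes])


def _markov_regimes(config: GeneratorConfig, n_total: int) -> np.ndarray:
    """Hidden regime index per timepoint.

    Baseline dynamics (first ``n_regimes_baseline`` regimes, baseline switch
    rate) apply pre-infusion and throughout the placebo-like condition; the
    drug-like condition switches to the full drug set and rate at the
    infusion onset.
    """
    rng = _rng(config, 11)
    t = config.n_timepoints
    regimes = np.zeros(t, dtype=int)
    n_base = min(config.n_regimes_baseline, n_total)
    state = int(rng.integers(n_base))
    for s in range(t):
        if config.condition == "drug_like" and s >= config.infusion_onset:
            allowed, rate = config.n_regimes, config.switch_rate
        else:
            allowed, rate = n_base, config.switch_rate_baseline
        if state >= allowed:
            state = int(rng.integers(allowed))
        elif s > 0 and allowed > 1 and rng.random() < rate:
            others = [r for r in range(allowed) if r != state]
            state = int(others[rng.integers(len(others))])
        regimes[s] = state
    return regimes


def generate_roi_dataset(config: GeneratorConfig) -> RoiDataset:
    """Generate regime-switching ROI signals plus their true regime sequence."""
    config.validate()
    if config.n_rois < 2:
        raise ConfigurationError(f"n_rois must be >= 2 for the motif analysis")
    patterns = _regime_patterns(config)
    chols = np.array([np.linalg.cholesky(_psd_correlation(p)) for p in patterns])
    regimes = _markov_regimes(config, len(patterns))
    k, t = config.n_rois, config.n_timepoints
    eta = _rng(config, 12).standard_normal((t + _BURN_IN, k))
    noise = config.roi_noise_sd * _rng(config, 13).standard_normal((k, t))
    scale = np.sqrt(1 - ROI_AR**2)
    y = np.zeros((k, t))
    prev = chols[regimes[0]] @ eta[0]
    for s in range(_BURN_IN):  # burn-in under the initial regime
        prev = ROI_AR * prev + scale * (chols[regimes[0]] @ eta[s])
    for s in range(t):
        prev = ROI_AR * prev + scale * (chols[regimes[s]] @ eta[s + _BURN_IN])
        y[:, s] = prev
    series = RegionTimeSeries(
        region_names=config.roi_names(),
        data=y + noise,
        sampling_interval=config.sampling_interval,
        infusion_onset=config.infusion_onset,
        infusion_duration=config.infusion_duration,
        condition=config.condition,
    )
    return RoiDataset(series, regimes, patterns)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

@dataclass
class ConditionArm:
    condition: str
    voxel: VoxelTimeSeriesSet
    roi: RoiDataset


@dataclass
class SubjectPair:
    subject_id: str
    seed: int
    placebo: ConditionArm
    drug: ConditionArm


def subject_seed(root_seed: int, subject_index: int) -> int:
    """Deterministic per-subject seed derived from the root seed (< 2^31)."""
    ss = np.random.SeedSequence(root_seed, spawn_key=(100, subject_index))
    return int(ss.generate_state(1)[0] % 2**31)


def generate_condition_pair(config: GeneratorConfig, n_subjects: int = 15,
                            include_roi: bool = True) -> List[SubjectPair]:
    """Matched placebo/drug datasets for ``n_subjects`` subjects.

    Each subject's two arms share a subject-level seed and differ only in
    the condition flag, mirroring a within-subject crossover design.
    """
    if n_subjects < 2:
        raise ConfigurationError(f"n_subjects must be >= 2, got {n_subjects}")
    pairs = []
    for i in range(n_subjects):
        sid = f"{i + 1:02d}"
        seed_i = subject_seed(config.seed, i)
        arms = {}
        for condition in ("placebo_like", "drug_like"):
            c = config.with_(condition=condition, seed=seed_i)
            voxel = generate_voxel_dataset(c)
            voxel.subject_id = sid
            roi = None
            if include_roi:
                roi = generate_roi_dataset(c)
                roi.series.subject_id = sid
            arms[condition] = ConditionArm(condition, voxel, roi)
        pairs.append(SubjectPair(sid, seed_i, arms["placebo_like"], arms["drug_like"]))
    return pairs
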