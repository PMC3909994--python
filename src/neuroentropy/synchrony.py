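"""Intra-network synchrony, metastability, and related signal statistics.

"Intrinsic synchrony" of a network is estimated in one of two modes:

* **phase** (default): each voxel series is detrended, band-pass filtered in
  the low-frequency BOLD band (0.01-0.1 Hz), and its instantaneous phase
  extracted via the analytic signal. Synchrony at time t is the Kuramoto
  order parameter R(t) = |mean_v exp(i theta_v(t))| in [0, 1]; 1 means all
  voxel phases aligned, 0 means uniform dispersion.
* **amplitude**: voxels are z-scored over the full scan and synchrony is the
  per-timepoint dispersion (standard deviation across voxels) of the z-scores
  around the network mean — higher dispersion = less synchronous.

**Metastability** of a network is the temporal variance of its synchrony
trace over a segment (unbiased, n-1 denominator). Pre/post comparisons use
percent change (post - pre) / pre x 100.

Phase-mode traces are trimmed at both ends (filter + Hilbert edge
transients); ``DEFAULT_TRIM`` timepoints at each end are marked invalid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import signal as sps

from .exceptions import AnalysisError, ConfigurationError, ValidationError
from .io import RegionTimeSeries, VoxelTimeSeriesSet, extract_network_mean

__all__ = [
    "SynchronyTrace",
    "MetastabilityResult",
    "kuramoto_order",
    "phase_trace",
    "amplitude_trace",
    "metastability",
    "percent_change",
    "metastability_change",
    "regional_variance_change",
    "network_anticorrelation",
]

#: Timepoints discarded at each trace end in phase mode (filter/Hilbert edge
#: transients at the default band and filter order).
DEFAULT_TRIM = 10

DEFAULT_BAND = (0.01, 0.1)
FILTER_ORDER = 2


@dataclass
class SynchronyTrace:
    """One synchrony value per timepoint for one network."""

    network_label: str
    values: np.ndarray
    mode: str  # "phase" | "amplitude"
    valid_range: Tuple[int, int]  # half-open [start, end)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        lo, hi = self.valid_range
        if not 0 <= lo < hi <= len(self.values):
            raise ValidationError(f"valid_range {self.valid_range} outside trace")
        seg = self.values[lo:hi]
        if not np.all(np.isfinite(seg)):
            raise ValidationError("non-finite synchrony inside valid_range")
        if self.mode == "phase" and (seg.min() < -1e-9 or seg.max() > 1 + 1e-9):
            raise ValidationError("phase-mode synchrony must lie in [0, 1]")
        if self.mode == "amplitude" and seg.min() < -1e-9:
            raise ValidationError("amplitude-mode synchrony must be >= 0")

    def segment_values(self, segment: Optional[Tuple[int, int]] = None) -> np.ndarray:
        """Values over ``segment`` clipped to the valid range."""
        lo, hi = self.valid_range
        if segment is not None:
            s, e = segment
            lo, hi = max(lo, s), min(hi, e)
        if hi - lo < 1:
            raise ValidationError(f"segment {segment} has no valid timepoints")
        return self.values[lo:hi]


@dataclass
class MetastabilityResult:
    network_label: str
    pre_value: float
    post_value: float
    percent_change: float


def kuramoto_order(phases: np.ndarray) -> np.ndarray:
    """Modulus of the mean unit phasor over axis 0.

    ``phases`` is (n_oscillators,) or (n_oscillators, n_timepoints), radians.
    """
    phases = np.asarray(phases, dtype=float)
    return np.abs(np.exp(1j * phases).mean(axis=0))


def _bandpass_sos(band_low_hz: float, band_high_hz: float, fs: float):
    nyq = fs / 2.0
    if not 0 < band_low_hz < band_high_hz < nyq:
        raise ConfigurationError(
            f"band ({band_low_hz}, {band_high_hz}) Hz must satisfy "
            f"0 < low < high < Nyquist ({nyq:.4g} Hz)"
        )
    return sps.butter(FILTER_ORDER, [band_low_hz, band_high_hz], btype="band",
                      fs=fs, output="sos")


def phase_trace(dataset: VoxelTimeSeriesSet, network_label,
                band_low_hz: float = DEFAULT_BAND[0],
                band_high_hz: float = DEFAULT_BAND[1],
                trim_len: int = DEFAULT_TRIM) -> SynchronyTrace:
    """Kuramoto order parameter of a network's voxel phases at each timepoint."""
    block = dataset.network_data(network_label)
    if block.shape[0] < 2:
        raise AnalysisError(
            f"phase synchrony undefined for single-voxel network {network_label!r}"
        )
    fs = 1.0 / dataset.sampling_interval
    sos = _bandpass_sos(band_low_hz, band_high_hz, fs)
    detrended = sps.detrend(block, axis=1)
    filtered = sps.sosfiltfilt(sos, detrended, axis=1)
    phases = np.angle(sps.hilbert(filtered, axis=1))
    values = kuramoto_order(phases)
    n_t = dataset.n_timepoints
    if 2 * trim_len >= n_t:
        raise ConfigurationError(f"trim_len {trim_len} leaves no valid timepoints")
    return SynchronyTrace(str(network_label), values, "phase", (trim_len, n_t - trim_len))


def amplitude_trace(dataset: VoxelTimeSeriesSet, network_label) -> SynchronyTrace:
    """Per-timepoint dispersion of z-scored voxels around the network mean."""
    block = dataset.network_data(network_label)
    if block.shape[0] < 2:
        raise AnalysisError(
            f"dispersion undefined for single-voxel network {network_label!r}"
        )
    sd = block.std(axis=1, ddof=1)
    degenerate = sd <= 1e-12 * (np.abs(block).max(axis=1) + 1.0)
    if np.any(degenerate):
        voxel = int(np.argwhere(degenerate)[0, 0])
        raise AnalysisError(
            f"zero-variance voxel (row {voxel} within network {network_label!r}) "
            "cannot be z-scored"
        )
    z = (block - block.mean(axis=1, keepdims=True)) / sd[:, None]
    dispersion = z.std(axis=0, ddof=1)
    return SynchronyTrace(str(network_label), dispersion, "amplitude",
                          (0, dataset.n_timepoints))


def metastability(trace: SynchronyTrace, segment: Optional[Tuple[int, int]] = None) -> float:
    """Unbiased temporal variance of the synchrony trace over ``segment``."""
    vals = trace.segment_values(segment)
    if len(vals) < 2:
        raise ValidationError(f"segment {segment} too short for a variance (need >= 2)")
    return float(np.var(vals, ddof=1))


def percent_change(pre_value: float, post_value: float) -> float:
    """(post - pre) / pre x 100; requires a strictly positive baseline."""
    if pre_value <= 0:
        raise AnalysisError(f"percent change undefined for baseline {pre_value} <= 0")
    return (post_value - pre_value) / pre_value * 100.0


def metastability_change(trace: SynchronyTrace, pre_segment, post_segment) -> MetastabilityResult:
    pre = metastability(trace, pre_segment)
    post = metastability(trace, post_segment)
    return MetastabilityResult(trace.network_label, pre, post, percent_change(pre, post))


def regional_variance_change(series: RegionTimeSeries, region: str,
                             pre_segment, post_segment) -> MetastabilityResult:
    """Sample variance of one region's raw signal in each segment + % change."""
    x = series.region(region)
    out = []
    for seg in (pre_segment, post_segment):
        s, e = seg
        if not (0 <= s < e <= len(x)) or e - s < 2:
            raise ValidationError(f"segment {seg} invalid for series of length {len(x)}")
        out.append(float(np.var(x[s:e], ddof=1)))
    pre, post = out
    return MetastabilityResult(region, pre, post, percent_change(pre, post))


def network_anticorrelation(trace_a: np.ndarray, trace_b: np.ndarray,
                            segment: Optional[Tuple[int, int]] = None) -> float:
    """Pearson correlation between two network mean series over ``segment``.

    Built for the default-mode vs task-positive anticorrelation contrast: a
    reduction of a negative r toward 0 post-infusion indicates weakened
    anticorrelation.
    """
    a = np.asarray(trace_a, dtype=float)
    b = np.asarray(trace_b, dtype=float)
    if segment is not None:
        s, e = segment
        a, b = a[s:e], b[s:e]
    if len(a) != len(b):
        raise ValidationError(f"length mismatch: {len(a)} vs {len(b)}")
    if len(a) < 3:
        raise ValidationError("need at least 3 timepoints for a correlation")
    if np.std(a) == 0 or np.std(b) == 0:
        raise AnalysisError("correlation undefined for a constant series")
    return float(np.corrcoef(a, b)[0, 1])


def dmn_tpn_anticorrelation(dataset: VoxelTimeSeriesSet, dmn_label, tpn_label,
                            segment=None) -> float:
    """Convenience wrapper: anticorrelation between two networks' mean signals."""
    return network_anticorrelation(
        extract_network_mean(dataset, dmn_label),
        extract_network_mean(dataset, tpn_label),
        segment,
    )
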