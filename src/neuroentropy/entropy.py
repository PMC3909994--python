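"""Binned probability distributions of synchrony and their Shannon entropy.

A synchrony trace is discretized into equal-width bins over a segment; the
bin occupancy frequencies form a :class:`BinnedDistribution` whose Shannon
entropy H = -sum p_i log2 p_i (bits) indexes how unpredictable the network's
synchrony is across time. Pre/post entropy change is only meaningful when
both distributions share bin edges, which :func:`pre_post_distributions`
enforces by building edges over the pooled pre+post range ("pooled"
strategy, the default).

Edge strategies
---------------
``segment``  equal-width bins over the segment's own [min, max]
``pooled``   (via :func:`pre_post_distributions`) shared equal-width bins
             over the union range of pre and post segments
``fixed``    user-supplied range or explicit edges
``centered`` equal-width bins on deviation from the (pooled or segment)
             mean, symmetric about it — bins then reflect the distance of a
             sample from the mean
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .exceptions import ValidationError

__all__ = [
    "BinnedDistribution",
    "discretize",
    "pre_post_distributions",
    "shannon_entropy",
    "entropy_change",
]

_PROB_TOL = 1e-9


@dataclass(frozen=True)
class BinnedDistribution:
    """Bin edges (n_bins + 1) and occupancy probabilities (n_bins)."""

    bin_edges: np.ndarray
    probabilities: np.ndarray
    n_samples: int

    def __post_init__(self):
        object.__setattr__(self, "bin_edges", np.asarray(self.bin_edges, dtype=float))
        object.__setattr__(self, "probabilities", np.asarray(self.probabilities, dtype=float))
        if len(self.bin_edges) != len(self.probabilities) + 1:
            raise ValidationError(
                f"{len(self.bin_edges)} edges for {len(self.probabilities)} bins"
            )
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValidationError("bin edges must be strictly increasing")
        if np.any(self.probabilities < -_PROB_TOL):
            raise ValidationError("probabilities must be non-negative")
        if abs(self.probabilities.sum() - 1.0) > 1e-6:
            raise ValidationError(
                f"probabilities sum to {self.probabilities.sum():.8f}, not 1"
            )

    @property
    def n_bins(self) -> int:
        return len(self.probabilities)


def _extract_values(trace, segment):
    """Accept a SynchronyTrace or a plain array."""
    if hasattr(trace, "segment_values"):
        return np.asarray(trace.segment_values(segment), dtype=float)
    values = np.asarray(trace, dtype=float)
    if segment is not None:
        s, e = segment
        values = values[s:e]
    return values


def _equal_width_edges(lo: float, hi: float, n_bins: int) -> np.ndarray:
    if hi <= lo:
        # degenerate (constant) input: a token unit-width support
        warnings.warn("degenerate value range; all mass in a single bin", stacklevel=3)
        lo, hi = lo - 0.5, lo + 0.5
    return np.linspace(lo, hi, n_bins + 1)


def discretize(trace, segment=None, n_bins: int = 10, edges_strategy: str = "segment",
               edges: Optional[np.ndarray] = None,
               value_range: Optional[Tuple[float, float]] = None) -> BinnedDistribution:
    """Discretize a synchrony trace (or array) into an equal-width histogram.

    Every sample lands in exactly one bin: bins are right-open except the
    last, and under the ``fixed`` strategy out-of-range samples are clipped
    into the end bins.
    """
    values = _extract_values(trace, segment)
    if n_bins < 2:
        raise ValidationError(f"n_bins must be >= 2, got {n_bins}")
    if len(values) < n_bins:
        raise ValidationError(
            f"segment has {len(values)} samples, fewer than n_bins={n_bins}"
        )
    if edges is not None:
        edges = np.asarray(edges, dtype=float)
        if len(edges) != n_bins + 1:
            raise ValidationError(f"expected {n_bins + 1} edges, got {len(edges)}")
    elif edges_strategy == "segment":
        edges = _equal_width_edges(values.min(), values.max(), n_bins)
    elif edges_strategy == "fixed":
        if value_range is None:
            raise ValidationError("'fixed' strategy requires value_range or edges")
        edges = _equal_width_edges(float(value_range[0]), float(value_range[1]), n_bins)
    elif edges_strategy == "centered":
        m = values.mean()
        half = np.max(np.abs(values - m)) if len(values) else 0.0
        edges = _equal_width_edges(m - half, m + half, n_bins)
    else:
        raise ValidationError(f"unknown edges_strategy {edges_strategy!r}")
    clipped = np.clip(values, edges[0], edges[-1])
    counts, _ = np.histogram(clipped, bins=edges)
    return BinnedDistribution(edges, counts / len(values), int(len(values)))


def pre_post_distributions(trace, pre_segment, post_segment, n_bins: int = 10,
                           edges_strategy: str = "pooled"):
    """Build pre and post distributions on shared edges.

    ``pooled`` (default) spans the union of both segments' value ranges;
    ``centered`` centers shared bins on the pooled mean. Returns
    ``(pre_dist, post_dist)``.
    """
    pre_vals = _extract_values(trace, pre_segment)
    post_vals = _extract_values(trace, post_segment)
    pooled = np.concatenate([pre_vals, post_vals])
    if edges_strategy == "pooled":
        edges = _equal_width_edges(pooled.min(), pooled.max(), n_bins)
    elif edges_strategy == "centered":
        m = pooled.mean()
        half = np.max(np.abs(pooled - m))
        edges = _equal_width_edges(m - half, m + half, n_bins)
    else:
        raise ValidationError(
            f"shared-edge strategy must be 'pooled' or 'centered', got {edges_strategy!r}"
        )
    return (
        discretize(pre_vals, None, n_bins, edges=edges),
        discretize(post_vals, None, n_bins, edges=edges),
    )


def shannon_entropy(dist: BinnedDistribution, miller_madow: bool = False) -> float:
    """Plug-in Shannon entropy in bits, with 0 log 0 = 0.

    ``miller_madow`` adds the first-order small-sample bias correction
    (K_occupied - 1) / (2 n ln 2); off by default.
    """
    p = np.asarray(dist.probabilities, dtype=float)
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValidationError("probabilities do not sum to 1")
    nz = p[p > 0]
    h = float(-(nz * np.log2(nz)).sum())
    if miller_madow:
        h += (len(nz) - 1) / (2.0 * dist.n_samples * np.log(2.0))
    return h


def entropy_change(pre: BinnedDistribution, post: BinnedDistribution, **kwargs) -> float:
    """H(post) - H(pre) in bits; both must share bin edges."""
    if pre.n_bins != post.n_bins or not np.allclose(pre.bin_edges, post.bin_edges):
        raise ValidationError("distributions built on different bin edges are not comparable")
    return shannon_entropy(post, **kwargs) - shannon_entropy(pre, **kwargs)
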