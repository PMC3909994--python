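"""Time-resolved connectivity motifs over a small ROI set.

Pairwise Pearson correlations are computed in sliding windows, thresholded
into binary graphs ("motifs"), and each motif is encoded as an integer by
assigning one bit per node pair in lexicographic order — for 4 nodes the
pairs (0,1),(0,2),(0,3),(1,2),(1,3),(2,3) give codes 0..63, so a 4-node
system has 2^6 = 64 possible motifs (the empty graph included).

Two summaries are reported per motif sequence:

* **repertoire** — number of distinct motifs observed (optionally with the
  set of motifs exclusive to the sequence relative to a baseline);
* **motif-sequence entropy** — order 0: plug-in Shannon entropy of the motif
  frequency distribution (how uneven the "vocabulary" usage is, analogous to
  word frequencies in speech); order 1: conditional entropy of the next
  motif given the current one (how predictable transitions are).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, ValidationError
from .io import RegionTimeSeries

__all__ = [
    "WindowSpec",
    "MotifSequence",
    "WindowedConnectivity",
    "windowed_connectivity",
    "binarize",
    "encode_motif",
    "decode_motif",
    "count_possible_motifs",
    "motif_sequence",
    "motif_repertoire",
    "motif_entropy",
]

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.5


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window parameters for time-resolved connectivity."""

    window_len: int = 20
    step: int = 1
    correlation: str = "pearson"

    def __post_init__(self):
        if self.window_len < 3:
            raise ConfigurationError(f"window_len must be >= 3, got {self.window_len}")
        if self.step < 1:
            raise ConfigurationError(f"step must be >= 1, got {self.step}")
        if self.correlation != "pearson":
            raise ConfigurationError(f"unsupported correlation {self.correlation!r}")


@dataclass
class WindowedConnectivity:
    """Per-window correlation matrices with their start indices."""

    matrices: np.ndarray  # (n_windows, k, k)
    window_starts: np.ndarray
    n_dropped: int = 0


@dataclass
class MotifSequence:
    """Ordered motif codes, one per retained window."""

    codes: np.ndarray
    window_spec: WindowSpec
    threshold: float
    node_names: Tuple[str, ...]
    window_starts: np.ndarray = field(default=None)

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=int)
        self.node_names = tuple(self.node_names)
        if len(self.codes) == 0:
            raise ValidationError("motif sequence is empty")
        limit = count_possible_motifs(self.k)
        if self.codes.min() < 0 or self.codes.max() >= limit:
            raise ValidationError(f"motif codes outside [0, {limit}) for k={self.k}")

    @property
    def k(self) -> int:
        return len(self.node_names)

    def __len__(self) -> int:
        return len(self.codes)


def count_possible_motifs(k: int) -> int:
    """2^(k(k-1)/2): number of labeled undirected graphs on k nodes."""
    if k < 2:
        raise ValidationError(f"need at least 2 nodes, got {k}")
    return 2 ** (k * (k - 1) // 2)


def _pairs(k: int):
    return list(itertools.combinations(range(k), 2))


def windowed_connectivity(series: RegionTimeSeries, spec: WindowSpec = WindowSpec(),
                          segment: Optional[Tuple[int, int]] = None) -> WindowedConnectivity:
    """Pearson correlation matrices in sliding windows over ``segment``.

    Windows containing a constant region (correlation undefined) are dropped
    and counted in ``n_dropped``.
    """
    s, e = segment if segment is not None else (0, series.n_timepoints)
    if not (0 <= s < e <= series.n_timepoints):
        raise ValidationError(f"segment ({s}, {e}) outside series")
    seg_len = e - s
    if seg_len < spec.window_len:
        raise ValidationError(
            f"segment length {seg_len} shorter than window_len {spec.window_len}"
        )
    mats, starts, dropped = [], [], 0
    for t in range(s, e - spec.window_len + 1, spec.step):
        win = series.data[:, t:t + spec.window_len]
        if np.any(win.std(axis=1) == 0):
            dropped += 1
            continue
        mats.append(np.corrcoef(win))
        starts.append(t)
    if dropped:
        logger.warning("dropped %d window(s) containing a constant region", dropped)
    if not mats:
        raise ValidationError("no valid windows (all contained a constant region)")
    return WindowedConnectivity(np.array(mats), np.array(starts), dropped)


def binarize(corr_matrix: np.ndarray, threshold: float = DEFAULT_THRESHOLD,
             use_absolute: bool = False) -> np.ndarray:
    """Threshold a correlation matrix into a binary adjacency (zero diagonal).

    An edge (i, j) exists iff c_ij > threshold (or |c_ij| > threshold when
    ``use_absolute``).
    """
    c = np.asarray(corr_matrix, dtype=float)
    if not -1 < threshold < 1:
        raise ValidationError(f"threshold must lie in (-1, 1), got {threshold}")
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValidationError(f"expected a square matrix, got shape {c.shape}")
    if not np.allclose(c, c.T, atol=1e-8):
        raise ValidationError("correlation matrix is not symmetric")
    strength = np.abs(c) if use_absolute else c
    adj = (strength > threshold).astype(int)
    np.fill_diagonal(adj, 0)
    return adj


def encode_motif(adjacency: np.ndarray) -> int:
    """Encode a binary adjacency as an integer, one bit per node pair.

    Bits follow lexicographic pair order; for k = 4 the pairs
    (0,1),(0,2),(0,3),(1,2),(1,3),(2,3) map to bits 0..5, so the empty graph
    is code 0 and the complete graph code 63.
    """
    a = np.asarray(adjacency)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValidationError(f"expected a square adjacency, got shape {a.shape}")
    if np.any(np.diag(a) != 0):
        raise ValidationError("adjacency diagonal must be zero")
    if not np.array_equal(a, a.T):
        raise ValidationError("adjacency must be symmetric")
    if not np.isin(a, (0, 1)).all():
        raise ValidationError("adjacency entries must be 0 or 1")
    code = 0
    for bit, (i, j) in enumerate(_pairs(a.shape[0])):
        if a[i, j]:
            code |= 1 << bit
    return code


def decode_motif(code: int, k: int) -> np.ndarray:
    """Inverse of :func:`encode_motif`."""
    if not 0 <= code < count_possible_motifs(k):
        raise ValidationError(f"code {code} outside [0, {count_possible_motifs(k)})")
    adj = np.zeros((k, k), dtype=int)
    for bit, (i, j) in enumerate(_pairs(k)):
        if code >> bit & 1:
            adj[i, j] = adj[j, i] = 1
    return adj


def motif_sequence(series: RegionTimeSeries, spec: WindowSpec = WindowSpec(),
                   threshold: float = DEFAULT_THRESHOLD, use_absolute: bool = False,
                   segment: Optional[Tuple[int, int]] = None) -> MotifSequence:
    """Full path: windowed correlation -> threshold -> encoded motif codes."""
    wc = windowed_connectivity(series, spec, segment)
    codes = [encode_motif(binarize(m, threshold, use_absolute)) for m in wc.matrices]
    return MotifSequence(np.array(codes), spec, threshold,
                         tuple(series.region_names), wc.window_starts)


@dataclass
class RepertoireResult:
    n_distinct: int
    frequencies: pd.Series  # motif code -> occurrence count
    exclusive: frozenset  # motifs in seq but not in baseline (empty if no baseline)


def _check_comparable(a: MotifSequence, b: MotifSequence) -> None:
    if a.k != b.k:
        raise ValidationError(f"node-count mismatch: {a.k} vs {b.k}")
    if a.window_spec != b.window_spec:
        raise ValidationError("sequences built with different window specs are not comparable")


def motif_repertoire(seq: MotifSequence,
                     baseline_seq: Optional[MotifSequence] = None) -> RepertoireResult:
    """Distinct-motif count, frequency table, and motifs exclusive to ``seq``."""
    if baseline_seq is not None:
        _check_comparable(seq, baseline_seq)
    freq = pd.Series(seq.codes).value_counts().sort_index()
    freq.index.name = "motif_code"
    exclusive = frozenset()
    if baseline_seq is not None:
        exclusive = frozenset(np.setdiff1d(seq.codes, baseline_seq.codes).tolist())
    return RepertoireResult(int(freq.size), freq, exclusive)


def motif_entropy(seq: MotifSequence, order: int = 0) -> float:
    """Entropy of a motif sequence in bits.

    order 0: plug-in Shannon entropy of the motif frequency distribution.
    order 1: conditional entropy H(next | current) from transition counts.
    Both are bounded by log2(count_possible_motifs(k)).
    """
    if order not in (0, 1):
        raise ConfigurationError(f"order must be 0 or 1, got {order}")
    codes = seq.codes
    if order == 0:
        if len(codes) < 2:
            raise ValidationError("need at least 2 windows for sequence entropy")
        _, counts = np.unique(codes, return_counts=True)
        p = counts / counts.sum()
        return float(-(p * np.log2(p)).sum())
    if len(codes) < 3:
        raise ValidationError("order-1 entropy needs at least 3 windows")
    cur, nxt = codes[:-1], codes[1:]
    h = 0.0
    n = len(cur)
    for c in np.unique(cur):
        nxt_c = nxt[cur == c]
        _, counts = np.unique(nxt_c, return_counts=True)
        p = counts / counts.sum()
        h += (len(nxt_c) / n) * float(-(p * np.log2(p)).sum())
    return h


def frequency_table(seq: MotifSequence) -> pd.DataFrame:
    """Tidy per-motif occurrence table (code, count, probability)."""
    rep = motif_repertoire(seq)
    return pd.DataFrame({
        "motif_code": rep.frequencies.index,
        "count": rep.frequencies.values,
        "probability": rep.frequencies.values / len(seq),
    })
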