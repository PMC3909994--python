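"""Group-level inference for the pre/post infusion design.

Mirrors the study's reported tests: one-sample two-tailed t-tests of per-
subject percent changes against zero, Bonferroni family-wise correction
(alpha / m, displayed rounded to 3 decimals: 0.05/9 -> 0.006, 0.05/23 ->
0.002), a paired drug-vs-placebo contrast of entropy changes, and per-item
Pearson correlations of a neural change score against subjective ratings.
Stored p-values and thresholds keep full precision; rounding is applied only
at the reporting layer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import AnalysisError, ValidationError

__all__ = [
    "TestResult",
    "one_sample_t",
    "bonferroni_threshold",
    "display_threshold",
    "condition_contrast",
    "rating_correlation",
]


@dataclass
class TestResult:
    measure: str
    t: float
    p: float
    n: int
    alpha_corrected: float
    significant: bool
    mean: float = float("nan")


def one_sample_t(values: Sequence[float], null_mean: float = 0.0,
                 alpha_corrected: float = 0.05, measure: str = "") -> TestResult:
    """Classical one-sample two-tailed t-test against ``null_mean``."""
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise ValidationError(f"need at least 2 observations, got {len(x)}")
    if np.std(x, ddof=1) == 0:
        # a constant sample exactly at the null is a perfect null fit (t=0, p=1),
        # e.g. identical paired change vectors; off the null it is degenerate
        if x[0] == null_mean:
            return TestResult(measure, 0.0, 1.0, len(x), alpha_corrected, False, float(x[0]))
        raise AnalysisError("degenerate sample: zero variance")
    t, p = stats.ttest_1samp(x, null_mean)
    return TestResult(measure, float(t), float(p), len(x), alpha_corrected,
                      bool(p < alpha_corrected), float(x.mean()))


def bonferroni_threshold(alpha_family: float, m_tests: int) -> float:
    """Per-test threshold alpha / m (full precision)."""
    if not 0 < alpha_family < 1:
        raise ValidationError(f"alpha_family must lie in (0, 1), got {alpha_family}")
    if m_tests < 1:
        raise ValidationError(f"m_tests must be >= 1, got {m_tests}")
    return alpha_family / m_tests


def display_threshold(alpha_family: float, m_tests: int, decimals: int = 3) -> float:
    """Reporting helper: the Bonferroni threshold rounded for display."""
    return round(bonferroni_threshold(alpha_family, m_tests), decimals)


def condition_contrast(drug_changes: Sequence[float], placebo_changes: Sequence[float],
                       paired: bool = True, alpha_corrected: float = 0.05,
                       measure: str = "") -> TestResult:
    """Two-tailed t-test of drug vs placebo change scores (paired by default).

    Paired mode tests the per-subject difference drug - placebo against zero,
    matching a within-subject design.
    """
    d = np.asarray(drug_changes, dtype=float)
    p_ = np.asarray(placebo_changes, dtype=float)
    if paired:
        if len(d) != len(p_):
            raise ValidationError(
                f"paired contrast requires equal n, got {len(d)} vs {len(p_)}"
            )
        return one_sample_t(d - p_, 0.0, alpha_corrected, measure)
    if len(d) < 2 or len(p_) < 2:
        raise ValidationError("need at least 2 observations per group")
    t, p = stats.ttest_ind(d, p_)
    return TestResult(measure, float(t), float(p), len(d) + len(p_),
                      alpha_corrected, bool(p < alpha_corrected),
                      float(d.mean() - p_.mean()))


def rating_correlation(neural_change_scores: Sequence[float],
                       rating_items_table: pd.DataFrame,
                       alpha_family: float = 0.05) -> pd.DataFrame:
    """Per-item Pearson correlation of a neural change score vs ratings.

    Returns a tidy frame (item, r, r2, p, significant, note) with the
    significance threshold Bonferroni-corrected over the number of items.
    A constant item column is reported as undefined (NaN r, note set)
    without affecting the other items or the correction count.
    """
    scores = np.asarray(neural_change_scores, dtype=float)
    if len(scores) < 3:
        raise ValidationError(f"need at least 3 subjects, got {len(scores)}")
    if rating_items_table.shape[0] != len(scores):
        raise ValidationError(
            f"{rating_items_table.shape[0]} rating rows for {len(scores)} subjects"
        )
    m = rating_items_table.shape[1]
    if m < 1:
        raise ValidationError("need at least 1 rating item")
    thr = bonferroni_threshold(alpha_family, m)
    rows = []
    for item in rating_items_table.columns:
        col = rating_items_table[item].to_numpy(dtype=float)
        if np.std(col) == 0 or np.std(scores) == 0:
            rows.append({"item": item, "r": np.nan, "r2": np.nan, "p": np.nan,
                         "significant": False, "note": "undefined (constant input)"})
            continue
        r, p = stats.pearsonr(scores, col)
        rows.append({"item": item, "r": float(r), "r2": float(r) ** 2, "p": float(p),
                     "significant": bool(p < thr), "note": ""})
    out = pd.DataFrame(rows)
    out.attrs["alpha_corrected"] = thr
    return out
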