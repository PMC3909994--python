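"""Cohort-level analysis tables: the glue between generator and statistics.

Each function takes the matched subject pairs produced by
:func:`neuroentropy.synthetic.generate_condition_pair` and returns a tidy
DataFrame ready for group inference, mirroring the study's reporting: per
subject x condition x network metastability percent change, binned-synchrony
entropy change, and per-condition motif summaries.
"""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import entropy as ent
from . import group_stats as gs
from . import motifs as mo
from . import synchrony as sy
from .io import VoxelTimeSeriesSet
from .synthetic import SubjectPair

__all__ = [
    "synchrony_trace",
    "metastability_table",
    "entropy_change_table",
    "motif_summary_table",
    "network_change_tests",
    "entropy_condition_contrast",
    "placebo_familywise_rejection",
]


def synchrony_trace(dataset: VoxelTimeSeriesSet, label, mode: str = "phase",
                    **kwargs) -> sy.SynchronyTrace:
    if mode == "phase":
        return sy.phase_trace(dataset, label, **kwargs)
    if mode == "amplitude":
        return sy.amplitude_trace(dataset, label)
    raise ValueError(f"mode must be 'phase' or 'amplitude', got {mode!r}")


def _arms(pair: SubjectPair):
    return (("placebo", pair.placebo), ("drug", pair.drug))


def metastability_table(pairs: Sequence[SubjectPair], mode: str = "phase") -> pd.DataFrame:
    """Per subject x condition x network metastability pre/post/% change."""
    rows = []
    for pair in pairs:
        for cond_name, arm in _arms(pair):
            ds = arm.voxel
            for label in ds.networks:
                trace = synchrony_trace(ds, label, mode)
                res = sy.metastability_change(trace, ds.pre_segment(), ds.post_segment())
                rows.append({
                    "subject": pair.subject_id, "condition": cond_name,
                    "network": label, "mode": mode,
                    "pre": res.pre_value, "post": res.post_value,
                    "percent_change": res.percent_change,
                })
    return pd.DataFrame(rows)


def entropy_change_table(pairs: Sequence[SubjectPair], mode: str = "phase",
                         n_bins: int = 10, edges_strategy: str = "pooled",
                         ) -> pd.DataFrame:
    """Per subject x condition x network Shannon-entropy change (bits)."""
    rows = []
    for pair in pairs:
        for cond_name, arm in _arms(pair):
            ds = arm.voxel
            for label in ds.networks:
                trace = synchrony_trace(ds, label, mode)
                pre_d, post_d = ent.pre_post_distributions(
                    trace, ds.pre_segment(), ds.post_segment(), n_bins, edges_strategy)
                rows.append({
                    "subject": pair.subject_id, "condition": cond_name,
                    "network": label, "mode": mode,
                    "h_pre": ent.shannon_entropy(pre_d),
                    "h_post": ent.shannon_entropy(post_d),
                    "delta_h": ent.entropy_change(pre_d, post_d),
                })
    return pd.DataFrame(rows)


def motif_summary_table(pairs: Sequence[SubjectPair],
                        spec: mo.WindowSpec = mo.WindowSpec(),
                        threshold: float = mo.DEFAULT_THRESHOLD,
                        use_absolute: bool = False) -> pd.DataFrame:
    """Per subject x condition x segment motif repertoire and entropies."""
    rows = []
    for pair in pairs:
        for cond_name, arm in _arms(pair):
            series = arm.roi.series
            for seg_name, seg in (("pre", series.pre_segment()),
                                  ("post", series.post_segment())):
                seq = mo.motif_sequence(series, spec, threshold, use_absolute, seg)
                rep = mo.motif_repertoire(seq)
                rows.append({
                    "subject": pair.subject_id, "condition": cond_name,
                    "segment": seg_name, "threshold": threshold,
                    "n_windows": len(seq), "repertoire": rep.n_distinct,
                    "h_order0": mo.motif_entropy(seq, 0),
                    "h_order1": mo.motif_entropy(seq, 1),
                })
    return pd.DataFrame(rows)


def network_change_tests(table: pd.DataFrame, value_col: str = "percent_change",
                         condition: str = "drug", alpha_family: float = 0.05,
                         ) -> pd.DataFrame:
    """One-sample two-tailed t-test of ``value_col`` vs 0 per network.

    The per-test threshold is Bonferroni-corrected over the number of
    networks in the table.
    """
    sub = table[table["condition"] == condition]
    networks = sub["network"].unique()
    thr = gs.bonferroni_threshold(alpha_family, len(networks))
    rows = []
    for net in networks:
        res = gs.one_sample_t(sub.loc[sub["network"] == net, value_col],
                              alpha_corrected=thr, measure=str(net))
        rows.append({"network": net, "mean": res.mean, "t": res.t, "p": res.p,
                     "n": res.n, "alpha_corrected": thr, "significant": res.significant})
    return pd.DataFrame(rows)


def entropy_condition_contrast(table: pd.DataFrame, value_col: str = "delta_h",
                               alpha_family: float = 0.05) -> pd.DataFrame:
    """Paired drug-vs-placebo contrast of entropy change, per network."""
    networks = table["network"].unique()
    thr = gs.bonferroni_threshold(alpha_family, len(networks))
    rows = []
    for net in networks:
        sub = table[table["network"] == net].pivot(
            index="subject", columns="condition", values=value_col)
        res = gs.condition_contrast(sub["drug"], sub["placebo"],
                                    paired=True, alpha_corrected=thr, measure=str(net))
        rows.append({"network": net, "mean_diff": res.mean, "t": res.t, "p": res.p,
                     "n": res.n, "alpha_corrected": thr, "significant": res.significant})
    return pd.DataFrame(rows)


def placebo_familywise_rejection(config, n_subjects: int = 15, mode: str = "amplitude",
                                 alpha_family: float = 0.05) -> bool:
    """One null-calibration replicate: does any network reject under placebo?

    Generates ``n_subjects`` placebo-like voxel datasets from ``config``'s
    seed, runs the per-network metastability percent-change t-test at the
    Bonferroni threshold, and reports whether any network is (falsely)
    declared significant.
    """
    from .synthetic import generate_voxel_dataset, subject_seed

    per_network: dict = {}
    for i in range(n_subjects):
        c = config.with_(condition="placebo_like", seed=subject_seed(config.seed, i))
        ds = generate_voxel_dataset(c)
        for label in ds.networks:
            trace = synchrony_trace(ds, label, mode)
            res = sy.metastability_change(trace, ds.pre_segment(), ds.post_segment())
            per_network.setdefault(label, []).append(res.percent_change)
    thr = gs.bonferroni_threshold(alpha_family, len(per_network))
    return any(
        gs.one_sample_t(vals, alpha_corrected=thr).significant
        for vals in per_network.values()
    )
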