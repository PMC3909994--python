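"""Reproducible multi-stage runs driven by a declarative YAML config.

Stages (in order): ``generate`` writes the synthetic cohort to disk as
delimited bundles; ``synchrony`` computes per-network metastability;
``entropy`` computes binned-synchrony entropy changes; ``motifs`` computes
ROI motif summaries (with a threshold sensitivity sweep); ``report`` runs
the group tests and writes a human-readable summary. Every run writes a
``manifest.json`` capturing the config snapshot, root seed, stages, file
paths, and package version; re-running the same manifest reproduces every
numeric output.

Config schema (all keys optional; defaults shown by ``validate_config``):

.. code-block:: yaml

    generator:          # any GeneratorConfig field, e.g.
      seed: 1
      n_networks: 9
      voxels_per_network: 16
    cohort:
      n_subjects: 15
    analysis:
      mode: phase        # phase | amplitude
      n_bins: 10
      edges_strategy: pooled
      window_len: 20
      step: 1
      threshold: 0.5
      threshold_sweep: [0.3, 0.4, 0.5, 0.6]
      use_absolute: false
      alpha_family: 0.05
"""

from __future__ import annotations

import difflib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path
from typing import List, Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from . import cohort as co
from . import motifs as mo
from .config import GeneratorConfig
from .exceptions import AnalysisError, ConfigurationError
from .io import (read_bundle, read_region_dataset, write_matrix_dataset,
                 write_region_dataset)
from .synthetic import (ConditionArm, RoiDataset, SubjectPair,
                        generate_condition_pair)

__all__ = ["validate_config", "load_config", "run_pipeline", "STAGES"]

logger = logging.getLogger(__name__)

STAGES = ("generate", "synchrony", "entropy", "motifs", "report")

_ANALYSIS_DEFAULTS = {
    "mode": "phase",
    "n_bins": 10,
    "edges_strategy": "pooled",
    "window_len": 20,
    "step": 1,
    "threshold": 0.5,
    "threshold_sweep": [0.3, 0.4, 0.5, 0.6],
    "use_absolute": False,
    "alpha_family": 0.05,
}
_COHORT_DEFAULTS = {"n_subjects": 15}


def _suggest(key: str, known: Sequence[str]) -> str:
    close = difflib.get_close_matches(key, known, n=1)
    return f" (did you mean {close[0]!r}?)" if close else ""


def _check_analysis(params: dict) -> List[str]:
    problems = []
    if params["mode"] not in ("phase", "amplitude"):
        problems.append(f"analysis.mode must be 'phase' or 'amplitude', got {params['mode']!r}")
    if not isinstance(params["n_bins"], int) or params["n_bins"] < 2:
        problems.append(f"analysis.n_bins must be an integer >= 2, got {params['n_bins']!r}")
    if params["edges_strategy"] not in ("pooled", "centered"):
        problems.append("analysis.edges_strategy must be 'pooled' or 'centered', "
                        f"got {params['edges_strategy']!r}")
    if not isinstance(params["window_len"], int) or params["window_len"] < 3:
        problems.append(f"analysis.window_len must be an integer >= 3, got {params['window_len']!r}")
    if not isinstance(params["step"], int) or params["step"] < 1:
        problems.append(f"analysis.step must be an integer >= 1, got {params['step']!r}")
    for name in ("threshold",):
        v = params[name]
        if not isinstance(v, (int, float)) or not -1 < v < 1:
            problems.append(f"analysis.{name} must lie in (-1, 1), got {v!r}")
    if not isinstance(params["threshold_sweep"], (list, tuple)) or any(
            not isinstance(v, (int, float)) or not -1 < v < 1
            for v in params["threshold_sweep"]):
        problems.append("analysis.threshold_sweep must be a list of values in (-1, 1)")
    if not isinstance(params["use_absolute"], bool):
        problems.append(f"analysis.use_absolute must be a boolean, got {params['use_absolute']!r}")
    a = params["alpha_family"]
    if not isinstance(a, (int, float)) or not 0 < a < 1:
        problems.append(f"analysis.alpha_family must lie in (0, 1), got {a!r}")
    return problems


def validate_config(config_path) -> List[str]:
    """Type- and range-check a config file; return a list of violations.

    An empty list means the config is valid. No side effects.
    """
    path = Path(config_path)
    try:
        raw = yaml.safe_load(path.read_text()) or {}
    except OSError as exc:
        raise OSError(f"cannot read config file {path}: {exc}") from exc
    except yaml.YAMLError as exc:
        return [f"not valid YAML: {exc}"]
    if not isinstance(raw, dict):
        return ["top level must be a mapping of sections"]
    problems = []
    known_sections = ("generator", "cohort", "analysis")
    for section in raw:
        if section not in known_sections:
            problems.append(f"unknown section {section!r}{_suggest(section, known_sections)}")
    gen = raw.get("generator") or {}
    gen_fields = GeneratorConfig.field_names()
    for key in gen:
        if key not in gen_fields:
            problems.append(f"unknown generator key {key!r}{_suggest(key, gen_fields)}")
    if not problems:
        try:
            GeneratorConfig(**gen)
        except (ConfigurationError, TypeError) as exc:
            problems.append(f"generator: {exc}")
    coh = raw.get("cohort") or {}
    for key in coh:
        if key not in _COHORT_DEFAULTS:
            problems.append(
                f"unknown cohort key {key!r}{_suggest(key, tuple(_COHORT_DEFAULTS))}")
    n_subjects = coh.get("n_subjects", _COHORT_DEFAULTS["n_subjects"])
    if not isinstance(n_subjects, int) or n_subjects < 2:
        problems.append(f"cohort.n_subjects must be an integer >= 2, got {n_subjects!r}")
    ana = raw.get("analysis") or {}
    for key in ana:
        if key not in _ANALYSIS_DEFAULTS:
            problems.append(
                f"unknown analysis key {key!r}{_suggest(key, tuple(_ANALYSIS_DEFAULTS))}")
    merged = {**_ANALYSIS_DEFAULTS, **{k: v for k, v in ana.items() if k in _ANALYSIS_DEFAULTS}}
    problems.extend(_check_analysis(merged))
    return problems


def load_config(config_path) -> dict:
    """Load and validate; raise :class:`ConfigurationError` on any violation."""
    problems = validate_config(config_path)
    if problems:
        raise ConfigurationError(
            "invalid config:\n  " + "\n  ".join(problems))
    raw = yaml.safe_load(Path(config_path).read_text()) or {}
    return {
        "generator": GeneratorConfig(**(raw.get("generator") or {})),
        "cohort": {**_COHORT_DEFAULTS, **(raw.get("cohort") or {})},
        "analysis": {**_ANALYSIS_DEFAULTS, **(raw.get("analysis") or {})},
    }


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _data_dir(outdir: Path) -> Path:
    return Path(outdir) / "data"


def _stage_generate(cfg: dict, outdir: Path) -> List[Path]:
    pairs = generate_condition_pair(cfg["generator"], cfg["cohort"]["n_subjects"])
    data = _data_dir(outdir)
    data.mkdir(parents=True, exist_ok=True)
    written = []
    for pair in pairs:
        for cond, arm in (("placebo", pair.placebo), ("drug", pair.drug)):
            stem = data / f"sub-{pair.subject_id}_{cond}"
            written += list(write_matrix_dataset(arm.voxel, stem))
            written += list(write_region_dataset(arm.roi.series, f"{stem}_roi"))
    logger.info("[generate] wrote %d files for %d subjects", len(written), len(pairs))
    return written


def _load_pairs(cfg: dict, outdir: Path, stage: str) -> List[SubjectPair]:
    data = _data_dir(outdir)
    if not data.is_dir():
        raise AnalysisError(
            f"stage '{stage}' requires outputs of stage 'generate' (missing {data})")
    pairs = []
    n = cfg["cohort"]["n_subjects"]
    for i in range(n):
        sid = f"{i + 1:02d}"
        arms = {}
        for cond in ("placebo", "drug"):
            stem = data / f"sub-{sid}_{cond}"
            if not stem.with_suffix(".tsv").exists():
                raise AnalysisError(
                    f"stage '{stage}' requires outputs of stage 'generate' "
                    f"(missing {stem}.tsv)")
            voxel = read_bundle(stem)
            roi = RoiDataset(read_region_dataset(f"{stem}_roi"), None, None)
            arms[cond] = ConditionArm(cond, voxel, roi)
        pairs.append(SubjectPair(sid, -1, arms["placebo"], arms["drug"]))
    return pairs


def _stage_synchrony(cfg: dict, outdir: Path) -> Path:
    pairs = _load_pairs(cfg, outdir, "synchrony")
    table = co.metastability_table(pairs, cfg["analysis"]["mode"])
    out = Path(outdir) / "metastability.tsv"
    table.to_csv(out, sep="\t", index=False)
    logger.info("[synchrony] %d rows -> %s", len(table), out)
    return out


def _stage_entropy(cfg: dict, outdir: Path) -> Path:
    pairs = _load_pairs(cfg, outdir, "entropy")
    ana = cfg["analysis"]
    table = co.entropy_change_table(pairs, ana["mode"], ana["n_bins"], ana["edges_strategy"])
    out = Path(outdir) / "entropy.tsv"
    table.to_csv(out, sep="\t", index=False)
    logger.info("[entropy] %d rows -> %s", len(table), out)
    return out


def _stage_motifs(cfg: dict, outdir: Path) -> Path:
    pairs = _load_pairs(cfg, outdir, "motifs")
    ana = cfg["analysis"]
    spec = mo.WindowSpec(ana["window_len"], ana["step"])
    thresholds = list(dict.fromkeys([ana["threshold"], *ana["threshold_sweep"]]))
    tables = [co.motif_summary_table(pairs, spec, thr, ana["use_absolute"])
              for thr in thresholds]
    table = pd.concat(tables, ignore_index=True)
    out = Path(outdir) / "motifs.tsv"
    table.to_csv(out, sep="\t", index=False)
    logger.info("[motifs] %d rows (%d thresholds) -> %s", len(table), len(thresholds), out)
    return out


def _stage_report(cfg: dict, outdir: Path) -> List[Path]:
    outdir = Path(outdir)
    ana = cfg["analysis"]
    needed = [outdir / "metastability.tsv", outdir / "entropy.tsv", outdir / "motifs.tsv"]
    for p, stage in zip(needed, ("synchrony", "entropy", "motifs")):
        if not p.exists():
            raise AnalysisError(f"stage 'report' requires outputs of stage '{stage}' "
                                f"(missing {p})")
    meta = pd.read_csv(needed[0], sep="\t")
    entv = pd.read_csv(needed[1], sep="\t")
    motif = pd.read_csv(needed[2], sep="\t")
    tests = co.network_change_tests(meta, alpha_family=ana["alpha_family"])
    contrast = co.entropy_condition_contrast(entv, alpha_family=ana["alpha_family"])
    p_tests = outdir / "metastability_tests.tsv"
    p_contrast = outdir / "entropy_contrast.tsv"
    tests.to_csv(p_tests, sep="\t", index=False)
    contrast.to_csv(p_contrast, sep="\t", index=False)

    lines = ["neuroentropy report", "===================", ""]
    thr = tests["alpha_corrected"].iloc[0]
    sig = tests[tests["significant"]]["network"].tolist()
    lines.append(f"metastability ({ana['mode']} mode): one-sample two-tailed t-test of "
                 f"% change vs 0, Bonferroni threshold p < {thr:.3f}")
    lines.append(f"  significant networks: {', '.join(sig) if sig else 'none'}")
    csig = contrast[contrast["significant"]]["network"].tolist()
    lines.append("entropy change, drug vs placebo (paired): "
                 f"significant networks: {', '.join(csig) if csig else 'none'}")
    base = motif[motif["threshold"] == ana["threshold"]]
    rep = base.groupby(["condition", "segment"])["repertoire"].mean()
    lines.append("motif repertoire (mean distinct motifs per subject, "
                 f"threshold {ana['threshold']}):")
    for (cond, seg), v in rep.items():
        lines.append(f"  {cond:8s} {seg:4s} {v:.2f}")
    p_summary = outdir / "summary.txt"
    p_summary.write_text("\n".join(lines) + "\n")
    logger.info("[report] -> %s", p_summary)
    return [p_tests, p_contrast, p_summary]


_STAGE_FUNCS = {
    "generate": _stage_generate,
    "synchrony": _stage_synchrony,
    "entropy": _stage_entropy,
    "motifs": _stage_motifs,
    "report": _stage_report,
}


def run_pipeline(config_path, outdir, stages: Optional[Sequence[str]] = None) -> dict:
    """Execute the requested stages in order and write a run manifest.

    Returns the manifest dict. Fails fast with a stage-named error if a
    stage's upstream outputs are missing.
    """
    cfg = load_config(config_path)
    stages = list(stages) if stages else list(STAGES)
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ConfigurationError(f"unknown stage(s) {unknown}; valid: {STAGES}")
    stages = [s for s in STAGES if s in stages]  # canonical order
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs = {}
    for stage in stages:
        result = _STAGE_FUNCS[stage](cfg, outdir)
        paths = result if isinstance(result, list) else [result]
        outputs[stage] = [str(p) for p in paths]
    manifest = {
        "package_version": __version__,
        "config_path": str(config_path),
        "config": {
            "generator": asdict(cfg["generator"]),
            "cohort": cfg["cohort"],
            "analysis": cfg["analysis"],
        },
        "root_seed": cfg["generator"].seed,
        "stages": stages,
        "outputs": outputs,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return manifest
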