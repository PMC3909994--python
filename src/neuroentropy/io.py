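"""Containers and I/O for labeled time-series data.

Two containers cover the pipeline:

* :class:`VoxelTimeSeriesSet` — voxels x timepoints with a per-voxel network
  label; the unit of the metastability / synchrony-entropy analysis.
* :class:`RegionTimeSeries` — named ROIs x timepoints; the unit of the 4-node
  connectivity-motif analysis.

On disk, a voxel dataset is a three-file bundle sharing a stem:

* ``<stem>.tsv`` — tab-separated numeric matrix, one row per voxel, no header;
* ``<stem>.labels.txt`` — one network label per matrix row;
* ``<stem>.meta.txt`` — ``key<TAB>value`` lines (sampling_interval,
  infusion_onset, infusion_duration, subject_id, condition).

A region dataset uses the same layout with region names in the labels file.
NIfTI-1 input (4D image + 3D integer label volume, label 0 = background) is
supported for real data; voxels are flattened x-fastest (x, then y, then z)
so voxel row indices are reproducible.

All time indexing is 0-based; segments are half-open ``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import FormatError, ValidationError

__all__ = [
    "VoxelTimeSeriesSet",
    "RegionTimeSeries",
    "read_matrix_dataset",
    "write_matrix_dataset",
    "read_region_dataset",
    "write_region_dataset",
    "read_nifti_dataset",
    "extract_network_mean",
]


def _check_finite(data: np.ndarray, what: str) -> None:
    if not np.all(np.isfinite(data)):
        bad = np.argwhere(~np.isfinite(np.atleast_2d(data)))[0]
        raise ValidationError(f"{what} contains a non-finite value at {tuple(bad)}")


@dataclass
class VoxelTimeSeriesSet:
    """Voxel x timepoint matrix with per-voxel network labels."""

    data: np.ndarray
    network_labels: np.ndarray
    sampling_interval: float
    infusion_onset: Optional[int] = None
    infusion_duration: int = 0
    subject_id: Optional[str] = None
    condition: Optional[str] = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.network_labels = np.asarray(self.network_labels)
        if self.data.ndim != 2:
            raise ValidationError(f"data must be 2-D (voxels x timepoints), got {self.data.ndim}-D")
        if len(self.network_labels) != self.data.shape[0]:
            raise ValidationError(
                f"{len(self.network_labels)} labels for {self.data.shape[0]} voxel rows"
            )
        _check_finite(self.data, "voxel data")
        if self.sampling_interval <= 0:
            raise ValidationError("sampling_interval must be > 0")
        if self.infusion_onset is not None and not 0 <= self.infusion_onset < self.n_timepoints:
            raise ValidationError(
                f"infusion_onset {self.infusion_onset} outside [0, {self.n_timepoints})"
            )

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]

    @property
    def networks(self) -> tuple:
        """Distinct labels in first-appearance order."""
        return tuple(pd.unique(self.network_labels))

    def network_data(self, label) -> np.ndarray:
        """Rows of all voxels carrying ``label`` (view, row order preserved)."""
        mask = self.network_labels == label
        if not mask.any():
            raise ValidationError(f"unknown network label {label!r}")
        return self.data[mask]

    def pre_segment(self) -> tuple:
        if self.infusion_onset is None:
            raise ValidationError("dataset has no infusion_onset")
        return (0, self.infusion_onset)

    def post_segment(self) -> tuple:
        if self.infusion_onset is None:
            raise ValidationError("dataset has no infusion_onset")
        return (self.infusion_onset + self.infusion_duration, self.n_timepoints)


@dataclass
class RegionTimeSeries:
    """Named-ROI x timepoint matrix."""

    region_names: Sequence[str]
    data: np.ndarray
    sampling_interval: float
    infusion_onset: Optional[int] = None
    infusion_duration: int = 0
    subject_id: Optional[str] = None
    condition: Optional[str] = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.region_names = tuple(str(n) for n in self.region_names)
        if len(set(self.region_names)) != len(self.region_names):
            raise ValidationError("region names must be distinct")
        if self.data.ndim != 2 or self.data.shape[0] != len(self.region_names):
            raise ValidationError(
                f"data shape {self.data.shape} inconsistent with "
                f"{len(self.region_names)} region names"
            )
        _check_finite(self.data, "region data")
        if self.sampling_interval <= 0:
            raise ValidationError("sampling_interval must be > 0")

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]

    def region(self, name: str) -> np.ndarray:
        try:
            i = self.region_names.index(name)
        except ValueError:
            raise ValidationError(f"unknown region {name!r}") from None
        return self.data[i]

    def pre_segment(self) -> tuple:
        if self.infusion_onset is None:
            raise ValidationError("dataset has no infusion_onset")
        return (0, self.infusion_onset)

    def post_segment(self) -> tuple:
        if self.infusion_onset is None:
            raise ValidationError("dataset has no infusion_onset")
        return (self.infusion_onset + self.infusion_duration, self.n_timepoints)


# ---------------------------------------------------------------------------
# delimited three-file bundle
# ---------------------------------------------------------------------------

_META_INT = ("infusion_onset", "infusion_duration")
_META_FLOAT = ("sampling_interval",)


def _read_meta(path) -> dict:
    meta = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise FormatError(f"{path}:{lineno}: expected 'key<TAB>value', got {line!r}")
        key, value = parts
        if key in _META_INT:
            meta[key] = int(value)
        elif key in _META_FLOAT:
            meta[key] = float(value)
        else:
            meta[key] = value
    return meta


def _write_meta(path, pairs: dict) -> None:
    lines = [f"{k}\t{v}" for k, v in pairs.items() if v is not None]
    Path(path).write_text("\n".join(lines) + "\n")


def _read_numeric_matrix(path) -> np.ndarray:
    try:
        raw = pd.read_csv(path, sep="\t", header=None, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"{path}: non-numeric cell {raw.iat[r, c]!r} at row {r}, column {c}"
        )
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise FormatError(f"{path}: missing value at row {r}, column {c}")
    return numeric.to_numpy(dtype=float)


def _bundle_paths(stem):
    stem = Path(stem)
    return stem.with_suffix(".tsv"), Path(str(stem) + ".labels.txt"), Path(str(stem) + ".meta.txt")


def read_matrix_dataset(path_matrix, path_labels, metadata=None,
                        label_set: Optional[Sequence[str]] = None) -> VoxelTimeSeriesSet:
    """Read a voxel dataset from a delimited matrix plus a label sidecar.

    ``metadata`` may be a dict, a path to a ``key<TAB>value`` file, or None
    (sampling_interval then defaults to 1.0). When ``label_set`` is given,
    any label outside it raises :class:`ValidationError`.
    """
    data = _read_numeric_matrix(path_matrix)
    labels = [l.strip() for l in Path(path_labels).read_text().splitlines() if l.strip()]
    if len(labels) != data.shape[0]:
        raise FormatError(
            f"row-count mismatch: {data.shape[0]} matrix rows but {len(labels)} labels"
        )
    if label_set is not None:
        unknown = set(labels) - set(label_set)
        if unknown:
            raise ValidationError(f"labels not in declared label set: {sorted(unknown)}")
    if metadata is None:
        meta = {}
    elif isinstance(metadata, dict):
        meta = dict(metadata)
    else:
        meta = _read_meta(metadata)
    return VoxelTimeSeriesSet(
        data=data,
        network_labels=np.array(labels),
        sampling_interval=float(meta.get("sampling_interval", 1.0)),
        infusion_onset=meta.get("infusion_onset"),
        infusion_duration=int(meta.get("infusion_duration", 0)),
        subject_id=meta.get("subject_id"),
        condition=meta.get("condition"),
    )


def write_matrix_dataset(dataset: VoxelTimeSeriesSet, stem) -> tuple:
    """Write the three-file bundle ``<stem>.tsv / .labels.txt / .meta.txt``."""
    p_mat, p_lab, p_meta = _bundle_paths(stem)
    p_mat.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(p_mat, dataset.data, delimiter="\t", fmt="%.10g")
    p_lab.write_text("\n".join(map(str, dataset.network_labels)) + "\n")
    _write_meta(p_meta, {
        "sampling_interval": dataset.sampling_interval,
        "infusion_onset": dataset.infusion_onset,
        "infusion_duration": dataset.infusion_duration,
        "subject_id": dataset.subject_id,
        "condition": dataset.condition,
    })
    return p_mat, p_lab, p_meta


def read_region_dataset(stem) -> RegionTimeSeries:
    p_mat, p_lab, p_meta = _bundle_paths(stem)
    data = _read_numeric_matrix(p_mat)
    names = [l.strip() for l in p_lab.read_text().splitlines() if l.strip()]
    if len(names) != data.shape[0]:
        raise FormatError(
            f"row-count mismatch: {data.shape[0]} matrix rows but {len(names)} region names"
        )
    meta = _read_meta(p_meta) if p_meta.exists() else {}
    return RegionTimeSeries(
        region_names=names,
        data=data,
        sampling_interval=float(meta.get("sampling_interval", 1.0)),
        infusion_onset=meta.get("infusion_onset"),
        infusion_duration=int(meta.get("infusion_duration", 0)),
        subject_id=meta.get("subject_id"),
        condition=meta.get("condition"),
    )


def write_region_dataset(series: RegionTimeSeries, stem) -> tuple:
    p_mat, p_lab, p_meta = _bundle_paths(stem)
    p_mat.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(p_mat, series.data, delimiter="\t", fmt="%.10g")
    p_lab.write_text("\n".join(series.region_names) + "\n")
    _write_meta(p_meta, {
        "sampling_interval": series.sampling_interval,
        "infusion_onset": series.infusion_onset,
        "infusion_duration": series.infusion_duration,
        "subject_id": series.subject_id,
        "condition": series.condition,
    })
    return p_mat, p_lab, p_meta


def read_bundle(stem, **kwargs) -> VoxelTimeSeriesSet:
    """Read a voxel bundle written by :func:`write_matrix_dataset`."""
    p_mat, p_lab, p_meta = _bundle_paths(stem)
    return read_matrix_dataset(p_mat, p_lab, p_meta if p_meta.exists() else None, **kwargs)


# ---------------------------------------------------------------------------
# NIfTI pathway
# ---------------------------------------------------------------------------

def read_nifti_dataset(path_4d_image, path_label_volume,
                       sampling_interval: Optional[float] = None,
                       **metadata) -> VoxelTimeSeriesSet:
    """Extract labeled voxel time series from a 4D NIfTI + 3D label volume.

    Voxels with label 0 (background) are excluded; the remaining voxels are
    flattened with the first (x) axis fastest, then y, then z, so a voxel's
    row index is reproducible from its grid coordinates. ``sampling_interval``
    defaults to the image's time-step header field.
    """
    import nibabel as nib

    img = nib.load(str(path_4d_image))
    lab_img = nib.load(str(path_label_volume))
    data = np.asanyarray(img.dataobj)
    labels = np.asanyarray(lab_img.dataobj)
    if data.ndim != 4:
        raise FormatError(f"expected a 4-D image, got {data.ndim}-D")
    if labels.ndim != 3:
        raise FormatError(f"expected a 3-D label volume, got {labels.ndim}-D")
    if data.shape[:3] != labels.shape:
        raise FormatError(
            f"grid mismatch: image grid {data.shape[:3]} vs label grid {labels.shape}"
        )
    labels = np.rint(labels).astype(int)
    # x-fastest flattening: put axes (z, y, x) so C-order ravel runs x fastest
    n_t = data.shape[3]
    flat_data = data.transpose(2, 1, 0, 3).reshape(-1, n_t)
    flat_labels = labels.transpose(2, 1, 0).ravel()
    mask = flat_labels != 0
    if not mask.any():
        raise ValidationError("label volume selects no voxels (all labels are 0)")
    if sampling_interval is None:
        zooms = img.header.get_zooms()
        sampling_interval = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
    return VoxelTimeSeriesSet(
        data=flat_data[mask].astype(float),
        network_labels=flat_labels[mask].astype(str),
        sampling_interval=sampling_interval,
        infusion_onset=metadata.get("infusion_onset"),
        infusion_duration=int(metadata.get("infusion_duration", 0)),
        subject_id=metadata.get("subject_id"),
        condition=metadata.get("condition"),
    )


def extract_network_mean(dataset: VoxelTimeSeriesSet, network_label) -> np.ndarray:
    """Per-timepoint arithmetic mean over the network's voxels."""
    return dataset.network_data(network_label).mean(axis=0)
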