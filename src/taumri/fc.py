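"""ROI time series, Fisher-z functional connectivity matrices, intra-node
strength and group averaging.

Averaging order is fixed throughout the package: correlations are Fisher
z-transformed per subject (or per voxel pair) first and averaged afterwards,
never the other way around.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import AtlasLabels, Bold4D

__all__ = [
    "TimeSeriesMatrix",
    "ConnMatrix",
    "NodeStrengthVector",
    "extract_roi_timeseries",
    "fisher_z",
    "connectivity_matrix",
    "intra_node_strength",
    "node_strength_vector",
    "group_average_matrix",
    "merge_hemispheres",
]

R_CLIP = 1.0 - 1e-7  # keeps atanh finite for degenerate |r| -> 1 inputs


@dataclass
class TimeSeriesMatrix:
    roi_order: list
    data: np.ndarray  # (n_rois, n_frames)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape[0] != len(self.roi_order):
            raise ValueError("row count does not match roi_order")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("time series must be finite")


@dataclass
class ConnMatrix:
    """Symmetric ROI x ROI Fisher-z connectivity; diagonal is undefined (NaN)."""

    roi_order: list
    z: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        n = len(self.roi_order)
        if self.z.shape != (n, n):
            raise ValueError("z must be square matching roi_order")
        off = ~np.eye(n, dtype=bool)
        if not np.allclose(self.z[off], self.z.T[off], equal_nan=True):
            raise ValueError("z must be symmetric")
        if not np.all(np.isfinite(self.z[off])):
            raise ValueError("off-diagonal z must be finite")

    def edge_values(self) -> np.ndarray:
        """Unique off-diagonal edges (upper triangle, row-major)."""
        iu = np.triu_indices(len(self.roi_order), k=1)
        return self.z[iu]


@dataclass
class NodeStrengthVector:
    roi_order: list
    strength: np.ndarray  # mean intra-ROI voxel-pair Fisher z per ROI


def extract_roi_timeseries(bold: Bold4D, atlas: AtlasLabels,
                           rois=None) -> TimeSeriesMatrix:
    """Mean voxel series per ROI, rows in the requested ROI order."""
    if not atlas.geometry.matches(bold.geometry):
        raise ValueError("atlas and BOLD geometry differ")
    names = list(rois) if rois is not None else atlas.roi_names
    flat = bold.data.reshape(-1, bold.n_frames)
    labels = atlas.labels.reshape(-1)
    rows = []
    for name in names:
        mask = labels == atlas.label_of(name)
        if not np.any(mask):
            raise ValueError(f"ROI {name!r} is empty")
        rows.append(flat[mask].mean(axis=0))
    return TimeSeriesMatrix(names, np.array(rows))


def fisher_z(r, *, clip: float = R_CLIP):
    """Fisher z = atanh(r), with |r| clipped at 1-1e-7 to stay finite.

    Scalar in, scalar out; array in, array out.  Which entries were clipped
    can be recovered with the companion :func:`clipped_mask`."""
    r = np.asarray(r, dtype=float)
    if not np.all(np.isfinite(r)):
        raise ValueError("correlation input must be finite")
    if np.any(np.abs(r) > 1 + 1e-12):
        raise ValueError("correlations must lie in [-1, 1]")
    z = np.arctanh(np.clip(r, -clip, clip))
    return z if z.shape else float(z)


def clipped_mask(r, *, clip: float = R_CLIP) -> np.ndarray:
    return np.abs(np.asarray(r, dtype=float)) >= clip


def connectivity_matrix(ts: TimeSeriesMatrix, metadata: dict | None = None) -> ConnMatrix:
    """Pairwise Pearson correlation of ROI rows, Fisher z-transformed.

    Diagonal is NaN (undefined).  Zero-variance rows are an error; perfectly
    (anti)correlated pairs are clipped and flagged in the metadata."""
    sd = ts.data.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(f"zero-variance ROI series: {[ts.roi_order[i] for i in bad]}")
    r = np.corrcoef(ts.data)
    np.fill_diagonal(r, 0.0)
    z = fisher_z(r)
    n_clipped = int(np.sum(clipped_mask(r)) // 2)
    np.fill_diagonal(z, np.nan)
    md = dict(metadata or {})
    md["n_clipped_edges"] = n_clipped
    return ConnMatrix(ts.roi_order, z, md)


def intra_node_strength(bold: Bold4D, atlas: AtlasLabels, roi: str) -> tuple[float, int]:
    """Mean Fisher-z over all unordered voxel pairs within one ROI.

    Pairs involving a zero-variance voxel are excluded; returns
    ``(strength, n_excluded_pairs)``."""
    if not atlas.geometry.matches(bold.geometry):
        raise ValueError("atlas and BOLD geometry differ")
    flat = bold.data.reshape(-1, bold.n_frames)
    series = flat[atlas.labels.reshape(-1) == atlas.label_of(roi)]
    n_total = series.shape[0]
    usable = series[series.std(axis=1) > 0]
    n = usable.shape[0]
    if n < 2:
        raise ValueError(f"ROI {roi!r} has fewer than 2 usable voxels")
    r = np.corrcoef(usable)
    iu = np.triu_indices(n, k=1)
    strength = float(np.mean(fisher_z(r[iu])))
    n_excluded = (n_total * (n_total - 1) - n * (n - 1)) // 2
    return strength, n_excluded


def node_strength_vector(bold: Bold4D, atlas: AtlasLabels, rois=None) -> NodeStrengthVector:
    names = list(rois) if rois is not None else atlas.roi_names
    vals = [intra_node_strength(bold, atlas, name)[0] for name in names]
    return NodeStrengthVector(names, np.array(vals))


def group_average_matrix(matrices: list[ConnMatrix],
                         metadata: dict | None = None) -> ConnMatrix:
    """Elementwise mean of Fisher-z matrices sharing one ROI order."""
    if not matrices:
        raise ValueError("need at least one matrix")
    order = matrices[0].roi_order
    for m in matrices[1:]:
        if m.roi_order != order:
            raise ValueError("roi_order mismatch across matrices")
    z = np.mean([m.z for m in matrices], axis=0)
    md = dict(metadata or {})
    md["n"] = len(matrices)
    return ConnMatrix(order, z, md)


def merge_hemispheres(atlas: AtlasLabels) -> AtlasLabels:
    """Merge left/right ROI pairs that share a name into single
    hemisphere-independent labels (the default analysis mode); ROIs tagged
    ``both`` pass through unchanged."""
    table = atlas.roi_table
    new_labels = atlas.labels.copy()
    rows = []
    next_label = 1
    for name in dict.fromkeys(table["name"]):
        labs = table.index[table["name"] == name]
        n_vox = int(table.loc[labs, "n_voxels"].sum())
        for lab in labs:
            new_labels[atlas.labels == lab] = next_label
        rows.append((next_label, name, "both", n_vox))
        next_label += 1
    new_table = pd.DataFrame(
        {"name": [r[1] for r in rows], "hemisphere": [r[2] for r in rows],
         "n_voxels": [r[3] for r in rows]},
        index=pd.Index([r[0] for r in rows], name="label"))
    return AtlasLabels(atlas.geometry, new_labels, new_table)
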