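"""Deterministic streamline tractography on a voxel-wise peak field, and
voxel-normalized ROI-pair fiber-density matrices.

Propagation rule, from each seed in both directions: at every step the
current voxel's peak most parallel to the incoming direction is selected
(nearest-voxel lookup, no interpolation); tracking stops when no peak
reaches the QA threshold, when the turn exceeds the maximal turning angle,
or when the track leaves the volume.  The new direction mixes the selected
peak with the incoming direction, ``d = normalize((1-w)*peak + w*d_in)``
(w = 0.1 by default, a momentum-style weighting), and the position advances
by one step (0.5 mm default).  Finished tracks are kept only when their
length lies in the 5-120 mm band.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .io import AtlasLabels, VolumeGeometry
from .qball import PeakField

__all__ = [
    "TrackingConfig",
    "StreamlineSet",
    "FiberDensityMatrix",
    "track_deterministic",
    "fiber_density_matrix",
    "group_average_density",
]


@dataclass
class TrackingConfig:
    qa_threshold: float = 0.03
    step_mm: float = 0.5
    direction_weighting: float = 0.1   # momentum on the incoming direction
    max_turning_deg: float = 55.0
    length_bounds_mm: tuple = (5.0, 120.0)
    seeds_per_voxel: int = 1
    rng_seed: int = 0

    def __post_init__(self):
        if self.step_mm <= 0:
            raise ValueError("step_mm must be positive")
        if not (0 <= self.direction_weighting < 1):
            raise ValueError("direction weighting must be in [0, 1)")
        if not (0 < self.max_turning_deg < 90):
            raise ValueError("max turning angle must be in (0, 90) degrees")
        lo, hi = self.length_bounds_mm
        if not (0 < lo < hi):
            raise ValueError("invalid length bounds")
        if self.seeds_per_voxel < 1:
            raise ValueError("seeds_per_voxel must be >= 1")


@dataclass
class StreamlineSet:
    """Polylines in world (mm) coordinates with provenance."""

    streamlines: list            # list of (n_pts, 3) arrays
    lengths: np.ndarray          # mm
    seed_voxels: list            # (i, j, k) per streamline
    config: TrackingConfig
    rng_seed: int

    @property
    def n(self) -> int:
        return len(self.streamlines)


@dataclass
class FiberDensityMatrix:
    """ROI-pair fiber density: streamline count / (voxels_i + voxels_j)."""

    roi_order: list
    density: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        if np.any(self.density < 0):
            raise ValueError("density must be nonnegative")


def _voxel_index(inv_affine: np.ndarray, pos: np.ndarray) -> np.ndarray:
    ijk = inv_affine[:3, :3] @ pos + inv_affine[:3, 3]
    return np.round(ijk).astype(int)


def _half_track(pos0, d0, peak_dirs, peak_qa, n_peaks, inv_affine, dims, cfg,
                max_steps):
    """Track one direction from a seed; returns positions after the seed."""
    cos_turn = np.cos(np.radians(cfg.max_turning_deg))
    pts = []
    pos = pos0.copy()
    d = d0.copy()
    for _ in range(max_steps):
        nxt = pos + cfg.step_mm * d
        ijk = _voxel_index(inv_affine, nxt)
        if np.any(ijk < 0) or np.any(ijk >= dims):
            break
        dirs = peak_dirs[tuple(ijk)]
        qa = peak_qa[tuple(ijk)]
        k = n_peaks[tuple(ijk)]
        usable = np.flatnonzero(qa[:k] >= cfg.qa_threshold)
        if usable.size == 0:
            break
        dots = dirs[usable] @ d
        best = usable[np.argmax(np.abs(dots))]
        peak = dirs[best] if dots[np.argmax(np.abs(dots))] >= 0 else -dirs[best]
        if peak @ d < cos_turn:
            break
        d_new = (1.0 - cfg.direction_weighting) * peak + cfg.direction_weighting * d
        d_new /= np.linalg.norm(d_new)
        pts.append(nxt)
        pos = nxt
        d = d_new
    return pts


def track_deterministic(peaks: PeakField, cfg: TrackingConfig | None = None) -> StreamlineSet:
    """Whole-volume deterministic tractography.

    Seeds are placed at ``seeds_per_voxel`` uniform sub-voxel positions in
    every voxel whose top QA reaches the threshold; each seed is tracked in
    both directions along the voxel's strongest peak and the halves are
    concatenated.  A pure function of (peaks, cfg): the same rng_seed gives
    bit-identical output."""
    cfg = cfg or TrackingConfig()
    geom = peaks.geometry
    dims = np.array(geom.dims)
    inv_affine = np.linalg.inv(geom.affine)
    eligible = np.argwhere(peaks.qa_volume >= cfg.qa_threshold)
    if eligible.size == 0:
        raise ValueError("no voxels reach the seeding QA threshold")
    rng = np.random.default_rng(cfg.rng_seed)
    max_steps = int(np.ceil(cfg.length_bounds_mm[1] / cfg.step_mm)) + 2
    lo, hi = cfg.length_bounds_mm
    lines, lengths, seed_vox = [], [], []
    for ijk in eligible:
        for _ in range(cfg.seeds_per_voxel):
            frac = rng.uniform(-0.5, 0.5, size=3)
            pos0 = geom.affine[:3, :3] @ (ijk + frac) + geom.affine[:3, 3]
            d0 = peaks.directions[tuple(ijk)][0]
            fwd = _half_track(pos0, d0, peaks.directions, peaks.qa,
                              peaks.n_peaks, inv_affine, dims, cfg, max_steps)
            bwd = _half_track(pos0, -d0, peaks.directions, peaks.qa,
                              peaks.n_peaks, inv_affine, dims, cfg, max_steps)
            pts = bwd[::-1] + [pos0] + fwd
            length = cfg.step_mm * (len(pts) - 1)
            if lo <= length <= hi:
                lines.append(np.asarray(pts))
                lengths.append(length)
                seed_vox.append(tuple(int(v) for v in ijk))
    return StreamlineSet(lines, np.asarray(lengths, dtype=float), seed_vox,
                         cfg, cfg.rng_seed)


def _streamline_labels(line: np.ndarray, atlas: AtlasLabels,
                       sample_mm: float) -> set:
    """Labels of every voxel a streamline passes through or ends in,
    by dense resampling of its segments."""
    inv = np.linalg.inv(atlas.geometry.affine)
    pts = [line[0]]
    for a, b in zip(line[:-1], line[1:]):
        seg = np.linalg.norm(b - a)
        n = max(1, int(np.ceil(seg / sample_mm)))
        for t in np.linspace(0, 1, n + 1)[1:]:
            pts.append(a + t * (b - a))
    pts = np.asarray(pts)
    ijk = np.round((inv[:3, :3] @ pts.T).T + inv[:3, 3]).astype(int)
    dims = np.array(atlas.geometry.dims)
    ok = np.all((ijk >= 0) & (ijk < dims), axis=1)
    labs = atlas.labels[tuple(ijk[ok].T)]
    return set(int(v) for v in np.unique(labs) if v != 0)


def fiber_density_matrix(streamlines: StreamlineSet, atlas: AtlasLabels,
                         rois=None, zero_sub_unit: bool = True) -> FiberDensityMatrix:
    """Count streamlines touching each ROI pair and voxel-normalize.

    ``count(i, j)`` = streamlines that pass through or end in both ROIs
    (once per streamline per pair); ``density = count / (n_vox_i + n_vox_j)``.
    With ``zero_sub_unit`` (the default for single matrices), densities
    below one fiber per voxel are set to exactly zero; when building
    group averages, compute raw matrices first and zero after averaging via
    :func:`group_average_density`."""
    names = list(rois) if rois is not None else atlas.roi_names
    unknown = [n for n in names if n not in atlas.roi_names]
    if unknown:
        raise KeyError(f"unknown ROIs {unknown}")
    labels_of = {atlas.label_of(n): i for i, n in enumerate(names)}
    n = len(names)
    counts = np.zeros((n, n))
    sample_mm = 0.5 * min(atlas.geometry.voxel_size)
    for line in streamlines.streamlines:
        hit = sorted(labels_of[l] for l in _streamline_labels(line, atlas, sample_mm)
                     if l in labels_of)
        for i, j in combinations(hit, 2):
            counts[i, j] += 1
            counts[j, i] += 1
    vox = np.array([int(atlas.roi_table.loc[atlas.label_of(nm), "n_voxels"]) for nm in names])
    denom = vox[:, None] + vox[None, :]
    density = counts / denom
    if zero_sub_unit:
        density = np.where(density < 1.0, 0.0, density)
    np.fill_diagonal(density, 0.0)
    return FiberDensityMatrix(names, density, counts)


def group_average_density(matrices: list[FiberDensityMatrix],
                          zero_sub_unit: bool = True) -> FiberDensityMatrix:
    """Average raw (un-zeroed) density matrices over a group, then apply the
    sub-unit zeroing rule to the average."""
    order = matrices[0].roi_order
    for m in matrices[1:]:
        if m.roi_order != order:
            raise ValueError("roi_order mismatch")
    density = np.mean([m.density for m in matrices], axis=0)
    counts = np.mean([m.counts for m in matrices], axis=0)
    if zero_sub_unit:
        density = np.where(density < 1.0, 0.0, density)
    return FiberDensityMatrix(order, density, counts)
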