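"""Imaging and tabular I/O: NIfTI volumes, diffusion gradient tables, matrix tables.

Conventions used throughout the package:

* voxel indices are 0-based;
* world (streamline) coordinates are in mm, obtained via the affine;
* matrix tables are CSV with ROI names as header row/column and ``NA``
  as the missing-value token (the connectivity diagonal is undefined).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "VolumeGeometry",
    "Bold4D",
    "NuisanceSet",
    "DiffusionScheme",
    "AtlasLabels",
    "read_volume",
    "write_volume",
    "read_diffusion_scheme",
    "write_diffusion_scheme",
    "write_matrix_table",
    "read_matrix_table",
]

MISSING_TOKEN = "NA"


@dataclass(frozen=True)
class VolumeGeometry:
    """Grid geometry of a 3-D image: shape, voxel size (mm) and voxel→world affine."""

    dims: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    affine: np.ndarray

    def __post_init__(self):
        if len(self.dims) != 3 or any(d < 1 for d in self.dims):
            raise ValueError(f"dims must be three positive integers, got {self.dims}")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel sizes must be positive, got {self.voxel_size}")
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4) or abs(np.linalg.det(aff[:3, :3])) < 1e-12:
            raise ValueError("affine must be an invertible 4x4 matrix")
        object.__setattr__(self, "affine", aff)

    @classmethod
    def from_voxel_size(cls, dims, voxel_size) -> "VolumeGeometry":
        aff = np.diag([*voxel_size, 1.0])
        return cls(tuple(int(d) for d in dims), tuple(float(v) for v in voxel_size), aff)

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(ijk)
        return (self.affine[:3, :3] @ ijk.T).T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.atleast_2d(xyz)
        inv = np.linalg.inv(self.affine)
        return (inv[:3, :3] @ xyz.T).T + inv[:3, 3]

    def matches(self, other: "VolumeGeometry", atol: float = 1e-6) -> bool:
        return self.dims == other.dims and np.allclose(self.affine, other.affine, atol=atol)


@dataclass
class Bold4D:
    """A 4-D BOLD acquisition: (x, y, z, t) data plus repetition time in seconds."""

    geometry: VolumeGeometry
    data: np.ndarray  # shape (*dims, n_frames)
    tr: float

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("Bold4D data must be 4-dimensional")
        if self.data.shape[:3] != self.geometry.dims:
            raise ValueError("data shape does not match geometry dims")
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("BOLD data must be finite")

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]


@dataclass
class NuisanceSet:
    """Per-scan nuisance records: respiratory trace, 6 motion parameters, drift order."""

    respiration: np.ndarray  # (n_frames,)
    motion: np.ndarray  # (n_frames, 6)
    drift_order: int = 2

    def __post_init__(self):
        self.respiration = np.asarray(self.respiration, dtype=float).ravel()
        self.motion = np.asarray(self.motion, dtype=float)
        if self.motion.ndim != 2 or self.motion.shape[1] != 6:
            raise ValueError("motion must be (n_frames, 6)")
        if self.motion.shape[0] != self.respiration.shape[0]:
            raise ValueError("respiration and motion lengths differ")
        if self.drift_order not in (0, 1, 2):
            raise ValueError("drift_order must be 0, 1 or 2")

    @property
    def n_frames(self) -> int:
        return self.respiration.shape[0]


@dataclass
class DiffusionScheme:
    """Diffusion gradient table: b-values (s/mm^2) and unit gradient directions."""

    bvals: np.ndarray  # (n_volumes,)
    bvecs: np.ndarray  # (n_volumes, 3); zero rows for b=0

    def __post_init__(self):
        self.bvals = np.asarray(self.bvals, dtype=float).ravel()
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.bvecs.shape != (self.bvals.size, 3):
            raise ValueError("bvecs must be (n_volumes, 3) matching bvals")
        if np.any(self.bvals < 0):
            raise ValueError("b-values must be nonnegative")
        norms = np.linalg.norm(self.bvecs, axis=1)
        dwi = self.bvals > 0
        if np.any(norms[dwi] < 1e-12):
            raise ValueError("zero-norm gradient vector with positive b-value")
        # normalize DWI directions, zero out b0 rows
        self.bvecs = self.bvecs.copy()
        self.bvecs[dwi] /= norms[dwi, None]
        self.bvecs[~dwi] = 0.0
        if not np.any(~dwi):
            raise ValueError("scheme must contain at least one b=0 volume")

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0

    @property
    def n_volumes(self) -> int:
        return self.bvals.size


@dataclass
class AtlasLabels:
    """Integer ROI label volume (0 = background) with its ROI table.

    ``roi_table`` is a DataFrame indexed by label with columns
    ``name``, ``hemisphere`` and ``n_voxels``.
    """

    geometry: VolumeGeometry
    labels: np.ndarray
    roi_table: pd.DataFrame

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("label volume must be integer-typed")
        if self.labels.shape != self.geometry.dims:
            raise ValueError("label volume shape does not match geometry")
        present = np.unique(self.labels)
        present = present[present != 0]
        missing = set(present.tolist()) - set(self.roi_table.index.tolist())
        if missing:
            raise ValueError(f"labels {sorted(missing)} missing from roi_table")
        counts = pd.Series(self.labels[self.labels != 0].ravel()).value_counts()
        for lab in present:
            if int(self.roi_table.loc[lab, "n_voxels"]) != int(counts[lab]):
                raise ValueError(f"roi_table voxel count wrong for label {lab}")

    @property
    def roi_names(self) -> list[str]:
        return list(self.roi_table["name"])

    def label_of(self, name: str) -> int:
        hits = self.roi_table.index[self.roi_table["name"] == name]
        if len(hits) != 1:
            raise KeyError(f"ROI name {name!r} not unique or not found")
        return int(hits[0])

    def mask(self, name: str) -> np.ndarray:
        return self.labels == self.label_of(name)


def _geometry_from_img(img) -> VolumeGeometry:
    zooms = img.header.get_zooms()[:3]
    return VolumeGeometry(tuple(int(d) for d in img.shape[:3]),
                          tuple(float(z) for z in zooms),
                          np.asarray(img.affine, dtype=float))


def read_volume(path, expected_frames: int | None = None, *,
                labels: bool = False, tr: float | None = None):
    """Read a NIfTI image.

    Returns an :class:`AtlasLabels` skeleton (``labels=True``), a
    :class:`Bold4D` (4-D data; ``tr`` taken from the header pixdim[4] unless
    given), or a bare ``(geometry, data)`` pair for 3-D scalar images and
    diffusion stacks.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    geom = _geometry_from_img(img)
    data = np.asarray(img.dataobj)
    if expected_frames is not None:
        n = data.shape[3] if data.ndim == 4 else 1
        if n != expected_frames:
            raise ValueError(f"expected {expected_frames} frames, file has {n}")
    if labels:
        if data.ndim != 3:
            raise ValueError("label image must be 3-D")
        if not np.allclose(data, np.round(data)):
            raise ValueError("label image contains non-integer values")
        lab = data.astype(np.int32)
        present = np.unique(lab)
        present = present[present != 0]
        counts = {int(v): int(np.sum(lab == v)) for v in present}
        table = pd.DataFrame(
            {"name": [f"roi{v}" for v in counts],
             "hemisphere": ["both"] * len(counts),
             "n_voxels": list(counts.values())},
            index=pd.Index(list(counts.keys()), name="label"),
        )
        return AtlasLabels(geom, lab, table)
    if data.ndim == 4 and tr is not None:
        return Bold4D(geom, data.astype(float), tr=tr)
    if data.ndim == 4:
        header_tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 0.0
        if header_tr > 0:
            return Bold4D(geom, data.astype(float), tr=header_tr)
        return geom, data.astype(float)
    return geom, data.astype(float)


def write_volume(path, geometry: VolumeGeometry, data: np.ndarray,
                 tr: float | None = None) -> None:
    data = np.asarray(data)
    img = nib.Nifti1Image(data, geometry.affine)
    zooms = list(geometry.voxel_size)
    if data.ndim == 4:
        zooms.append(tr if tr is not None else 1.0)
    img.header.set_zooms(tuple(zooms))
    nib.save(img, str(path))


def read_diffusion_scheme(bval_path, bvec_path) -> DiffusionScheme:
    """Read FSL-style bval/bvec text files.

    bvec may be 3xN (FSL) or Nx3; disambiguated by shape.
    """
    bvals = np.loadtxt(bval_path, dtype=float).ravel()
    bvecs = np.atleast_2d(np.loadtxt(bvec_path, dtype=float))
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    elif bvecs.shape[0] == 3 and bvecs.shape[1] == 3:
        pass  # ambiguous 3x3: treat rows as entries
    if bvecs.shape[1] != 3 or bvecs.shape[0] != bvals.size:
        raise ValueError(
            f"bval/bvec length mismatch: {bvals.size} b-values, {bvecs.shape[0]} vectors")
    return DiffusionScheme(bvals, bvecs)


def write_diffusion_scheme(scheme: DiffusionScheme, bval_path, bvec_path) -> None:
    np.savetxt(bval_path, scheme.bvals[None, :], fmt="%.6g")
    np.savetxt(bvec_path, scheme.bvecs.T, fmt="%.17g")


def write_matrix_table(matrix: np.ndarray, roi_names, path) -> None:
    """Write a square ROI matrix as CSV with names on both axes; NaN -> ``NA``."""
    matrix = np.asarray(matrix, dtype=float)
    names = list(roi_names)
    if matrix.shape != (len(names), len(names)):
        raise ValueError("matrix dimension does not match number of ROI names")
    if len(set(names)) != len(names):
        raise ValueError("duplicate ROI names")
    df = pd.DataFrame(matrix, index=names, columns=names)
    df.to_csv(path, na_rep=MISSING_TOKEN, float_format="%.17g")


def read_matrix_table(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, index_col=0, na_values=[MISSING_TOKEN], keep_default_na=False)
    names = [str(c) for c in df.columns]
    if [str(i) for i in df.index] != names:
        raise ValueError("matrix table rows and columns disagree")
    return df.to_numpy(dtype=float), names
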