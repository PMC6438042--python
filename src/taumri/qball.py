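"""Analytic Q-ball reconstruction: regularized spherical-harmonic fit of the
single-shell signal, Funk-Radon transform to the diffusion ODF, and peak /
QA extraction on an icosahedral tessellation mesh.

Method outline, per voxel:

1. normalize the diffusion-weighted signal by the mean b0;
2. fit real, even-order spherical-harmonic coefficients (max order L,
   default 8 -> 45 coefficients) by least squares with a Laplace-Beltrami
   smoothness penalty ``lambda * sum l^2 (l+1)^2 c_lm^2`` (default
   lambda = 0.006);
3. obtain the ODF analytically through the Funk-Radon transform, which
   scales each order-l coefficient by ``2 pi P_l(0)`` (Legendre polynomial
   at zero); odd orders are implicitly zero, so the ODF is antipodally
   symmetric by construction;
4. sample the ODF on a subdivided icosahedron (3 subdivisions = 642
   vertices, the classic 8-fold tessellation), find mesh-local maxima,
   refine each by a tangent-plane quadratic fit, and define quantitative
   anisotropy QA(peak) = ODF(peak) - min(ODF), normalized to [0, 1] by the
   largest such value in the mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.special import eval_legendre, sph_harm_y

from .io import DiffusionScheme, VolumeGeometry

__all__ = [
    "sh_degrees",
    "real_sh_basis",
    "laplace_beltrami_weights",
    "fit_sh_coefficients",
    "funk_radon_coefficients",
    "ODFField",
    "OdfMesh",
    "PeakField",
    "make_odf_mesh",
    "fit_qball_odf",
    "evaluate_odf_peaks",
]


# --------------------------------------------------------------------------
# real even spherical-harmonic basis

def sh_degrees(max_order: int) -> tuple[np.ndarray, np.ndarray]:
    """(l, m) index arrays of the real even-order basis up to ``max_order``."""
    ls, ms = [], []
    for l in range(0, max_order + 1, 2):
        for m in range(-l, l + 1):
            ls.append(l)
            ms.append(m)
    return np.array(ls), np.array(ms)


def real_sh_basis(max_order: int, dirs: np.ndarray) -> np.ndarray:
    """Real even SH design matrix, rows = unit directions, columns = (l, m).

    Real basis from the complex harmonics: sqrt(2) Im(Y_l^|m|) for m < 0,
    Y_l^0 for m = 0, sqrt(2) Re(Y_l^m) for m > 0 (orthonormal on the
    sphere)."""
    dirs = np.atleast_2d(np.asarray(dirs, dtype=float))
    theta = np.arccos(np.clip(dirs[:, 2], -1.0, 1.0))  # polar
    phi = np.arctan2(dirs[:, 1], dirs[:, 0])           # azimuth
    ls, ms = sh_degrees(max_order)
    basis = np.empty((dirs.shape[0], ls.size))
    for j, (l, m) in enumerate(zip(ls, ms)):
        y = sph_harm_y(l, abs(m), theta, phi)
        if m < 0:
            basis[:, j] = np.sqrt(2.0) * y.imag
        elif m == 0:
            basis[:, j] = y.real
        else:
            basis[:, j] = np.sqrt(2.0) * y.real
    return basis


def laplace_beltrami_weights(max_order: int) -> np.ndarray:
    """Diagonal of the Laplace-Beltrami penalty: l^2 (l+1)^2 per coefficient."""
    ls, _ = sh_degrees(max_order)
    return (ls * (ls + 1.0)) ** 2


def fit_sh_coefficients(signal: np.ndarray, dirs: np.ndarray,
                        max_order: int = 8, lam: float = 0.006) -> np.ndarray:
    """Regularized least-squares SH fit: c = (B'B + lam*L)^-1 B' s.

    ``signal`` may be (n_dirs,) or (n_samples, n_dirs)."""
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    b = real_sh_basis(max_order, dirs)
    n_coef = b.shape[1]
    if dirs.shape[0] < n_coef:
        raise ValueError(f"need >= {n_coef} directions for order {max_order}")
    reg = np.diag(lam * laplace_beltrami_weights(max_order))
    solver = np.linalg.solve(b.T @ b + reg, b.T)
    signal = np.asarray(signal, dtype=float)
    return (solver @ signal.T).T


def funk_radon_coefficients(max_order: int) -> np.ndarray:
    """Funk-Radon transform eigenvalues 2 pi P_l(0) per coefficient."""
    ls, _ = sh_degrees(max_order)
    return 2.0 * np.pi * eval_legendre(ls, 0.0)


# --------------------------------------------------------------------------
# containers

@dataclass
class ODFField:
    """Per-voxel ODF spherical-harmonic coefficients (post Funk-Radon)."""

    geometry: VolumeGeometry
    coefficients: np.ndarray  # (*dims, n_coef)
    max_order: int
    lam: float
    mask: np.ndarray  # bool (*dims)

    def __post_init__(self):
        n_coef = (self.max_order + 1) * (self.max_order + 2) // 2
        if self.coefficients.shape != (*self.geometry.dims, n_coef):
            raise ValueError("coefficient array shape mismatch")
        if self.lam < 0:
            raise ValueError("lambda must be nonnegative")


@dataclass
class OdfMesh:
    """Subdivided icosahedral direction set with vertex adjacency.

    ``vertices`` covers the full sphere (antipodal pairs present);
    ``hemisphere`` indexes one representative of each pair."""

    vertices: np.ndarray        # (n, 3) unit
    neighbors: list             # vertex index -> neighbor indices
    hemisphere: np.ndarray      # indices into vertices
    subdivisions: int

    @property
    def n_hemisphere(self) -> int:
        return self.hemisphere.size


def make_odf_mesh(subdivisions: int = 3) -> OdfMesh:
    """Icosphere mesh; 3 subdivisions give 642 vertices (321 per hemisphere),
    the 8-fold tessellated icosahedron."""
    mesh = trimesh.creation.icosphere(subdivisions=subdivisions)
    verts = np.asarray(mesh.vertices, dtype=float)
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    neigh = [[] for _ in range(len(verts))]
    for a, b, c in mesh.faces:
        for u, v in ((a, b), (b, c), (c, a)):
            neigh[u].append(v)
            neigh[v].append(u)
    neigh = [sorted(set(n)) for n in neigh]
    eps = 1e-9
    hemi = np.flatnonzero(
        (verts[:, 2] > eps)
        | ((np.abs(verts[:, 2]) <= eps) & (verts[:, 0] > eps))
        | ((np.abs(verts[:, 2]) <= eps) & (np.abs(verts[:, 0]) <= eps) & (verts[:, 1] > 0)))
    return OdfMesh(verts, neigh, hemi, subdivisions)


@dataclass
class PeakField:
    """Up to K ODF peaks per voxel, sorted by descending QA."""

    geometry: VolumeGeometry
    directions: np.ndarray   # (*dims, K, 3); zero rows where absent
    qa: np.ndarray           # (*dims, K); normalized to [0, 1] over the mask
    odf_value: np.ndarray    # (*dims, K)
    n_peaks: np.ndarray      # (*dims,) int
    mask: np.ndarray

    @property
    def qa_volume(self) -> np.ndarray:
        """Top-peak QA per voxel (0 where no peaks)."""
        return self.qa[..., 0]


# --------------------------------------------------------------------------
# reconstruction

def fit_qball_odf(dwi: np.ndarray, scheme: DiffusionScheme,
                  geometry: VolumeGeometry, max_order: int = 8,
                  lam: float = 0.006, mask: np.ndarray | None = None) -> ODFField:
    """Analytic Q-ball reconstruction of a 4-D diffusion stack."""
    dwi = np.asarray(dwi, dtype=float)
    if dwi.shape != (*geometry.dims, scheme.n_volumes):
        raise ValueError("dwi shape does not match geometry/scheme")
    if mask is None:
        mask = np.ones(geometry.dims, dtype=bool)
    b0 = dwi[..., scheme.b0_mask].mean(axis=-1)
    if np.any(b0[mask] <= 0):
        raise ValueError("non-positive mean b0 signal inside the mask")
    dirs = scheme.bvecs[~scheme.b0_mask]
    signal = dwi[..., ~scheme.b0_mask][mask] / b0[mask][:, None]
    coef = fit_sh_coefficients(signal, dirs, max_order, lam)
    coef *= funk_radon_coefficients(max_order)
    n_coef = coef.shape[1]
    out = np.zeros((*geometry.dims, n_coef))
    out[mask] = coef
    return ODFField(geometry, out, max_order, lam, mask)


def _refine_peak(mesh: OdfMesh, values: np.ndarray, idx: int):
    """Tangent-plane quadratic refinement of a mesh peak.

    Gnomonic-projects the peak vertex and its neighbors onto the tangent
    plane, fits a 2-D quadratic, and returns the stationary point if it is
    a nearby maximum; falls back to the mesh vertex otherwise."""
    v = mesh.vertices[idx]
    nb = mesh.neighbors[idx]
    pts = mesh.vertices[[idx] + list(nb)]
    vals = values[[idx] + list(nb)]
    # tangent basis
    ref = np.array([1.0, 0, 0]) if abs(v[0]) < 0.9 else np.array([0, 1.0, 0])
    e1 = np.cross(v, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(v, e1)
    proj = pts / (pts @ v)[:, None]  # gnomonic projection
    u = proj @ e1
    w = proj @ e2
    design = np.column_stack([np.ones_like(u), u, w, u * u, u * w, w * w])
    coef, *_ = np.linalg.lstsq(design, vals, rcond=None)
    a0, b1, b2, c11, c12, c22 = coef
    hess = np.array([[2 * c11, c12], [c12, 2 * c22]])
    if np.linalg.det(hess) <= 0 or hess[0, 0] >= 0:
        return v, values[idx]
    step = np.linalg.solve(hess, -np.array([b1, b2]))
    max_step = np.max(np.hypot(u, w))
    if np.hypot(*step) > max_step:
        return v, values[idx]
    refined = v + step[0] * e1 + step[1] * e2
    refined /= np.linalg.norm(refined)
    value = float(a0 + b1 * step[0] + b2 * step[1]
                  + c11 * step[0] ** 2 + c12 * step[0] * step[1] + c22 * step[1] ** 2)
    return refined, value


def evaluate_odf_peaks(odf: ODFField, mesh: OdfMesh | None = None,
                       max_peaks: int = 3, refine: bool = True,
                       rel_tol: float = 1e-10) -> PeakField:
    """Sample each voxel's ODF on the mesh, keep strict local maxima over the
    mesh adjacency (one representative per antipodal pair), refine them, and
    attach QA values normalized over the mask."""
    mesh = mesh or make_odf_mesh()
    if not np.any(odf.mask):
        raise ValueError("empty mask")
    dims = odf.geometry.dims
    basis = real_sh_basis(odf.max_order, mesh.vertices)
    flat_mask = odf.mask.reshape(-1)
    coef = odf.coefficients.reshape(-1, odf.coefficients.shape[-1])
    k = max_peaks
    directions = np.zeros((flat_mask.size, k, 3))
    qa = np.zeros((flat_mask.size, k))
    odfval = np.zeros((flat_mask.size, k))
    n_peaks = np.zeros(flat_mask.size, dtype=int)

    # neighbor table as padded array for vectorized local-max detection
    max_deg = max(len(n) for n in mesh.neighbors)
    nb_idx = np.zeros((len(mesh.vertices), max_deg), dtype=int)
    nb_valid = np.zeros((len(mesh.vertices), max_deg), dtype=bool)
    for i, nb in enumerate(mesh.neighbors):
        nb_idx[i, :len(nb)] = nb
        nb_valid[i, :len(nb)] = True

    voxels = np.flatnonzero(flat_mask)
    values_all = coef[voxels] @ basis.T  # (n_vox, n_verts)
    hemi = mesh.hemisphere
    for row, vox in enumerate(voxels):
        vals = values_all[row]
        scale = np.max(np.abs(vals)) or 1.0
        nb_vals = np.where(nb_valid, vals[nb_idx], -np.inf)
        is_peak = vals > nb_vals.max(axis=1) + rel_tol * scale
        cand = [i for i in hemi if is_peak[i]]
        if not cand:
            continue
        peaks = []
        for i in cand:
            if refine:
                d, v = _refine_peak(mesh, vals, i)
            else:
                d, v = mesh.vertices[i], vals[i]
            peaks.append((v, d))
        peaks.sort(key=lambda t: -t[0])
        floor = float(vals.min())
        for j, (v, d) in enumerate(peaks[:k]):
            directions[vox, j] = d
            odfval[vox, j] = v
            qa[vox, j] = max(v - floor, 0.0)
        n_peaks[vox] = min(len(peaks), k)

    qa_max = qa.max()
    if qa_max > 0:
        qa /= qa_max
    return PeakField(odf.geometry,
                     directions.reshape(*dims, k, 3),
                     qa.reshape(*dims, k),
                     odfval.reshape(*dims, k),
                     n_peaks.reshape(dims),
                     odf.mask)
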