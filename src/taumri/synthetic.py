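"""Synthetic study cohorts and diffusion phantoms with known ground truth.

The BOLD generator emulates the study design this pipeline targets: three
groups (pro-aggregant, anti-aggregant transgenics and wildtype littermates,
n = 8/8/7) scanned at two time points (baseline with the transgene ON, and
after eight weeks of doxycycline switch-off), where transgenic baseline
functional connectivity is scaled down (default 0.5, i.e. roughly half the
control strength) and recovers to full strength after treatment.

Latent ROI signals are band-limited (0.01-0.08 Hz) Gaussian series whose
*sample* correlation matrix equals the target exactly: band-limited white
noise is ZCA-whitened on its realized covariance and then mixed with a
symmetric PSD square root of the target matrix.  Voxel-level white noise,
polynomial drifts, a respiratory sinusoid and motion-coupled fluctuations
are added on top and returned as the matching :class:`~taumri.io.NuisanceSet`.

Diffusion phantoms use the standard multi-tensor signal model
``S(g) = S0 * sum_k f_k exp(-b g^T D_k g)`` with Rician noise, on the
single-shell b = 2000 s/mm^2, 126 half-sphere-direction scheme (8 b0
volumes interleaved) that the functional counterpart of this pipeline pairs
with.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import AtlasLabels, Bold4D, DiffusionScheme, NuisanceSet, VolumeGeometry

__all__ = [
    "BoldNoiseSpec",
    "SyntheticStudySpec",
    "PhantomSpec",
    "CohortEntry",
    "make_block_atlas",
    "default_base_corr",
    "default_study_spec",
    "scale_off_diagonal",
    "band_limited_latents",
    "simulate_bold_dataset",
    "simulate_study_cohort",
    "make_qball_scheme",
    "straight_tube_phantom",
    "crossing_phantom",
    "isotropic_phantom",
    "simulate_dwi_phantom",
]


# --------------------------------------------------------------------------
# atlas construction

def make_block_atlas(n_rois: int, roi_shape=(3, 3, 2), layout=None, gap: int = 2,
                     roi_names=None, hemispheres=None) -> AtlasLabels:
    """Grid of disjoint rectangular ROIs; stands in for a coregistered atlas.

    Blocks are separated by ``gap`` background voxels so that sub-voxel
    spatial smoothing cannot leak signal between ROIs.
    """
    if layout is None:
        nx = int(np.ceil(np.sqrt(n_rois)))
        ny = int(np.ceil(n_rois / nx))
        layout = (nx, ny, 1)
    if int(np.prod(layout)) < n_rois:
        raise ValueError(f"layout {layout} cannot hold {n_rois} ROIs")
    bx, by, bz = roi_shape
    dims = (layout[0] * (bx + gap) + gap,
            layout[1] * (by + gap) + gap,
            layout[2] * (bz + gap) + gap)
    geom = VolumeGeometry.from_voxel_size(dims, (0.182, 0.182, 0.5))
    labels = np.zeros(dims, dtype=np.int32)
    lab = 0
    for k in range(layout[2]):
        for j in range(layout[1]):
            for i in range(layout[0]):
                if lab >= n_rois:
                    break
                lab += 1
                x0 = gap + i * (bx + gap)
                y0 = gap + j * (by + gap)
                z0 = gap + k * (bz + gap)
                block = labels[x0:x0 + bx, y0:y0 + by, z0:z0 + bz]
                if block.shape != (bx, by, bz):
                    raise ValueError("blocks exceed volume bounds")
                if np.any(block != 0):
                    raise ValueError("blocks would overlap")
                block[...] = lab
    names = list(roi_names) if roi_names is not None else [f"roi{i+1}" for i in range(n_rois)]
    hemi = list(hemispheres) if hemispheres is not None else ["both"] * n_rois
    table = pd.DataFrame(
        {"name": names, "hemisphere": hemi, "n_voxels": [bx * by * bz] * n_rois},
        index=pd.Index(range(1, n_rois + 1), name="label"))
    return AtlasLabels(geom, labels, table)


# --------------------------------------------------------------------------
# study specification

@dataclass
class BoldNoiseSpec:
    """Amplitudes of the non-neural signal components, in units of the
    latent network signal SD (which is 1)."""

    sigma_voxel: float = 0.5        # white thermal noise per voxel
    drift_amp: tuple = (0.5, 0.25)  # SD of random linear / quadratic drift
    resp_freq: float = 0.12         # apparent (sampled) respiratory frequency, Hz
    resp_amp: float = 0.5
    motion_amp: float = 0.1         # voxel coupling SD to motion traces


# Paper-style functional node vocabulary: memory, sensorimotor and default
# mode network modules (hemisphere-independent labels).
DEFAULT_ROI_NAMES = [
    "Hp", "Th", "CPu", "GP", "HyTh",              # memory / subcortical
    "M1", "M2", "S1", "S2", "AC", "VC",           # sensorimotor
    "Cg", "PrL", "RSD", "RSG", "MO",              # default mode network
]
_MODULES = [list(range(0, 5)), list(range(5, 11)), list(range(11, 16))]


def default_base_corr(n_rois: int = 16, within: float = 0.6, between: float = 0.25) -> np.ndarray:
    """Modular target correlation matrix: three functional networks with
    stronger within- than between-network coupling."""
    modules = _MODULES if n_rois == 16 else None
    c = np.full((n_rois, n_rois), between)
    if modules is None:
        k = int(np.ceil(n_rois / 3))
        modules = [list(range(i, min(i + k, n_rois))) for i in range(0, n_rois, k)]
    for mod in modules:
        ix = np.ix_(mod, mod)
        c[ix] = within
    np.fill_diagonal(c, 1.0)
    if np.min(np.linalg.eigvalsh(c)) < -1e-10:
        raise ValueError("base correlation matrix is not PSD")
    return c


@dataclass
class SyntheticStudySpec:
    """Generative description of the 3-group x 2-time-point cohort."""

    groups: dict          # name -> (scale at baseline, scale after treatment)
    n_subjects: dict      # name -> count
    base_corr: np.ndarray
    noise: BoldNoiseSpec = field(default_factory=BoldNoiseSpec)
    tr: float = 2.84
    n_frames: int = 105
    band: tuple = (0.01, 0.08)
    master_seed: int = 0

    def __post_init__(self):
        self.base_corr = np.asarray(self.base_corr, dtype=float)
        c = self.base_corr
        if not np.allclose(c, c.T) or not np.allclose(np.diag(c), 1.0):
            raise ValueError("base_corr must be symmetric with unit diagonal")
        if np.min(np.linalg.eigvalsh(c)) < -1e-10:
            raise ValueError("base_corr must be positive semidefinite")
        for g, (s1, s2) in self.groups.items():
            for s in (s1, s2):
                if not (0 < s <= 1):
                    raise ValueError(f"scale factors must be in (0,1], got {s} for {g}")
        if any(n < 1 for n in self.n_subjects.values()):
            raise ValueError("n_subjects must be >= 1")


def default_study_spec(master_seed: int = 0, n_frames: int = 105,
                       n_rois: int = 16, transgenic_scale: float = 0.5,
                       n_subjects=(8, 8, 7)) -> SyntheticStudySpec:
    """The study conditions: pro/anti-aggregant baselines at half strength,
    full recovery after switch-off; wildtype controls unchanged."""
    return SyntheticStudySpec(
        groups={"pro": (transgenic_scale, 1.0),
                "anti": (transgenic_scale, 1.0),
                "control": (1.0, 1.0)},
        n_subjects={"pro": n_subjects[0], "anti": n_subjects[1], "control": n_subjects[2]},
        base_corr=default_base_corr(n_rois),
        tr=2.84, n_frames=n_frames, master_seed=master_seed)


def scale_off_diagonal(corr: np.ndarray, scale: float) -> np.ndarray:
    """Multiply off-diagonal correlations by ``scale``.

    Equals the convex combination ``scale*C + (1-scale)*I``, hence PSD is
    preserved for any scale in (0, 1].
    """
    out = scale * corr + (1.0 - scale) * np.eye(corr.shape[0])
    return out


# --------------------------------------------------------------------------
# BOLD simulation

def band_limited_latents(n_series: int, n_frames: int, tr: float, band,
                         rng: np.random.Generator) -> np.ndarray:
    """Gaussian series with all spectral power inside ``band`` (Hz),
    zero mean, empirically whitened (sample covariance = identity)."""
    low, high = band
    freqs = np.fft.rfftfreq(n_frames, d=tr)
    keep = (freqs >= low) & (freqs <= high)
    n_bins = int(np.sum(keep))
    if 2 * n_bins <= n_series:
        raise ValueError("too few in-band frequency bins to whiten these series")
    x = rng.standard_normal((n_series, n_frames))
    spec = np.fft.rfft(x, axis=1)
    spec[:, ~keep] = 0.0
    x = np.fft.irfft(spec, n=n_frames, axis=1)
    x -= x.mean(axis=1, keepdims=True)
    cov = (x @ x.T) / (n_frames - 1)
    evals, evecs = np.linalg.eigh(cov)
    if np.min(evals) < 1e-12:
        raise ValueError("degenerate realized covariance")
    zca = evecs @ np.diag(evals ** -0.5) @ evecs.T
    return zca @ x


def _psd_sqrt(corr: np.ndarray) -> np.ndarray:
    evals, evecs = np.linalg.eigh(corr)
    if np.min(evals) < -1e-10:
        raise ValueError("correlation matrix is not PSD")
    return evecs @ np.diag(np.sqrt(np.clip(evals, 0, None))) @ evecs.T


def _smoothed_walk(n: int, rng: np.random.Generator, width: int = 9) -> np.ndarray:
    w = np.cumsum(rng.standard_normal(n))
    kernel = np.ones(width) / width
    pad = np.pad(w, (width, width), mode="edge")
    s = np.convolve(pad, kernel, mode="same")[width:-width]
    s -= s.mean()
    sd = s.std()
    return s / sd if sd > 0 else s


def simulate_bold_dataset(atlas: AtlasLabels, corr: np.ndarray,
                          noise: BoldNoiseSpec | None = None,
                          tr: float = 2.84, n_frames: int = 105,
                          seed=0, band=(0.01, 0.08)):
    """Simulate one BOLD session over ``atlas`` with latent inter-ROI sample
    correlations exactly equal to ``corr``.

    Returns ``(Bold4D, NuisanceSet, truth)`` where ``truth`` records the
    latent ROI series and the target matrix.
    """
    if n_frames < 10:
        raise ValueError("n_frames must be >= 10")
    corr = np.asarray(corr, dtype=float)
    n_rois = len(atlas.roi_table)
    if corr.shape != (n_rois, n_rois):
        raise ValueError("corr dimension does not match atlas ROI count")
    noise = noise or BoldNoiseSpec()
    rng = np.random.default_rng(seed)

    latent = _psd_sqrt(corr) @ band_limited_latents(n_rois, n_frames, tr, band, rng)

    t = np.arange(n_frames, dtype=float) / (n_frames - 1)  # 0..1
    respiration = np.sin(2 * np.pi * noise.resp_freq * tr * np.arange(n_frames))
    motion = np.column_stack([_smoothed_walk(n_frames, rng) for _ in range(6)])

    dims = atlas.geometry.dims
    n_vox = int(np.prod(dims))
    flat_labels = atlas.labels.reshape(-1)
    data = rng.standard_normal((n_vox, n_frames)) * noise.sigma_voxel
    # network signal shared by all voxels of an ROI
    for k, lab in enumerate(atlas.roi_table.index):
        data[flat_labels == lab] += latent[k]
    # per-voxel polynomial drift (orders 1..2), respiratory and motion coupling
    drift_basis = np.vstack([t - t.mean(), (t - t.mean()) ** 2])
    drift_coef = rng.standard_normal((n_vox, 2)) * np.asarray(noise.drift_amp)
    data += drift_coef @ drift_basis
    data += (1.0 + 0.2 * rng.standard_normal(n_vox))[:, None] * noise.resp_amp * respiration
    motion_coef = rng.standard_normal((n_vox, 6)) * noise.motion_amp
    data += motion_coef @ motion.T

    bold = Bold4D(atlas.geometry, data.reshape(*dims, n_frames), tr=tr)
    nuis = NuisanceSet(respiration=respiration, motion=motion, drift_order=2)
    truth = {"latent": latent, "corr_target": corr,
             "roi_order": atlas.roi_names, "seed": seed}
    return bold, nuis, truth


@dataclass
class CohortEntry:
    subject_id: str
    group: str
    timepoint: int  # 0 = baseline, 1 = after treatment
    bold: Bold4D
    nuisance: NuisanceSet
    truth: dict


def simulate_study_cohort(spec: SyntheticStudySpec, atlas: AtlasLabels) -> list[CohortEntry]:
    """Simulate the full cohort: every subject of every group at both time
    points, with the group/time connectivity scaling applied to the
    off-diagonal of the base matrix.  Deterministic in ``spec.master_seed``."""
    entries = []
    for gi, (group, (s1, s2)) in enumerate(sorted(spec.groups.items())):
        n = spec.n_subjects[group]
        for si in range(n):
            for tp, scale in enumerate((s1, s2)):
                scaled = scale_off_diagonal(spec.base_corr, scale)
                if np.min(np.linalg.eigvalsh(scaled)) < -1e-10:
                    raise ValueError(f"scaled matrix not PSD for {group} t{tp}")
                ss = np.random.SeedSequence([spec.master_seed, gi, si, tp])
                bold, nuis, truth = simulate_bold_dataset(
                    atlas, scaled, spec.noise, spec.tr, spec.n_frames,
                    seed=ss, band=spec.band)
                truth["scale"] = scale
                entries.append(CohortEntry(f"{group}{si+1:02d}", group, tp, bold, nuis, truth))
    return entries


# --------------------------------------------------------------------------
# diffusion scheme + phantoms

def make_qball_scheme(n_dirs: int = 126, n_b0: int = 8, bval: float = 2000.0) -> DiffusionScheme:
    """Single-shell half-sphere scheme: ``n_dirs`` Fibonacci-spiral directions
    on a hemisphere at ``bval`` with ``n_b0`` b0 volumes evenly interleaved
    (one preceding each block, mirroring acquisition in separate scans)."""
    i = np.arange(n_dirs)
    z = (i + 0.5) / n_dirs  # upper hemisphere
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(1 - z ** 2)
    dirs = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    # split into n_b0 blocks, b0 before each
    splits = np.array_split(np.arange(n_dirs), n_b0)
    bvals, bvecs = [], []
    for blk in splits:
        bvals.append(0.0)
        bvecs.append([0.0, 0.0, 0.0])
        for j in blk:
            bvals.append(bval)
            bvecs.append(dirs[j])
    return DiffusionScheme(np.array(bvals), np.array(bvecs))


@dataclass
class PhantomSpec:
    """Known-geometry diffusion phantom: fiber bundles as voxel masks with a
    single direction each, isotropic background, optional endpoint ROIs."""

    kind: str                      # straight_tube | crossing | isotropic
    geometry: VolumeGeometry
    fiber_dirs: np.ndarray         # (n_bundles, 3) unit vectors
    bundle_masks: list             # list of bool volumes, one per bundle
    d_axial: float = 1.7e-3        # mm^2/s
    d_radial: float = 0.3e-3
    d_iso: float = 2.0e-3
    snr: float | None = None       # None => noiseless
    s0: float = 100.0
    atlas: AtlasLabels | None = None

    def __post_init__(self):
        self.fiber_dirs = np.atleast_2d(np.asarray(self.fiber_dirs, dtype=float))
        norms = np.linalg.norm(self.fiber_dirs, axis=1)
        if self.fiber_dirs.size and not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("fiber directions must be unit length")
        if self.snr is not None and self.snr <= 0:
            raise ValueError("snr must be positive")
        for m in self.bundle_masks:
            if m.shape != self.geometry.dims:
                raise ValueError("bundle mask outside volume bounds")


def _tube_geometry(n_long: int, cross: int, pad: int, voxel_mm: float):
    dims = (n_long + 2 * pad, cross + 2 * pad, cross + 2 * pad)
    return VolumeGeometry.from_voxel_size(dims, (voxel_mm,) * 3)


def straight_tube_phantom(length_mm: float = 20.0, voxel_mm: float = 0.5,
                          cross: int = 3, pad: int = 3, snr=None,
                          with_endpoint_rois: bool = True) -> PhantomSpec:
    """A single straight bundle along +x of the given physical length."""
    n_long = int(round(length_mm / voxel_mm))
    geom = _tube_geometry(n_long, cross, pad, voxel_mm)
    mask = np.zeros(geom.dims, dtype=bool)
    mask[pad:pad + n_long, pad:pad + cross, pad:pad + cross] = True
    atlas = None
    if with_endpoint_rois:
        labels = np.zeros(geom.dims, dtype=np.int32)
        end = max(1, int(round(1.0 / voxel_mm)))  # ~1 mm end caps
        labels[pad:pad + end, pad:pad + cross, pad:pad + cross] = 1
        labels[pad + n_long - end:pad + n_long, pad:pad + cross, pad:pad + cross] = 2
        table = pd.DataFrame({"name": ["endA", "endB"], "hemisphere": ["both"] * 2,
                              "n_voxels": [int(np.sum(labels == 1)), int(np.sum(labels == 2))]},
                             index=pd.Index([1, 2], name="label"))
        atlas = AtlasLabels(geom, labels, table)
    return PhantomSpec("straight_tube", geom, np.array([[1.0, 0, 0]]), [mask],
                       snr=snr, atlas=atlas)


def crossing_phantom(length_mm: float = 20.0, voxel_mm: float = 0.5,
                     cross: int = 3, pad: int = 3, snr=None) -> PhantomSpec:
    """Two orthogonal in-plane bundles (x and y) crossing at 90 degrees."""
    n_long = int(round(length_mm / voxel_mm))
    side = n_long + 2 * pad
    geom = VolumeGeometry.from_voxel_size((side, side, cross + 2 * pad), (voxel_mm,) * 3)
    mid = side // 2 - cross // 2
    mx = np.zeros(geom.dims, dtype=bool)
    mx[pad:pad + n_long, mid:mid + cross, pad:pad + cross] = True
    my = np.zeros(geom.dims, dtype=bool)
    my[mid:mid + cross, pad:pad + n_long, pad:pad + cross] = True
    return PhantomSpec("crossing", geom,
                       np.array([[1.0, 0, 0], [0, 1.0, 0]]), [mx, my], snr=snr)


def isotropic_phantom(dims=(5, 5, 5), voxel_mm: float = 0.5, snr=None) -> PhantomSpec:
    geom = VolumeGeometry.from_voxel_size(dims, (voxel_mm,) * 3)
    return PhantomSpec("isotropic", geom, np.empty((0, 3)), [], snr=snr)


def simulate_dwi_phantom(spec: PhantomSpec, scheme: DiffusionScheme, seed=0):
    """Multi-tensor diffusion signal over the phantom, with Rician noise at
    the stated SNR (relative to S0).  Returns ``(dwi 4-D stack, truth)``;
    ``truth['dirs']`` maps flat voxel index -> list of true directions."""
    rng = np.random.default_rng(seed)
    dims = spec.geometry.dims
    n_vol = scheme.n_volumes
    dwi = np.zeros((*dims, n_vol))
    membership = np.zeros((len(spec.bundle_masks), *dims), dtype=bool)
    for k, m in enumerate(spec.bundle_masks):
        membership[k] = m
    n_bundles = membership.sum(axis=0)  # bundles per voxel

    iso_sig = np.exp(-scheme.bvals * spec.d_iso)
    iso_sig[scheme.b0_mask] = 1.0
    bundle_sig = []
    for k in range(len(spec.bundle_masks)):
        adc = spec.d_radial + (spec.d_axial - spec.d_radial) * (scheme.bvecs @ spec.fiber_dirs[k]) ** 2
        sig = np.exp(-scheme.bvals * adc)
        sig[scheme.b0_mask] = 1.0
        bundle_sig.append(sig)

    # background isotropic
    dwi[...] = iso_sig
    # bundle voxels: equal-fraction mixture over member bundles
    if len(spec.bundle_masks):
        any_bundle = n_bundles > 0
        acc = np.zeros((*dims, n_vol))
        for k in range(len(spec.bundle_masks)):
            acc[membership[k]] += bundle_sig[k]
        dwi[any_bundle] = acc[any_bundle] / n_bundles[any_bundle, None]
    dwi *= spec.s0

    if spec.snr is not None:
        sigma = spec.s0 / spec.snr
        n1 = rng.standard_normal(dwi.shape) * sigma
        n2 = rng.standard_normal(dwi.shape) * sigma
        dwi = np.sqrt((dwi + n1) ** 2 + n2 ** 2)

    truth = {"dirs": {}, "spec": spec}
    if len(spec.bundle_masks):
        flat = membership.reshape(len(spec.bundle_masks), -1)
        for v in np.flatnonzero(flat.any(axis=0)):
            truth["dirs"][int(v)] = [spec.fiber_dirs[k] for k in range(flat.shape[0]) if flat[k, v]]
    return dwi, truth
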