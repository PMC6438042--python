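"""End-to-end workflows tying the modules together.

These are the compositions the analysis drivers and the acceptance checks
run: simulate -> preprocess -> connectivity -> statistics -> slopes for the
functional arm, and phantom -> Q-ball -> tracking -> fiber density for the
diffusion arm.  Both are pure functions of their seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fc import ConnMatrix, connectivity_matrix, extract_roi_timeseries, group_average_matrix
from .io import AtlasLabels
from .longitudinal import SlopeFit, origin_slope_fit
from .preproc import PreprocConfig, preprocess_bold
from .qball import evaluate_odf_peaks, fit_qball_odf, make_odf_mesh
from .stats import GroupStack, friedman_within_group, kruskal_dunn_between_groups
from .synthetic import (DEFAULT_ROI_NAMES, PhantomSpec, SyntheticStudySpec,
                        make_block_atlas, make_qball_scheme, simulate_dwi_phantom,
                        simulate_study_cohort)
from .tracking import TrackingConfig, fiber_density_matrix, track_deterministic

__all__ = ["FunctionalResult", "run_functional_pipeline",
           "DiffusionResult", "run_diffusion_pipeline"]


@dataclass
class FunctionalResult:
    atlas: AtlasLabels
    subject_matrices: dict      # (group, timepoint) -> GroupStack
    group_averages: dict        # (group, timepoint) -> ConnMatrix
    slopes: dict                # group -> SlopeFit
    truth: dict                 # (group, timepoint, subject) -> truth record


def run_functional_pipeline(spec: SyntheticStudySpec, atlas: AtlasLabels | None = None,
                            preproc_config: PreprocConfig | None = None,
                            compute_stats: bool = False) -> FunctionalResult:
    """Simulate the cohort, preprocess every session, build per-subject and
    group-average Fisher-z matrices and per-group origin slopes.

    ``compute_stats=True`` additionally attaches the Friedman within-group
    and Kruskal-Wallis/Dunn between-group StatMatrix objects."""
    if atlas is None:
        n_rois = spec.base_corr.shape[0]
        names = DEFAULT_ROI_NAMES if n_rois == len(DEFAULT_ROI_NAMES) else None
        atlas = make_block_atlas(n_rois, roi_names=names)
    cfg = preproc_config or PreprocConfig()
    entries = simulate_study_cohort(spec, atlas)

    stacks: dict = {}
    truth: dict = {}
    for e in entries:
        clean, _ = preprocess_bold(e.bold, e.nuisance, cfg)
        ts = extract_roi_timeseries(clean, atlas)
        conn = connectivity_matrix(ts, metadata={
            "subject": e.subject_id, "group": e.group, "timepoint": e.timepoint})
        key = (e.group, e.timepoint)
        stacks.setdefault(key, ([], []))
        stacks[key][0].append(e.subject_id)
        stacks[key][1].append(conn)
        truth[(e.group, e.timepoint, e.subject_id)] = e.truth

    group_stacks = {k: GroupStack(k[0], k[1], v[0], v[1]) for k, v in stacks.items()}
    averages = {k: group_average_matrix(v.matrices, {"group": k[0], "timepoint": k[1]})
                for k, v in group_stacks.items()}
    slopes = {g: origin_slope_fit(averages[(g, 0)], averages[(g, 1)])
              for g in spec.groups}
    result = FunctionalResult(atlas, group_stacks, averages, slopes, truth)
    if compute_stats:
        result.friedman = {g: friedman_within_group(group_stacks[(g, 0)], group_stacks[(g, 1)])
                           for g in spec.groups}
        result.kruskal = {}
        for tp in (0, 1):
            ordered = [group_stacks[(g, tp)] for g in sorted(spec.groups)]
            result.kruskal[tp] = kruskal_dunn_between_groups(ordered)
    return result


@dataclass
class DiffusionResult:
    peaks: object
    streamlines: object
    density: object
    truth: dict


def run_diffusion_pipeline(phantom: PhantomSpec, scheme=None,
                           tracking_config: TrackingConfig | None = None,
                           seed: int = 0, max_order: int = 8,
                           lam: float = 0.006, rois=None) -> DiffusionResult:
    """Phantom signal -> Q-ball ODFs -> peaks -> tractography -> fiber
    density (when the phantom carries endpoint ROIs)."""
    scheme = scheme or make_qball_scheme()
    cfg = tracking_config or TrackingConfig(rng_seed=seed)
    dwi, truth = simulate_dwi_phantom(phantom, scheme, seed=seed)
    odf = fit_qball_odf(dwi, scheme, phantom.geometry, max_order, lam)
    peaks = evaluate_odf_peaks(odf, make_odf_mesh())
    lines = track_deterministic(peaks, cfg)
    density = None
    if phantom.atlas is not None:
        density = fiber_density_matrix(lines, phantom.atlas, rois)
    return DiffusionResult(peaks, lines, density, truth)
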