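"""Shared fixtures: small synthetic atlases, diffusion schemes/phantoms and
pipeline runs reused across test modules (session-scoped where expensive)."""

import numpy as np
import pytest

from taumri.qball import evaluate_odf_peaks, fit_qball_odf, make_odf_mesh
from taumri.synthetic import (crossing_phantom, default_base_corr, make_block_atlas,
                              make_qball_scheme, simulate_dwi_phantom,
                              straight_tube_phantom)


@pytest.fixture
def small_atlas():
    return make_block_atlas(6, roi_shape=(3, 3, 2))


@pytest.fixture(scope="session")
def qball_scheme():
    return make_qball_scheme()


@pytest.fixture(scope="session")
def odf_mesh():
    return make_odf_mesh()


@pytest.fixture(scope="session")
def tube_reconstruction(qball_scheme, odf_mesh):
    """Noiseless 20 mm straight-tube phantom, reconstructed through the
    Q-ball chain."""
    phantom = straight_tube_phantom(snr=None)
    dwi, truth = simulate_dwi_phantom(phantom, qball_scheme, seed=0)
    odf = fit_qball_odf(dwi, qball_scheme, phantom.geometry)
    peaks = evaluate_odf_peaks(odf, odf_mesh)
    return phantom, dwi, odf, peaks, truth


@pytest.fixture(scope="session")
def crossing_reconstruction(qball_scheme, odf_mesh):
    """Noiseless 90-degree crossing phantom through the Q-ball chain."""
    phantom = crossing_phantom(snr=None)
    dwi, truth = simulate_dwi_phantom(phantom, qball_scheme, seed=0)
    odf = fit_qball_odf(dwi, qball_scheme, phantom.geometry)
    peaks = evaluate_odf_peaks(odf, odf_mesh)
    return phantom, dwi, odf, peaks, truth


@pytest.fixture(scope="session")
def study_result():
    """Full-size study cohort (n = 8/8/7, T = 105, TR 2.84 s, transgenic
    baseline scale 0.5) run through the functional pipeline."""
    from taumri.synthetic import default_study_spec
    from taumri.workflows import run_functional_pipeline
    spec = default_study_spec(master_seed=11)
    return spec, run_functional_pipeline(spec)
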