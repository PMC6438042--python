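#!/usr/bin/env python
"""Diffusion arm: Q-ball reconstruction, tractography and fiber density on
known-geometry phantoms.

Simulates single-shell (b = 2000 s/mm^2, 126 half-sphere directions)
multi-tensor phantoms, reconstructs ODFs with the regularized spherical-
harmonic fit (L = 8, lambda = 0.006), runs deterministic streamline
tractography (QA >= 0.03, 0.5 mm steps, 0.1 weighting, 55 degree turn
limit, 5-120 mm lengths) and assembles voxel-normalized fiber-density
matrices, including a two-condition difference.  Writes tables under
results/ and prints the fidelity summary.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from taumri.io import write_matrix_table
from taumri.longitudinal import matrix_difference
from taumri.tracking import TrackingConfig
from taumri.synthetic import crossing_phantom, straight_tube_phantom
from taumri.workflows import run_diffusion_pipeline

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 1


def main() -> None:
    OUT.mkdir(exist_ok=True)

    tube = straight_tube_phantom(snr=30.0)
    res = run_diffusion_pipeline(tube, seed=SEED,
                                 tracking_config=TrackingConfig(rng_seed=SEED))
    d = res.peaks.directions[20, 4, 4][0]
    err = np.degrees(np.arccos(min(1.0, abs(d @ [1.0, 0, 0]))))
    print(f"tube phantom (SNR 30): {res.streamlines.n} streamlines, "
          f"mid-tube peak error {err:.2f} deg")
    print(f"fiber density endA-endB: {res.density.density[0, 1]:.3f} fibers/voxel")
    write_matrix_table(res.density.density, res.density.roi_order,
                       OUT / "fiber_density_baseline.csv")

    # second 'time point': same geometry, different noise realization, to
    # exercise the difference-matrix view of structural change
    res2 = run_diffusion_pipeline(tube, seed=SEED + 1,
                                  tracking_config=TrackingConfig(rng_seed=SEED + 1))
    diff = matrix_difference(res2.density.density, res.density.density)
    write_matrix_table(diff, res.density.roi_order, OUT / "fiber_density_difference.csv")
    print(f"density difference (rerun - baseline): {diff[0, 1]:+.3f}")

    crossing = crossing_phantom(snr=30.0)
    resx = run_diffusion_pipeline(crossing, seed=SEED)
    mid = crossing.geometry.dims[0] // 2
    vox = (mid, mid, 4)
    found = resx.peaks.directions[vox][:resx.peaks.n_peaks[vox]]
    errs = {ax: float(np.degrees(np.arccos(np.minimum(1.0, np.abs(found @ t)))).min())
            for ax, t in (("x", [1.0, 0, 0]), ("y", [0, 1.0, 0]))}
    print(f"crossing phantom (SNR 30): {resx.peaks.n_peaks[vox]} peaks at center, "
          f"errors {errs['x']:.2f}/{errs['y']:.2f} deg; "
          f"{resx.streamlines.n} streamlines")

    lengths = res.streamlines.lengths
    pd.DataFrame({"length_mm": lengths}).describe().to_csv(OUT / "streamline_lengths.csv")
    print(f"\nwrote density matrices and length summary under {OUT}")


if __name__ == "__main__":
    main()
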