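#!/usr/bin/env python
"""Edge-wise nonparametric statistics over the cohort.

Within each group, a Friedman test (k = 2 paired time points) per edge; at
each time point, Kruskal-Wallis across the three groups with Dunn's
adjusted pairwise p-values.  Writes the p-value matrices and star tiers
(p < 0.05: 1, p < 0.005: 2) under results/ and prints the count of
significant edges per contrast.
"""

from pathlib import Path

import numpy as np

from taumri.io import write_matrix_table
from taumri.stats import significance_mask
from taumri.synthetic import default_study_spec
from taumri.workflows import run_functional_pipeline

OUT = Path(__file__).resolve().parents[1] / "results"
MASTER_SEED = 1


def main() -> None:
    spec = default_study_spec(master_seed=MASTER_SEED)
    res = run_functional_pipeline(spec, compute_stats=True)
    OUT.mkdir(exist_ok=True)

    n_rois = spec.base_corr.shape[0]
    n_edges = n_rois * (n_rois - 1) // 2
    for group, sm in res.friedman.items():
        write_matrix_table(sm.p, sm.roi_order, OUT / f"friedman_p_{group}.csv")
        tiers = significance_mask(sm)
        iu = np.triu_indices(n_rois, 1)
        print(f"friedman {group:8s}: {int(np.sum(tiers[iu] >= 1)):3d}/{n_edges} "
              f"edges p<0.05 ({int(np.sum(tiers[iu] == 2))} at p<0.005)")

    for tp, (omni, pairwise) in res.kruskal.items():
        write_matrix_table(omni.p, omni.roi_order, OUT / f"kruskal_p_t{tp}.csv")
        iu = np.triu_indices(n_rois, 1)
        print(f"kruskal  t{tp}      : {int(np.sum(significance_mask(omni)[iu] >= 1)):3d}"
              f"/{n_edges} omnibus edges p<0.05")
        for (g1, g2), sm in pairwise.items():
            write_matrix_table(sm.p, sm.roi_order, OUT / f"dunn_p_t{tp}_{g1}_vs_{g2}.csv")
            sig = int(np.sum(significance_mask(sm)[iu] >= 1))
            print(f"  dunn {g1} vs {g2}: {sig}/{n_edges} adjusted p<0.05")
    print(f"\nwrote p-value matrices under {OUT}")


if __name__ == "__main__":
    main()
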