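"""Edge-wise nonparametric group statistics.

The connectivity matrices fail Shapiro-Wilk normality screening, so the
analysis track is nonparametric throughout: a Friedman test for the
within-group time effect (k = 2 paired conditions), and Kruskal-Wallis with
Dunn's post hoc pairwise comparisons (Bonferroni-type adjustment over the
three group pairs) for between-group effects at each time point.  Following
the reporting convention this pipeline mirrors, p-values are adjusted within
each edge's pairwise family only; no correction is applied across edges
(an optional Benjamini-Hochberg flag is available).

The Friedman statistic is implemented here because the two-condition case
falls outside scipy's k >= 3 requirement; Kruskal-Wallis is delegated to
scipy, while Dunn's z and its adjustment are implemented in-package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats as sps

from .fc import ConnMatrix

__all__ = [
    "GroupStack",
    "StatMatrix",
    "normality_screen",
    "friedman_statistic",
    "friedman_exact_p",
    "friedman_within_group",
    "dunn_pairwise",
    "kruskal_dunn_between_groups",
    "significance_mask",
    "bh_adjust",
]


@dataclass
class GroupStack:
    """Subject-ordered connectivity matrices of one group at one time point."""

    group: str
    timepoint: int
    subjects: list          # subject ids, order defines pairing
    matrices: list          # ConnMatrix per subject

    def __post_init__(self):
        if len(self.subjects) != len(self.matrices):
            raise ValueError("subjects and matrices differ in length")
        if len(set(self.subjects)) != len(self.subjects):
            raise ValueError("subject ids must be unique")
        order = self.roi_order
        for m in self.matrices:
            if m.roi_order != order:
                raise ValueError("roi_order mismatch within stack")

    @property
    def roi_order(self):
        return self.matrices[0].roi_order

    @property
    def n(self) -> int:
        return len(self.subjects)

    def edge_array(self) -> np.ndarray:
        """(n_subjects, n_edges) upper-triangle edge values."""
        return np.array([m.edge_values() for m in self.matrices])


@dataclass
class StatMatrix:
    """Edge-wise test results assembled into symmetric ROI x ROI matrices."""

    roi_order: list
    p: np.ndarray
    statistic: np.ndarray
    test: str
    n_per_group: tuple = ()
    adjustment: str = "none"

    def __post_init__(self):
        n = len(self.roi_order)
        for mat in (self.p, self.statistic):
            if mat.shape != (n, n):
                raise ValueError("matrices must be square matching roi_order")
        ok = np.isfinite(self.p)
        if np.any((self.p[ok] < 0) | (self.p[ok] > 1)):
            raise ValueError("p-values out of [0, 1]")


def _edges_to_matrix(values: np.ndarray, n_rois: int) -> np.ndarray:
    mat = np.full((n_rois, n_rois), np.nan)
    iu = np.triu_indices(n_rois, k=1)
    mat[iu] = values
    mat[(iu[1], iu[0])] = values
    return mat


def normality_screen(values) -> float:
    """Shapiro-Wilk p-value for one edge sample; used at report level to
    justify the nonparametric track, not as a per-edge gate."""
    values = np.asarray(values, dtype=float)
    if values.size < 3 or values.size > 5000:
        raise ValueError("Shapiro-Wilk needs 3 <= n <= 5000")
    if np.ptp(values) == 0:
        raise ValueError("constant sample")
    return float(sps.shapiro(values).pvalue)


def friedman_statistic(data: np.ndarray) -> float:
    """Friedman rank statistic for an (n_blocks, k_conditions) table with
    the standard tie correction.  Returns NaN when every block is fully tied
    (the statistic is undefined)."""
    data = np.asarray(data, dtype=float)
    n, k = data.shape
    ranks = np.apply_along_axis(sps.rankdata, 1, data)
    rbar = ranks.mean(axis=0)
    q = 12.0 * n / (k * (k + 1)) * np.sum((rbar - (k + 1) / 2.0) ** 2)
    # tie correction: 1 - sum(t^3 - t) / (n k (k^2 - 1))
    tie_sum = 0.0
    for row in data:
        _, counts = np.unique(row, return_counts=True)
        tie_sum += np.sum(counts ** 3 - counts)
    c = 1.0 - tie_sum / (n * k * (k ** 2 - 1))
    if c <= 0:
        return np.nan
    return float(q / c)


def friedman_exact_p(x1: np.ndarray, x2: np.ndarray) -> float:
    """Exact two-condition Friedman p by full sign-permutation enumeration
    (2^n assignments of which condition each paired observation came from)."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    n = x1.size
    if n > 16:
        raise ValueError("exact enumeration limited to n <= 16")
    obs = friedman_statistic(np.column_stack([x1, x2]))
    if np.isnan(obs):
        return np.nan
    count = 0
    total = 2 ** n
    for mask in range(total):
        flip = np.array([(mask >> i) & 1 for i in range(n)], dtype=bool)
        a = np.where(flip, x2, x1)
        b = np.where(flip, x1, x2)
        q = friedman_statistic(np.column_stack([a, b]))
        if not np.isnan(q) and q >= obs - 1e-12:
            count += 1
    return count / total


def friedman_within_group(stack_t1: GroupStack, stack_t2: GroupStack,
                          exact: bool = False) -> StatMatrix:
    """Per-edge Friedman test of the time effect within one group.

    The two stacks must be paired by subject (same ids, same order).  With
    k = 2 conditions the chi-square reference has 1 degree of freedom; for
    small cohorts ``exact=True`` switches to full sign-permutation p-values.
    Fully tied edges are reported as NaN."""
    if stack_t1.subjects != stack_t2.subjects:
        raise ValueError("stacks are not paired by subject")
    if stack_t1.n < 2:
        raise ValueError("need at least 2 subjects")
    e1 = stack_t1.edge_array()
    e2 = stack_t2.edge_array()
    n_rois = len(stack_t1.roi_order)
    n_edges = e1.shape[1]
    stat = np.empty(n_edges)
    pval = np.empty(n_edges)
    for j in range(n_edges):
        table = np.column_stack([e1[:, j], e2[:, j]])
        q = friedman_statistic(table)
        stat[j] = q
        if np.isnan(q):
            pval[j] = np.nan
        elif exact:
            pval[j] = friedman_exact_p(e1[:, j], e2[:, j])
        else:
            pval[j] = sps.chi2.sf(q, df=1)
    return StatMatrix(stack_t1.roi_order,
                      _edges_to_matrix(pval, n_rois),
                      _edges_to_matrix(stat, n_rois),
                      test="friedman", n_per_group=(stack_t1.n,),
                      adjustment="exact" if exact else "chi2")


def dunn_pairwise(samples: list[np.ndarray]) -> dict:
    """Dunn's post hoc z and p for every group pair after a Kruskal-Wallis
    omnibus, with tie-corrected variance and Bonferroni-type adjustment over
    the pairwise family.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j))
    where T = sum(t^3 - t) over tie groups of the pooled data.
    """
    pooled = np.concatenate(samples)
    n_tot = pooled.size
    ranks = sps.rankdata(pooled)
    sizes = [s.size for s in samples]
    edges = np.cumsum([0] + sizes)
    rbar = [ranks[edges[i]:edges[i + 1]].mean() for i in range(len(samples))]
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts ** 3 - counts) / (12.0 * (n_tot - 1))
    var_base = n_tot * (n_tot + 1) / 12.0 - tie_term
    n_pairs = len(samples) * (len(samples) - 1) // 2
    out = {}
    for i, j in combinations(range(len(samples)), 2):
        se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (rbar[i] - rbar[j]) / se if se > 0 else np.nan
        p_raw = 2.0 * sps.norm.sf(abs(z)) if np.isfinite(z) else np.nan
        out[(i, j)] = {"z": z, "p_unadjusted": p_raw,
                       "p_adjusted": min(1.0, p_raw * n_pairs) if np.isfinite(z) else np.nan}
    return out


def kruskal_dunn_between_groups(stacks: list[GroupStack]):
    """Per-edge Kruskal-Wallis omnibus across groups at one time point, plus
    Dunn's adjusted pairwise p per group pair.

    Returns ``(omnibus StatMatrix, {(group_i, group_j): StatMatrix})``.
    All-tied edges are NaN."""
    if len(stacks) < 2:
        raise ValueError("need at least 2 groups")
    order = stacks[0].roi_order
    for s in stacks[1:]:
        if s.roi_order != order:
            raise ValueError("roi_order mismatch across groups")
    if any(s.n < 2 for s in stacks):
        raise ValueError("every group needs at least 2 subjects")
    arrays = [s.edge_array() for s in stacks]
    n_rois = len(order)
    n_edges = arrays[0].shape[1]
    h_stat = np.empty(n_edges)
    h_p = np.empty(n_edges)
    pair_keys = list(combinations(range(len(stacks)), 2))
    pair_z = {k: np.empty(n_edges) for k in pair_keys}
    pair_p = {k: np.empty(n_edges) for k in pair_keys}
    for j in range(n_edges):
        samples = [a[:, j] for a in arrays]
        pooled = np.concatenate(samples)
        if np.ptp(pooled) == 0:
            h_stat[j] = np.nan
            h_p[j] = np.nan
            for k in pair_keys:
                pair_z[k][j] = np.nan
                pair_p[k][j] = np.nan
            continue
        res = sps.kruskal(*samples)
        h_stat[j], h_p[j] = res.statistic, res.pvalue
        dunn = dunn_pairwise(samples)
        for k in pair_keys:
            pair_z[k][j] = dunn[k]["z"]
            pair_p[k][j] = dunn[k]["p_adjusted"]
    ns = tuple(s.n for s in stacks)
    omnibus = StatMatrix(order, _edges_to_matrix(h_p, n_rois),
                         _edges_to_matrix(h_stat, n_rois),
                         test="kruskal-wallis", n_per_group=ns)
    pairwise = {}
    for (i, j) in pair_keys:
        pairwise[(stacks[i].group, stacks[j].group)] = StatMatrix(
            order, _edges_to_matrix(pair_p[(i, j)], n_rois),
            _edges_to_matrix(pair_z[(i, j)], n_rois),
            test="dunn", n_per_group=(stacks[i].n, stacks[j].n),
            adjustment="bonferroni-3")
    return omnibus, pairwise


def significance_mask(stat: StatMatrix, alpha: float = 0.05,
                      alpha2: float = 0.005) -> np.ndarray:
    """Star tiers per edge: 0 (ns), 1 (p < 0.05), 2 (p < 0.005); strict
    inequalities, NaN edges are tier 0."""
    p = stat.p
    tiers = np.zeros(p.shape, dtype=int)
    with np.errstate(invalid="ignore"):
        tiers[p < alpha] = 1
        tiers[p < alpha2] = 2
    return tiers


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjustment over finite entries (optional matrix-wide
    correction, off by default in the analysis track)."""
    p = np.asarray(p, dtype=float)
    flat = p.ravel()
    ok = np.isfinite(flat)
    vals = flat[ok]
    m = vals.size
    order = np.argsort(vals)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m - 1, -1, -1):
        running = min(running, vals[order[rank]] * m / (rank + 1))
        adj[order[rank]] = running
    out = np.full(flat.shape, np.nan)
    out[ok] = adj
    return out.reshape(p.shape)
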