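"""Global longitudinal change metrics between the two time points.

The central quantity is the origin-constrained slope of the edge scatter:
plotting every unique off-diagonal Fisher-z edge of the later time point
against the same edge at baseline, a least-squares line through the origin
(slope = sum(x*y)/sum(x^2), vertical residuals, x = earlier time point)
summarizes the overall connectivity change.  Slope 1 means no change;
slope > 1 a global strengthening.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fc import ConnMatrix

__all__ = ["SlopeFit", "origin_slope_fit", "matrix_difference", "node_edge_profile"]


@dataclass
class SlopeFit:
    slope: float
    n_points: int
    rms_residual: float
    axis_convention: str = "x = earlier time point"


def origin_slope_fit(m1: ConnMatrix, m2: ConnMatrix) -> SlopeFit:
    """Least-squares line through the origin fitted to the edge scatter
    (x = edges of the earlier matrix ``m1``, y = the later ``m2``).

    Each unordered off-diagonal edge enters once (upper triangle),
    unweighted.  slope = sum(xy)/sum(x^2)."""
    if m1.roi_order != m2.roi_order:
        raise ValueError("roi_order mismatch between time points")
    x = m1.edge_values()
    y = m2.edge_values()
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 2:
        raise ValueError("need at least 2 edges")
    sxx = float(np.sum(x * x))
    if sxx == 0:
        raise ValueError("all baseline edges are zero; slope undefined")
    slope = float(np.sum(x * y) / sxx)
    resid = y - slope * x
    return SlopeFit(slope=slope, n_points=int(x.size),
                    rms_residual=float(np.sqrt(np.mean(resid ** 2))))


def matrix_difference(m_late: np.ndarray, m_early: np.ndarray,
                      roi_order_late=None, roi_order_early=None) -> np.ndarray:
    """Elementwise later-minus-earlier matrix (connectivity or fiber
    density); symmetric whenever the inputs are."""
    if roi_order_late is not None and roi_order_early is not None \
            and list(roi_order_late) != list(roi_order_early):
        raise ValueError("roi_order mismatch")
    m_late = np.asarray(m_late, dtype=float)
    m_early = np.asarray(m_early, dtype=float)
    if m_late.shape != m_early.shape:
        raise ValueError("shape mismatch")
    return m_late - m_early


def node_edge_profile(m: ConnMatrix, node: str, targets) -> np.ndarray:
    """Fisher-z values of one node's connections to the named target ROIs,
    in target order (the single-node edge profile view)."""
    targets = list(targets)
    if node not in m.roi_order:
        raise KeyError(f"unknown node {node!r}")
    unknown = [t for t in targets if t not in m.roi_order]
    if unknown:
        raise KeyError(f"unknown targets {unknown}")
    if node in targets:
        raise ValueError("node must not be among the targets")
    i = m.roi_order.index(node)
    idx = [m.roi_order.index(t) for t in targets]
    return m.z[i, idx]
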