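"""Binary submodular energy minimization via s-t min-cut.

Solves min over x in {0,1}^n of

    sum_i theta_i(x_i) + sum_(i,j) E_ij(x_i, x_j)

for pairwise terms satisfying the submodularity condition
E(0,1) + E(1,0) >= E(0,0) + E(1,1), using the standard reparametrization into
an s-t network (source side = label 0) and ``scipy.sparse.csgraph.maximum_flow``.
Capacities are scaled to int64, so cuts are exact to ~1e-8 of an energy unit.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import coo_array
from scipy.sparse.csgraph import breadth_first_order, maximum_flow

SCALE = 1e8


def binary_mincut(
    theta0: np.ndarray,
    theta1: np.ndarray,
    edges_i: np.ndarray,
    edges_j: np.ndarray,
    e00: np.ndarray,
    e01: np.ndarray,
    e10: np.ndarray,
    e11: np.ndarray,
) -> np.ndarray:
    """Return the optimal binary labels (0 = source side).

    ``theta0``/``theta1`` are per-node unary costs; the remaining arrays give
    the pairwise table for each edge (i, j).
    """
    theta0 = np.asarray(theta0, dtype=float).copy()
    theta1 = np.asarray(theta1, dtype=float).copy()
    n = theta0.size
    gap = e01 + e10 - e00 - e11
    if np.any(gap < -1e-9):
        raise ValueError("pairwise terms are not submodular")
    # reparametrize: const += e00; theta_i(1) += e10-e00; theta_j(1) += e11-e10
    np.add.at(theta1, edges_i, e10 - e00)
    np.add.at(theta1, edges_j, e11 - e10)
    w = np.maximum(gap, 0.0)

    s, t = n, n + 1
    # normalize t-links so capacities are non-negative
    base = np.minimum(theta0, theta1)
    cap_s = theta1 - base  # s->i, cut when x_i = 1
    cap_t = theta0 - base  # i->t, cut when x_i = 0

    rows = np.concatenate([
        np.full(n, s), np.arange(n),           # t-links
        edges_i, edges_j,                      # n-link + reverse (0 cap)
        np.arange(n), np.full(n, t),           # zero-cap reverses of t-links
    ])
    cols = np.concatenate([
        np.arange(n), np.full(n, t),
        edges_j, edges_i,
        np.full(n, s), np.arange(n),
    ])
    caps = np.concatenate([
        cap_s, cap_t,
        w, np.zeros_like(w),
        np.zeros(n), np.zeros(n),
    ])
    icaps = np.round(caps * SCALE).astype(np.int64)
    g = coo_array((icaps, (rows, cols)), shape=(n + 2, n + 2)).tocsr()
    res = maximum_flow(g, s, t)
    residual = (g - res.flow).tocoo()
    pos = residual.data > 0
    adj = coo_array(
        (np.ones(int(pos.sum()), dtype=np.int8),
         (residual.row[pos], residual.col[pos])),
        shape=(n + 2, n + 2),
    ).tocsr()
    order = breadth_first_order(adj, s, directed=True,
                                return_predecessors=False)
    reach = np.zeros(n + 2, dtype=bool)
    reach[order] = True
    return (~reach[:n]).astype(np.uint8)  # sink side takes label 1
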