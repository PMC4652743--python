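"""Independent brute-force oracles used only by the test suite."""

import itertools

import numpy as np
from scipy.optimize import linprog


def dip_brute_force(x):
    """Exact dip by linear programming over every modal placement.

    Minimises the sup-distance between the empirical CDF and a unimodal CDF
    (convex left of the mode, concave right, atom allowed at the mode) by
    solving one LP per candidate mode: between each pair of adjacent distinct
    values, beyond the extremes, and at each value.  Completely independent
    of the production algorithm.
    """
    x = np.sort(np.asarray(x, float))
    n = x.size
    xu, start = np.unique(x, return_index=True)
    m = xu.size
    if n < 2 or m == 1:
        return 0.0
    counts = np.diff(np.append(start, n))
    hi = np.cumsum(counts)
    lo = hi - counts
    best = np.inf
    for s in range(m + 1):  # mode between node s-1 and s (convex part: 0..s-1)
        best = min(best, _lp_min_d(xu, lo, hi, lo, hi, n, s))
    for j in range(m):  # mode at node j, with an atom
        # duplicate node j: convex copy bound by the lower rank, concave copy
        # by the upper rank (the CDF may jump between them at the mode)
        pos = np.concatenate([xu[: j + 1], xu[j:]])
        lo2 = np.concatenate([lo[:j], [lo[j], hi[j]], lo[j + 1:]])
        hi2 = np.concatenate([hi[:j], [lo[j], hi[j]], hi[j + 1:]])
        best = min(best, _lp_min_d(pos, lo2, hi2, lo2, hi2, n, j + 1))
    return float(best)


def _lp_min_d(pos, lo_rank, hi_rank, lo_b, hi_b, n, split):
    """min d s.t. exists nondecreasing w, convex on nodes < split, concave on
    nodes >= split, with hi_rank/n - d <= w_i <= lo_rank/n + d."""
    m = len(pos)
    nv = m + 1  # w_0..w_{m-1}, d
    A, b = [], []
    for i in range(m):
        row = np.zeros(nv)
        row[i], row[m] = 1.0, -1.0
        A.append(row.copy())
        b.append(lo_rank[i] / n)
        row = np.zeros(nv)
        row[i], row[m] = -1.0, -1.0
        A.append(row)
        b.append(-hi_rank[i] / n)
    for i in range(m - 1):
        row = np.zeros(nv)
        row[i], row[i + 1] = 1.0, -1.0
        A.append(row)
        b.append(0.0)
    for i in range(1, m - 1):
        dx1 = pos[i] - pos[i - 1]
        dx2 = pos[i + 1] - pos[i]
        if dx1 <= 0 or dx2 <= 0:
            continue  # duplicated atom node: no curvature constraint across it
        row = np.zeros(nv)
        if i + 1 <= split - 1:  # all three nodes in the convex part
            row[i - 1], row[i], row[i + 1] = -dx2, dx1 + dx2, -dx1
            A.append(row)
            b.append(0.0)
        elif i - 1 >= split:  # all three in the concave part
            row[i - 1], row[i], row[i + 1] = dx2, -(dx1 + dx2), dx1
            A.append(row)
            b.append(0.0)
    c = np.zeros(nv)
    c[m] = 1.0
    res = linprog(
        c, A_ub=np.array(A), b_ub=np.array(b),
        bounds=[(0.0, 1.0)] * m + [(0.0, 0.5)], method="highs",
        options={"primal_feasibility_tolerance": 1e-10,
                 "dual_feasibility_tolerance": 1e-10},
    )
    return res.fun if res.status == 0 else np.inf


def mann_whitney_exact_p(a, b):
    """Two-sided Mann-Whitney p by full enumeration of group assignments."""
    a = list(a)
    b = list(b)
    pooled = a + b
    na = len(a)
    idx_all = range(len(pooled))

    def u_stat(idx_a):
        xa = [pooled[i] for i in idx_a]
        xb = [pooled[i] for i in idx_all if i not in idx_a]
        u = sum(1.0 if x > y else (0.5 if x == y else 0.0) for x in xa for y in xb)
        return u

    u_obs = u_stat(tuple(range(na)))
    n_ab = len(a) * len(b)
    dev_obs = abs(u_obs - n_ab / 2.0)
    total = more = 0
    for comb in itertools.combinations(idx_all, na):
        total += 1
        if abs(u_stat(comb) - n_ab / 2.0) >= dev_obs - 1e-12:
            more += 1
    return more / total


def lambda_grid_search(d, k, n, n_grid=10_000):
    """Least-squares lambda by exhaustive log-grid search (independent of the
    production optimiser)."""
    d = np.asarray(d, float)
    freq = np.asarray(k, float) / np.asarray(n, float)
    lams = np.concatenate([[0.0], np.logspace(-4, np.log10(50.0 / d.min()), n_grid)])
    sse = ((freq[None, :] - (1.0 - np.exp(-np.outer(lams, d)))) ** 2).sum(axis=1)
    return float(lams[np.argmin(sse)])
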