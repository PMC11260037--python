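"""Independent oracles used by the test suite.

Each oracle takes a different computational route than the implementation it
checks: GBLUP via the phenotypic covariance inverse instead of the
marker-block MME, kinship via memoized coancestry recursion instead of the
tabular matrix, mate-allocation optima by exhaustive enumeration instead of
annealing, and ridge solutions via augmented least squares instead of the
mixed-model equations.
"""
from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np


def gblup_gebv_oracle(X, y, lam):
    """GEBVs from the individual-level (GBLUP / GLS) formulation.

    With g ~ N(0, I sg2) and e ~ N(0, I se2), u = Xg has covariance
    XX' sg2 and V = XX' sg2 + I se2; then mu = (1'V^-1 1)^-1 1'V^-1 y and
    u_hat = sg2 XX' V^-1 (y - mu).  Only lam = se2/sg2 matters, so take
    sg2 = 1, se2 = lam.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n = len(y)
    G = X @ X.T
    V = G + lam * np.eye(n)
    Vi = np.linalg.inv(V)
    ones = np.ones(n)
    mu = (ones @ Vi @ y) / (ones @ Vi @ ones)
    return G @ Vi @ (y - mu * ones)


def ridge_lstsq_oracle(X, y, lam):
    """(mu, g) from augmented least squares: stack sqrt(lam)*I rows under X."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, m = X.shape
    top = np.hstack([np.ones((n, 1)), X])
    bottom = np.hstack([np.zeros((m, 1)), np.sqrt(lam) * np.eye(m)])
    A = np.vstack([top, bottom])
    b = np.concatenate([y, np.zeros(m)])
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    return sol[0], sol[1:]


def recursive_kinship(sire, dam):
    """Pairwise coancestry by memoized recursion (Malecot), -1 = unknown."""
    sire = [int(s) for s in sire]
    dam = [int(d) for d in dam]

    @lru_cache(maxsize=None)
    def f(i, j):
        if i < 0 or j < 0:
            return 0.0
        if i == j:
            return 0.5 * (1.0 + f(sire[i], dam[i]))
        if j > i:
            i, j = j, i
        # i is the younger (higher row): recurse through i's parents
        return 0.5 * (f(sire[i], j) + f(dam[i], j))

    n = len(sire)
    return np.array([[f(i, j) for j in range(n)] for i in range(n)])


def balanced_allocations(n_sires, n_dams):
    """All assignments of dams to sires with near-equal block sizes."""
    base, rem = divmod(n_dams, n_sires)
    sizes = [base + 1] * rem + [base] * (n_sires - rem)
    slots = [s for s, k in enumerate(sizes) for _ in range(k)]
    return sorted(set(itertools.permutations(slots)))


def enumerate_mate_optimum(kinship_sd, objective):
    """Exhaustive best mean pair-kinship over all balanced allocations."""
    n_s, n_d = kinship_sd.shape
    vals = [np.mean([kinship_sd[a[d], d] for d in range(n_d)])
            for a in balanced_allocations(n_s, n_d)]
    return min(vals) if objective == "min" else max(vals)


def pairwise_r2_bruteforce(H, positions, edges):
    """Per-bin (count, mean r2) by looping every eligible pair."""
    from matesim.metrics import ld_r2_pair

    H = np.asarray(H, float)
    p = H.mean(axis=0)
    seg = np.flatnonzero((p > 0) & (p < 1))
    per_bin = {b: [] for b in range(len(edges) - 1)}
    for a_i, b_i in itertools.combinations(seg, 2):
        d = abs(positions[b_i] - positions[a_i])
        if d > edges[-1]:
            continue
        for b in range(len(edges) - 1):
            if edges[b] < d <= edges[b + 1]:
                per_bin[b].append(ld_r2_pair(H[:, a_i], H[:, b_i]))
                break
    return {b: (len(v), float(np.mean(v)) if v else float("nan"))
            for b, v in per_bin.items()}
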