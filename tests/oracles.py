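"""Independent oracles used to cross-check the package's core numerics.

These deliberately avoid the code paths they verify: the superposition
oracle searches rotation space numerically instead of solving the Kabsch
SVD, and the clustering oracle re-runs average-linkage agglomeration as a
naive O(n^3) loop over the raw distance matrix instead of scipy's
dendrogram machinery.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import minimize


def _euler_zyz(a: float, b: float, c: float) -> np.ndarray:
    ca, sa = np.cos(a), np.sin(a)
    cb, sb = np.cos(b), np.sin(b)
    cc, sc = np.cos(c), np.sin(c)
    rz1 = np.array([[ca, -sa, 0], [sa, ca, 0], [0, 0, 1]])
    ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
    rz2 = np.array([[cc, -sc, 0], [sc, cc, 0], [0, 0, 1]])
    return rz1 @ ry @ rz2


def grid_search_min_rmsd(mobile: np.ndarray, reference: np.ndarray, n_grid: int = 18) -> float:
    """Minimum RMSD over rigid motions by Euler-grid search + simplex polish.

    Centering makes the optimal translation exact, so only the rotation is
    searched: a coarse z-y-z Euler grid followed by Nelder-Mead refinement
    from the best grid point.
    """
    p = mobile - mobile.mean(axis=0)
    q = reference - reference.mean(axis=0)
    n = p.shape[0]

    def cost(angles):
        r = _euler_zyz(*angles)
        return float(np.sqrt(np.mean(np.sum((p @ r.T - q) ** 2, axis=1))))

    alphas = np.linspace(0.0, 2 * np.pi, n_grid, endpoint=False)
    betas = np.linspace(0.0, np.pi, n_grid)
    best_val, best_angles = np.inf, None
    for a, b, c in itertools.product(alphas, betas, alphas):
        v = cost((a, b, c))
        if v < best_val:
            best_val, best_angles = v, (a, b, c)
    res = minimize(cost, best_angles, method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000})
    return float(min(best_val, res.fun))


def naive_average_linkage(matrix: np.ndarray, epsilon: float) -> list[set[int]]:
    """Average-linkage agglomeration as a literal merge loop.

    Start from singletons; repeatedly merge the pair of clusters with the
    smallest average inter-cluster distance (recomputed from the raw matrix
    each round, ties to the lexicographically smallest pair) until that
    minimum exceeds epsilon.
    """
    m = np.asarray(matrix, dtype=float)
    clusters: list[set[int]] = [{i} for i in range(m.shape[0])]
    while len(clusters) > 1:
        best = (np.inf, None)
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = np.mean([m[a, b] for a in clusters[i] for b in clusters[j]])
                if d < best[0] - 1e-12:
                    best = (d, (i, j))
        if best[0] > epsilon:
            break
        i, j = best[1]
        clusters[i] = clusters[i] | clusters[j]
        del clusters[j]
    return clusters


def partition_from_assignments(assignments: np.ndarray) -> set[frozenset]:
    """Canonical (order-free) form of a flat clustering."""
    groups: dict[int, set[int]] = {}
    for i, k in enumerate(assignments):
        groups.setdefault(int(k), set()).add(i)
    return {frozenset(g) for g in groups.values()}


def brute_force_bfactor(frames: np.ndarray, convention: str = "peraxis") -> np.ndarray:
    """Per-residue B by explicit accumulation loops (no vectorisation)."""
    f, n, _ = frames.shape
    out = np.zeros(n)
    for i in range(n):
        mean = [0.0, 0.0, 0.0]
        for t in range(f):
            for k in range(3):
                mean[k] += frames[t, i, k] / f
        acc = 0.0
        for t in range(f):
            for k in range(3):
                acc += (frames[t, i, k] - mean[k]) ** 2
        msf = acc / f
        factor = 8 * np.pi**2 / 3 if convention == "peraxis" else 8 * np.pi**2
        out[i] = factor * msf
    return out
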