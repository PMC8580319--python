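"""Independent brute-force oracles used by the tests.

Each oracle recomputes a quantity by direct enumeration or generic
optimization, sharing no code path with the implementation it checks.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np
from scipy.optimize import minimize


def enumerate_score_pmf(int_scores: np.ndarray, frequencies: np.ndarray):
    """Exact null PMF of total integer window scores by full enumeration.

    Returns {total_score: probability} over all |alphabet|^width words.
    """
    width = int_scores.shape[0]
    n = len(frequencies)
    pmf: dict[int, float] = {}
    for word in itertools.product(range(n), repeat=width):
        total = int(sum(int_scores[i, a] for i, a in enumerate(word)))
        prob = float(np.prod([frequencies[a] for a in word]))
        pmf[total] = pmf.get(total, 0.0) + prob
    return pmf


def enumeration_p_value(pmf: dict[int, float], score: int) -> float:
    return sum(p for s, p in pmf.items() if s >= score)


def affine_align_score(a: str, b: str, score_fn, gap_open: float,
                       gap_extend: float) -> float:
    """Optimal global affine-gap alignment score by exhaustive recursion.

    Convention: a gap of length k costs gap_open + k * gap_extend.
    State: (i, j, state) with state in {match, gap-in-b, gap-in-a}.
    """
    NEG = float("-inf")

    @lru_cache(maxsize=None)
    def rec(i: int, j: int, state: int) -> float:
        if i == 0 and j == 0:
            return 0.0 if state == 0 else NEG
        best = NEG
        if state == 0 and i > 0 and j > 0:
            sub = score_fn(a[i - 1], b[j - 1])
            best = max(rec(i - 1, j - 1, s) + sub for s in range(3))
        elif state == 1 and i > 0:   # gap in b, consuming a[i-1]
            best = max(rec(i - 1, j, 0) - gap_open - gap_extend,
                       rec(i - 1, j, 1) - gap_extend)
        elif state == 2 and j > 0:   # gap in a
            best = max(rec(i, j - 1, 0) - gap_open - gap_extend,
                       rec(i, j - 1, 2) - gap_extend,
                       rec(i, j - 1, 1) - gap_open - gap_extend)
        return best

    result = max(rec(len(a), len(b), s) for s in range(3))
    rec.cache_clear()
    return result


def _quat_to_rot(q: np.ndarray) -> np.ndarray:
    q = q / np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def brute_force_rmsd(x: np.ndarray, y: np.ndarray, n_starts: int = 512,
                     seed: int = 0) -> float:
    """Minimum RMSD over rigid motions by direct search over unit quaternions.

    Coarse random quaternion sampling followed by Nelder-Mead refinement of
    the best candidates; translation handled by centering (optimal for any
    rotation).  Independent of the SVD route.
    """
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    n = len(x)

    def rmsd_of(q: np.ndarray) -> float:
        R = _quat_to_rot(q)
        return float(np.sqrt(((xc - yc @ R.T) ** 2).sum() / n))

    rng = np.random.default_rng(seed)
    quats = rng.normal(size=(n_starts, 4))
    values = np.array([rmsd_of(q) for q in quats])
    best = np.inf
    for idx in np.argsort(values)[:5]:
        res = minimize(rmsd_of, quats[idx], method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12,
                                "maxiter": 5000})
        best = min(best, float(res.fun))
    return best


def random_additive_matrix(n: int, seed: int):
    """(labels, D) from a random binary tree with random branch lengths."""
    rng = np.random.default_rng(seed)
    labels = [f"t{i}" for i in range(n)]
    idx = {l: i for i, l in enumerate(labels)}
    D = np.zeros((n, n))

    def build(ls):
        if len(ls) == 1:
            return {ls[0]: 0.0}
        k = int(rng.integers(1, len(ls)))
        dl = build(ls[:k])
        dr = build(ls[k:])
        bl = rng.uniform(0.1, 2.0)
        br = rng.uniform(0.1, 2.0)
        for l1, d1 in dl.items():
            for l2, d2 in dr.items():
                D[idx[l1], idx[l2]] = D[idx[l2], idx[l1]] = d1 + bl + d2 + br
        out = {l: d + bl for l, d in dl.items()}
        out.update({l: d + br for l, d in dr.items()})
        return out

    build(labels)
    return labels, D
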