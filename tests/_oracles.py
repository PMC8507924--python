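"""Independent oracles used by the test suite.

Everything here is deliberately naive (dynamic programming, brute-force
enumeration, direct formula evaluation) and shares no code with the package
implementations it checks.
"""

from __future__ import annotations

from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd


def dp_kmeans_inertia(values: Sequence[float], k: int) -> float:
    """Exact optimal 1-D k-means inertia by dynamic programming over the
    sorted values (clusters of a 1-D optimum are contiguous in sort order)."""
    v = np.sort(np.asarray(values, dtype=np.float64))
    n = len(v)
    pre = np.concatenate([[0.0], np.cumsum(v)])
    pre2 = np.concatenate([[0.0], np.cumsum(v ** 2)])

    def sse(i: int, j: int) -> float:
        # inclusive i..j (0-based)
        s = pre[j + 1] - pre[i]
        s2 = pre2[j + 1] - pre2[i]
        m = j - i + 1
        return s2 - s * s / m

    INF = np.inf
    D = np.full((k + 1, n), INF)
    for j in range(n):
        D[1, j] = sse(0, j)
    for m in range(2, k + 1):
        for j in range(m - 1, n):
            best = INF
            for i in range(m - 1, j + 1):
                cand = D[m - 1, i - 1] + sse(i, j)
                if cand < best:
                    best = cand
            D[m, j] = best
    return float(D[k, n - 1])


def glcm_bruteforce(levels: np.ndarray, mask: np.ndarray, n_levels: int,
                    offsets: Sequence[Tuple[int, int]],
                    ) -> Tuple[float, float, float, float]:
    """GLCM features by explicit pair enumeration (returns contrast,
    correlation, energy, homogeneity; NaNs if no valid pair)."""
    lv = np.asarray(levels)
    msk = np.asarray(mask, dtype=bool)
    if lv.ndim == 2:
        lv = lv[:, :, None]
        msk = msk[:, :, None]
    P = np.zeros((n_levels, n_levels), dtype=np.float64)
    nr, nc, ns = lv.shape
    for z in range(ns):
        for r in range(nr):
            for c in range(nc):
                if not msk[r, c, z]:
                    continue
                for dr, dc in offsets:
                    r2, c2 = r + dr, c + dc
                    if 0 <= r2 < nr and 0 <= c2 < nc and msk[r2, c2, z]:
                        i, j = lv[r, c, z] - 1, lv[r2, c2, z] - 1
                        P[i, j] += 1
                        P[j, i] += 1
    total = P.sum()
    if total == 0:
        return (np.nan,) * 4
    P /= total
    idx = np.arange(1, n_levels + 1, dtype=np.float64)
    contrast = sum(P[i, j] * (idx[i] - idx[j]) ** 2
                   for i in range(n_levels) for j in range(n_levels))
    energy = float((P ** 2).sum())
    homog = sum(P[i, j] / (1 + abs(idx[i] - idx[j]))
                for i in range(n_levels) for j in range(n_levels))
    pi = P.sum(axis=1)
    pj = P.sum(axis=0)
    mi = float((idx * pi).sum())
    mj = float((idx * pj).sum())
    si = np.sqrt(float((pi * (idx - mi) ** 2).sum()))
    sj = np.sqrt(float((pj * (idx - mj) ** 2).sum()))
    if si * sj <= 0:
        corr = 0.0
    else:
        corr = sum(P[i, j] * (idx[i] - mi) * (idx[j] - mj)
                   for i in range(n_levels)
                   for j in range(n_levels)) / (si * sj)
    return float(contrast), float(corr), energy, float(homog)


def best_tree_sse(X: np.ndarray, y: np.ndarray, max_depth: int,
                  min_leaf: int = 1) -> float:
    """Minimum training SSE over all depth-limited CART trees, by exhaustive
    enumeration of (feature, adjacent-midpoint) splits."""
    y = np.asarray(y, dtype=np.float64)

    def node_sse(idx: np.ndarray) -> float:
        return float(((y[idx] - y[idx].mean()) ** 2).sum())

    def rec(idx: np.ndarray, depth: int) -> float:
        best = node_sse(idx)
        if depth == 0 or len(idx) < 2 * min_leaf:
            return best
        for f in range(X.shape[1]):
            vals = np.unique(X[idx, f])
            for a, b in zip(vals[:-1], vals[1:]):
                thr = (a + b) / 2
                left = idx[X[idx, f] <= thr]
                right = idx[X[idx, f] > thr]
                if len(left) < min_leaf or len(right) < min_leaf:
                    continue
                cand = rec(left, depth - 1) + rec(right, depth - 1)
                if cand < best:
                    best = cand
        return best

    return rec(np.arange(len(y)), max_depth)


def pair_auc(y: Sequence[int], prob: Sequence[float]) -> float:
    """AUC by direct pair counting, ties 1/2."""
    y = np.asarray(y)
    p = np.asarray(prob, dtype=np.float64)
    pos = p[y == 1]
    neg = p[y == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


def synthetic_table(n: int = 20, p: int = 8, signal: float = 0.0,
                    seed: int = 0):
    """A minimal FeatureTable-like cohort: Gaussian features, alternating
    short/long labels, optional mean shift on the first two features."""
    from habitatsurv import radiomics

    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    labels = ["short" if i % 2 == 0 else "long" for i in range(n)]
    y = np.array([1 if l == "short" else 0 for l in labels])
    X[:, :2] += signal * y[:, None]
    names = [f"f{i:04d}" for i in range(p)]
    ids = [f"S{i + 1:03d}" for i in range(n)]
    df = pd.DataFrame(X, columns=names, index=ids)
    return radiomics.FeatureTable(
        features=df, raw=df.copy(),
        labels=pd.Series(labels, index=ids, name="label"))
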