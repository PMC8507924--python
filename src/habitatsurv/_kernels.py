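"""Numba kernels for CART growing and prediction.

Trees are grown on squared-error reduction.  For 0/1 targets the node sum of
squares equals n*p*(1-p), so the variance-reduction split is exactly the
Gini-impurity split and the recorded per-feature gain is half the Gini
decrease; importances are normalized downstream, so the factor is irrelevant.

Node layout (parallel arrays): ``feature[i] < 0`` marks a leaf; otherwise a
sample goes left iff ``x[feature[i]] <= threshold[i]``.  Split ties are
broken in favor of the first candidate feature scanned, which for the
deterministic tree (ordered candidates) means the lowest feature index.
"""

import numpy as np
from numba import njit

_EPS = 1e-12


@njit(cache=True)
def grow_tree(X, y, max_depth, min_leaf, mtry, seed, use_random):
    n, p = X.shape
    max_nodes = 2 * n + 1
    feature = np.full(max_nodes, -1, np.int64)
    threshold = np.zeros(max_nodes, np.float64)
    left = np.full(max_nodes, -1, np.int64)
    right = np.full(max_nodes, -1, np.int64)
    value = np.zeros(max_nodes, np.float64)
    imp = np.zeros(p, np.float64)
    leaf_of = np.full(n, -1, np.int64)
    idx = np.arange(n)
    if use_random:
        np.random.seed(seed)

    stack_start = np.empty(max_nodes, np.int64)
    stack_end = np.empty(max_nodes, np.int64)
    stack_depth = np.empty(max_nodes, np.int64)
    stack_node = np.empty(max_nodes, np.int64)
    sp = 0
    stack_start[sp] = 0
    stack_end[sp] = n
    stack_depth[sp] = 0
    stack_node[sp] = 0
    sp += 1
    n_nodes = 1

    vbuf = np.empty(n, np.float64)
    ybuf = np.empty(n, np.float64)
    tmp = np.empty(n, np.int64)

    while sp > 0:
        sp -= 1
        start = stack_start[sp]
        end = stack_end[sp]
        depth = stack_depth[sp]
        node = stack_node[sp]
        n_s = end - start

        ysum = 0.0
        ysq = 0.0
        for t in range(start, end):
            yi = y[idx[t]]
            ysum += yi
            ysq += yi * yi
        mean = ysum / n_s
        sse = ysq - n_s * mean * mean
        value[node] = mean

        split_done = False
        if depth < max_depth and n_s >= 2 * min_leaf and sse > _EPS:
            if use_random and mtry < p:
                cand = np.random.permutation(p)[:mtry]
            else:
                cand = np.arange(p)
            best_gain = 0.0
            best_f = -1
            best_thr = 0.0
            base = ysum * ysum / n_s
            for ci in range(cand.shape[0]):
                f = cand[ci]
                for t in range(n_s):
                    vbuf[t] = X[idx[start + t], f]
                order = np.argsort(vbuf[:n_s])
                for t in range(n_s):
                    ybuf[t] = y[idx[start + order[t]]]
                s_left = 0.0
                for s in range(1, n_s):
                    s_left += ybuf[s - 1]
                    lo = vbuf[order[s - 1]]
                    hi = vbuf[order[s]]
                    if hi <= lo:
                        continue
                    if s < min_leaf or n_s - s < min_leaf:
                        continue
                    s_right = ysum - s_left
                    gain = (s_left * s_left / s
                            + s_right * s_right / (n_s - s) - base)
                    if gain > best_gain + _EPS:
                        best_gain = gain
                        best_f = f
                        best_thr = 0.5 * (lo + hi)
            if best_f >= 0:
                # stable partition of idx[start:end] by the chosen split
                n_left = 0
                for t in range(start, end):
                    if X[idx[t], best_f] <= best_thr:
                        tmp[n_left] = idx[t]
                        n_left += 1
                n_right = 0
                for t in range(start, end):
                    if X[idx[t], best_f] > best_thr:
                        tmp[n_left + n_right] = idx[t]
                        n_right += 1
                for t in range(n_s):
                    idx[start + t] = tmp[t]
                feature[node] = best_f
                threshold[node] = best_thr
                left[node] = n_nodes
                right[node] = n_nodes + 1
                imp[best_f] += best_gain
                stack_start[sp] = start
                stack_end[sp] = start + n_left
                stack_depth[sp] = depth + 1
                stack_node[sp] = n_nodes
                sp += 1
                stack_start[sp] = start + n_left
                stack_end[sp] = end
                stack_depth[sp] = depth + 1
                stack_node[sp] = n_nodes + 1
                sp += 1
                n_nodes += 2
                split_done = True
        if not split_done:
            feature[node] = -1
            for t in range(start, end):
                leaf_of[idx[t]] = node
    return (feature[:n_nodes], threshold[:n_nodes], left[:n_nodes],
            right[:n_nodes], value[:n_nodes], imp, leaf_of)


@njit(cache=True)
def predict_tree(X, feature, threshold, left, right, value):
    n = X.shape[0]
    out = np.empty(n, np.float64)
    for i in range(n):
        node = 0
        while feature[node] >= 0:
            if X[i, feature[node]] <= threshold[node]:
                node = left[node]
            else:
                node = right[node]
        out[i] = value[node]
    return out
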