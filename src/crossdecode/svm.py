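"""Soft-margin linear support-vector classification for tiny pattern sets.

The decoding stages of this package fit enormous numbers of very small
binary SVM problems (tens of samples, tens to hundreds of voxels), most of
them inside permutation loops. This module implements the standard C-SVC
dual problem

    min_a  (1/2) a' Q a - e' a,   0 <= a_i <= C,  sum_i a_i y_i = 0,
    Q_ij = y_i y_j x_i . x_j

with an SMO solver (maximal-violating-pair working-set selection, the
classic LIBSVM scheme) compiled with numba so a fit costs microseconds.
The decision rule is f(x) = w.x + b with w = sum_i a_i y_i x_i.

Conventions shared by all callers:

* condition labels are small positive integers; within a pair the smaller
  label maps to y = -1 and the larger to y = +1;
* a test score of exactly 0 is classified as the smaller label, so ties
  break toward the lexicographically smaller condition id.

Equivalence with the reference libsvm implementation (sklearn.svm.SVC,
kernel='linear') is asserted in the test suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "svc_fit",
    "pairwise_decode",
    "permuted_null_accuracies",
    "condition_pairs",
]

_EPS_QUAD = 1e-12


@njit(cache=True)
def _smo(K, y, C, tol, max_iter):
    """Solve the C-SVC dual for gram matrix K and labels y in {-1,+1}.

    Returns (alpha, b). Gradient of the minimized dual is maintained
    incrementally; the working pair is the maximal KKT-violating pair.
    """
    n = y.shape[0]
    alpha = np.zeros(n)
    grad = -np.ones(n)
    for _ in range(max_iter):
        i = -1
        gmax = -1e300
        j = -1
        gmin = 1e300
        for t in range(n):
            yg = -y[t] * grad[t]
            up = (y[t] > 0 and alpha[t] < C) or (y[t] < 0 and alpha[t] > 0)
            lo = (y[t] > 0 and alpha[t] > 0) or (y[t] < 0 and alpha[t] < C)
            if up and yg > gmax:
                gmax = yg
                i = t
            if lo and yg < gmin:
                gmin = yg
                j = t
        if i < 0 or j < 0 or gmax - gmin < tol:
            break
        quad = K[i, i] + K[j, j] - 2.0 * K[i, j]
        if quad <= _EPS_QUAD:
            quad = _EPS_QUAD
        step = (gmax - gmin) / quad
        # feasible range along (alpha_i += y_i t, alpha_j -= y_j t), t >= 0
        tmax = (C - alpha[i]) if y[i] > 0 else alpha[i]
        other = alpha[j] if y[j] > 0 else (C - alpha[j])
        if other < tmax:
            tmax = other
        if step > tmax:
            step = tmax
        di = y[i] * step
        dj = -y[j] * step
        alpha[i] += di
        alpha[j] += dj
        for t in range(n):
            grad[t] += y[t] * (y[i] * di * K[t, i] + y[j] * dj * K[t, j])
    # bias from free support vectors; midpoint of the KKT interval otherwise
    nfree = 0
    bsum = 0.0
    ub = -1e300
    lb = 1e300
    for t in range(n):
        yg = -y[t] * grad[t]
        if 0.0 < alpha[t] < C:
            nfree += 1
            bsum += yg
        else:
            up = (y[t] > 0 and alpha[t] < C) or (y[t] < 0 and alpha[t] > 0)
            lo = (y[t] > 0 and alpha[t] > 0) or (y[t] < 0 and alpha[t] < C)
            if up and yg > ub:
                ub = yg
            if lo and yg < lb:
                lb = yg
    b = bsum / nfree if nfree > 0 else (ub + lb) / 2.0
    return alpha, b


@njit(cache=True)
def svc_fit(X, y, C, tol):
    """Fit a linear C-SVC on samples X (n, p) with labels y in {-1, +1}.

    Returns (w, b) of the primal decision rule f(x) = w.x + b.
    """
    K = X @ X.T
    alpha, b = _smo(K, y, C, tol, 100000)
    w = (alpha * y) @ X
    return w, b


def condition_pairs(conditions):
    """Unordered pairs of the distinct condition ids, ascending."""
    uniq = sorted(set(int(c) for c in conditions))
    return [(a, b) for k, a in enumerate(uniq) for b in uniq[k + 1:]]


@njit(cache=True)
def _pair_accuracy(Xtr, ctr, Xte, cte, lo, hi, C, tol):
    """Train on the (lo, hi) pair, return accuracy on that pair's test
    samples (nan if the pair is absent from the test set)."""
    n_tr = ctr.shape[0]
    idx = np.empty(n_tr, np.int64)
    m = 0
    for t in range(n_tr):
        if ctr[t] == lo or ctr[t] == hi:
            idx[m] = t
            m += 1
    Xp = Xtr[idx[:m]]
    yp = np.empty(m)
    for t in range(m):
        yp[t] = -1.0 if ctr[idx[t]] == lo else 1.0
    w, b = svc_fit(Xp, yp, C, tol)
    hits = 0
    tot = 0
    for t in range(cte.shape[0]):
        if cte[t] == lo or cte[t] == hi:
            score = np.dot(Xte[t], w) + b
            pred = hi if score > 0.0 else lo  # ties -> smaller id
            tot += 1
            if pred == cte[t]:
                hits += 1
    if tot == 0:
        return np.nan
    return hits / tot


@njit(cache=True)
def _decode_all_pairs(Xtr, ctr, Xte, cte, pairs, C, tol):
    n_pairs = pairs.shape[0]
    accs = np.empty(n_pairs)
    for k in range(n_pairs):
        accs[k] = _pair_accuracy(Xtr, ctr, Xte, cte, pairs[k, 0], pairs[k, 1], C, tol)
    return accs


def pairwise_decode(Xtr, cond_tr, Xte, cond_te, C=1.0, tol=1e-4):
    """All-pairs decode: train one binary SVC per condition pair on the
    training set, score each pair on its own test samples.

    Returns (mean_accuracy, per_pair_accuracies, pairs).
    """
    pairs = np.asarray(condition_pairs(cond_tr), dtype=np.int64)
    accs = _decode_all_pairs(
        np.ascontiguousarray(Xtr, dtype=np.float64),
        np.asarray(cond_tr, dtype=np.int64),
        np.ascontiguousarray(Xte, dtype=np.float64),
        np.asarray(cond_te, dtype=np.int64),
        pairs, float(C), float(tol),
    )
    return float(np.nanmean(accs)), accs, pairs


@njit(cache=True)
def _shuffle_within_runs(cond, runs, out):
    """Permute condition labels independently within each run (in place
    into ``out``), using numba's global np.random stream."""
    n = cond.shape[0]
    for t in range(n):
        out[t] = cond[t]
    # iterate distinct runs
    done = np.zeros(n, np.uint8)
    for s in range(n):
        if done[s]:
            continue
        r = runs[s]
        idx = np.empty(n, np.int64)
        m = 0
        for t in range(n):
            if runs[t] == r:
                idx[m] = t
                m += 1
                done[t] = 1
        # Fisher-Yates over the labels at idx[:m]
        for t in range(m - 1, 0, -1):
            u = np.random.randint(0, t + 1)
            tmp = out[idx[t]]
            out[idx[t]] = out[idx[u]]
            out[idx[u]] = tmp


@njit(cache=True)
def _null_accs(Xtr, ctr, runs_tr, Xte, cte, pairs, n_perm, C, tol, seed):
    np.random.seed(seed)
    out = np.empty(n_perm)
    shuffled = np.empty(ctr.shape[0], np.int64)
    for it in range(n_perm):
        _shuffle_within_runs(ctr, runs_tr, shuffled)
        accs = _decode_all_pairs(Xtr, shuffled, Xte, cte, pairs, C, tol)
        s = 0.0
        m = 0
        for k in range(accs.shape[0]):
            if not np.isnan(accs[k]):
                s += accs[k]
                m += 1
        out[it] = s / m if m > 0 else np.nan
    return out


def permuted_null_accuracies(Xtr, cond_tr, runs_tr, Xte, cond_te,
                             n_perm, seed, C=1.0, tol=1e-4):
    """Mean all-pairs accuracies under n_perm within-run shuffles of the
    training labels; the full train->test chain is re-run per iteration.

    ``seed`` must be a non-negative int < 2**32 (numba RNG seed).
    """
    pairs = np.asarray(condition_pairs(cond_tr), dtype=np.int64)
    return _null_accs(
        np.ascontiguousarray(Xtr, dtype=np.float64),
        np.asarray(cond_tr, dtype=np.int64),
        np.asarray(runs_tr, dtype=np.int64),
        np.ascontiguousarray(Xte, dtype=np.float64),
        np.asarray(cond_te, dtype=np.int64),
        pairs, int(n_perm), float(C), float(tol), np.uint32(seed),
    )
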