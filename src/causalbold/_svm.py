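"""Minimal linear SVM used inside the recursive cluster elimination loop.

The cluster-scoring step of RCE-SVM fits on the order of 10^5 linear
SVMs on tiny matrices (a few dozen subjects, a handful of features).
This module solves the L1-hinge dual by coordinate descent (the
liblinear-style algorithm of Hsieh et al., 2008) with the bias handled
as an augmented constant feature, JIT-compiled with numba; the whole
clusters x repetitions x folds cross-validation loop runs inside one
kernel.  Its decision boundaries agree with
``sklearn.svm.SVC(kernel="linear")`` on such problems, which the test
suite checks directly.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_MAX_PASSES = 400
_TOL = 1e-4


@njit(cache=False)
def _dcd_fit(xa: np.ndarray, yv: np.ndarray, c: float, max_passes: int, tol: float) -> np.ndarray:
    """Dual coordinate descent on pre-augmented rows ``xa`` (bias column last)."""
    n, d = xa.shape
    q = np.empty(n)
    for i in range(n):
        s = 0.0
        for j in range(d):
            s += xa[i, j] * xa[i, j]
        q[i] = s
    alpha = np.zeros(n)
    w = np.zeros(d)
    for it in range(max_passes):
        max_pg = 0.0
        for k in range(n):
            i = (it * 7 + k) % n  # rotating deterministic sweep order
            g = 0.0
            for j in range(d):
                g += xa[i, j] * w[j]
            grad = yv[i] * g - 1.0
            a = alpha[i]
            if a == 0.0:
                pg = grad if grad < 0.0 else 0.0
            elif a == c:
                pg = grad if grad > 0.0 else 0.0
            else:
                pg = grad
            apg = -pg if pg < 0.0 else pg
            if apg > 1e-12:
                if apg > max_pg:
                    max_pg = apg
                a_new = a - grad / q[i]
                if a_new < 0.0:
                    a_new = 0.0
                elif a_new > c:
                    a_new = c
                coef = (a_new - a) * yv[i]
                for j in range(d):
                    w[j] += coef * xa[i, j]
                alpha[i] = a_new
        if max_pg < tol:
            break
    return w


@njit(cache=False)
def _score_clusters_kernel(
    x: np.ndarray,          # (n_subjects, n_features) standardized training data
    y: np.ndarray,          # (n_subjects,) labels in {-1, +1}
    feat_idx: np.ndarray,   # flattened cluster feature indices
    ptr: np.ndarray,        # cluster ci owns feat_idx[ptr[ci]:ptr[ci+1]]
    fold_ids: np.ndarray,   # (n_reps, n_subjects) fold id per subject
    n_folds: int,
    c: float,
) -> np.ndarray:
    n = x.shape[0]
    n_clusters = ptr.shape[0] - 1
    n_reps = fold_ids.shape[0]
    scores = np.zeros(n_clusters)
    for ci in range(n_clusters):
        k = ptr[ci + 1] - ptr[ci]
        xa = np.empty((n, k + 1))
        for i in range(n):
            for j in range(k):
                xa[i, j] = x[i, feat_idx[ptr[ci] + j]]
            xa[i, k] = 1.0
        total = 0.0
        count = 0
        xtr = np.empty((n, k + 1))
        ytr = np.empty(n)
        for r in range(n_reps):
            for f in range(n_folds):
                n_tr = 0
                n_te = 0
                for i in range(n):
                    if fold_ids[r, i] != f:
                        for j in range(k + 1):
                            xtr[n_tr, j] = xa[i, j]
                        ytr[n_tr] = y[i]
                        n_tr += 1
                    else:
                        n_te += 1
                if n_te == 0:
                    continue
                w = _dcd_fit(xtr[:n_tr], ytr[:n_tr], c, _MAX_PASSES, _TOL)
                correct = 0
                for i in range(n):
                    if fold_ids[r, i] == f:
                        dec = w[k]
                        for j in range(k):
                            dec += xa[i, j] * w[j]
                        pred = 1.0 if dec >= 0.0 else -1.0
                        if pred == y[i]:
                            correct += 1
                total += correct / n_te
                count += 1
        scores[ci] = total / count
    return scores


def score_feature_clusters(
    x: np.ndarray,
    y_signed: np.ndarray,
    clusters: list[np.ndarray],
    fold_ids: np.ndarray,
    n_folds: int,
    c: float = 1.0,
) -> np.ndarray:
    """Cross-validated SVM score per feature cluster (vectorized kernel).

    ``fold_ids`` assigns each subject to a fold for every repetition;
    the score of a cluster is the mean held-out accuracy over all
    repetitions and folds using only that cluster's features.
    """
    feat_idx = (
        np.concatenate(clusters).astype(np.int64)
        if clusters
        else np.empty(0, dtype=np.int64)
    )
    ptr = np.zeros(len(clusters) + 1, dtype=np.int64)
    for i, cl in enumerate(clusters):
        ptr[i + 1] = ptr[i] + len(cl)
    return _score_clusters_kernel(
        np.ascontiguousarray(x, dtype=np.float64),
        np.ascontiguousarray(y_signed, dtype=np.float64),
        feat_idx,
        ptr,
        np.ascontiguousarray(fold_ids, dtype=np.int64),
        int(n_folds),
        float(c),
    )


def svm_fit(x: np.ndarray, y_signed: np.ndarray, c: float = 1.0) -> np.ndarray:
    """Fit a linear SVM; returns weights with the bias as the last entry.

    ``y_signed`` must be ±1.  Deterministic.
    """
    x = np.ascontiguousarray(x, dtype=np.float64)
    xa = np.hstack([x, np.ones((x.shape[0], 1))])
    return _dcd_fit(
        xa, np.ascontiguousarray(y_signed, dtype=np.float64), c, _MAX_PASSES, _TOL
    )


def svm_decision(w: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Signed decision values for samples in rows of ``x``."""
    return x @ w[:-1] + w[-1]


def svm_predict(w: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Predicted ±1 labels (ties go to +1)."""
    return np.where(svm_decision(w, x) >= 0.0, 1.0, -1.0)
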