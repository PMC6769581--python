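"""Independent brute-force reference implementations used as test oracles.

Everything here is written for clarity, not speed: explicit loops and
full-matrix decompositions, kept free of any code path from the package
internals they are checking.
"""

from __future__ import annotations

import numpy as np


def conv1d_same_bruteforce(
    x: np.ndarray, filters: np.ndarray, biases: np.ndarray
) -> np.ndarray:
    """Triple-loop same-padded multi-channel convolution.

    ``out[i, m] = sum_{u,d} filters[m, d, u] * x[i + u - k//2, d] + b[m]``
    with zero padding outside the input.
    """
    L, D = x.shape
    n, Df, k = filters.shape
    assert D == Df and k % 2 == 1
    pad = k // 2
    out = np.zeros((L, n), dtype=float)
    for m in range(n):
        for i in range(L):
            s = float(biases[m])
            for u in range(k):
                ii = i + u - pad
                if 0 <= ii < L:
                    for d in range(D):
                        s += float(filters[m, d, u]) * float(x[ii, d])
            out[i, m] = s
    return out


def column_mode(col: np.ndarray, n_classes: int) -> int:
    """Most frequent observed class; ties toward the lower class."""
    counts = [(col == c).sum() for c in range(1, n_classes + 1)]
    return int(np.argmax(counts)) + 1


def knn_impute_bruteforce(
    values: np.ndarray,
    n_classes: int,
    k: int,
    weighting: str = "uniform",
) -> np.ndarray:
    """Exhaustive-search KNN voting with normalised euclidean distances.

    Candidate neighbours of a missing entry (i, j) are rows observed at j;
    distances are root-mean-square differences over markers observed in
    both rows; distance ties resolve to the lower sample index; class-vote
    ties resolve to the lower class.
    """
    n, m = values.shape
    completed = values.copy()

    def dist(a: int, b: int) -> float:
        shared = (values[a] > 0) & (values[b] > 0)
        if not shared.any():
            return np.inf
        diff = values[a, shared].astype(float) - values[b, shared].astype(float)
        return float(np.sqrt((diff**2).mean()))

    for i in range(n):
        for j in range(m):
            if values[i, j] != 0:
                continue
            pairs = [
                (dist(i, r), r)
                for r in range(n)
                if r != i and values[r, j] > 0
            ]
            pairs = [(d, r) for d, r in pairs if np.isfinite(d)]
            if not pairs:
                obs = values[values[:, j] > 0, j]
                completed[i, j] = column_mode(obs, n_classes) if len(obs) else 1
                continue
            pairs.sort(key=lambda t: (t[0], t[1]))
            chosen = pairs[: min(k, len(pairs))]
            votes = np.zeros(n_classes)
            for d, r in chosen:
                w = 1.0 if weighting == "uniform" else 1.0 / max(d, 1e-8)
                votes[values[r, j] - 1] += w
            completed[i, j] = int(np.argmax(votes)) + 1
    return completed


def svd_em_trace(
    values: np.ndarray, rank: int, n_iter: int
) -> np.ndarray:
    """Step-by-step reference of the EM-style low-rank completion.

    Missing entries start at observed column means; each iteration replaces
    them with the rank-``rank`` truncated-SVD reconstruction of the filled
    matrix. Returns the continuous filled matrix after ``n_iter`` steps.
    """
    obs = values > 0
    miss = ~obs
    cnt = obs.sum(axis=0)
    overall = values[obs].mean() if obs.any() else 1.0
    col_means = np.where(cnt > 0, values.sum(axis=0) / np.maximum(cnt, 1), overall)
    filled = values.astype(float)
    filled[miss] = np.broadcast_to(col_means, values.shape)[miss]
    for _ in range(n_iter):
        U, s, Vt = np.linalg.svd(filled, full_matrices=False)
        approx = (U[:, :rank] * s[:rank]) @ Vt[:rank]
        filled[miss] = approx[miss]
    return filled


def round_to_class_bruteforce(x: np.ndarray, n_classes: int) -> np.ndarray:
    """Nearest valid class with half-way ties toward the lower class."""
    out = np.empty(x.shape, dtype=np.int64)
    flat_x = x.ravel()
    flat_o = out.ravel()
    for idx, val in enumerate(flat_x):
        best, best_d = 1, abs(val - 1)
        for c in range(2, n_classes + 1):
            d = abs(val - c)
            if d < best_d - 1e-12:
                best, best_d = c, d
        flat_o[idx] = best
    return out
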