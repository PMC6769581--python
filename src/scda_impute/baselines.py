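"""Reference-free classical imputation baselines.

Three training-free methods complete a corrupted genotype matrix in place
of the autoencoder: a per-column central value (mode or rounded mean),
k-nearest-neighbour voting over sample rows, and iterative low-rank SVD
completion fitted by expectation-maximisation. All three preserve observed
entries and emit valid genotype classes; continuous estimates are rounded
to the nearest class with ties broken toward the lower class index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse.linalg

from .genotype_io import GenotypeMatrix, ImputationResult, MaskIndex

logger = logging.getLogger(__name__)

__all__ = [
    "KNNConfig",
    "SVDConfig",
    "impute_column_central",
    "impute_knn",
    "impute_svd_em",
]


@dataclass(frozen=True)
class KNNConfig:
    k: int = 10
    metric: str = "euclidean"  # euclidean | pearson | cosine
    weighting: str = "inverse_distance"  # uniform | inverse_distance

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.metric not in ("euclidean", "pearson", "cosine"):
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.weighting not in ("uniform", "inverse_distance"):
            raise ValueError(f"unknown weighting {self.weighting!r}")


@dataclass(frozen=True)
class SVDConfig:
    rank: int = 10
    max_iter: int = 100
    tol: float = 1e-4

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ValueError("rank must be >= 1")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


def _round_to_class(x: np.ndarray, n_classes: int) -> np.ndarray:
    """Round continuous estimates to the nearest valid class, clamped to
    ``[1, n_classes]``; exact half-way values go to the lower class."""
    x = np.clip(x, 1.0, float(n_classes))
    return np.ceil(x - 0.5).astype(np.int64).clip(1, n_classes)


def _column_modes(values: np.ndarray, n_classes: int) -> tuple[np.ndarray, int]:
    """Per-column mode over observed entries (ties toward the lower class)
    and the global mode for fully-missing columns."""
    counts = np.stack(
        [(values == c).sum(axis=0) for c in range(1, n_classes + 1)], axis=0
    )
    modes = counts.argmax(axis=0) + 1  # argmax keeps the first/lowest class
    global_counts = counts.sum(axis=1)
    global_mode = int(global_counts.argmax()) + 1
    empty = counts.sum(axis=0) == 0
    if empty.any():
        logger.warning(
            "%d fully-missing columns filled with global mode %d",
            int(empty.sum()),
            global_mode,
        )
        modes[empty] = global_mode
    return modes, global_mode


def impute_column_central(
    gm: GenotypeMatrix, statistic: str = "mode", mask: MaskIndex | None = None
) -> ImputationResult:
    """Fill each missing entry with its column's central value.

    ``statistic="mode"`` uses the most frequent observed class per column;
    ``"mean_rounded"`` uses the observed-class mean rounded to the nearest
    class (half-way ties toward the lower class). Fully-missing columns
    fall back to the global mode with a logged warning.
    """
    if statistic not in ("mode", "mean_rounded"):
        raise ValueError(f"unknown statistic {statistic!r}")
    v = gm.values
    obs = v > 0
    modes, global_mode = _column_modes(v, gm.n_classes)
    if statistic == "mode":
        fill = modes
    else:
        cnt = obs.sum(axis=0)
        with np.errstate(invalid="ignore"):
            means = np.where(cnt > 0, v.sum(axis=0) / np.maximum(cnt, 1), global_mode)
        fill = _round_to_class(means, gm.n_classes)
        fill = np.where(cnt > 0, fill, global_mode)
    completed = gm.copy()
    miss_i, miss_j = np.nonzero(~obs)
    completed.values[miss_i, miss_j] = fill[miss_j]
    return ImputationResult(completed, mask_used=mask)


def _pairwise_distances(values: np.ndarray, metric: str) -> np.ndarray:
    """Row-pair distances over markers observed in *both* rows.

    Euclidean distances are normalised by the shared-observed count (root
    mean squared difference) so rows with different missingness are
    comparable. Pairs with no shared markers get +inf.
    """
    O = (values > 0).astype(np.float64)
    X = values.astype(np.float64) * O
    n_shared = O @ O.T
    with np.errstate(divide="ignore", invalid="ignore"):
        if metric == "euclidean":
            sq = (X**2) @ O.T
            d2 = (sq + sq.T - 2 * (X @ X.T)) / n_shared
            d = np.sqrt(np.maximum(d2, 0.0))
        elif metric == "cosine":
            dot = X @ X.T
            sq = (X**2) @ O.T
            denom = np.sqrt(sq * sq.T)
            d = 1.0 - dot / denom
        else:  # pearson
            s1 = X @ O.T  # sum of row-i values over shared markers
            sxy = X @ X.T
            sxx = (X**2) @ O.T
            n = n_shared
            cov = n * sxy - s1 * s1.T
            var_i = n * sxx - s1**2
            denom = np.sqrt(var_i * var_i.T)
            d = 1.0 - cov / denom
    d[n_shared == 0] = np.inf
    d[~np.isfinite(d)] = np.inf
    np.fill_diagonal(d, np.inf)  # a row never neighbours itself
    return d


def impute_knn(
    gm: GenotypeMatrix, cfg: KNNConfig = KNNConfig(), mask: MaskIndex | None = None
) -> ImputationResult:
    """K-nearest-neighbour imputation by weighted class vote.

    For a missing entry (i, j), candidate neighbours are the samples
    observed at marker j; distances are computed over markers observed in
    both rows (normalised by the shared count). The k nearest candidates
    vote for their class at j — plain mode under uniform weighting,
    inverse-distance-weighted mode otherwise — with ties toward the lower
    class. If no candidate is observed at j the column mode is used. When
    fewer than k candidates exist, all of them vote.
    """
    v = gm.values
    n, m = v.shape
    if cfg.k > n - 1:
        logger.warning("k=%d exceeds n_samples-1=%d; truncating", cfg.k, n - 1)
    completed = gm.copy()
    miss = v == 0
    if not miss.any():
        return ImputationResult(completed, mask_used=mask)
    d = _pairwise_distances(v, cfg.metric)
    modes, _ = _column_modes(v, gm.n_classes)
    eps = 1e-8
    for j in np.nonzero(miss.any(axis=0))[0]:
        cand = np.nonzero(v[:, j] > 0)[0]
        rows = np.nonzero(miss[:, j])[0]
        if len(cand) == 0:
            completed.values[rows, j] = modes[j]
            logger.warning("no observed neighbour at marker %d; column mode used", j)
            continue
        for i in rows:
            di = d[i, cand]
            finite = np.isfinite(di)
            if not finite.any():
                completed.values[i, j] = modes[j]
                continue
            cand_f, di_f = cand[finite], di[finite]
            k = min(cfg.k, len(cand_f))
            # stable sort: distance ties resolve to the lowest sample index
            nearest = np.argsort(di_f, kind="stable")[:k]
            classes = v[cand_f[nearest], j]
            if cfg.weighting == "uniform":
                w = np.ones(k)
            else:
                w = 1.0 / np.maximum(di_f[nearest], eps)
            votes = np.zeros(gm.n_classes)
            np.add.at(votes, classes - 1, w)
            completed.values[i, j] = int(votes.argmax()) + 1
    return ImputationResult(completed, mask_used=mask)


def _truncated_svd(filled: np.ndarray, rank: int) -> np.ndarray:
    """Best rank-r approximation of a dense matrix."""
    if rank >= min(filled.shape) - 1 or min(filled.shape) <= 200:
        U, s, Vt = np.linalg.svd(filled, full_matrices=False)
        return (U[:, :rank] * s[:rank]) @ Vt[:rank]
    U, s, Vt = scipy.sparse.linalg.svds(filled, k=rank)
    return (U * s) @ Vt


def impute_svd_em(
    gm: GenotypeMatrix, cfg: SVDConfig = SVDConfig(), mask: MaskIndex | None = None
) -> ImputationResult:
    """Iterative low-rank SVD completion (EM-style).

    Missing entries are initialised with column means of observed classes,
    then alternately re-estimated from the rank-r truncated SVD of the
    filled matrix until the largest absolute change at a missing entry
    drops below ``tol`` or ``max_iter`` is reached. Final continuous
    estimates are rounded to the nearest valid class. The result's ``info``
    carries convergence diagnostics and the per-iteration observed-entry
    Frobenius error of the low-rank fit.
    """
    v = gm.values
    n, m = v.shape
    if cfg.rank >= min(n, m):
        raise ValueError(f"rank {cfg.rank} must be < min(n_samples, n_markers)")
    obs = v > 0
    miss = ~obs
    cnt = obs.sum(axis=0)
    global_mean = v[obs].mean() if obs.any() else 1.0
    with np.errstate(invalid="ignore"):
        col_means = np.where(cnt > 0, v.sum(axis=0) / np.maximum(cnt, 1), global_mean)
    filled = v.astype(np.float64)
    filled[miss] = np.broadcast_to(col_means, (n, m))[miss]

    converged = False
    n_iter = 0
    objective: list[float] = []
    raw_missing = filled[miss]
    for n_iter in range(1, cfg.max_iter + 1):
        approx = _truncated_svd(filled, cfg.rank)
        objective.append(float(np.linalg.norm((approx - filled)[obs])))
        new_missing = approx[miss]
        delta = float(np.abs(new_missing - raw_missing).max()) if miss.any() else 0.0
        filled[miss] = new_missing
        raw_missing = new_missing
        if delta < cfg.tol:
            converged = True
            break
    if not converged and miss.any():
        logger.warning("SVD-EM did not converge in %d iterations", cfg.max_iter)

    completed = gm.copy()
    completed.values[miss] = _round_to_class(filled[miss], gm.n_classes)
    return ImputationResult(
        completed,
        mask_used=mask,
        info={
            "converged": converged,
            "n_iter": n_iter,
            "objective": objective,
            "raw_estimates": filled,
        },
    )
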