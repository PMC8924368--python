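"""Resampling consensus clustering with CDF / delta-area selection of k.

Samples are repeatedly subsampled and partitioned with PAM (k-medoids,
Euclidean distance, deterministic greedy build + swap), and the consensus
matrix entry M(i, j) is the fraction of co-samplings in which i and j landed
in the same cluster.  Stability across k is summarized by the empirical CDF
of consensus entries and its area; the relative area gain (delta-area) as k
grows drives the choice of k.  Final assignments come from Ward-linkage
agglomeration on the dissimilarity 1 - M.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)

CDF_GRID = np.linspace(0.0, 1.0, 101)


def pam(D: np.ndarray, k: int) -> np.ndarray:
    """Deterministic PAM k-medoids on a precomputed distance matrix.

    Greedy BUILD phase then best-improvement SWAP passes; ties broken by the
    smallest index, so the partition is a pure function of (D, k).
    Returns integer labels 0..k-1 (label = order of the medoid's index).
    """
    n = D.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds number of points n={n}")
    # BUILD: start from the most central point, then add the point giving the
    # largest reduction in total distance to the nearest medoid
    medoids = [int(np.argmin(D.sum(axis=0)))]
    nearest = D[medoids[0]].copy()
    while len(medoids) < k:
        gain = np.maximum(nearest[None, :] - D, 0.0).sum(axis=1)
        gain[medoids] = -1.0
        c = int(np.argmax(gain))
        medoids.append(c)
        nearest = np.minimum(nearest, D[c])
    # SWAP: replace (medoid, candidate) pairs while total cost decreases
    medoids = np.array(sorted(medoids))
    cost = D[medoids].min(axis=0).sum()
    for _ in range(200):
        best = (0.0, None)
        for mi, m in enumerate(medoids):
            others = np.delete(medoids, mi)
            d_others = D[others].min(axis=0) if len(others) else np.full(n, np.inf)
            # cost after swapping m for each candidate h (rows of D)
            cand_cost = np.minimum(D, d_others[None, :]).sum(axis=1)
            cand_cost[medoids] = np.inf
            h = int(np.argmin(cand_cost))
            improvement = cost - cand_cost[h]
            if improvement > best[0] + 1e-12:
                best = (improvement, (mi, h))
        if best[1] is None:
            break
        mi, h = best[1]
        medoids[mi] = h
        medoids = np.sort(medoids)
        cost = D[medoids].min(axis=0).sum()
    return np.argmin(D[medoids], axis=0)


def consensus_matrix(
    data: np.ndarray | pd.DataFrame,
    k: int,
    n_resamples: int = 1000,
    subsample_frac: float = 0.8,
    seed: int = 0,
) -> np.ndarray:
    """Co-clustering frequency matrix over subsampled PAM partitions.

    M(i, j) = (# resamples clustering i and j together) / (# resamples
    containing both), with unit diagonal.  Pairs never co-sampled are set to
    0 with a warning.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if not (0 < subsample_frac <= 1):
        raise ValueError("subsample_frac must be in (0, 1]")
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    X = np.asarray(data, dtype=float)
    n = X.shape[0]
    m = int(np.ceil(subsample_frac * n))
    if k > m:
        raise ValueError(f"k={k} exceeds subsample size {m}")
    D = squareform(pdist(X))
    rng = np.random.default_rng(seed)
    together = np.zeros((n, n))
    cosampled = np.zeros((n, n))
    for _ in range(n_resamples):
        idx = np.sort(rng.choice(n, size=m, replace=False)) if m < n else np.arange(n)
        labels = pam(D[np.ix_(idx, idx)], k)
        onehot = np.zeros((m, k))
        onehot[np.arange(m), labels] = 1.0
        together[np.ix_(idx, idx)] += onehot @ onehot.T
        cosampled[np.ix_(idx, idx)] += 1.0
    never = (cosampled == 0) & ~np.eye(n, dtype=bool)
    if never.any():
        logger.warning(
            "%d sample pair(s) never co-sampled; consensus set to 0", int(never.sum() // 2)
        )
    M = np.divide(together, cosampled, out=np.zeros((n, n)), where=cosampled > 0)
    np.fill_diagonal(M, 1.0)
    return M


def consensus_cdf(M: np.ndarray) -> np.ndarray:
    """Empirical CDF of the upper-triangle consensus entries on CDF_GRID."""
    tri = np.sort(M[np.triu_indices(M.shape[0], 1)])
    return np.searchsorted(tri, CDF_GRID, side="right") / len(tri)


@dataclass
class ConsensusResult:
    """Consensus matrices, CDF summaries, and assignments at the selected k."""

    k_range: list[int]
    matrices: dict[int, np.ndarray]
    cdfs: dict[int, np.ndarray]
    areas: dict[int, float]
    delta_areas: dict[int, float]
    selected_k: int
    assignments: pd.Series  # labels 1..k, cluster 1 = largest


def select_k(
    areas: dict[int, float],
    delta_threshold: float = 0.1,
    elbow_frac: float = 0.5,
) -> tuple[int, dict[int, float]]:
    """Pick k from the areas under the consensus CDFs.

    Delta-area for the smallest k is its own area; for larger k it is the
    relative gain (A_k - A_{k-1}) / A_{k-1}.  A k qualifies when its delta is
    at least ``delta_threshold`` AND has not collapsed relative to the
    previous gain (delta_k >= ``elbow_frac`` * delta_{k-1}): adding a cluster
    beyond the true number still inflates the CDF area slightly (an extra
    cluster splits a real one semi-stably), so an absolute threshold alone
    over-selects; the elbow condition demands that the gain be comparable to
    the preceding one.  The selected k is the largest qualifying k; if none
    qualifies, the k maximizing delta (fallback, logged).
    """
    ks = sorted(areas)
    if not ks:
        raise ValueError("empty k range")
    deltas: dict[int, float] = {}
    for i, k in enumerate(ks):
        if i == 0:
            deltas[k] = areas[k]
        else:
            prev = areas[ks[i - 1]]
            deltas[k] = (areas[k] - prev) / prev if prev > 0 else np.inf
    qualifying = [
        k for i, k in enumerate(ks)
        if deltas[k] >= delta_threshold
        and (i == 0 or deltas[k] >= elbow_frac * deltas[ks[i - 1]])
    ]
    if qualifying:
        return max(qualifying), deltas
    fallback = max(ks, key=lambda k: deltas[k])
    logger.warning("no k qualified at delta-area >= %.2f; falling back to argmax delta (k=%d)",
                   delta_threshold, fallback)
    return fallback, deltas


def assign_clusters(M: np.ndarray, k: int, sample_ids=None) -> pd.Series:
    """Ward-linkage clustering of 1 - M cut at k clusters.

    Labels are renamed deterministically: cluster 1 is the largest, ties
    broken by the smallest member index.
    """
    n = M.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    dist = 1.0 - M
    np.fill_diagonal(dist, 0.0)
    # symmetrize against floating noise before condensing
    dist = (dist + dist.T) / 2.0
    Z = linkage(squareform(dist, checks=False), method="ward")
    raw = fcluster(Z, t=k, criterion="maxclust")
    order = sorted(
        np.unique(raw),
        key=lambda lab: (-(raw == lab).sum(), int(np.flatnonzero(raw == lab)[0])),
    )
    rename = {lab: i + 1 for i, lab in enumerate(order)}
    labels = np.array([rename[lab] for lab in raw])
    if sample_ids is None:
        sample_ids = pd.RangeIndex(n)
    return pd.Series(labels, index=sample_ids, name="cluster")


def run_consensus(
    data: pd.DataFrame,
    k_range=range(2, 7),
    n_resamples: int = 1000,
    subsample_frac: float = 0.8,
    delta_threshold: float = 0.1,
    seed: int = 0,
) -> ConsensusResult:
    """Full consensus-clustering sweep: matrices for each k, CDF/delta-area
    selection, and Ward assignments at the selected k.

    ``data`` is samples x features (e.g. cell fractions, or transposed
    expression restricted to DEGs).
    """
    ks = sorted(k_range)
    if not ks or min(ks) < 2:
        raise ValueError("k_range must be non-empty with min >= 2")
    rng = np.random.default_rng(seed)
    matrices, cdfs, areas = {}, {}, {}
    for k in ks:
        M = consensus_matrix(
            data, k, n_resamples=n_resamples, subsample_frac=subsample_frac,
            seed=int(rng.integers(2**31)),
        )
        matrices[k] = M
        cdfs[k] = consensus_cdf(M)
        areas[k] = float(np.trapezoid(cdfs[k], CDF_GRID))
    selected, deltas = select_k(areas, delta_threshold=delta_threshold)
    assignments = assign_clusters(matrices[selected], selected, sample_ids=data.index)
    return ConsensusResult(
        k_range=ks, matrices=matrices, cdfs=cdfs, areas=areas,
        delta_areas=deltas, selected_k=selected, assignments=assignments,
    )
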