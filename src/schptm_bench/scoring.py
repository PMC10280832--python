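"""Concordance scoring of embeddings: neighbor score, clustering, ARI/AMI.

The neighbor score measures the agreement of two embeddings of the same
cells.  For a grid of neighborhood sizes k (given as fractions of the cell
count), it builds the k-nearest-neighbor graph in each embedding, counts per
cell the shared neighbors, divides by k, averages over cells, and finally
averages over the k grid.  A score of 1 means the embeddings agree perfectly
on which cells are similar; two unrelated representations of ~1e4 cells
score about 0.05 under the default self-inclusive convention.

Neighborhoods include the query cell itself by default: with self-inclusive
neighborhoods the random-pairing expectation is mean_k(1/k + ~k/n), which is
about 0.05 at n ~= 1e4 on the default k grid; with self excluded it would be
about 0.028.  The convention is exposed in :class:`NeighborScoreConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.cluster import AgglomerativeClustering, KMeans
from sklearn.metrics import adjusted_mutual_info_score, adjusted_rand_score

from .embeddings import Embedding

__all__ = [
    "NeighborScoreConfig",
    "KnnGraph",
    "k_grid",
    "knn_graph",
    "neighbor_score_single",
    "neighbor_score",
    "cluster_cells",
    "ari",
    "ami",
]

DEFAULT_K_FRACTIONS = (0.001, 0.003, 0.005, 0.01, 0.03, 0.05, 0.10)


@dataclass(frozen=True)
class NeighborScoreConfig:
    k_fractions: tuple = DEFAULT_K_FRACTIONS
    include_self: bool = True
    metric: str = "euclidean"

    def __post_init__(self):
        fr = tuple(self.k_fractions)
        if not fr or any(not 0 < f <= 1 for f in fr):
            raise ValueError("k_fractions must lie in (0, 1]")
        if any(b <= a for a, b in zip(fr, fr[1:])):
            raise ValueError("k_fractions must be strictly increasing")
        object.__setattr__(self, "k_fractions", fr)


@dataclass(frozen=True)
class KnnGraph:
    k: int
    indices: np.ndarray  # n_cells x k, ordered by distance then cell index

    def __post_init__(self):
        idx = np.asarray(self.indices, dtype=np.int64)
        if idx.ndim != 2 or idx.shape[1] != self.k:
            raise ValueError("indices must be n_cells x k")
        object.__setattr__(self, "indices", idx)


def k_grid(n_cells: int, config: NeighborScoreConfig = NeighborScoreConfig()) -> list:
    """Neighborhood sizes from fractions: k = max(1, round-half-up(f * n)),
    capped at n-1 (n when the query cell itself counts), deduplicated
    preserving order."""
    if n_cells < 2:
        raise ValueError("need at least 2 cells")
    cap = n_cells if config.include_self else n_cells - 1
    ks = []
    for f in config.k_fractions:
        k = max(1, int(np.floor(f * n_cells + 0.5)))
        k = min(k, cap)
        if k not in ks:
            ks.append(k)
    return ks


def _ordered_neighbors(coords: np.ndarray, k: int, include_self: bool,
                       metric: str = "euclidean") -> np.ndarray:
    """First k neighbors of every cell, distance-ordered with ascending-index
    tie-break (stable sort over the natural index order)."""
    n = coords.shape[0]
    out = np.empty((n, k), dtype=np.int64)
    chunk = max(1, int(2**25 // max(n, 1)))  # ~256 MiB of float64 distances max
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        d = cdist(coords[lo:hi], coords, metric=metric)
        order = np.argsort(d, axis=1, kind="stable")
        if include_self:
            out[lo:hi] = order[:, :k]
        else:
            for i, row in enumerate(order):
                out[lo + i] = row[row != lo + i][:k]
    return out


def knn_graph(embedding: Embedding, k: int, config: NeighborScoreConfig = NeighborScoreConfig()) -> KnnGraph:
    """k-nearest-neighbor graph of an embedding (deterministic).

    With ``include_self`` the query cell is a candidate like any other (its
    distance 0 sorts first); otherwise it is excluded from its own list.
    """
    n = embedding.n_cells
    cap = n if config.include_self else n - 1
    if not 1 <= k <= cap:
        raise ValueError(f"k must be in [1, {cap}]")
    return KnnGraph(k, _ordered_neighbors(embedding.coords, k, config.include_self, config.metric))


def neighbor_score_single(neighbors_a, neighbors_b, k: int) -> float:
    """Per-cell, single-k agreement: |A intersect B| / k."""
    a, b = set(neighbors_a), set(neighbors_b)
    if len(a) != k or len(b) != k:
        raise ValueError("neighbor sets must both have size k")
    return len(a & b) / k


def _prefix_overlap_scores(idx_a: np.ndarray, idx_b: np.ndarray, ks) -> dict:
    """Mean per-cell overlap fraction for each prefix size k."""
    n = idx_a.shape[0]
    out = {}
    for k in ks:
        shared = np.empty(n)
        for i in range(n):
            shared[i] = np.intersect1d(idx_a[i, :k], idx_b[i, :k], assume_unique=True).size
        out[k] = float(shared.mean() / k)
    return out


def neighbor_score(emb_a: Embedding, emb_b: Embedding,
                   config: NeighborScoreConfig = NeighborScoreConfig()) -> float:
    """Multi-k averaged neighbor score of two embeddings of the same cells.

    For each k in the grid, the mean over cells of the shared-neighbor
    fraction; the final score is the unweighted mean over k values.
    """
    if emb_a.n_cells != emb_b.n_cells or np.any(emb_a.barcodes != emb_b.barcodes):
        offenders = sorted(set(emb_a.barcodes) ^ set(emb_b.barcodes))[:5]
        raise ValueError(f"embeddings must share an aligned barcode set; offenders: {offenders}")
    ks = k_grid(emb_a.n_cells, config)
    kmax = max(ks)
    idx_a = _ordered_neighbors(emb_a.coords, kmax, config.include_self, config.metric)
    idx_b = _ordered_neighbors(emb_b.coords, kmax, config.include_self, config.metric)
    per_k = _prefix_overlap_scores(idx_a, idx_b, ks)
    return float(np.mean([per_k[k] for k in ks]))


def cluster_cells(embedding: Embedding, n_clusters: int, method: str = "kmeans",
                  seed: int | None = 0) -> pd.Series:
    """Cluster an embedding; returns a barcode-indexed label Series.

    ``kmeans`` uses 10 seeded restarts keeping the best inertia; ``ward`` is
    agglomerative with Ward linkage on Euclidean distances, cut at
    ``n_clusters`` (deterministic regardless of seed).
    """
    X = embedding.coords
    if n_clusters > embedding.n_cells:
        raise ValueError("n_clusters exceeds the number of cells")
    if n_clusters > np.unique(X, axis=0).shape[0]:
        raise ValueError("n_clusters exceeds the number of distinct points")
    if method == "kmeans":
        model = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed)
        labels = model.fit_predict(X)
    elif method == "ward":
        labels = AgglomerativeClustering(n_clusters=n_clusters, linkage="ward").fit_predict(X)
    else:
        raise ValueError(f"unknown clustering method {method!r}")
    return pd.Series(labels, index=embedding.barcodes)


def _check_aligned(labels_a, labels_b):
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if len(a) != len(b):
        raise ValueError("label vectors differ in length")
    return a, b


def ari(labels_a, labels_b) -> float:
    """Adjusted Rand index (pair counting, hypergeometric chance model)."""
    a, b = _check_aligned(labels_a, labels_b)
    return float(adjusted_rand_score(a, b))


def ami(labels_a, labels_b) -> float:
    """Adjusted mutual information (arithmetic-mean normaliser)."""
    a, b = _check_aligned(labels_a, labels_b)
    return float(adjusted_mutual_info_score(a, b, average_method="arithmetic"))
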