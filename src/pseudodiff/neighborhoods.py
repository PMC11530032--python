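"""KNN-graph neighborhoods: construction, per-sample counting, pseudotime placement.

A neighborhood is an index cell plus its k nearest neighbors in a
PCA-reduced expression space.  Per-neighborhood per-sample cell counts
form the N x S matrix that the differential tests operate on; the
distance from an index cell to its kth neighbor serves as the density
weight used by the spatial FDR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from pseudodiff.core import CellTable

__all__ = ["KnnGraph", "NeighborhoodSet", "build_knn", "sample_neighborhoods",
           "count_cells", "nhood_pseudotime"]


@dataclass
class KnnGraph:
    """Exact KNN over a PCA embedding; row i holds cell i's k neighbors."""

    indices: np.ndarray   # (n, k) neighbor indices, self excluded
    distances: np.ndarray  # (n, k) matching Euclidean distances
    embedding: np.ndarray  # (n, n_pcs)
    k: int

    @property
    def n_cells(self) -> int:
        return self.indices.shape[0]


@dataclass
class NeighborhoodSet:
    index_cells: np.ndarray        # (N,) cell indices
    membership: sp.csr_matrix      # (N, n_cells) binary
    counts: np.ndarray | None      # (N, S) cells per neighborhood per sample
    nhood_pseudotime: np.ndarray | None
    weights: np.ndarray            # (N,) kth-NN distance of each index cell
    k: int
    embedding_dim: int
    sample_order: list | None = None

    @property
    def n_nhoods(self) -> int:
        return len(self.index_cells)

    def sizes(self) -> np.ndarray:
        return np.asarray(self.membership.sum(axis=1)).ravel().astype(int)


def build_knn(expr, k: int = 15, n_pcs: int = 30, seed: int = 0) -> KnnGraph:
    """PCA to ``n_pcs`` then exact Euclidean KNN (self excluded).

    ``expr`` is log-normalized (optionally HVG-restricted) expression,
    cells as rows; dense or sparse.
    """
    if sp.issparse(expr):
        expr = np.asarray(expr.todense())
    expr = np.asarray(expr, dtype=float)
    n = expr.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of cells ({n})")
    n_pcs = min(n_pcs, n - 1, expr.shape[1])
    emb = PCA(n_components=n_pcs, svd_solver="full", random_state=seed).fit_transform(
        expr - expr.mean(axis=0)
    )
    nn = NearestNeighbors(n_neighbors=k + 1, algorithm="brute", metric="euclidean").fit(emb)
    dist, idx = nn.kneighbors(emb)
    # drop self (first column; guaranteed by zero self-distance with brute force)
    self_col = idx[:, 0] == np.arange(n)
    if not self_col.all():  # degenerate duplicates: remove self wherever it appears
        keep = np.empty((n, k), dtype=int)
        kd = np.empty((n, k))
        for i in range(n):
            row = [(d, j) for d, j in zip(dist[i], idx[i]) if j != i][:k]
            kd[i] = [d for d, _ in row]
            keep[i] = [j for _, j in row]
        idx, dist = keep, kd
    else:
        idx, dist = idx[:, 1:], dist[:, 1:]
    return KnnGraph(indices=idx, distances=dist, embedding=emb, k=k)


def sample_neighborhoods(
    graph: KnnGraph,
    proportion: float = 0.1,
    refined: bool = True,
    seed: int = 0,
) -> NeighborhoodSet:
    """Sample index cells and expand each into index-cell + k-NN neighborhoods.

    With ``refined=True`` each sampled candidate is replaced by the
    candidate-or-neighbor that minimizes the mean distance to the
    candidate's neighbors (pulls index cells toward local density
    peaks), then duplicates are collapsed keeping the lowest cell index.
    The spatial-FDR weight of a neighborhood is the distance from its
    index cell to that cell's kth nearest neighbor.
    """
    if not (0 < proportion <= 1):
        raise ValueError("proportion must lie in (0, 1]")
    n = graph.n_cells
    rng = np.random.default_rng(seed)
    n_cand = int(np.ceil(proportion * n))
    candidates = rng.choice(n, size=n_cand, replace=False)

    if refined:
        refined_idx = np.empty(n_cand, dtype=int)
        for i, c in enumerate(candidates):
            pool = np.concatenate(([c], graph.indices[c]))
            targets = graph.embedding[graph.indices[c]]
            mean_d = np.linalg.norm(
                graph.embedding[pool][:, None, :] - targets[None, :, :], axis=2
            ).mean(axis=1)
            best = np.flatnonzero(mean_d == mean_d.min())
            refined_idx[i] = pool[best].min()  # tie: lowest cell index
        index_cells = refined_idx
    else:
        index_cells = candidates
    index_cells = np.unique(index_cells)

    rows, cols = [], []
    for r, c in enumerate(index_cells):
        members = np.concatenate(([c], graph.indices[c]))
        members = np.unique(members)
        rows.extend([r] * len(members))
        cols.extend(members)
    membership = sp.csr_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)),
        shape=(len(index_cells), n),
    )
    weights = graph.distances[index_cells, -1].astype(float)
    weights = np.maximum(weights, np.finfo(float).tiny)  # strictly positive
    return NeighborhoodSet(
        index_cells=index_cells,
        membership=membership,
        counts=None,
        nhood_pseudotime=None,
        weights=weights,
        k=graph.k,
        embedding_dim=graph.embedding.shape[1],
    )


def count_cells(nhoods: NeighborhoodSet, ct: CellTable) -> np.ndarray:
    """N x S matrix of member-cell counts per sample (stable sample order)."""
    samples = ct.samples
    sample_idx = pd.Categorical(ct.obs["sample"], categories=samples).codes
    onehot = sp.csr_matrix(
        (np.ones(ct.n_cells), (np.arange(ct.n_cells), sample_idx)),
        shape=(ct.n_cells, len(samples)),
    )
    counts = np.asarray((nhoods.membership @ onehot).todense()).astype(int)
    nhoods.counts = counts
    nhoods.sample_order = samples
    return counts


def nhood_pseudotime(nhoods: NeighborhoodSet, ct: CellTable) -> np.ndarray:
    """Median member-cell pseudotime per neighborhood."""
    if "pseudotime" not in ct.obs.columns or ct.obs["pseudotime"].isna().any():
        raise ValueError("all cells need pseudotime before neighborhood placement")
    pt = ct.pseudotime
    med = np.empty(nhoods.n_nhoods)
    m = nhoods.membership
    for r in range(nhoods.n_nhoods):
        members = m.indices[m.indptr[r] : m.indptr[r + 1]]
        med[r] = np.median(pt[members])
    nhoods.nhood_pseudotime = med
    return med
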