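"""Pseudotemporal gene attributes, common-pseudotime transfer and bin merging.

Attributes per (gene, trajectory) are the three dotplot statistics:
Pearson correlation of expression with pseudotime, the peak bin (argmax
of 10 equal-width bin means, lowest index on ties) and the mean of the
10 bin means.  Common pseudotime is transferred between datasets by a
seeded gradient-boosted regression-tree model on shared log-normalized
genes.  Bin similarity asks how well a cross-validated
ensemble-of-trees classifier can tell two pseudotime bins apart:
misclassification at the 0.5 chance ceiling means indistinguishable
(similarity 1), perfect separation means similarity 0; same-pseudotime
bins with similarity above a threshold are merged by union-find.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import pearsonr

from pseudodiff.core import CellTable, normalize_log_cpm
from pseudodiff.trajdiff import assign_intervals

logger = logging.getLogger(__name__)

__all__ = [
    "GeneTrajAttributes",
    "BinSimilarity",
    "gene_attributes",
    "attribute_table",
    "PseudotimeModel",
    "fit_common_pseudotime",
    "predict_common_pseudotime",
    "partition_bins",
    "bin_similarity",
    "merge_bins",
]


@dataclass
class GeneTrajAttributes:
    correlation: float   # Pearson r of expression vs pseudotime, 0 if flat (flagged)
    peak: int            # 1..n_bins
    expression: float    # mean of bin means
    flat: bool = False


@dataclass
class BinSimilarity:
    pair: tuple
    misclassification: float  # in [0, 0.5]
    similarity: float         # chance-normalized, in [0, 1]


# ----------------------------------------------------------------------
# Gene attributes
# ----------------------------------------------------------------------

def gene_attributes(expr, pt, n_bins: int = 10) -> GeneTrajAttributes:
    """Correlation/peak/expression of one gene along one trajectory.

    Bins are equal-width on [0, 1]; bin means ignore empty bins for the
    expression average; correlation is per-cell Pearson, reported as 0
    (flagged) for zero-variance expression.
    """
    expr = np.asarray(expr, dtype=float).ravel()
    pt = np.asarray(pt, dtype=float).ravel()
    if len(expr) < n_bins:
        raise ValueError(f"need at least {n_bins} cells, got {len(expr)}")
    bins = assign_intervals(pt, n_bins)
    means = np.full(n_bins, np.nan)
    for b in range(1, n_bins + 1):
        m = bins == b
        if m.any():
            means[b - 1] = expr[m].mean()
    peak = int(np.nanargmax(means)) + 1
    expression = float(np.nanmean(means))
    if expr.max() == expr.min() or pt.max() == pt.min():
        return GeneTrajAttributes(0.0, peak, expression, flat=True)
    r = float(pearsonr(expr, pt)[0])
    return GeneTrajAttributes(r, peak, expression)


def attribute_table(ct: CellTable, genes: list[str] | None = None,
                    n_bins: int = 10) -> pd.DataFrame:
    """Attributes for many genes of one trajectory (rows: gene_id, corr, peak, expr)."""
    expr = normalize_log_cpm(ct)
    pt = ct.pseudotime
    genes = genes if genes is not None else ct.gene_ids
    gidx = {g: i for i, g in enumerate(ct.gene_ids)}
    rows = []
    for g in genes:
        a = gene_attributes(np.asarray(expr[:, gidx[g]].todense()).ravel(), pt, n_bins)
        rows.append((g, a.correlation, a.peak, a.expression))
    return pd.DataFrame(rows, columns=["gene_id", "correlation", "peak", "expression"])


# ----------------------------------------------------------------------
# Common-pseudotime transfer
# ----------------------------------------------------------------------

@dataclass
class PseudotimeModel:
    """Gradient-boosted pseudotime regressor plus its training feature list."""

    regressor: object
    features: list[str]

    def to_file(self, path) -> None:
        import pickle

        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @classmethod
    def from_file(cls, path) -> "PseudotimeModel":
        import pickle

        with open(path, "rb") as fh:
            return pickle.load(fh)


def _feature_matrix(ct: CellTable, features: list[str]) -> tuple[np.ndarray, int]:
    """Log-normalized expression aligned to ``features``; absent genes are zero columns."""
    expr = normalize_log_cpm(ct)
    gidx = {g: i for i, g in enumerate(ct.gene_ids)}
    X = np.zeros((ct.n_cells, len(features)))
    n_missing = 0
    for j, g in enumerate(features):
        if g in gidx:
            X[:, j] = np.asarray(expr[:, gidx[g]].todense()).ravel()
        else:
            n_missing += 1
    return X, n_missing


def fit_common_pseudotime(
    reference: CellTable,
    features: list[str] | None = None,
    seed: int = 0,
    **gbm_kwargs,
) -> PseudotimeModel:
    """Train a gradient-boosted tree ensemble regressing pseudotime on expression."""
    from sklearn.ensemble import HistGradientBoostingRegressor

    if reference.n_cells < 200:
        raise ValueError("need at least 200 reference cells")
    features = list(features) if features is not None else list(reference.gene_ids)
    X, _ = _feature_matrix(reference, features)
    y = reference.pseudotime
    params = dict(max_iter=300, learning_rate=0.1, max_depth=None, random_state=seed)
    params.update(gbm_kwargs)
    reg = HistGradientBoostingRegressor(**params).fit(X, y)
    return PseudotimeModel(regressor=reg, features=features)


def predict_common_pseudotime(
    model: PseudotimeModel,
    query: CellTable,
    rescale: bool = True,
) -> np.ndarray:
    """Predict pseudotime in [0, 1] for query cells.

    Features missing from the query are imputed as zero (count
    reported); an overlap below 50% warns and below 10% errors.  With
    ``rescale`` the predictions are monotonically min-max rescaled per
    query sample.
    """
    X, n_missing = _feature_matrix(query, model.features)
    overlap = 1.0 - n_missing / len(model.features)
    if overlap < 0.1:
        raise ValueError(f"only {overlap:.0%} of model features present in query")
    if overlap < 0.5:
        logger.warning("only %.0f%% of model features present in query", 100 * overlap)
    if n_missing:
        logger.info("imputed %d missing features as zero", n_missing)
    pred = np.clip(model.regressor.predict(X), 0.0, 1.0)
    if rescale:
        out = np.empty_like(pred)
        for s in query.samples:
            m = (query.obs["sample"] == s).to_numpy()
            lo, hi = pred[m].min(), pred[m].max()
            out[m] = (pred[m] - lo) / (hi - lo) if hi > lo else 0.5
        pred = out
    return pred


# ----------------------------------------------------------------------
# Bin partitioning, similarity, merging
# ----------------------------------------------------------------------

def partition_bins(pt: np.ndarray, n_bins: int = 10) -> np.ndarray:
    """Equal-width pseudotime bins 1..n_bins (same convention as intervals)."""
    return assign_intervals(pt, n_bins)


def bin_similarity(
    rep_a: np.ndarray,
    rep_b: np.ndarray,
    pair=("a", "b"),
    seed: int = 0,
    min_cells: int = 20,
    n_folds: int = 5,
) -> BinSimilarity:
    """Chance-normalized classifier confusion between two cell bins.

    Both bins are downsampled to equal size; an extremely-randomized
    trees classifier is evaluated by stratified ``n_folds``-fold CV on
    the given representation; the out-of-fold misclassification rate m
    (clipped to [0, 0.5]) yields similarity m / 0.5.
    """
    from sklearn.ensemble import ExtraTreesClassifier
    from sklearn.model_selection import StratifiedKFold, cross_val_predict

    rep_a, rep_b = np.asarray(rep_a, float), np.asarray(rep_b, float)
    if min(len(rep_a), len(rep_b)) < min_cells:
        raise ValueError(f"both bins need >= {min_cells} cells")
    rng = np.random.default_rng(seed)
    n = min(len(rep_a), len(rep_b))
    ia = np.sort(rng.choice(len(rep_a), size=n, replace=False))
    ib = np.sort(rng.choice(len(rep_b), size=n, replace=False))
    X = np.vstack([rep_a[ia], rep_b[ib]])
    y = np.concatenate([np.zeros(n, int), np.ones(n, int)])

    clf = ExtraTreesClassifier(n_estimators=100, random_state=seed)
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    pred = cross_val_predict(clf, X, y, cv=cv)
    m = float(np.clip(np.mean(pred != y), 0.0, 0.5))
    return BinSimilarity(pair=tuple(pair), misclassification=m, similarity=m / 0.5)


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # deterministic root: smaller id wins
            lo, hi = sorted((ra, rb))
            self.parent[hi] = lo


def merge_bins(similarities: list[BinSimilarity], threshold: float = 0.75) -> dict:
    """Union-find merge of bin pairs with similarity >= threshold.

    Returns a mapping from each bin id to its merged-node id, where a
    merged node is named by the sorted tuple of its member bin ids.
    """
    items = sorted({b for s in similarities for b in s.pair})
    uf = _UnionFind(items)
    for s in similarities:
        if s.similarity >= threshold:
            uf.union(s.pair[0], s.pair[1])
    groups: dict = {}
    for x in items:
        groups.setdefault(uf.find(x), []).append(x)
    out = {}
    for members in groups.values():
        node = tuple(sorted(members))
        for x in members:
            out[x] = node
    return out
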