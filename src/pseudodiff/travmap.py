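"""Cross-trajectory gene-module (TRAV) discovery.

Each trajectory yields a genes x pseudotime-interval CPM matrix (empty
intervals dropped, rows max-scaled), factorized by seeded
multiplicative-update NMF.  Factors pooled over all trajectories are
hierarchically clustered (average linkage, correlation distance) into
``floor(D*K / 8)`` clusters; each cluster's mean loading vector is a
TRAV, its top-100 loading genes the TRAV gene module.  TRAV *activity*
in a trajectory is the maximal Pearson correlation between the TRAV
loading vector and that trajectory's factor loadings; conserved TRAVs
exceed an activity threshold in strictly more than a given fraction of
trajectories, and covariate-associated TRAVs are found with a linear
mixed model (random intercept per project).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

from pseudodiff.core import CellTable, normalize_log_cpm, select_hvg
from pseudodiff.trajdiff import assign_intervals

logger = logging.getLogger(__name__)

__all__ = [
    "TrajMatrix",
    "TrajFactorization",
    "TravSet",
    "build_traj_matrix",
    "nmf_decompose",
    "choose_rank",
    "trav_cluster_count",
    "pool_and_cluster",
    "trav_activity",
    "conserved_travs",
    "covariate_travs",
    "trav_temporal_profile",
    "embed_trajectories",
]


@dataclass
class TrajMatrix:
    traj_id: str
    matrix: np.ndarray          # genes x occupied intervals, max-scaled rows
    gene_ids: list[str]
    interval_mask: np.ndarray   # (n_intervals,) bool, True = occupied


@dataclass
class TrajFactorization:
    traj_id: str
    W: np.ndarray               # genes x K, columns L2-normalized
    H: np.ndarray               # K x occupied intervals
    K: int
    recon_error: float
    objective: list[float] = field(default_factory=list)
    gene_ids: list[str] = field(default_factory=list)


@dataclass
class TravSet:
    trav_ids: list[str]
    loadings: np.ndarray        # C x genes mean loading vectors
    members: list[list[tuple[str, int]]]   # per TRAV: (traj_id, factor index)
    modules: list[list[str]]    # per TRAV: top-100 gene ids
    gene_ids: list[str]
    cluster_count: int

    @property
    def n_travs(self) -> int:
        return len(self.trav_ids)


# ----------------------------------------------------------------------
# Pseudotemporal expression matrix
# ----------------------------------------------------------------------

def build_traj_matrix(
    ct: CellTable,
    traj_id: str = "traj",
    n_intervals: int = 100,
    hvg_idx: np.ndarray | None = None,
    n_hvg: int = 2000,
    min_occupied: int = 5,
) -> TrajMatrix:
    """Genes x occupied-interval CPM matrix, rows scaled by their maximum.

    ``hvg_idx`` (0-based gene columns) supports a shared HVG vocabulary
    across trajectories; when absent, HVGs are selected from this
    trajectory alone.
    """
    pt = ct.pseudotime
    ids = assign_intervals(pt, n_intervals)
    counts = ct.counts.tocsc()
    pooled = np.zeros((n_intervals, ct.n_genes))
    for iv in range(1, n_intervals + 1):
        members = np.flatnonzero(ids == iv)
        if len(members):
            pooled[iv - 1] = np.asarray(counts[members].sum(axis=0)).ravel()
    occupied = pooled.sum(axis=1) > 0
    if occupied.sum() < min_occupied:
        raise ValueError(
            f"trajectory {traj_id!r} occupies only {int(occupied.sum())} "
            f"intervals (< {min_occupied}); rejected"
        )
    pooled = pooled[occupied]
    cpm = pooled / pooled.sum(axis=1, keepdims=True) * 1e6  # interval CPM

    if hvg_idx is None:
        hvg_idx = select_hvg(normalize_log_cpm(ct), ct.gene_ids, n_top=n_hvg)
    hvg_idx = np.asarray(hvg_idx)
    mat = cpm[:, hvg_idx].T  # genes x intervals
    row_max = mat.max(axis=1, keepdims=True)
    mat = np.divide(mat, row_max, out=np.zeros_like(mat), where=row_max > 0)
    return TrajMatrix(
        traj_id=traj_id,
        matrix=mat,
        gene_ids=[ct.gene_ids[i] for i in hvg_idx],
        interval_mask=occupied,
    )


# ----------------------------------------------------------------------
# NMF (multiplicative updates; monotone Frobenius objective)
# ----------------------------------------------------------------------

def _mu_nmf(V, K, seed, mask=None, max_iter=500, tol=1e-6):
    rng = np.random.default_rng(seed)
    G, T = V.shape
    scale = np.sqrt(max(V.mean(), 1e-12) / K)
    W = rng.uniform(0.0, 1.0, size=(G, K)) * scale + 1e-6
    H = rng.uniform(0.0, 1.0, size=(K, T)) * scale + 1e-6
    M = np.ones_like(V) if mask is None else mask.astype(float)
    Vm = V * M
    eps = 1e-12
    objective = []
    prev = None
    for _ in range(max_iter):
        WH = W @ H
        H *= (W.T @ Vm) / np.maximum(W.T @ (M * WH), eps)
        WH = W @ H
        W *= (Vm @ H.T) / np.maximum((M * WH) @ H.T, eps)
        obj = float(np.sum(M * (V - W @ H) ** 2))
        objective.append(obj)
        if prev is not None and prev > 0 and (prev - obj) / prev < tol:
            break
        prev = obj
    return W, H, objective


def nmf_decompose(tm: TrajMatrix, K: int = 15, seed: int = 0) -> TrajFactorization:
    """Seeded multiplicative-update NMF of the trajectory matrix into K factors."""
    V = tm.matrix
    if K >= min(V.shape):
        raise ValueError(f"K={K} must be < min(genes, intervals) = {min(V.shape)}")
    W, H, objective = _mu_nmf(V, K, seed)
    norms = np.linalg.norm(W, axis=0)
    norms = np.where(norms > 0, norms, 1.0)
    W = W / norms
    H = H * norms[:, None]
    return TrajFactorization(
        traj_id=tm.traj_id,
        W=W,
        H=H,
        K=K,
        recon_error=float(np.linalg.norm(V - W @ H) ** 2),
        objective=objective,
        gene_ids=list(tm.gene_ids),
    )


def choose_rank(
    tm: TrajMatrix,
    candidate_Ks: list[int],
    mask_frac: float = 0.1,
    seed: int = 0,
    n_masks: int = 3,
) -> int:
    """Pick K by held-out reconstruction error under random entry masking.

    Ties favor the smaller K; a single candidate is returned unchanged.
    """
    candidates = sorted(set(candidate_Ks))
    if len(candidates) == 1:
        return candidates[0]
    V = tm.matrix
    rng = np.random.default_rng(seed)
    errors = {k: [] for k in candidates}
    for rep in range(n_masks):
        held = rng.random(V.shape) < mask_frac
        train_mask = ~held
        for k in candidates:
            if k >= min(V.shape):
                errors[k].append(np.inf)
                continue
            W, H, _ = _mu_nmf(V, k, seed=seed + 1000 * rep + k, mask=train_mask)
            resid = (V - W @ H)[held]
            errors[k].append(float(np.mean(resid**2)) if held.any() else np.inf)
    mean_err = {k: float(np.mean(v)) for k, v in errors.items()}
    best = min(candidates, key=lambda k: (mean_err[k], k))
    return best


# ----------------------------------------------------------------------
# Pooling & clustering
# ----------------------------------------------------------------------

def trav_cluster_count(n_trajectories: int, n_factors: int) -> int:
    """Cluster-count rule: integer floor of D*K / 8 (minimum 1)."""
    return max((n_trajectories * n_factors) // 8, 1)


def pool_and_cluster(
    factorizations: list[TrajFactorization],
    n_top: int = 100,
) -> TravSet:
    """Pool all factor loading vectors and cut an average-linkage tree.

    Clustering is on gene-loading vectors with correlation distance; the
    cut produces ``trav_cluster_count(D, K)`` clusters.  Every pooled
    factor lands in exactly one TRAV.
    """
    gene_ids = factorizations[0].gene_ids
    for f in factorizations:
        if f.gene_ids != gene_ids:
            raise ValueError("factorizations must share the gene vocabulary")
    D = len(factorizations)
    K = factorizations[0].K
    pooled = np.hstack([f.W for f in factorizations]).T  # (D*K) x genes
    owners = [(f.traj_id, k) for f in factorizations for k in range(f.K)]

    C = trav_cluster_count(D, K)
    if D * K < 8:
        logger.warning("only %d pooled factors; forming a single TRAV", D * K)
    if C >= len(pooled):
        assignments = np.arange(len(pooled)) + 1
        C = len(pooled)
    else:
        # guard constant rows for correlation distance
        jitter = pooled + 1e-12 * (pooled.std(axis=1, keepdims=True) == 0)
        dist = pdist(jitter, metric="correlation")
        Z = sch.linkage(dist, method="average")
        assignments = sch.fcluster(Z, t=C, criterion="maxclust")

    trav_ids, loadings, members, modules = [], [], [], []
    for c in sorted(set(assignments)):
        idx = np.flatnonzero(assignments == c)
        mean_vec = pooled[idx].mean(axis=0)
        top = np.argsort(-mean_vec, kind="stable")[:n_top]
        trav_ids.append(f"TRAV{len(trav_ids) + 1}")
        loadings.append(mean_vec)
        members.append([owners[i] for i in idx])
        modules.append([gene_ids[i] for i in top])
    return TravSet(
        trav_ids=trav_ids,
        loadings=np.vstack(loadings),
        members=members,
        modules=modules,
        gene_ids=list(gene_ids),
        cluster_count=len(trav_ids),
    )


# ----------------------------------------------------------------------
# Activity & detection
# ----------------------------------------------------------------------

def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def trav_activity(
    travset: TravSet, factorizations: list[TrajFactorization]
) -> pd.DataFrame:
    """TRAVs x trajectories activity: max factor-loading correlation per trajectory."""
    act = np.zeros((travset.n_travs, len(factorizations)))
    for j, f in enumerate(factorizations):
        for i in range(travset.n_travs):
            act[i, j] = max(
                _safe_corr(travset.loadings[i], f.W[:, k]) for k in range(f.K)
            )
    return pd.DataFrame(
        act, index=travset.trav_ids, columns=[f.traj_id for f in factorizations]
    )


def conserved_travs(
    activity: pd.DataFrame, threshold: float = 0.4, frac: float = 1 / 3
) -> list[str]:
    """TRAVs with activity > threshold in strictly more than ``frac`` of trajectories."""
    high = (activity > threshold).mean(axis=1)
    return activity.index[high > frac].tolist()


def covariate_travs(
    activity: pd.DataFrame,
    covariate: pd.Series,
    project: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-TRAV covariate effect on activity.

    Linear mixed model ``activity ~ covariate`` with a random intercept
    per project (REML, Wald p on the covariate slope); plain least
    squares when all trajectories share one project.  Returns effect, p
    and BH FDR per TRAV; degenerate fits are reported with NaN.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    cov = pd.Series(covariate).loc[activity.columns]
    if cov.nunique() < 2:
        raise ValueError("covariate needs at least 2 levels")
    x = cov if pd.api.types.is_numeric_dtype(cov) else pd.Categorical(cov).codes
    x = np.asarray(x, dtype=float)
    proj = None
    if project is not None:
        proj = pd.Series(project).loc[activity.columns]
        if proj.nunique() < 2:
            proj = None

    rows = []
    for trav in activity.index:
        y = activity.loc[trav].to_numpy(dtype=float)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                if proj is not None:
                    df = pd.DataFrame({"y": y, "x": x, "proj": proj.to_numpy()})
                    fit = smf.mixedlm("y ~ x", df, groups=df["proj"]).fit(reml=True)
                    eff, p = float(fit.params["x"]), float(fit.pvalues["x"])
                else:
                    X = sm.add_constant(x)
                    fit = sm.OLS(y, X).fit()
                    eff, p = float(fit.params[1]), float(fit.pvalues[1])
        except Exception:  # degenerate design for this TRAV
            eff, p = np.nan, np.nan
        rows.append((trav, eff, p))
    out = pd.DataFrame(rows, columns=["trav", "effect", "p_value"]).set_index("trav")
    ok = out["p_value"].notna()
    fdr = np.full(len(out), np.nan)
    if ok.any():
        fdr[ok.to_numpy()] = multipletests(out.loc[ok, "p_value"], method="fdr_bh")[1]
    out["fdr"] = fdr
    return out


def trav_temporal_profile(
    travset: TravSet,
    activity: pd.DataFrame,
    trajectories: dict[str, CellTable],
    n_bins: int = 10,
) -> pd.DataFrame:
    """Expression/peak/correlation of each module in its most-active trajectory."""
    from pseudodiff.features import gene_attributes

    rows = []
    for i, trav in enumerate(travset.trav_ids):
        best_traj = activity.loc[trav].idxmax()
        ct = trajectories[best_traj]
        gidx = [ct.gene_ids.index(g) for g in travset.modules[i] if g in ct.gene_ids]
        expr = normalize_log_cpm(ct)[:, gidx]
        module_expr = np.asarray(expr.mean(axis=1)).ravel()
        attr = gene_attributes(module_expr, ct.pseudotime, n_bins=n_bins)
        rows.append((trav, best_traj, attr.expression, attr.peak, attr.correlation))
    return pd.DataFrame(
        rows, columns=["trav", "trajectory", "expression", "peak", "correlation"]
    ).set_index("trav")


# ----------------------------------------------------------------------
# Trajectory embedding
# ----------------------------------------------------------------------

def embed_trajectories(
    blocks: dict[str, np.ndarray],
    seed: int = 0,
    n_pcs: int = 10,
) -> np.ndarray:
    """2-D trajectory embedding from equal-weighted z-scored attribute blocks.

    Each block is (trajectories x features); blocks are z-scored per
    feature, scaled to equal total weight, concatenated, reduced by PCA
    and embedded with t-SNE (exact method, PCA init, fixed seed).
    """
    mats = []
    n = None
    for name, m in blocks.items():
        m = np.asarray(m, dtype=float)
        if m.ndim == 1:
            m = m[:, None]
        if n is None:
            n = m.shape[0]
        elif m.shape[0] != n:
            raise ValueError(f"block {name!r} has {m.shape[0]} rows, expected {n}")
        sd = m.std(axis=0)
        z = (m - m.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
        mats.append(z / np.sqrt(z.shape[1]))
    if n is None or n < 3:
        raise ValueError("need at least 3 trajectories to embed")
    X = np.hstack(mats)

    from sklearn.decomposition import PCA
    from sklearn.manifold import TSNE

    n_pcs = min(n_pcs, n - 1, X.shape[1])
    Xp = PCA(n_components=n_pcs, svd_solver="full", random_state=seed).fit_transform(X)
    perplexity = max(2.0, min(30.0, (n - 1) / 3.0))
    ts = TSNE(
        n_components=2,
        perplexity=perplexity,
        init="pca",
        method="exact",
        random_state=seed,
    )
    return ts.fit_transform(Xp)
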