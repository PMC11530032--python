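"""Pseudotime-resolved differential abundance (DA) and expression (DE) tests.

Pipeline for both modes: neighborhood-level negative-binomial tests
against a two-level group factor, weighted ("spatial") FDR over
neighborhoods, Accept/Rejection labeling, projection of neighborhoods
onto equal-width pseudotime intervals, and a per-interval binomial test

    p_interval = P(X <= N_accept),  X ~ Binomial(N_accept + N_rejection, lambda)

whose null acceptance rate ``lambda`` is estimated by re-running the
pipeline on datasets with sample-to-group assignments shuffled.  Small
p_interval marks intervals with unusually many Rejections.  Interval
effect summaries are CPM_interval (per-group mean fitted CPM) and
DiffExpr_interval = mean(logFC * CPM); DE additionally reduces each
gene's interval profile to a two-stage pattern label (e.g. "Up_0").

Sign convention: logFC compares the second group level (stable order of
appearance in the sample metadata) against the first, so "Up" means
higher in the second level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom
from statsmodels.stats.multitest import multipletests

from pseudodiff.core import CellTable
from pseudodiff.nbglm import NbGlmResult, _design, _ml_alpha, _test_one
from pseudodiff.neighborhoods import NeighborhoodSet, count_cells, nhood_pseudotime

logger = logging.getLogger(__name__)

__all__ = [
    "NhoodTestResult",
    "IntervalSummary",
    "spatial_fdr",
    "assign_intervals",
    "label_accept_reject",
    "estimate_lambda",
    "binomial_interval_test",
    "overall_test",
    "interval_summaries",
    "run_da",
    "run_de",
    "label_pattern",
    "cluster_patterns",
]


@dataclass
class NhoodTestResult:
    """Per-neighborhood test output; ``frame`` columns: nhood, pseudotime,
    interval, logfc, cpm, cpm_g0, cpm_g1, p_value, spatial_fdr, label."""

    frame: pd.DataFrame
    groups: tuple

    @property
    def n_nhoods(self) -> int:
        return len(self.frame)


@dataclass
class IntervalSummary:
    """Per-interval results; ``frame`` columns: interval, n_nhoods, n_accept,
    n_rejection, lam, p_interval, fdr_interval, cpm_g0, cpm_g1, diff_expr,
    occupied.  Empty intervals carry NaN statistics and occupied=False."""

    frame: pd.DataFrame
    p_overall: float
    lambda_overall: float
    groups: tuple
    n_intervals: int

    def occupied(self) -> pd.DataFrame:
        return self.frame[self.frame["occupied"]]


# ----------------------------------------------------------------------
# Building blocks
# ----------------------------------------------------------------------

def spatial_fdr(p: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Weighted Benjamini-Hochberg over neighborhoods.

    With p sorted ascending, ``fdr_j = min_{l >= j} p_l * W / W_l`` where
    ``W`` is the total weight and ``W_l`` the cumulative weight through
    rank ``l``; clipped to 1 and returned in the input order.  Unit
    weights reduce to classical BH.
    """
    p = np.asarray(p, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if p.shape != weights.shape:
        raise ValueError("p and weights must have equal length")
    if (weights <= 0).any():
        raise ValueError("weights must be strictly positive")
    order = np.argsort(p, kind="stable")
    w_sorted = weights[order]
    cumw = np.cumsum(w_sorted)
    adj = p[order] * cumw[-1] / cumw
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty_like(adj)
    out[order] = adj
    return out


def assign_intervals(nhood_pt: np.ndarray, n_intervals: int = 100) -> np.ndarray:
    """Equal-width half-open bins of [0, 1]; ids 1..n, last bin closed at 1."""
    pt = np.asarray(nhood_pt, dtype=float)
    ids = np.floor(pt * n_intervals).astype(int) + 1
    return np.minimum(ids, n_intervals)


def label_accept_reject(fdr: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """'Rejection' iff fdr < alpha (strict), else 'Accept'."""
    return np.where(np.asarray(fdr) < alpha, "Rejection", "Accept")


def estimate_lambda(
    null_runs: list[np.ndarray],
    n_shuffles: int | None = None,
) -> np.ndarray:
    """Per-interval null acceptance rate from shuffled runs.

    Each element of ``null_runs`` is an (n_intervals, 2) array of
    (N_accept, N_rejection) per interval from one shuffle.  lambda is the
    mean acceptance fraction across shuffles; a mean of exactly 0 falls
    back to the estimation precision 1/((N_accept+N_rejection)*n_shuffles)
    and, symmetrically, a mean of exactly 1 to its complement (the
    binomial test requires lambda in (0, 1)).  Intervals empty in every
    shuffle come back NaN (flagged, not fabricated).
    """
    if n_shuffles is None:
        n_shuffles = len(null_runs)
    if n_shuffles < 1:
        raise ValueError("need at least one shuffle")
    stack = np.stack(null_runs)  # (n_shuffles, n_intervals, 2)
    totals = stack.sum(axis=2).astype(float)  # per shuffle, per interval
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(totals > 0, stack[:, :, 0] / np.maximum(totals, 1), np.nan)
        n_obs = (~np.isnan(frac)).sum(axis=0)
        lam = np.where(n_obs > 0, np.nansum(frac, axis=0) / np.maximum(n_obs, 1), np.nan)
        t0 = totals.max(axis=0)  # interval totals (constant across shuffles in-pipeline)
        precision = np.where(t0 > 0, 1.0 / np.maximum(t0, 1) / n_shuffles, np.nan)
        lam = np.where(lam == 0.0, precision, lam)
        lam = np.where(lam == 1.0, 1.0 - precision, lam)
    return lam


def binomial_interval_test(n_accept: int, n_rejection: int, lam: float) -> float:
    """Binomial CDF at ``n_accept`` out of ``n_accept + n_rejection`` at rate ``lam``."""
    if n_accept < 0 or n_rejection < 0 or (n_accept + n_rejection) == 0:
        raise ValueError("need non-negative counts with a positive total")
    if not (0.0 < lam < 1.0):
        raise ValueError("lambda must lie strictly in (0, 1); apply the precision fallback")
    return float(binom.cdf(n_accept, n_accept + n_rejection, lam))


def overall_test(n_accept: int, n_rejection: int, lam: float) -> float:
    """Same binomial test applied to whole-analysis Accept/Rejection counts."""
    return binomial_interval_test(n_accept, n_rejection, lam)


def interval_summaries(
    nhood_frame: pd.DataFrame,
    interval_stats: pd.DataFrame,
    n_intervals: int,
) -> pd.DataFrame:
    """Join per-interval accept/reject statistics with effect summaries.

    ``CPM_interval`` per group is the mean fitted CPM over in-interval
    neighborhoods; ``DiffExpr_interval`` is mean(logFC * CPM).
    """
    grouped = nhood_frame.groupby("interval")
    eff = grouped.apply(
        lambda d: pd.Series(
            {
                "n_nhoods": len(d),
                "cpm_g0": d["cpm_g0"].mean(),
                "cpm_g1": d["cpm_g1"].mean(),
                "diff_expr": (d["logfc"] * d["cpm"]).mean(),
            }
        ),
        include_groups=False,
    )
    frame = pd.DataFrame({"interval": np.arange(1, n_intervals + 1)})
    frame = frame.merge(interval_stats, on="interval", how="left")
    frame = frame.merge(eff, left_on="interval", right_index=True, how="left")
    frame["n_nhoods"] = frame["n_nhoods"].fillna(0).astype(int)
    frame["occupied"] = frame["n_nhoods"] > 0
    return frame


# ----------------------------------------------------------------------
# Shared test machinery
# ----------------------------------------------------------------------

def _fit_features(Y, codes, offsets, alphas=None, masks=None):
    """NB-test each row of Y (features x samples).

    ``offsets`` is (S,) or (F, S); ``masks`` optionally drops samples per
    feature (e.g. samples absent from a neighborhood).  When ``alphas``
    is None, per-feature ML dispersions are estimated and shrunk 50/50
    toward their mean; the shrunk values are returned for reuse.
    """
    Y = np.asarray(Y, dtype=float)
    F, S = Y.shape
    offsets = np.asarray(offsets, dtype=float)
    if offsets.ndim == 1:
        offsets = np.broadcast_to(offsets, (F, S))
    if masks is None:
        masks = np.ones((F, S), dtype=bool)

    usable = np.zeros(F, dtype=bool)
    for i in range(F):
        m = masks[i]
        usable[i] = min((codes[m] == 0).sum(), (codes[m] == 1).sum()) >= 2

    if alphas is None:
        raw = np.full(F, np.nan)
        for i in range(F):
            if not usable[i] or Y[i, masks[i]].sum() == 0:
                continue
            m = masks[i]
            raw[i] = _ml_alpha(Y[i, m], _design(codes[m]), offsets[i, m])
        valid = np.isfinite(raw)
        common = float(raw[valid].mean()) if valid.any() else 1e-6
        alphas = np.where(valid, 0.5 * raw + 0.5 * common, common)

    results: list[NbGlmResult] = []
    for i in range(F):
        m = masks[i]
        if not usable[i]:
            results.append(NbGlmResult(0.0, 0.0, 1.0, np.full(2, np.nan), alphas[i], True))
            continue
        results.append(_test_one(Y[i, m], _design(codes[m]), offsets[i, m], alphas[i], codes[m]))
    return results, np.asarray(alphas)


def _accept_reject_by_interval(p, weights, intervals, n_intervals, alpha):
    fdr = spatial_fdr(p, weights)
    labels = label_accept_reject(fdr, alpha)
    stats = np.zeros((n_intervals, 2), dtype=int)
    for iv, lab in zip(intervals, labels):
        stats[iv - 1, 0 if lab == "Accept" else 1] += 1
    return fdr, labels, stats


def _group_codes(ct: CellTable):
    sample_groups = ct.sample_groups
    levels = list(dict.fromkeys(sample_groups.tolist()))
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {levels}")
    codes = (sample_groups.to_numpy() == levels[1]).astype(float)
    for lv in levels:
        if (sample_groups == lv).sum() < 2:
            raise ValueError(f"group {lv!r} has fewer than 2 samples")
    return codes, tuple(levels)


def _shuffled_codes(codes, rng):
    return rng.permutation(codes)


def _assemble_summary(stats_obs, lam, nhood_frame, n_intervals, groups,
                      n_accept_glob, n_reject_glob, lam_glob):
    rows = []
    for i in range(n_intervals):
        na, nr = int(stats_obs[i, 0]), int(stats_obs[i, 1])
        tot = na + nr
        if tot == 0 or not np.isfinite(lam[i]):
            rows.append((i + 1, na, nr, np.nan, np.nan))
            continue
        rows.append((i + 1, na, nr, lam[i], binomial_interval_test(na, nr, lam[i])))
    stats_frame = pd.DataFrame(rows, columns=["interval", "n_accept", "n_rejection",
                                              "lam", "p_interval"])
    occ = stats_frame["p_interval"].notna()
    fdr_col = np.full(len(stats_frame), np.nan)
    if occ.any():
        fdr_col[occ.to_numpy()] = multipletests(
            stats_frame.loc[occ, "p_interval"], method="fdr_bh"
        )[1]
    stats_frame["fdr_interval"] = fdr_col

    frame = interval_summaries(nhood_frame, stats_frame, n_intervals)
    if (n_accept_glob + n_reject_glob) > 0 and np.isfinite(lam_glob):
        p_overall = overall_test(n_accept_glob, n_reject_glob, lam_glob)
    else:
        p_overall = np.nan
    return IntervalSummary(frame=frame, p_overall=p_overall,
                           lambda_overall=lam_glob, groups=groups,
                           n_intervals=n_intervals)


# ----------------------------------------------------------------------
# Differential abundance
# ----------------------------------------------------------------------

def run_da(
    ct: CellTable,
    nhoods: NeighborhoodSet,
    n_intervals: int = 100,
    alpha: float = 0.05,
    n_shuffles: int = 5,
    seed: int = 0,
) -> tuple[NhoodTestResult, IntervalSummary]:
    """Differential-abundance pipeline over neighborhood cell counts.

    Offsets are log total cells per sample.  Shuffling for the lambda
    estimate permutes the sample-to-group assignment; the per-feature
    dispersions estimated on the observed data are reused in shuffles.
    """
    codes, groups = _group_codes(ct)
    counts = nhoods.counts if nhoods.counts is not None else count_cells(nhoods, ct)
    pt = (nhoods.nhood_pseudotime if nhoods.nhood_pseudotime is not None
          else nhood_pseudotime(nhoods, ct))
    intervals = assign_intervals(pt, n_intervals)
    sample_totals = ct.obs["sample"].value_counts().loc[nhoods.sample_order
                                                       or ct.samples].to_numpy()
    offsets = np.log(sample_totals.astype(float))

    results, alphas = _fit_features(counts, codes, offsets)
    p = np.array([r.p_value for r in results])
    fdr, labels, stats_obs = _accept_reject_by_interval(
        p, nhoods.weights, intervals, n_intervals, alpha
    )

    rng = np.random.default_rng(seed)
    null_runs, null_glob = [], []
    for _ in range(n_shuffles):
        sh_codes = _shuffled_codes(codes, rng)
        sh_res, _ = _fit_features(counts, sh_codes, offsets, alphas=alphas)
        sh_p = np.array([r.p_value for r in sh_res])
        _, sh_labels, sh_stats = _accept_reject_by_interval(
            sh_p, nhoods.weights, intervals, n_intervals, alpha
        )
        null_runs.append(sh_stats)
        null_glob.append(np.array([[int((sh_labels == "Accept").sum()),
                                    int((sh_labels == "Rejection").sum())]]))
    lam = estimate_lambda(null_runs, n_shuffles)
    lam_glob = float(estimate_lambda(null_glob, n_shuffles)[0])

    nhood_frame = pd.DataFrame(
        {
            "nhood": np.arange(len(results)),
            "index_cell": nhoods.index_cells,
            "pseudotime": pt,
            "interval": intervals,
            "logfc": [r.logfc for r in results],
            "cpm": [r.cpm for r in results],
            "cpm_g0": [r.cpm_per_group[0] for r in results],
            "cpm_g1": [r.cpm_per_group[1] for r in results],
            "p_value": p,
            "spatial_fdr": fdr,
            "label": labels,
        }
    )
    summary = _assemble_summary(
        stats_obs, lam, nhood_frame, n_intervals, groups,
        int((labels == "Accept").sum()), int((labels == "Rejection").sum()), lam_glob,
    )
    return NhoodTestResult(frame=nhood_frame, groups=groups), summary


# ----------------------------------------------------------------------
# Differential expression
# ----------------------------------------------------------------------

def _pseudobulk(ct: CellTable, nhoods: NeighborhoodSet):
    """(N, S, G) per-neighborhood per-sample gene count sums + (N, S) totals."""
    samples = ct.samples
    slabs = []
    for s in samples:
        in_s = (ct.obs["sample"] == s).to_numpy()
        sub = nhoods.membership[:, in_s] @ ct.counts[in_s, :]
        slabs.append(np.asarray(sub.todense()))
    pb = np.stack(slabs, axis=1).astype(float)  # N x S x G
    totals = pb.sum(axis=2)
    return pb, totals


def run_de(
    ct: CellTable,
    nhoods: NeighborhoodSet,
    genes: list[str] | None = None,
    n_intervals: int = 100,
    alpha: float = 0.05,
    n_shuffles: int = 5,
    seed: int = 0,
    stage_split: float = 0.5,
    min_sig_frac: float = 0.2,
) -> tuple[dict[str, IntervalSummary], pd.DataFrame]:
    """Per-gene differential expression on neighborhood pseudobulks.

    For each gene the abundance machinery runs on its N x S pseudobulk
    slab with offsets log(total pseudobulk counts per neighborhood and
    sample); samples contributing no cells to a neighborhood are dropped
    from that neighborhood's fit.  Returns per-gene interval summaries
    and a pattern-label table (BH across genes on p_overall).
    """
    codes, groups = _group_codes(ct)
    pt = (nhoods.nhood_pseudotime if nhoods.nhood_pseudotime is not None
          else nhood_pseudotime(nhoods, ct))
    intervals = assign_intervals(pt, n_intervals)
    pb, totals = _pseudobulk(ct, nhoods)
    masks = totals > 0
    with np.errstate(divide="ignore"):
        offsets = np.where(masks, np.log(np.maximum(totals, 1e-300)), 0.0)

    gene_index = {g: i for i, g in enumerate(ct.gene_ids)}
    if genes is None:
        genes = list(ct.gene_ids)
    missing = [g for g in genes if g not in gene_index]
    if missing:
        raise KeyError(f"unknown genes: {missing[:5]}")

    rng = np.random.default_rng(seed)
    shuffle_codes = [_shuffled_codes(codes, rng) for _ in range(n_shuffles)]

    summaries: dict[str, IntervalSummary] = {}
    skipped: list[str] = []
    label_rows = []
    for g in genes:
        gi = gene_index[g]
        Y = pb[:, :, gi]
        if Y.sum() == 0:
            skipped.append(g)
            continue
        res, alphas = _fit_features(Y, codes, offsets, masks=masks)
        p = np.array([r.p_value for r in res])
        fdr, labels, stats_obs = _accept_reject_by_interval(
            p, nhoods.weights, intervals, n_intervals, alpha
        )
        null_runs, null_glob = [], []
        for sh in shuffle_codes:
            sh_res, _ = _fit_features(Y, sh, offsets, alphas=alphas, masks=masks)
            sh_p = np.array([r.p_value for r in sh_res])
            _, sh_labels, sh_stats = _accept_reject_by_interval(
                sh_p, nhoods.weights, intervals, n_intervals, alpha
            )
            null_runs.append(sh_stats)
            null_glob.append(np.array([[int((sh_labels == "Accept").sum()),
                                        int((sh_labels == "Rejection").sum())]]))
        lam = estimate_lambda(null_runs, n_shuffles)
        lam_glob = float(estimate_lambda(null_glob, n_shuffles)[0])

        nhood_frame = pd.DataFrame(
            {
                "interval": intervals,
                "logfc": [r.logfc for r in res],
                "cpm": [r.cpm for r in res],
                "cpm_g0": [np.nan_to_num(r.cpm_per_group[0]) for r in res],
                "cpm_g1": [np.nan_to_num(r.cpm_per_group[1]) for r in res],
            }
        )
        summary = _assemble_summary(
            stats_obs, lam, nhood_frame, n_intervals, groups,
            int((labels == "Accept").sum()), int((labels == "Rejection").sum()),
            lam_glob,
        )
        summaries[g] = summary
        early, late, pattern = label_pattern(
            summary, alpha=alpha, stage_split=stage_split, min_sig_frac=min_sig_frac
        )
        label_rows.append((g, early, late, pattern, summary.p_overall))

    if skipped:
        logger.warning("skipped %d genes with all-zero pseudobulk", len(skipped))
    labels_frame = pd.DataFrame(
        label_rows, columns=["gene_id", "early", "late", "pattern", "p_overall"]
    )
    if len(labels_frame):
        ok = labels_frame["p_overall"].notna()
        fdr_overall = np.full(len(labels_frame), np.nan)
        if ok.any():
            fdr_overall[ok.to_numpy()] = multipletests(
                labels_frame.loc[ok, "p_overall"], method="fdr_bh"
            )[1]
        labels_frame["fdr_overall"] = fdr_overall
    labels_frame.attrs["skipped"] = skipped
    return summaries, labels_frame


def label_pattern(
    summary: IntervalSummary,
    alpha: float = 0.05,
    stage_split: float = 0.5,
    min_sig_frac: float = 0.2,
) -> tuple[str, str, str]:
    """Two-stage pattern call from a gene's interval summary.

    Per stage (interval centers before/after ``stage_split``): "0" if
    fewer than ``min_sig_frac`` of occupied intervals are significant
    (fdr_interval < alpha); otherwise the sign of the mean DiffExpr over
    the significant intervals gives "Up"/"Down".  Returns
    (early, late, "early_late").
    """
    frame = summary.occupied()
    centers = (frame["interval"] - 0.5) / summary.n_intervals
    calls = []
    for stage_mask in (centers < stage_split, centers >= stage_split):
        sub = frame[stage_mask.to_numpy()]
        if len(sub) == 0:
            logger.warning("no occupied intervals in one stage; calling '0'")
            calls.append("0")
            continue
        sig = sub[sub["fdr_interval"] < alpha]
        if len(sig) / len(sub) < min_sig_frac:
            calls.append("0")
        else:
            calls.append("Up" if sig["diff_expr"].mean() > 0 else "Down")
    return calls[0], calls[1], f"{calls[0]}_{calls[1]}"


def cluster_patterns(summaries: dict[str, IntervalSummary], k: int = 8, seed: int = 0):
    """Optional k-means over per-gene DiffExpr interval profiles (figure-style clusters)."""
    from sklearn.cluster import KMeans

    genes = list(summaries)
    n_intervals = summaries[genes[0]].n_intervals
    profiles = np.zeros((len(genes), n_intervals))
    for i, g in enumerate(genes):
        f = summaries[g].frame
        profiles[i] = np.nan_to_num(f["diff_expr"].to_numpy())
    k = min(k, len(genes))
    km = KMeans(n_clusters=k, random_state=seed, n_init=10).fit(profiles)
    return pd.Series(km.labels_, index=genes, name="cluster")
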