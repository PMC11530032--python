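"""Data model, I/O, QC filtering, normalization and HVG selection.

The universal input is a :class:`CellTable`: a sparse cells × genes raw
count matrix plus per-cell metadata (sample, group, pseudotime, mito
fraction, extra covariates).  On disk a table is the plain-text trio

* ``counts.mtx`` — Matrix Market integer coordinate format,
* ``cells.tsv`` — one row per cell (``cell_id``, ``sample``, ``group``,
  optional ``pseudotime``, ``mito_frac`` and covariate columns),
* ``genes.tsv`` — one row per gene (``gene_id``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "CellTable",
    "QCReport",
    "CellTableError",
    "read_cell_table",
    "write_cell_table",
    "qc_filter",
    "normalize_log_cpm",
    "select_hvg",
    "mito_fraction_from_prefix",
]


class CellTableError(ValueError):
    """Raised on structural validation failures of a :class:`CellTable`."""


_RESERVED_OBS = ("cell_id", "sample", "group", "pseudotime", "mito_frac")


@dataclass
class CellTable:
    """Sparse cell × gene count matrix with per-cell metadata.

    Parameters
    ----------
    counts
        Non-negative integer sparse matrix, cells as rows.
    obs
        Per-cell metadata indexed like ``cell_ids``; must contain
        ``sample`` and ``group`` columns.  ``pseudotime`` (in [0, 1]) and
        ``mito_frac`` are optional; any further columns are treated as
        covariates.
    gene_ids
        Unique gene identifiers, one per matrix column.
    """

    counts: sp.csr_matrix
    obs: pd.DataFrame
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.obs = self.obs.reset_index(drop=True)
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        n_cells, n_genes = self.counts.shape
        if len(self.obs) != n_cells:
            raise CellTableError(
                f"cell metadata has {len(self.obs)} rows but counts has {n_cells} cells"
            )
        if len(self.gene_ids) != n_genes:
            raise CellTableError(
                f"gene list has {len(self.gene_ids)} entries but counts has {n_genes} genes"
            )
        if len(set(self.gene_ids)) != n_genes:
            raise CellTableError("gene_ids are not unique")
        if "cell_id" not in self.obs.columns:
            self.obs.insert(0, "cell_id", [f"cell{i}" for i in range(n_cells)])
        if self.obs["cell_id"].duplicated().any():
            raise CellTableError("cell_ids are not unique")
        for col in ("sample", "group"):
            if col not in self.obs.columns:
                raise CellTableError(f"cell metadata lacks required column '{col}'")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise CellTableError("counts contain negative entries")
        data = self.counts.data
        if data.size and not np.allclose(data, np.round(data)):
            raise CellTableError("counts contain non-integer entries")
        # each sample must map to exactly one group
        mapping = self.obs.groupby("sample", observed=True)["group"].nunique()
        bad = mapping[mapping > 1]
        if len(bad):
            raise CellTableError(
                f"samples map to multiple groups: {', '.join(map(str, bad.index))}"
            )
        if self.has_pseudotime:
            pt = self.obs["pseudotime"].to_numpy(dtype=float)
            if np.nanmin(pt) < 0 or np.nanmax(pt) > 1:
                raise CellTableError("pseudotime values fall outside [0, 1]")

    # ------------------------------------------------------------------
    @property
    def cell_ids(self) -> list[str]:
        return self.obs["cell_id"].astype(str).tolist()

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def has_pseudotime(self) -> bool:
        return "pseudotime" in self.obs.columns and self.obs["pseudotime"].notna().all()

    @property
    def samples(self) -> list:
        """Stable sample order: first appearance in ``obs``."""
        return list(pd.unique(self.obs["sample"]))

    @property
    def sample_groups(self) -> pd.Series:
        """Group label per sample, indexed by sample, in stable sample order."""
        g = self.obs.drop_duplicates("sample").set_index("sample")["group"]
        return g.loc[self.samples]

    @property
    def pseudotime(self) -> np.ndarray:
        if "pseudotime" not in self.obs.columns:
            raise CellTableError("CellTable has no pseudotime column")
        return self.obs["pseudotime"].to_numpy(dtype=float)

    def subset_cells(self, mask: np.ndarray) -> "CellTable":
        mask = np.asarray(mask)
        return CellTable(
            counts=self.counts[mask],
            obs=self.obs.loc[mask].reset_index(drop=True),
            gene_ids=self.gene_ids,
        )

    def subset_genes(self, idx: Sequence[int]) -> "CellTable":
        idx = np.asarray(idx)
        return CellTable(
            counts=self.counts[:, idx],
            obs=self.obs,
            gene_ids=[self.gene_ids[i] for i in idx],
        )


@dataclass
class QCReport:
    """Per-rule removal accounting for :func:`qc_filter`."""

    n_cells_in: int
    n_cells_out: int
    n_genes_in: int
    n_genes_out: int
    removed_by_rule: dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("cells_in", self.n_cells_in),
            ("cells_out", self.n_cells_out),
            ("genes_in", self.n_genes_in),
            ("genes_out", self.n_genes_out),
        ] + sorted(self.removed_by_rule.items())
        return pd.DataFrame(rows, columns=["metric", "count"])

    def __str__(self) -> str:  # human-readable log
        lines = [
            f"cells: {self.n_cells_in} -> {self.n_cells_out}",
            f"genes: {self.n_genes_in} -> {self.n_genes_out}",
        ]
        for rule, n in sorted(self.removed_by_rule.items()):
            lines.append(f"  removed by {rule}: {n}")
        return "\n".join(lines)


# ----------------------------------------------------------------------
# I/O
# ----------------------------------------------------------------------

def read_cell_table(counts_path, cells_path, genes_path) -> CellTable:
    """Read a CellTable from a Matrix Market file plus cell/gene TSVs.

    Orientation (cells × genes vs genes × cells) is auto-detected from
    the metadata row counts and logged; square matrices are taken as
    cells × genes.
    """
    counts_path, cells_path, genes_path = map(Path, (counts_path, cells_path, genes_path))
    for p in (counts_path, cells_path, genes_path):
        if not p.exists():
            raise FileNotFoundError(p)
    mat = scipy.io.mmread(counts_path)
    obs = pd.read_csv(cells_path, sep="\t", dtype={"cell_id": str, "sample": str})
    genes = pd.read_csv(genes_path, sep="\t")
    if "gene_id" not in genes.columns:
        raise CellTableError(f"{genes_path}: missing 'gene_id' header")
    gene_ids = genes["gene_id"].astype(str).tolist()

    n_cells, n_genes = len(obs), len(gene_ids)
    if mat.shape == (n_cells, n_genes):
        pass
    elif mat.shape == (n_genes, n_cells):
        logger.info("matrix stored genes x cells; transposing to cells x genes")
        mat = mat.T
    else:
        raise CellTableError(
            f"{counts_path}: matrix shape {mat.shape} matches neither "
            f"{cells_path} ({n_cells} cells) x {genes_path} ({n_genes} genes) "
            "nor its transpose"
        )
    mat = sp.csr_matrix(mat)
    if mat.nnz and mat.data.min() < 0:
        raise CellTableError(f"{counts_path}: negative entries")
    if mat.nnz and not np.allclose(mat.data, np.round(mat.data)):
        raise CellTableError(f"{counts_path}: non-integer entries")
    return CellTable(counts=mat.astype(np.int64), obs=obs, gene_ids=gene_ids)


def write_cell_table(ct: CellTable, out_dir, prefix: str = "") -> dict[str, Path]:
    """Write the MTX + TSV trio under ``out_dir``; returns written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out_dir / f"{prefix}counts.mtx",
        "cells": out_dir / f"{prefix}cells.tsv",
        "genes": out_dir / f"{prefix}genes.tsv",
    }
    scipy.io.mmwrite(paths["counts"], sp.coo_matrix(ct.counts), field="integer")
    ct.obs.to_csv(paths["cells"], sep="\t", index=False)
    pd.DataFrame({"gene_id": ct.gene_ids}).to_csv(paths["genes"], sep="\t", index=False)
    return paths


# ----------------------------------------------------------------------
# QC
# ----------------------------------------------------------------------

def mito_fraction_from_prefix(ct: CellTable, prefix: str = "mt-") -> np.ndarray:
    """Fraction of counts from genes whose id starts with ``prefix`` (case-insensitive)."""
    is_mito = np.array([g.lower().startswith(prefix.lower()) for g in ct.gene_ids])
    totals = np.asarray(ct.counts.sum(axis=1)).ravel().astype(float)
    mito = np.asarray(ct.counts[:, is_mito].sum(axis=1)).ravel().astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(totals > 0, mito / np.maximum(totals, 1), 0.0)
    return frac


def qc_filter(
    ct: CellTable,
    min_features: int = 300,
    min_counts: int = 800,
    max_mito: float = 0.20,
    min_cells_per_gene: int = 3,
) -> tuple[CellTable, QCReport]:
    """Remove low-quality cells, then genes rarely detected in surviving cells.

    Cell rules (a cell is removed if it fails any):

    * detected genes (nonzero entries) < ``min_features``
    * total counts < ``min_counts``
    * mitochondrial fraction > ``max_mito`` (only when a ``mito_frac``
      column is present)

    Gene rule, applied after cell removal: detected in fewer than
    ``min_cells_per_gene`` surviving cells.
    """
    n_features = np.asarray((ct.counts > 0).sum(axis=1)).ravel()
    n_counts = np.asarray(ct.counts.sum(axis=1)).ravel()
    fail_feat = n_features < min_features
    fail_counts = n_counts < min_counts
    if "mito_frac" in ct.obs.columns:
        fail_mito = ct.obs["mito_frac"].to_numpy(dtype=float) > max_mito
    else:
        fail_mito = np.zeros(ct.n_cells, dtype=bool)
    keep_cells = ~(fail_feat | fail_counts | fail_mito)
    if not keep_cells.any():
        raise CellTableError("qc_filter removed every cell; thresholds too strict for this data")

    sub = ct.subset_cells(keep_cells)
    cells_per_gene = np.asarray((sub.counts > 0).sum(axis=0)).ravel()
    keep_genes = cells_per_gene >= min_cells_per_gene
    out = sub.subset_genes(np.flatnonzero(keep_genes))

    report = QCReport(
        n_cells_in=ct.n_cells,
        n_cells_out=out.n_cells,
        n_genes_in=ct.n_genes,
        n_genes_out=out.n_genes,
        removed_by_rule={
            "cell_min_features": int(fail_feat.sum()),
            "cell_min_counts": int(fail_counts.sum()),
            "cell_max_mito": int(fail_mito.sum()),
            "gene_min_cells": int((~keep_genes).sum()),
        },
    )
    return out, report


# ----------------------------------------------------------------------
# Normalization & HVG
# ----------------------------------------------------------------------

def normalize_log_cpm(ct: CellTable, scale: float = 1e4) -> sp.csr_matrix:
    """Per-cell library normalization: ``ln(1 + scale * count / cell_total)``.

    Zeros stay zero, so sparsity is preserved.
    """
    totals = np.asarray(ct.counts.sum(axis=1)).ravel().astype(float)
    if (totals == 0).any():
        raise CellTableError(
            "cells with zero total counts present; run qc_filter before normalization"
        )
    mat = ct.counts.tocsr().astype(float)
    row_scale = scale / totals
    mat = sp.diags(row_scale) @ mat
    mat.data = np.log1p(mat.data)
    return sp.csr_matrix(mat)


def select_hvg(
    expr: sp.spmatrix | np.ndarray,
    gene_ids: Sequence[str] | None = None,
    n_top: int = 2000,
    n_bins: int = 20,
) -> np.ndarray:
    """Select highly variable genes by bin-normalized dispersion.

    Dispersion = variance / mean of the (log-normalized) expression per
    gene; genes are grouped into ``n_bins`` equal-frequency mean bins and
    each dispersion divided by its bin's median dispersion (mean-trend
    removal).  Returns 0-based column indices of the ``n_top`` genes with
    the highest normalized dispersion.  Deterministic: ties break by gene
    id (lexicographic) when ids are given, else by column index.
    """
    if sp.issparse(expr):
        mean = np.asarray(expr.mean(axis=0)).ravel()
        sq = np.asarray(expr.multiply(expr).mean(axis=0)).ravel()
    else:
        expr = np.asarray(expr, dtype=float)
        mean = expr.mean(axis=0)
        sq = (expr**2).mean(axis=0)
    n = expr.shape[0]
    var = (sq - mean**2) * n / max(n - 1, 1)
    n_genes = len(mean)
    if n_top >= n_genes:
        logger.warning("n_top=%d >= %d genes available; returning all genes", n_top, n_genes)
        return np.arange(n_genes)

    with np.errstate(invalid="ignore", divide="ignore"):
        disp = np.where(mean > 0, var / np.maximum(mean, 1e-12), 0.0)
    n_bins = min(n_bins, max(1, n_genes // 5))
    # equal-frequency mean bins
    order = np.argsort(mean, kind="stable")
    bin_of = np.empty(n_genes, dtype=int)
    bin_of[order] = np.minimum((np.arange(n_genes) * n_bins) // n_genes, n_bins - 1)
    z = np.zeros(n_genes)
    for b in range(n_bins):
        m = bin_of == b
        if m.sum() == 0:
            continue
        med = np.median(disp[m])
        z[m] = disp[m] / med if med > 0 else disp[m]

    if gene_ids is not None:
        tie = np.array([str(g) for g in gene_ids])
    else:
        tie = np.arange(n_genes)
    order = np.lexsort((tie, -z))  # primary: z desc; secondary: id asc
    return np.sort(order[:n_top])
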