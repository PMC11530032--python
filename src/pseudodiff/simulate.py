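"""Seeded multi-sample differentiation-trajectory simulator.

Counts are negative binomial with variance ``mu + mu^2 * dispersion``
(gamma-Poisson mixture).  Per-cell log-means are

    baseline(gene) + sum of program bumps + sum of applicable DE effects
    + log(library factor)

where a *program* is a Gaussian bump in pseudotime shared by a subset of
samples (a planted co-regulated module) and a *DE effect* is a
group-specific log-fold-change restricted to a pseudotime window.
Per-group pseudotime follows a Beta law; giving groups different Beta
parameters plants a differential-abundance signal along pseudotime.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from pseudodiff.core import CellTable

__all__ = [
    "GeneProgram",
    "DEEffect",
    "SimConfig",
    "simulate",
    "simulate_null",
    "tiling_programs",
]

_LN2 = math.log(2.0)


@dataclass(frozen=True)
class GeneProgram:
    """A pseudotemporal gene module: Gaussian bump ``amplitude * exp(-(t-t0)^2 / 2w^2)``.

    ``active_samples`` restricts the program to a subset of sample names;
    ``None`` means active everywhere.
    """

    genes: tuple[int, ...]
    t0: float
    width: float
    amplitude: float
    active_samples: tuple[str, ...] | None = None

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("program width must be > 0")
        if self.amplitude < 0:
            raise ValueError("program amplitude must be >= 0")


@dataclass(frozen=True)
class DEEffect:
    """Group-specific log2 fold change on ``genes`` inside pseudotime window [t_lo, t_hi]."""

    genes: tuple[int, ...]
    group: str
    t_lo: float
    t_hi: float
    lfc: float  # log2

    def __post_init__(self):
        if not self.t_lo < self.t_hi:
            raise ValueError("DE effect requires t_lo < t_hi")


@dataclass(frozen=True)
class SimConfig:
    n_samples_per_group: int = 4
    groups: tuple[str, ...] = ("A", "B")
    n_cells_per_sample: int = 500
    n_genes: int = 300
    library_size_lognormal: tuple[float, float] = (0.0, 0.3)
    nb_dispersion: float = 0.3
    pseudotime_law: tuple[float, float] = (2.0, 2.0)
    abundance_shift: dict[str, tuple[float, float]] | None = None
    baseline_mean_range: tuple[float, float] = (0.1, 2.0)
    baseline_means: dict[int, float] | None = None  # per-gene mean-count overrides
    programs: tuple[GeneProgram, ...] = ()
    de_effects: tuple[DEEffect, ...] = ()
    seed: int = 0

    def __post_init__(self):
        if min(self.n_samples_per_group, self.n_cells_per_sample, self.n_genes) <= 0:
            raise ValueError("sizes must be positive")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        for g in self.groups:
            a, b = self.group_beta(g)
            if a <= 0 or b <= 0:
                raise ValueError(f"degenerate Beta law ({a}, {b}) for group {g!r}")

    def group_beta(self, group: str) -> tuple[float, float]:
        a, b = self.pseudotime_law
        if self.abundance_shift and group in self.abundance_shift:
            da, db = self.abundance_shift[group]
            a, b = a + da, b + db
        return a, b

    @property
    def sample_names(self) -> list[str]:
        return [f"{g}{i + 1}" for g in self.groups for i in range(self.n_samples_per_group)]


def tiling_programs(
    start_gene: int,
    n_programs: int = 8,
    genes_per_program: int = 15,
    width: float = 0.08,
    amplitude: float = 2.5,
) -> tuple[GeneProgram, ...]:
    """Programs with bump centers tiling [0, 1] over consecutive gene blocks.

    Gives simulated expression a pseudotime-coherent manifold (KNN
    neighborhoods then resolve pseudotime), mimicking the temporally
    structured transcriptome of a real differentiation trajectory.
    """
    centers = (np.arange(n_programs) + 0.5) / n_programs
    return tuple(
        GeneProgram(
            genes=tuple(
                range(start_gene + i * genes_per_program,
                      start_gene + (i + 1) * genes_per_program)
            ),
            t0=float(centers[i]),
            width=width,
            amplitude=amplitude,
        )
        for i in range(n_programs)
    )


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, disp: float) -> np.ndarray:
    if disp == 0:
        return rng.poisson(mu)
    lam = rng.gamma(shape=1.0 / disp, scale=mu * disp)
    return rng.poisson(lam)


def simulate(cfg: SimConfig) -> CellTable:
    """Draw a multi-sample trajectory CellTable; truth tables on ``.truth``.

    ``.truth`` maps ``"de"`` to a frame of planted DE effects per gene,
    ``"modules"`` to program membership per gene, and the returned obs
    carries the generated (true) pseudotime.
    """
    rng = np.random.default_rng(cfg.seed)
    n_genes = cfg.n_genes
    gene_ids = [f"g{j:04d}" for j in range(n_genes)]

    lo, hi = cfg.baseline_mean_range
    baseline = rng.uniform(math.log(lo), math.log(hi), size=n_genes)
    if cfg.baseline_means:
        for j, mean in cfg.baseline_means.items():
            baseline[j] = math.log(mean)

    obs_rows = []
    blocks = []
    mu_lib, sd_lib = cfg.library_size_lognormal
    for g in cfg.groups:
        a, b = cfg.group_beta(g)
        for i in range(cfg.n_samples_per_group):
            sample = f"{g}{i + 1}"
            n = cfg.n_cells_per_sample
            pt = rng.beta(a, b, size=n)
            libf = np.exp(rng.normal(mu_lib, sd_lib, size=n))

            log_mu = np.tile(baseline, (n, 1))
            for prog in cfg.programs:
                if prog.active_samples is not None and sample not in prog.active_samples:
                    continue
                bump = prog.amplitude * np.exp(-((pt - prog.t0) ** 2) / (2 * prog.width**2))
                log_mu[:, list(prog.genes)] += bump[:, None]
            for eff in cfg.de_effects:
                if eff.group != g:
                    continue
                in_win = (pt >= eff.t_lo) & (pt <= eff.t_hi)
                log_mu[np.ix_(in_win, list(eff.genes))] += eff.lfc * _LN2
            log_mu += np.log(libf)[:, None]

            counts = _nb_draw(rng, np.exp(log_mu), cfg.nb_dispersion)
            blocks.append(sp.csr_matrix(counts))
            obs_rows.append(
                pd.DataFrame(
                    {
                        "cell_id": [f"{sample}_c{j:04d}" for j in range(n)],
                        "sample": sample,
                        "group": g,
                        "pseudotime": pt,
                        "mito_frac": rng.uniform(0.0, 0.1, size=n),
                    }
                )
            )

    ct = CellTable(
        counts=sp.vstack(blocks, format="csr"),
        obs=pd.concat(obs_rows, ignore_index=True),
        gene_ids=gene_ids,
    )
    ct.truth = _truth_tables(cfg, gene_ids)
    return ct


def _truth_tables(cfg: SimConfig, gene_ids: list[str]) -> dict[str, pd.DataFrame]:
    de_rows = [
        {
            "gene_id": gene_ids[j],
            "group": eff.group,
            "t_lo": eff.t_lo,
            "t_hi": eff.t_hi,
            "lfc": eff.lfc,
        }
        for eff in cfg.de_effects
        for j in eff.genes
    ]
    mod_rows = [
        {
            "gene_id": gene_ids[j],
            "program": p_idx,
            "t0": prog.t0,
            "width": prog.width,
            "amplitude": prog.amplitude,
        }
        for p_idx, prog in enumerate(cfg.programs)
        for j in prog.genes
    ]
    return {
        "de": pd.DataFrame(de_rows, columns=["gene_id", "group", "t_lo", "t_hi", "lfc"]),
        "modules": pd.DataFrame(
            mod_rows, columns=["gene_id", "program", "t0", "width", "amplitude"]
        ),
    }


def simulate_null(cfg: SimConfig) -> CellTable:
    """As :func:`simulate` with every group-dependent effect removed.

    DE effects and abundance shifts are dropped and programs are made
    active in all samples, so group labels are pure relabelings of
    exchangeable samples.
    """
    null_cfg = replace(
        cfg,
        de_effects=(),
        abundance_shift=None,
        programs=tuple(replace(p, active_samples=None) for p in cfg.programs),
    )
    return simulate(null_cfg)
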