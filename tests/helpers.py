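"""Shared builders for simulated trajectory datasets and neighborhoods."""

from __future__ import annotations

import numpy as np

from pseudodiff.core import CellTable, normalize_log_cpm, select_hvg
from pseudodiff.neighborhoods import (
    build_knn,
    count_cells,
    nhood_pseudotime,
    sample_neighborhoods,
)
from pseudodiff.simulate import DEEffect, SimConfig, tiling_programs

# planted-gene layout used across trajdiff tests: genes 0-4 early-up,
# 5-9 down-everywhere, 10-19 untouched nulls at matched expression,
# 100+ temporal manifold programs
BOOSTED = {j: 5.0 for j in range(20)}
UP_EARLY = tuple(range(0, 5))
DOWN_ALL = tuple(range(5, 10))
NULL_GENES = tuple(range(10, 20))


def structured_cfg(seed: int = 0, **overrides) -> SimConfig:
    """Toy-scale trajectory config with a pseudotime-coherent manifold."""
    base = dict(
        n_samples_per_group=4,
        n_cells_per_sample=250,
        n_genes=300,
        nb_dispersion=0.3,
        baseline_means=BOOSTED,
        programs=tiling_programs(100, n_programs=8, genes_per_program=15),
        seed=seed,
    )
    base.update(overrides)
    return SimConfig(**base)


def de_cfg(seed: int = 0, lfc: float = 1.5, **overrides) -> SimConfig:
    """Structured config with planted early-up and whole-trajectory-down genes."""
    return structured_cfg(
        seed=seed,
        de_effects=(
            DEEffect(genes=UP_EARLY, group="B", t_lo=0.0, t_hi=0.4, lfc=lfc),
            DEEffect(genes=DOWN_ALL, group="B", t_lo=0.0, t_hi=1.0, lfc=-lfc),
        ),
        **overrides,
    )


def shift_cfg(seed: int = 0, **overrides) -> SimConfig:
    """Structured config with a late-stage abundance shift in group B
    (Beta(2,2) -> Beta(3,1.5))."""
    return structured_cfg(seed=seed, abundance_shift={"B": (1.0, -0.5)}, **overrides)


def build_nhoods(ct: CellTable, k: int = 30, n_hvg: int = 200,
                 proportion: float = 0.1, n_pcs: int = 30, seed: int = 1):
    expr = normalize_log_cpm(ct)
    hvg = select_hvg(expr, ct.gene_ids, n_top=n_hvg)
    graph = build_knn(expr[:, hvg], k=k, n_pcs=n_pcs, seed=seed)
    nhoods = sample_neighborhoods(graph, proportion=proportion, seed=seed)
    count_cells(nhoods, ct)
    nhood_pseudotime(nhoods, ct)
    return nhoods


def bump_matrix(rng: np.random.Generator, n_genes: int = 90, n_t: int = 40,
                n_blocks: int = 3, noise: float = 0.01):
    """Non-negative matrix of disjoint gene-block x time-bump programs."""
    t = np.linspace(0, 1, n_t)
    V = np.zeros((n_genes, n_t))
    block = n_genes // n_blocks
    truth = []
    for b in range(n_blocks):
        genes = np.arange(b * block, (b + 1) * block)
        t0 = (b + 0.5) / n_blocks
        bumpy = np.exp(-((t - t0) ** 2) / (2 * 0.08**2))
        V[genes] += np.outer(rng.uniform(0.5, 1.5, size=len(genes)), bumpy)
        truth.append(genes)
    V += noise * rng.random(V.shape)
    return V, truth
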