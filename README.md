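# pseudodiff

Pseudotime-resolved differential analysis for multi-sample single-cell
trajectories, plus cross-trajectory gene-module discovery:

* **Data core** — a `CellTable` (sparse counts + per-cell sample/group/
  pseudotime metadata) read and written as a plain-text trio
  (Matrix Market `counts.mtx`, `cells.tsv`, `genes.tsv`), with QC
  filtering, log-CPM normalization and highly-variable-gene selection.
* **Simulator** — seeded negative-binomial multi-sample trajectories with
  planted temporal gene programs, stage-specific differential expression
  and group-specific abundance shifts, so the whole stack is testable
  without any external data.
* **Differential abundance / expression (DA/DE)** — KNN-graph
  neighborhoods, per-neighborhood negative-binomial GLM tests against a
  two-level group factor, weighted ("spatial") FDR, projection onto
  pseudotime intervals, and a per-interval binomial test whose null
  acceptance rate is estimated by shuffling sample-to-group assignments.
  DE runs the same machinery per gene on neighborhood pseudobulks and
  reduces each gene to a two-stage pattern label (`Up_0`, `Down_Down`, …).
* **TRAV map** — per-trajectory gene × pseudotime-interval CPM matrices,
  seeded NMF, pooled hierarchical clustering of factors into recurrent
  axes of variation (TRAVs) with top-100 gene modules, activity scoring,
  conserved/covariate-associated TRAV detection and a 2-D trajectory
  embedding.
* **Trajectory features** — per-gene correlation/peak/expression
  attributes, common-pseudotime transfer by gradient-boosted regression
  trees, and classifier-based pseudotime-bin similarity with union-find
  merging.

## Test

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the property-based acceptance criteria
(exact oracles for the binomial interval test and weighted FDR, DA/DE
type-I and power contracts, NMF/TRAV recovery, pseudotime-transfer
accuracy); the other files are per-module unit and property tests.

## CLI

All commands read/write the plain-text trio. A typical loop:

```sh
# simulate a 2-group dataset with planted structure
pseudodiff simulate --config sim.yaml --seed 7 --out data/

# QC (thresholds per-dataset; toy simulations need looser ones)
pseudodiff qc --counts data/counts.mtx --cells data/cells.tsv \
    --genes data/genes.tsv --min-features 300 --min-counts 800 \
    --max-mito 0.2 --out qc/

# neighborhoods, differential abundance, differential expression
pseudodiff nhood --counts ... --k 15 --proportion 0.1 --seed 7 --out nh/
pseudodiff da    --counts ... --n-intervals 100 --seed 7 --out da/
pseudodiff de    --counts ... --gene-list genes.txt --seed 7 --out de/

# gene attributes, pseudotime transfer, TRAV discovery
pseudodiff attributes --counts ... --out attributes.tsv
pseudodiff transfer --ref-counts ... --query-counts ... --out pt.tsv
pseudodiff travmap --counts ... --k-factors 15 --seed 7 --out trav/
```

`sim.yaml` (or `.json`) overrides `SimConfig` fields, e.g.:

```yaml
n_samples_per_group: 4
n_cells_per_sample: 500
n_genes: 300
abundance_shift: {B: [1.0, -0.5]}
programs:
  - {genes: [0, 1, 2], t0: 0.3, width: 0.08, amplitude: 2.5}
```

## Conventions

* Counts matrices are cells × rows internally; Matrix Market files are
  accepted in either orientation (auto-detected from metadata row counts).
* Pseudotime lives in [0, 1]; intervals/bins are equal-width, half-open,
  with the last bin closed at 1; ids are 1-based.
* log-fold changes are log2 and compare the *second* group level (stable
  order of appearance) against the first.
* Every stochastic step takes an explicit seed.
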