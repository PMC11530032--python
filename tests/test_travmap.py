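import numpy as np
import pandas as pd
import pytest
from scipy.optimize import linear_sum_assignment

from helpers import bump_matrix

from pseudodiff.simulate import GeneProgram, SimConfig, simulate, tiling_programs
from pseudodiff.trajdiff import assign_intervals
from pseudodiff.travmap import (
    TrajFactorization,
    TravSet,
    build_traj_matrix,
    choose_rank,
    conserved_travs,
    covariate_travs,
    embed_trajectories,
    nmf_decompose,
    pool_and_cluster,
    trav_activity,
    trav_cluster_count,
    trav_temporal_profile,
)

MANIFOLD = tiling_programs(100, n_programs=8, genes_per_program=15)


def make_trajectory(seed, extra_programs=(), n_cells=250, n_genes=300):
    cfg = SimConfig(
        n_samples_per_group=1,
        groups=("A",),
        n_cells_per_sample=n_cells,
        n_genes=n_genes,
        nb_dispersion=0.3,
        programs=MANIFOLD + tuple(extra_programs),
        seed=seed,
    )
    return simulate(cfg)


@pytest.fixture(scope="module")
def trajectories():
    return [make_trajectory(100 + i) for i in range(8)]


@pytest.fixture(scope="module")
def factorizations(trajectories):
    facts = []
    for i, ct in enumerate(trajectories):
        tm = build_traj_matrix(ct, traj_id=f"t{i}", n_intervals=50, n_hvg=300)
        facts.append(nmf_decompose(tm, K=8, seed=7))
    return facts


# ----------------------------------------------------------------------
# trajectory matrix
# ----------------------------------------------------------------------

class TestBuildTrajMatrix:
    def test_constant_gene_row_of_ones(self, trajectories):
        tm = build_traj_matrix(trajectories[0], n_intervals=20, n_hvg=300)
        # find a housekeeping-like gene: nonzero in every occupied interval
        full_rows = np.flatnonzero((tm.matrix > 0).all(axis=1))
        assert len(full_rows) > 0
        assert np.isclose(tm.matrix[full_rows].max(axis=1), 1.0).all()

    def test_late_gene_mass_late(self):
        late_prog = GeneProgram(genes=(0,), t0=0.9, width=0.05, amplitude=4.0)
        ct = make_trajectory(3, extra_programs=(late_prog,))
        tm = build_traj_matrix(ct, n_intervals=10, n_hvg=300)
        gi = tm.gene_ids.index("g0000")
        row = tm.matrix[gi]
        n_cols = row.shape[0]
        assert row[: n_cols // 2].sum() < row[n_cols // 2 :].sum()

    def test_matches_brute_force_cpm(self, trajectories):
        ct = trajectories[1]
        n_intervals = 10
        tm = build_traj_matrix(ct, n_intervals=n_intervals, n_hvg=300)
        ids = assign_intervals(ct.pseudotime, n_intervals)
        X = np.asarray(ct.counts.todense())
        occupied = [iv for iv in range(1, n_intervals + 1) if (ids == iv).any()
                    and X[ids == iv].sum() > 0]
        col = {iv: c for c, iv in enumerate(occupied)}
        gidx = {g: i for i, g in enumerate(ct.gene_ids)}
        rng = np.random.default_rng(0)
        for g in rng.choice(tm.gene_ids, size=10, replace=False):
            raw = np.array(
                [X[ids == iv, gidx[g]].sum() / X[ids == iv].sum() * 1e6 for iv in occupied]
            )
            expect = raw / raw.max() if raw.max() > 0 else raw
            assert np.allclose(tm.matrix[tm.gene_ids.index(g)], expect)

    def test_too_few_intervals_rejected(self):
        ct = make_trajectory(5, n_cells=30)
        # squeeze pseudotime into a sliver so < 5 of 100 intervals are hit
        ct.obs["pseudotime"] = 0.5 + 0.01 * ct.obs["pseudotime"]
        with pytest.raises(ValueError, match="rejected"):
            build_traj_matrix(ct, n_intervals=100, n_hvg=300)


# ----------------------------------------------------------------------
# NMF
# ----------------------------------------------------------------------

class TestNmf:
    def test_exact_rank_one(self):
        rng = np.random.default_rng(0)
        V = np.outer(rng.uniform(0.1, 1, 30), rng.uniform(0.1, 1, 20))
        from pseudodiff.travmap import TrajMatrix

        tm = TrajMatrix("x", V, [f"g{i}" for i in range(30)], np.ones(20, bool))
        fact = nmf_decompose(tm, K=1, seed=1)
        assert fact.recon_error < 1e-8

    def test_objective_monotone_nonincreasing(self):
        rng = np.random.default_rng(1)
        from pseudodiff.travmap import TrajMatrix

        V = rng.random((40, 25))
        tm = TrajMatrix("x", V, [f"g{i}" for i in range(40)], np.ones(25, bool))
        fact = nmf_decompose(tm, K=4, seed=2)
        obj = np.array(fact.objective)
        assert np.all(np.diff(obj) <= 1e-9 * np.maximum(obj[:-1], 1))

    def test_w_columns_unit_norm(self):
        rng = np.random.default_rng(2)
        from pseudodiff.travmap import TrajMatrix

        V = rng.random((40, 25))
        tm = TrajMatrix("x", V, [f"g{i}" for i in range(40)], np.ones(25, bool))
        fact = nmf_decompose(tm, K=5, seed=0)
        assert np.allclose(np.linalg.norm(fact.W, axis=0), 1.0)
        assert np.allclose(fact.W @ fact.H, V, atol=1.0)  # sanity, not exact

    def test_k_too_large(self):
        from pseudodiff.travmap import TrajMatrix

        tm = TrajMatrix("x", np.ones((5, 4)), [f"g{i}" for i in range(5)], np.ones(4, bool))
        with pytest.raises(ValueError, match="K="):
            nmf_decompose(tm, K=4)

    def test_planted_three_programs_recovered(self):
        rng = np.random.default_rng(3)
        V, truth = bump_matrix(rng, n_genes=90, n_t=40, n_blocks=3)
        from pseudodiff.travmap import TrajMatrix

        tm = TrajMatrix("x", V, [f"g{i}" for i in range(90)], np.ones(40, bool))
        fact = nmf_decompose(tm, K=3, seed=4)
        # Hungarian match factors to planted blocks on loading correlation
        indicators = np.zeros((3, 90))
        for b, genes in enumerate(truth):
            indicators[b, genes] = 1.0
        corr = np.zeros((3, 3))
        for b in range(3):
            for k in range(3):
                corr[b, k] = np.corrcoef(indicators[b], fact.W[:, k])[0, 1]
        rows, cols = linear_sum_assignment(-corr)
        assert (corr[rows, cols] > 0.9).all()


class TestChooseRank:
    def test_single_candidate(self):
        from pseudodiff.travmap import TrajMatrix

        tm = TrajMatrix("x", np.ones((10, 8)), [f"g{i}" for i in range(10)], np.ones(8, bool))
        assert choose_rank(tm, [3]) == 3

    def test_noise_free_rank_one(self):
        rng = np.random.default_rng(5)
        V = np.outer(rng.uniform(0.5, 1, 30), rng.uniform(0.5, 1, 20))
        from pseudodiff.travmap import TrajMatrix

        tm = TrajMatrix("x", V, [f"g{i}" for i in range(30)], np.ones(20, bool))
        assert choose_rank(tm, [1, 4], seed=0) == 1

    def test_planted_rank_two(self):
        from pseudodiff.travmap import TrajMatrix

        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(50 + seed)
            # two distinguishable components: disjoint gene support
            u1 = np.r_[rng.uniform(0.5, 1, 20), np.zeros(20)]
            u2 = np.r_[np.zeros(20), rng.uniform(0.5, 1, 20)]
            V = (np.outer(u1, rng.uniform(0.5, 1, 30))
                 + np.outer(u2, rng.uniform(0.5, 1, 30))
                 + 0.01 * rng.random((40, 30)))
            tm = TrajMatrix("x", V, [f"g{i}" for i in range(40)], np.ones(30, bool))
            hits += choose_rank(tm, [1, 2, 6], seed=seed) == 2
        assert hits >= 8


# ----------------------------------------------------------------------
# pooling / clustering
# ----------------------------------------------------------------------

class TestClusterCount:
    def test_paper_scale(self):
        assert trav_cluster_count(121, 15) == 226

    def test_small(self):
        assert trav_cluster_count(8, 15) == 15

    def test_floor_property(self):
        for d in (1, 3, 8, 40, 121):
            for k in (2, 8, 15):
                if d * k >= 8:
                    assert trav_cluster_count(d, k) == (d * k) // 8

    def test_minimum_one(self):
        assert trav_cluster_count(1, 3) == 1


class TestPoolAndCluster:
    def test_partition_property(self, factorizations):
        ts = pool_and_cluster(factorizations)
        total = sum(len(m) for m in ts.members)
        assert total == 8 * 8
        seen = set()
        for mem in ts.members:
            for owner in mem:
                assert owner not in seen
                seen.add(owner)

    def test_cluster_count_rule(self, factorizations):
        ts = pool_and_cluster(factorizations)
        assert ts.cluster_count == trav_cluster_count(8, 8)

    def test_modules_capped_at_100(self, factorizations):
        ts = pool_and_cluster(factorizations)
        assert all(len(m) <= 100 for m in ts.modules)

    def test_shared_module_co_clusters(self, factorizations, trajectories):
        ts = pool_and_cluster(factorizations)
        # each planted program should be concentrated in some TRAV's module
        for prog in MANIFOLD[2:5]:
            planted = {f"g{j:04d}" for j in prog.genes}
            best = max(len(planted & set(m)) for m in ts.modules)
            assert best >= int(0.7 * len(planted))

    def test_vocabulary_mismatch_rejected(self, factorizations):
        import dataclasses

        bad = dataclasses.replace(factorizations[0],
                                  gene_ids=list(reversed(factorizations[0].gene_ids)))
        with pytest.raises(ValueError, match="vocabulary"):
            pool_and_cluster([factorizations[1], bad])


# ----------------------------------------------------------------------
# activity / conserved / covariate
# ----------------------------------------------------------------------

class TestActivity:
    def test_own_member_factor_max_activity(self):
        rng = np.random.default_rng(6)
        W = rng.random((50, 3))
        W /= np.linalg.norm(W, axis=0)
        fact = TrajFactorization("t0", W, np.ones((3, 10)), 3, 0.0, [],
                                 [f"g{i}" for i in range(50)])
        ts = TravSet(
            trav_ids=["TRAV1"], loadings=W[:, 1][None, :], members=[[("t0", 1)]],
            modules=[["g0"]], gene_ids=fact.gene_ids, cluster_count=1,
        )
        act = trav_activity(ts, [fact])
        assert np.isclose(act.loc["TRAV1", "t0"], 1.0)

    def test_bounded(self, factorizations):
        ts = pool_and_cluster(factorizations)
        act = trav_activity(ts, factorizations)
        assert (act.to_numpy() >= -1 - 1e-12).all() and (act.to_numpy() <= 1 + 1e-12).all()

    def test_orthogonal_random_near_zero(self):
        rng = np.random.default_rng(7)
        n_genes = 2000
        W = rng.random((n_genes, 4))
        W /= np.linalg.norm(W, axis=0)
        fact = TrajFactorization("t0", W, np.ones((4, 10)), 4, 0.0, [],
                                 [f"g{i}" for i in range(n_genes)])
        ts = TravSet(
            trav_ids=["TRAV1"], loadings=rng.random((1, n_genes)), members=[[("x", 0)]],
            modules=[["g0"]], gene_ids=fact.gene_ids, cluster_count=1,
        )
        act = trav_activity(ts, [fact])
        # max of 4 near-zero correlations stays small
        assert abs(act.loc["TRAV1", "t0"]) < 0.1


class TestConserved:
    def _activity(self, values):
        return pd.DataFrame([values], index=["TRAV1"],
                            columns=[f"t{i}" for i in range(len(values))])

    def test_forty_percent_conserved(self):
        act = self._activity([0.5, 0.5, 0.5, 0.5] + [0.1] * 6)  # 40% above
        assert conserved_travs(act) == ["TRAV1"]

    def test_exactly_one_third_not_conserved(self):
        act = self._activity([0.5, 0.5] + [0.1] * 4)  # exactly 1/3
        assert conserved_travs(act) == []

    def test_threshold_strict(self):
        act = self._activity([0.4] * 10)  # at threshold, not above
        assert conserved_travs(act, threshold=0.4) == []

    def test_planted_universal_module_conserved(self, factorizations):
        ts = pool_and_cluster(factorizations)
        act = trav_activity(ts, factorizations)
        conserved = conserved_travs(act)
        # manifold programs recur in all 8 trajectories
        assert len(conserved) >= 4


class TestCovariate:
    def test_identical_activity_across_levels_null(self):
        rng = np.random.default_rng(8)
        half = 0.5 + 0.1 * rng.standard_normal((3, 6))
        act = pd.DataFrame(np.hstack([half, half]),  # identical across levels
                           index=["TRAV1", "TRAV2", "TRAV3"],
                           columns=[f"t{i}" for i in range(12)])
        cov = pd.Series(["old"] * 6 + ["young"] * 6, index=act.columns)
        out = covariate_travs(act, cov)
        assert np.allclose(out["effect"], 0.0, atol=1e-10)
        assert (out["p_value"] > 0.99).all()

    def test_planted_covariate_trav_detected(self):
        rng = np.random.default_rng(9)
        n_traj = 12
        act = pd.DataFrame(0.2 + 0.05 * rng.standard_normal((4, n_traj)),
                           index=[f"TRAV{i}" for i in range(4)],
                           columns=[f"t{i}" for i in range(n_traj)])
        cov = pd.Series(["old"] * 6 + ["young"] * 6, index=act.columns)
        act.iloc[2, :6] += 0.5  # active only in old trajectories
        out = covariate_travs(act, cov)
        assert out.loc["TRAV2", "fdr"] < 0.05

    def test_mixed_model_with_projects(self):
        rng = np.random.default_rng(10)
        n_traj = 12
        act = pd.DataFrame(0.3 + 0.05 * rng.standard_normal((2, n_traj)),
                           index=["TRAV1", "TRAV2"],
                           columns=[f"t{i}" for i in range(n_traj)])
        cov = pd.Series(["old", "young"] * 6, index=act.columns)
        proj = pd.Series(["p1"] * 6 + ["p2"] * 6, index=act.columns)
        act.loc["TRAV1", cov == "old"] += 0.4
        out = covariate_travs(act, cov, project=proj)
        assert out.loc["TRAV1", "p_value"] < 0.05
        assert out.loc["TRAV2", "p_value"] > 0.05

    def test_single_level_rejected(self):
        act = pd.DataFrame(np.ones((1, 4)), index=["TRAV1"],
                           columns=["a", "b", "c", "d"])
        with pytest.raises(ValueError, match="levels"):
            covariate_travs(act, pd.Series(["x"] * 4, index=act.columns))


# ----------------------------------------------------------------------
# temporal profile + embedding
# ----------------------------------------------------------------------

class TestTemporalProfile:
    def test_mid_module_peak(self, factorizations, trajectories):
        ts = pool_and_cluster(factorizations)
        act = trav_activity(ts, factorizations)
        trajs = {f"t{i}": ct for i, ct in enumerate(trajectories)}
        prof = trav_temporal_profile(ts, act, trajs, n_bins=10)
        # the TRAV matching the t0=0.5625 program peaks mid-trajectory
        mid_prog = {f"g{j:04d}" for j in MANIFOLD[4].genes}  # t0 = 0.5625
        best_i = int(np.argmax([len(mid_prog & set(m)) for m in ts.modules]))
        peak = prof.iloc[best_i]["peak"]
        assert 5 <= peak <= 7

    def test_early_module_peak_early(self, factorizations, trajectories):
        ts = pool_and_cluster(factorizations)
        act = trav_activity(ts, factorizations)
        trajs = {f"t{i}": ct for i, ct in enumerate(trajectories)}
        prof = trav_temporal_profile(ts, act, trajs, n_bins=10)
        early_prog = {f"g{j:04d}" for j in MANIFOLD[0].genes}  # t0 = 0.0625
        best_i = int(np.argmax([len(early_prog & set(m)) for m in ts.modules]))
        assert prof.iloc[best_i]["peak"] <= 3


class TestEmbedding:
    def test_identical_trajectories_near_identical(self):
        rng = np.random.default_rng(11)
        base = rng.random(6)
        block = np.vstack([base, base] + [rng.random(6) for _ in range(6)])
        coords = embed_trajectories({"activity": block}, seed=0)
        d01 = np.linalg.norm(coords[0] - coords[1])
        others = np.linalg.norm(coords[2:] - coords[0], axis=1).min()
        assert d01 < others

    def test_deterministic(self):
        rng = np.random.default_rng(12)
        block = rng.random((10, 5))
        a = embed_trajectories({"b": block}, seed=3)
        b = embed_trajectories({"b": block.copy()}, seed=3)
        assert np.allclose(a, b)

    def test_two_families_separate(self):
        from sklearn.metrics import silhouette_score

        rng = np.random.default_rng(13)
        fam_a = rng.random(8) + np.array([3] * 4 + [0] * 4)
        fam_b = rng.random(8) + np.array([0] * 4 + [3] * 4)
        block = np.vstack(
            [fam_a + 0.2 * rng.standard_normal(8) for _ in range(6)]
            + [fam_b + 0.2 * rng.standard_normal(8) for _ in range(6)]
        )
        coords = embed_trajectories({"activity": block}, seed=1)
        labels = [0] * 6 + [1] * 6
        assert silhouette_score(coords, labels) > 0.3

    def test_too_few_rejected(self):
        with pytest.raises(ValueError, match="3 trajectories"):
            embed_trajectories({"b": np.ones((2, 3))})
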