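"""Co-occurrence scores, bee similarity, MCL clustering, cluster stats."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mastkit import (
    MCLParams,
    StrainTable,
    bee_similarity_matrix,
    build_cooccurrence_graph,
    cluster_stats,
    cooccurrence_score,
    mcl_cluster,
    within_vs_between_snps,
)

from _mcl_oracle import mcl_reference


class TestCooccurrenceScore:
    @pytest.mark.parametrize(
        "b_ab,b_a,b_b,expected",
        [(5, 5, 5, 1.0), (0, 4, 6, 0.0), (3, 4, 6, 0.6)],
        ids=["identical-hosts", "never-together", "partial"],
    )
    def test_direct_evaluation(self, b_ab, b_a, b_b, expected):
        assert cooccurrence_score(b_ab, b_a, b_b) == pytest.approx(expected)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            cooccurrence_score(5, 4, 6)
        with pytest.raises(ValueError):
            cooccurrence_score(0, 0, 3)

    @settings(max_examples=100, deadline=None)
    @given(st.integers(1, 50), st.integers(1, 50), st.data())
    def test_bounds(self, b_a, b_b, data):
        b_ab = data.draw(st.integers(0, min(b_a, b_b)))
        s = cooccurrence_score(b_ab, b_a, b_b)
        assert 0.0 <= s <= 1.0
        assert (s == 1.0) == (b_ab == b_a == b_b)


def _presence_table(matrix, samples=None, marker="m"):
    strains = [f"s{i}" for i in range(len(matrix))]
    samples = samples or [f"b{j}" for j in range(len(matrix[0]))]
    pres = pd.DataFrame(matrix, index=strains, columns=samples, dtype=bool)
    return StrainTable.from_presence(pres, marker)


class TestBuildGraph:
    def test_always_together_scores_one(self):
        table = _presence_table([[1] * 10, [1] * 10])
        g = build_cooccurrence_graph(table, "m")
        assert g.S[0, 1] == pytest.approx(1.0)

    def test_symmetric_unit_diagonal(self, clean_table):
        marker = clean_table.markers[0]
        g = build_cooccurrence_graph(clean_table, marker)
        assert np.allclose(g.S, g.S.T)
        assert np.allclose(np.diag(g.S), 1.0)
        assert g.S.min() >= 0 and g.S.max() <= 1

    def test_planted_clusters_separate_scores(self, small_truth, clean_table):
        """Within-cluster scores far exceed between-cluster scores."""
        marker = small_truth.markers[0]
        g = build_cooccurrence_graph(clean_table, marker)
        planted = small_truth.partition(marker)
        labels = [planted[clean_table.registry[sid].sequence] for sid in g.strain_ids]
        within, between = [], []
        for i in range(len(g)):
            for j in range(i + 1, len(g)):
                (within if labels[i] == labels[j] else between).append(g.S[i, j])
        assert min(within) > max(between)

    def test_single_strain_graph_warns_empty(self):
        table = _presence_table([[1, 1, 0]])
        with pytest.warns(UserWarning):
            g = build_cooccurrence_graph(table, "m")
        assert len(g) <= 1


class TestBeeSimilarity:
    def test_formula_endpoints_and_partial_overlap(self):
        # bees: x={s0,s1}, y={s0,s1,s2,s3}, z={s4}, w={} (missing)
        m = [
            [1, 1, 0, 0],
            [1, 1, 0, 0],
            [0, 1, 0, 0],
            [0, 1, 0, 0],
            [0, 0, 1, 0],
        ]
        table = _presence_table(m, samples=["x", "y", "z", "w"])
        sim = bee_similarity_matrix(table, "m")
        assert sim.loc["x", "y"] == pytest.approx(2 * 2 / (2 + 4))
        assert sim.loc["x", "x"] == 1.0
        assert sim.loc["x", "z"] == 0.0
        assert np.isnan(sim.loc["w", "x"])


class TestMCL:
    def test_two_disconnected_cliques(self):
        S = np.zeros((8, 8))
        S[:4, :4] = 1.0
        S[4:, 4:] = 1.0
        clusters = mcl_cluster(S)
        assert sorted(len(m) for m in clusters.partition.values()) == [4, 4]

    def test_identity_graph_all_singletons(self):
        clusters = mcl_cluster(np.eye(6))
        assert sorted(len(m) for m in clusters.partition.values()) == [1] * 6

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        A = rng.random((12, 12)) * (rng.random((12, 12)) < 0.3)
        S = np.triu(A, 1)
        S = S + S.T
        np.fill_diagonal(S, 1.0)
        p1 = mcl_cluster(S).partition
        p2 = mcl_cluster(7.3 * S).partition
        assert {frozenset(m) for m in p1.values()} == {frozenset(m) for m in p2.values()}

    def test_node_order_invariance_up_to_relabeling(self):
        rng = np.random.default_rng(5)
        A = rng.random((10, 10)) * (rng.random((10, 10)) < 0.4)
        S = np.triu(A, 1)
        S = S + S.T
        np.fill_diagonal(S, 1.0)
        ids = [f"s{i}" for i in range(10)]
        p = rng.permutation(10)
        base = {
            frozenset(m) for m in mcl_cluster(S, strain_ids=ids).partition.values()
        }
        permuted = {
            frozenset(m)
            for m in mcl_cluster(S[np.ix_(p, p)], strain_ids=[ids[i] for i in p]).partition.values()
        }
        assert base == permuted

    @pytest.mark.parametrize("inflation", [1.2, 2.0, 4.0, 6.0])
    def test_matches_reference_mcl(self, inflation):
        """Partitions agree with an independent dense MCL implementation."""
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            n = 30
            A = rng.random((n, n)) * (rng.random((n, n)) < 0.25)
            S = np.triu(A, 1)
            S = S + S.T
            np.fill_diagonal(S, 1.0)
            clusters = mcl_cluster(
                S, MCLParams(inflation=inflation), strain_ids=[f"n{i}" for i in range(n)]
            )
            mine = {
                frozenset(int(s[1:]) for s in m) for m in clusters.partition.values()
            }
            assert mine == set(mcl_reference(S, inflation))

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            MCLParams(inflation=1.0)
        with pytest.raises(ValueError):
            mcl_cluster(np.array([[1.0, -0.1], [-0.1, 1.0]]))


class TestClusterRecovery:
    def test_planted_partition_recovered(self, small_truth, clean_table):
        """MCL at I=2.0 reproduces the planted clusters exactly."""
        for marker in small_truth.markers:
            g = build_cooccurrence_graph(clean_table, marker)
            clusters = mcl_cluster(g, MCLParams(inflation=2.0))
            planted = small_truth.partition(marker)
            got = {
                frozenset(planted[clean_table.registry[sid].sequence] for sid in members)
                for members in clusters.partition.values()
            }
            # every recovered cluster is pure and planted clusters are not split
            assert all(len(s) == 1 for s in got)
            assert len(clusters.partition) == len(
                {planted[clean_table.registry[s.strain_id].sequence] for s in clean_table.strains(marker)}
            )

    def test_cluster_stats_modal_values(self, small_truth, clean_table):
        marker = small_truth.markers[0]
        g = build_cooccurrence_graph(clean_table, marker)
        clusters = mcl_cluster(g)
        stats = cluster_stats(clusters, clean_table, marker)
        sizes = pd.Series(stats.sizes)
        assert sizes.mode().iloc[0] == 4
        assert stats.clusters_per_bee.mode().iloc[0] == 1
        finite = [v for v in stats.within_cluster_snp_means.values() if v == v]
        assert all(1.0 <= v <= 2.0 for v in finite)

    def test_singleton_clustering_counts_strains(self, clean_table):
        from mastkit import StrainClusterSet

        marker = clean_table.markers[0]
        sids = [s.strain_id for s in clean_table.strains(marker)]
        singletons = StrainClusterSet(partition={f"c{i}": [sid] for i, sid in enumerate(sids)})
        stats = cluster_stats(singletons, clean_table, marker)
        per_bee_strains = clean_table.presence(marker).sum(axis=0)
        for bee in clean_table.marker_samples(marker):
            assert stats.clusters_per_bee[bee] == per_bee_strains[bee]


class TestWithinVsBetween:
    def test_planted_distances_strongly_separated(self, small_truth, clean_table):
        """~1 SNP within vs ~8+ SNPs between gives a tiny rank-sum p."""
        marker = small_truth.markers[0]
        g = build_cooccurrence_graph(clean_table, marker)
        clusters = mcl_cluster(g)
        res = within_vs_between_snps(clusters, clean_table.registry)
        assert res.applicable
        assert res.within.mean() < res.between.mean()
        assert res.pvalue < 1e-6

    def test_single_cluster_not_applicable(self, clean_table):
        from mastkit import StrainClusterSet

        marker = clean_table.markers[0]
        sids = [s.strain_id for s in clean_table.strains(marker)]
        one = StrainClusterSet(partition={"c0": sids})
        res = within_vs_between_snps(one, clean_table.registry)
        assert not res.applicable

    def test_label_shuffle_calibration(self, small_truth, clean_table):
        """Random relabelling kills the within/between separation: p is
        roughly uniform, so small p-values appear at near-nominal rate."""
        from mastkit import StrainClusterSet

        marker = small_truth.markers[0]
        sids = [s.strain_id for s in clean_table.strains(marker)]
        rng = np.random.default_rng(0)
        pvals = []
        for _ in range(100):
            perm = rng.permutation(len(sids))
            part = {}
            for i, j in enumerate(perm):
                part.setdefault(f"c{i % 5}", []).append(sids[j])
            res = within_vs_between_snps(StrainClusterSet(partition=part), clean_table.registry)
            pvals.append(res.pvalue)
        pvals = np.array(pvals)
        assert 0.01 <= (pvals < 0.05).mean() <= 0.15
        assert 0.25 <= (pvals < 0.5).mean() <= 0.75
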