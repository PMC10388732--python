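import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from binet.implication import RelationType, pairwise_relations
from binet.io import ExpressionMatrix
from binet.network import (GeneCluster, ImplicationNetwork, build_bin,
                           check_scale_free, cluster_equivalences,
                           connect_clusters, filter_genes,
                           select_representatives)
from conftest import planted_cluster_map

R = RelationType


def _em(arr, genes=None):
    arr = np.asarray(arr, dtype=float)
    genes = genes or [f"G{i}" for i in range(arr.shape[0])]
    return ExpressionMatrix(pd.DataFrame(
        arr, index=genes, columns=[f"s{i}" for i in range(arr.shape[1])]))


class TestFilterGenes:
    def _codes(self, rows):
        return pd.DataFrame(np.asarray(rows, dtype=np.int8),
                            index=[f"G{i}" for i in range(len(rows))],
                            columns=[f"s{i}" for i in range(len(rows[0]))])

    def test_one_sided_gene_dropped(self):
        codes = self._codes([[-1] * 20, [-1] * 10 + [1] * 10])
        em = _em(np.zeros((2, 20)) + np.arange(20))
        kept = filter_genes(em, codes=codes)
        assert kept.gene_ids == ["G1"]

    def test_boundary_fraction_kept(self):
        # exactly 5% high of 20 samples sits on the inclusive boundary
        codes = self._codes([[1] + [-1] * 19])
        em = _em([np.arange(20)])
        assert filter_genes(em, codes=codes).gene_ids == ["G0"]

    def test_empty_result_is_error(self):
        codes = self._codes([[-1] * 20])
        with pytest.raises(ValueError):
            filter_genes(_em([np.arange(20)]), codes=codes)


class TestBuildBin:
    def test_identical_rows_give_equivalent_edge(self, rng):
        row = np.r_[rng.normal(2, 0.1, 25), rng.normal(8, 0.1, 25)]
        bn = build_bin(_em([row, row + 0.05]))
        assert bn.relation("G0", "G1") == R.EQUIVALENT
        assert len(bn.edges) == 1

    def test_planted_blocks_recovered(self, dataset_clean):
        bn = build_bin(dataset_clean.matrix.subset_genes(
            dataset_clean.gene_clusters[13][:5] + dataset_clean.gene_clusters[14][:5]))
        for i in range(5):
            for j in range(5):
                a, b = f"C13G{i + 1:03d}", f"C14G{j + 1:03d}"
                assert bn.relation(a, b) == R.OPPOSITE
                if i != j:
                    assert bn.relation(a, f"C13G{j + 1:03d}") == R.EQUIVALENT

    def test_noise_matrix_has_few_edges(self, rng):
        em = _em(rng.normal(6, 1, (40, 200)))
        bn = build_bin(em)
        n_pairs = 40 * 39 / 2
        assert len(bn.edges) / n_pairs <= 0.001


class TestClusterEquivalences:
    def _net_from_rel(self, genes, rel_pairs):
        n = len(genes)
        rel = np.zeros((n, n), dtype=np.int8)
        idx = {g: i for i, g in enumerate(genes)}
        for a, b, r in rel_pairs:
            rel[idx[a], idx[b]] = int(r)
            rel[idx[b], idx[a]] = int(r.mirror() if r == R.LOW_LOW else r)
        return ImplicationNetwork(genes=genes,
                                  rel=pd.DataFrame(rel, index=genes, columns=genes))

    def test_shared_neighbors_stay_together(self):
        genes = ["A", "B", "C", "D"]
        pairs = [(a, b, R.EQUIVALENT) for a in genes for b in genes if a < b]
        clusters = cluster_equivalences(self._net_from_rel(genes, pairs))
        assert len(clusters) == 1 and clusters[0].size == 4

    def test_weak_bridge_cut(self):
        # two triangles bridged by a single equivalence: Jaccard 0 < 0.5
        genes = ["A1", "A2", "A3", "B1", "B2", "B3"]
        pairs = [("A1", "A2", R.EQUIVALENT), ("A1", "A3", R.EQUIVALENT),
                 ("A2", "A3", R.EQUIVALENT), ("B1", "B2", R.EQUIVALENT),
                 ("B1", "B3", R.EQUIVALENT), ("B2", "B3", R.EQUIVALENT),
                 ("A1", "B1", R.EQUIVALENT)]
        clusters = cluster_equivalences(self._net_from_rel(genes, pairs))
        assert sorted(c.size for c in clusters) == [3, 3]

    def test_planted_partition_recovery(self, dataset, fitted):
        mapping = planted_cluster_map(dataset, fitted.cbin.clusters)
        truth, pred = [], []
        recovered = {g: mapping[c.id] for c in fitted.cbin.clusters
                     for g in c.members}
        for cid, genes in dataset.gene_clusters.items():
            for g in genes:
                truth.append(cid)
                pred.append(recovered.get(g, -1))
        assert adjusted_rand_score(truth, pred) >= 0.95

    def test_partition_and_numbering(self, fitted):
        seen = set()
        sizes = []
        for c in fitted.cbin.clusters:
            assert not (set(c.members) & seen)
            seen |= set(c.members)
            sizes.append(c.size)
        assert sizes == sorted(sizes, reverse=True)
        assert [c.id for c in fitted.cbin.clusters] == list(range(1, len(sizes) + 1))

    def test_no_equivalences_warns_empty(self, rng):
        genes = ["A", "B"]
        clusters = cluster_equivalences(self._net_from_rel(genes, []))
        assert clusters == []


class TestScaleFree:
    def test_power_law_sizes_fit_line(self, rng):
        sizes = np.sort((rng.pareto(1.2, 400) * 4 + 1).astype(int))[::-1]
        slope, r2 = check_scale_free(sizes)
        assert slope < 0 and r2 >= 0.8

    def test_equal_sizes_undefined(self):
        slope, r2 = check_scale_free([4, 4, 4])
        assert np.isnan(slope) and np.isnan(r2)

    def test_two_sizes_still_fits(self):
        slope, r2 = check_scale_free([8, 2])
        assert np.isfinite(slope)


class TestRepresentatives:
    @pytest.mark.parametrize("n,expected", [
        (16, [1, 2, 8, 7, 4]),
        (5, [1, 2, 3]),
        (1, [1]),
        (2, [1, 2]),
        (12, [1, 2, 6, 5, 3, 1]),
    ])
    def test_rank_sampling_rule(self, n, expected):
        c = GeneCluster(id=1, members=[f"g{i}" for i in range(n)])
        got = select_representatives(c)
        if n == 12:  # floor(12/8) = 1 duplicates rank 1
            assert got == [1, 2, 6, 5, 3]
        else:
            assert got == expected


class TestConnectClusters:
    def test_planted_cbin_edges(self, dataset, fitted):
        mapping = planted_cluster_map(dataset, fitted.cbin.clusters)
        got = {(mapping[a], mapping[b]): r for a, b, r, _ in fitted.cbin.edges}
        plan = dataset.blueprint.relation_plan
        assert len(got) == len(plan)
        for (a, b), r in plan.items():
            if (a, b) in got:
                assert got[(a, b)] == r
            else:
                assert got[(b, a)] == r.mirror()

    def test_determinism(self, dataset_clean):
        sub = dataset_clean.matrix
        runs = []
        for _ in range(2):
            bn = build_bin(sub)
            clusters = cluster_equivalences(bn)
            cbin = connect_clusters(clusters, bn)
            runs.append(([tuple(c.members) for c in clusters],
                         [(a, b, r) for a, b, r, _ in cbin.edges]))
        assert runs[0] == runs[1]

    def test_independent_noise_clusters_unconnected(self, rng):
        # two equivalence blocks driven by independent latent switches
        s1 = np.r_[np.full(60, 2.0), np.full(60, 8.0)] + rng.normal(0, 0.2, 120)
        s2 = rng.permutation(np.r_[np.full(60, 2.0), np.full(60, 8.0)]) \
            + rng.normal(0, 0.2, 120)
        em = _em([s1, s1 + 0.1, s1 - 0.1, s2, s2 + 0.1, s2 - 0.1])
        bn = build_bin(em)
        clusters = cluster_equivalences(bn)
        cbin = connect_clusters(clusters, bn)
        assert len(clusters) == 2
        assert cbin.edges == []
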