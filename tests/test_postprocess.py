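"""Stouffer combination, enrichment, bicluster network, operon
inference, exports."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest
from scipy import stats

from mscm.model import (
    AnnotationTerm,
    Bicluster,
    BiclusterSide,
    Motif,
    MotifHit,
    OrthologPair,
)
from mscm.postprocess import (
    BiclusterNetwork,
    RelatedThresholds,
    annotation_enrichment,
    export_bicluster_network,
    export_gene_network,
    infer_operons,
    related_biclusters,
    stouffer_bicluster_score,
)


class TestStouffer:
    def test_four_equal_unit_components(self):
        p = float(stats.norm.sf(1.0))
        assert stouffer_bicluster_score([p, p, p, p]) == pytest.approx(2.0, abs=1e-9)

    def test_half_p_is_zero(self):
        assert stouffer_bicluster_score([0.5]) == pytest.approx(0.0, abs=1e-12)

    def test_two_p05_components(self):
        z = stouffer_bicluster_score([0.05, 0.05])
        assert z == pytest.approx((1.6449 + 1.6449) / math.sqrt(2), abs=1e-3)
        assert z == pytest.approx(2.3262, abs=1e-3)

    def test_out_of_range_p_errors(self):
        for bad in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                stouffer_bicluster_score([bad])
        with pytest.raises(ValueError):
            stouffer_bicluster_score([])

    def test_permutation_invariance(self):
        ps = [0.01, 0.2, 0.77, 0.4]
        base = stouffer_bicluster_score(ps)
        for perm in itertools.permutations(ps):
            assert stouffer_bicluster_score(list(perm)) == pytest.approx(base)

    def test_adding_half_component_rescales_by_sqrt_k(self):
        ps = [0.02, 0.3, 0.1]
        z3 = stouffer_bicluster_score(ps)
        z4 = stouffer_bicluster_score(ps + [0.5])
        assert z4 == pytest.approx(z3 * math.sqrt(3) / math.sqrt(4), abs=1e-9)

    def test_none_components_are_skipped(self):
        assert stouffer_bicluster_score([0.05, None, 0.05]) == pytest.approx(
            stouffer_bicluster_score([0.05, 0.05])
        )

    def test_direction_flips_sign(self):
        z = stouffer_bicluster_score([(0.05, -1)])
        assert z == pytest.approx(-stouffer_bicluster_score([0.05]))


def brute_hypergeom_tail(N, K, n, k):
    return sum(
        math.comb(K, x) * math.comb(N - K, n - x) / math.comb(N, n)
        for x in range(k, min(K, n) + 1)
    )


class TestEnrichment:
    def _ns(self, sets):
        return {
            t: AnnotationTerm(t, f"desc {t}", frozenset(genes), len(genes) >= 2)
            for t, genes in sets.items()
        }

    def test_disjoint_term_has_p_one(self):
        universe = [f"g{i}" for i in range(20)]
        ns = self._ns({"T": universe[10:14]})
        table, assigned = annotation_enrichment(universe[:5], ns, universe)
        assert table.loc[0, "p"] == pytest.approx(1.0)
        assert assigned == set()

    def test_perfect_overlap_is_inverse_binomial(self):
        universe = [f"g{i}" for i in range(100)]
        term_genes = universe[:10]
        ns = self._ns({"T": term_genes})
        table, assigned = annotation_enrichment(term_genes, ns, universe)
        assert table.loc[0, "p"] == pytest.approx(1 / math.comb(100, 10), rel=1e-9)
        assert assigned == {"T"}

    def test_matches_enumeration_small_universe(self):
        rng = np.random.default_rng(0)
        universe = [f"g{i}" for i in range(40)]
        sets = {
            f"T{t}": rng.choice(universe, size=int(rng.integers(2, 12)), replace=False)
            for t in range(6)
        }
        ns = self._ns({t: set(v) for t, v in sets.items()})
        members = set(rng.choice(universe, size=8, replace=False))
        table, _ = annotation_enrichment(members, ns, universe)
        for row in table.itertuples():
            K = len(ns[row.term].genes)
            k = len(ns[row.term].genes & members)
            assert row.p == pytest.approx(brute_hypergeom_tail(40, K, 8, k), abs=1e-6)

    def test_untestable_terms_excluded(self):
        universe = [f"g{i}" for i in range(10)]
        ns = self._ns({"small": {"g1"}})
        table, _ = annotation_enrichment(["g1"], ns, universe)
        assert len(table) == 0

    def test_monotone_in_overlap(self):
        universe = [f"g{i}" for i in range(30)]
        ns = self._ns({"T": universe[:8]})
        previous = 1.1
        members = ["g20", "g21", "g22"]
        for extra in universe[:5]:
            members = members + [extra]
            table, _ = annotation_enrichment(members, ns, universe)
            # adding a term-member gene never increases p
            assert table.loc[0, "p"] <= previous + 1e-12
            previous = table.loc[0, "p"]

    def test_table_sorted_and_q_reported(self):
        universe = [f"g{i}" for i in range(50)]
        ns = self._ns({"A": universe[:10], "B": universe[10:14], "C": universe[30:40]})
        table, _ = annotation_enrichment(universe[:10], ns, universe)
        assert list(table["p"]) == sorted(table["p"])
        assert "q" in table.columns
        assert (table["q"] >= table["p"] - 1e-12).all()


def _bc(bid, genes_a, genes_b=None, motifs_a=(), assigned=None, conds=("c0", "c1")):
    sides = {"A": BiclusterSide(list(genes_a), [], list(conds), list(motifs_a),
                                {"residual": 0.1})}
    if genes_b is not None:
        sides["B"] = BiclusterSide(list(genes_b), [], ["d0", "d1"], [], {"residual": 0.2})
    return Bicluster(bicluster_id=bid, sides=sides)


class TestRelatedBiclusters:
    def test_no_self_edges_and_symmetry(self):
        b1 = _bc(1, ["g1", "g2", "g3"])
        b2 = _bc(2, ["g2", "g3", "g4"])
        net = related_biclusters([b1, b2])
        assert not any(u == v for u, v, _ in net.graph.edges(keys=True))
        net2 = related_biclusters([b2, b1])
        assert set(map(frozenset, ((u, v) for u, v, _ in net.graph.edges(keys=True)))) == set(
            map(frozenset, ((u, v) for u, v, _ in net2.graph.edges(keys=True)))
        )

    def test_gene_overlap_edge_weight(self):
        genes1 = [f"g{i}" for i in range(20)]
        genes2 = genes1[:5] + [f"h{i}" for i in range(20)]
        b1, b2 = _bc(1, genes1), _bc(2, genes2)
        net = related_biclusters([b1, b2], thresholds=RelatedThresholds(min_jaccard=0.1))
        data = net.graph.get_edge_data(1, 2)
        assert "gene-overlap" in data
        assert data["gene-overlap"]["weight"] == pytest.approx(5 / 40)

    def test_disjoint_everything_gives_no_edge(self):
        b1 = _bc(1, ["g1", "g2"])
        b2 = _bc(2, ["h1", "h2"])
        net = related_biclusters([b1, b2])
        assert net.graph.number_of_edges() == 0

    def test_shared_assigned_term_edge(self):
        b1, b2 = _bc(1, ["g1", "g2"]), _bc(2, ["h1", "h2"])
        assignments = {1: {"GO": {"GO:x"}}, 2: {"GO": {"GO:x", "GO:y"}}}
        net = related_biclusters([b1, b2], assignments=assignments)
        assert "shared-GO" in net.graph.get_edge_data(1, 2)

    def test_motif_similarity_edge(self):
        rng = np.random.default_rng(0)
        pwm = rng.dirichlet(np.ones(4) * 0.1, size=8)
        m = Motif(1, pwm)
        b1 = _bc(1, ["g1", "g2"], motifs_a=[m])
        b2 = _bc(2, ["h1", "h2"], motifs_a=[Motif(2, pwm.copy())])
        net = related_biclusters([b1, b2])
        data = net.graph.get_edge_data(1, 2)
        assert data["motif-similarity"]["weight"] == pytest.approx(1.0)

    def test_node_size_attributes(self):
        b = _bc(1, ["g1", "g2", "g3"], genes_b=["h1", "h2"])
        net = related_biclusters([b])
        node = net.graph.nodes[1]
        assert node["width_attr"] == 5   # genes across both species
        assert node["height_attr"] == 4  # conditions across both species


class TestOperons:
    def _motif(self, mid, hits):
        return Motif(mid, np.full((6, 4), 0.25),
                     hits={g: MotifHit(s, st, lp) for g, (s, st, lp) in hits.items()})

    def test_identical_patterns_group(self):
        strong = math.log(1e-6)
        m1 = self._motif(1, {"g1": (10, "+", strong), "g2": (12, "+", strong)})
        m2 = self._motif(2, {"g1": (40, "-", strong), "g2": (41, "-", strong)})
        groups = infer_operons([m1, m2], ["g1", "g2"], tolerance_nt=5)
        assert {"g1", "g2"} in groups

    def test_different_motif_sets_do_not_group(self):
        """A promoter showing motifs {1, 3} does not group with one
        showing all three motifs."""
        strong = math.log(1e-6)
        m1 = self._motif(1, {"g1": (10, "+", strong), "g2": (10, "+", strong)})
        m2 = self._motif(2, {"g2": (30, "+", strong)})
        m3 = self._motif(3, {"g1": (50, "+", strong), "g2": (50, "+", strong)})
        groups = infer_operons([m1, m2, m3], ["g1", "g2"], tolerance_nt=5)
        assert {"g1"} in groups and {"g2"} in groups

    def test_tolerance_boundary(self):
        strong = math.log(1e-6)
        tol = 5
        # aligned on motif 1; motif 2 offset differs by tol -> group
        m1 = self._motif(1, {"g1": (0, "+", strong), "g2": (100, "+", strong)})
        m2 = self._motif(2, {"g1": (20, "+", strong), "g2": (120 + tol, "+", strong)})
        groups = infer_operons([m1, m2], ["g1", "g2"], tolerance_nt=tol)
        assert {"g1", "g2"} in groups
        # offset differing by tol + 1 -> separate
        m2b = self._motif(2, {"g1": (20, "+", strong), "g2": (120 + tol + 1, "+", strong)})
        groups = infer_operons([m1, m2b], ["g1", "g2"], tolerance_nt=tol)
        assert {"g1"} in groups and {"g2"} in groups

    def test_strand_mismatch_separates(self):
        strong = math.log(1e-6)
        m1 = self._motif(1, {"g1": (10, "+", strong), "g2": (10, "-", strong)})
        groups = infer_operons([m1], ["g1", "g2"], tolerance_nt=5)
        assert {"g1"} in groups and {"g2"} in groups

    def test_no_hits_are_singletons(self):
        groups = infer_operons([], ["g1", "g2", "g3"])
        assert sorted(map(sorted, groups)) == [["g1"], ["g2"], ["g3"]]


class TestExports:
    def test_empty_network_is_valid_graphml(self, tmp_path):
        files = export_bicluster_network(BiclusterNetwork(), tmp_path / "net")
        g = nx.read_graphml(files[0])
        assert g.number_of_nodes() == 0

    def test_round_trip_attributes(self, tmp_path):
        net = BiclusterNetwork()
        net.graph.add_node(1, width_attr=5, height_attr=3, residual=0.1)
        net.graph.add_node(2, width_attr=7, height_attr=4, residual=0.2)
        net.graph.add_edge(1, 2, key="gene-overlap", edge_type="gene-overlap", weight=0.5)
        files = export_bicluster_network(net, tmp_path / "net")
        g = nx.read_graphml(files[0])
        assert g.number_of_edges() == 1
        assert g.nodes["1"]["width_attr"] == 5
        sif = (tmp_path / "net.sif").read_text().strip().splitlines()
        assert sif == ["1\tgene-overlap\t2"]

    def test_induced_subgraph_edge_count(self, tmp_path):
        g = nx.Graph()
        for u, v in itertools.combinations(range(4), 2):
            g.add_edge(f"g{u}", f"g{v}", types={"operon"})
        from mscm.model import SpeciesDataset
        import pandas as pd

        ds = SpeciesDataset(
            species_id="s",
            expression=pd.DataFrame(np.zeros((4, 2)),
                                    index=[f"g{i}" for i in range(4)], columns=["c0", "c1"]),
            network=g,
        )
        files = export_gene_network(ds, ["g0", "g1", "g2"], tmp_path / "genes")
        sif_lines = (tmp_path / "genes.sif").read_text().strip().splitlines()
        assert len(sif_lines) == 3  # 3 of the clique's 6 edges
        gm = nx.read_graphml(files[0])
        assert gm.number_of_edges() == 3
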