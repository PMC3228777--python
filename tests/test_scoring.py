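"""Evidence-score properties: residual formula, network cohesion,
motif components, membership standardization."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from mscm.model import Motif, MotifHit, OrthologPair
from mscm.scoring import (
    ScoreWeights,
    SpeciesContext,
    SpeciesState,
    bicluster_motif_mean,
    candidate_condition_score,
    expression_residual,
    gene_membership_score,
    loo_col_residuals,
    loo_row_residuals,
    member_condition_scores,
    member_gene_scores,
    motif_component_score,
    multispecies_pair_score,
    network_cohesion_score,
    residual_matrix,
)


def brute_residual(X):
    """Independent direct implementation of the residual formula."""
    X = np.asarray(X, float)
    cells = [(i, j) for i in range(X.shape[0]) for j in range(X.shape[1])
             if np.isfinite(X[i, j])]
    if not cells:
        return float("inf")
    def row_mean(i):
        vals = [X[i, j] for j in range(X.shape[1]) if np.isfinite(X[i, j])]
        return sum(vals) / len(vals)
    def col_mean(j):
        vals = [X[i, j] for i in range(X.shape[0]) if np.isfinite(X[i, j])]
        return sum(vals) / len(vals)
    grand = sum(X[i, j] for i, j in cells) / len(cells)
    num = sum(abs(X[i, j] - row_mean(i) - col_mean(j) + grand) for i, j in cells) / len(cells)
    vals = [X[i, j] for i, j in cells]
    return num / max(max(vals) - min(vals), 1e-12)


class TestResidual:
    def test_additive_matrix_is_zero(self):
        r = np.array([0.3, -1.2, 4.0])
        c = np.array([2.0, 0.0, -5.0, 1.1])
        X = r[:, None] + c[None, :]
        assert residual_matrix(X) == pytest.approx(0.0, abs=1e-12)

    def test_single_gene_or_condition_is_zero(self):
        assert residual_matrix(np.array([[1.0, 5.0, -2.0]])) == pytest.approx(0.0, abs=1e-12)
        assert residual_matrix(np.array([[1.0], [5.0], [-2.0]])) == pytest.approx(0.0, abs=1e-12)

    def test_3x3_integer_matrix_matches_brute_force(self):
        X = np.array([[1, 2, 3], [2, 3, 4], [4, 3, 2]], dtype=float)
        assert residual_matrix(X) == pytest.approx(brute_residual(X), abs=1e-12)

    def test_all_missing_is_infinite(self):
        assert residual_matrix(np.full((3, 3), np.nan)) == float("inf")

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_matches_brute_force_with_missing_values(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(rng.integers(2, 6), rng.integers(2, 6)))
        X[rng.random(X.shape) < 0.25] = np.nan
        assert residual_matrix(X) == pytest.approx(brute_residual(X), abs=1e-9)

    @given(st.floats(0.1, 10.0), st.floats(-5.0, 5.0), st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_affine_invariance(self, a, b, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(4, 5))
        assert residual_matrix(a * X + b) == pytest.approx(residual_matrix(X), rel=1e-9)

    def test_loo_matches_explicit_deletion(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(6, 8))
        X[0, 3] = np.nan
        expect_rows = [residual_matrix(np.delete(X, i, 0)) for i in range(6)]
        expect_cols = [residual_matrix(np.delete(X, j, 1)) for j in range(8)]
        assert np.allclose(loo_row_residuals(X), expect_rows)
        assert np.allclose(loo_col_residuals(X), expect_cols)

    def test_dataframe_wrapper(self, tiny_dataset):
        genes = list(tiny_dataset.expression.index[:3])
        conds = list(tiny_dataset.expression.columns[:2])
        sub = tiny_dataset.expression.loc[genes, conds].to_numpy()
        assert expression_residual(tiny_dataset.expression, genes, conds) == pytest.approx(
            brute_residual(sub)
        )


def brute_cohesion(network, genes):
    """Exhaustive hypergeometric tail: P(X >= k) by summing the pmf."""
    N = network.number_of_nodes()
    M = network.number_of_edges()
    genes = [g for g in set(genes) if g in network]
    k = nx.induced_subgraph(network, genes).number_of_edges()
    total = N * (N - 1) // 2
    draws = len(set(genes)) * (len(set(genes)) - 1) // 2
    p = sum(
        math.comb(M, x) * math.comb(total - M, draws - x) / math.comb(total, draws)
        for x in range(k, min(M, draws) + 1)
    )
    return min(-math.log10(max(p, 1e-300)), 300.0)


class TestNetworkCohesion:
    def test_no_edges_scores_zero(self):
        g = nx.Graph()
        g.add_nodes_from(range(10))
        g.add_edge(0, 1)
        assert network_cohesion_score(g, [5, 6, 7]) == 0.0

    def test_single_gene_scores_zero(self):
        g = nx.complete_graph(5)
        assert network_cohesion_score(g, [0]) == 0.0

    def test_clique_matches_brute_force_tail(self):
        rng = np.random.default_rng(2)
        g = nx.Graph()
        g.add_nodes_from(range(12))
        for a in range(4):
            for b in range(a + 1, 4):
                g.add_edge(a, b)
        extra = 0
        while extra < 5:
            u, v = rng.integers(0, 12, size=2)
            if u != v and not g.has_edge(u, v):
                g.add_edge(u, v)
                extra += 1
        score = network_cohesion_score(g, [0, 1, 2, 3])
        assert score == pytest.approx(brute_cohesion(g, [0, 1, 2, 3]), abs=1e-6)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_matches_enumeration_on_small_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 12))
        g = nx.gnp_random_graph(n, 0.3, seed=int(rng.integers(2**31)))
        genes = list(rng.choice(n, size=int(rng.integers(2, min(6, n))), replace=False))
        assert network_cohesion_score(g, genes) == pytest.approx(
            brute_cohesion(g, genes), abs=1e-6
        )

    def test_adding_internal_edge_never_decreases_score(self):
        g = nx.gnp_random_graph(20, 0.1, seed=3)
        genes = [0, 1, 2, 3, 4]
        before = network_cohesion_score(g, genes)
        pair = next(
            (u, v) for u in genes for v in genes if u < v and not g.has_edge(u, v)
        )
        g.add_edge(*pair)
        assert network_cohesion_score(g, genes) >= before


class TestMotifComponents:
    def _motifs(self):
        pwm = np.full((6, 4), 0.25)
        m1 = Motif(1, pwm, hits={"g1": MotifHit(0, "+", math.log(0.01))})
        m2 = Motif(2, pwm, hits={"g1": MotifHit(5, "-", math.log(0.1))})
        return [m1, m2]

    def test_no_motifs_scores_zero(self):
        assert motif_component_score([], "g1") == 0.0
        assert bicluster_motif_mean([], ["g1", "g2"]) == 0.0

    def test_single_motif_is_the_log_p(self):
        assert motif_component_score(self._motifs()[:1], "g1") == pytest.approx(math.log(0.01))

    def test_two_motifs_mean_of_logs(self):
        expect = (math.log(0.01) + math.log(0.1)) / 2
        assert motif_component_score(self._motifs(), "g1") == pytest.approx(expect)

    def test_missing_promoter_contributes_zero(self):
        assert motif_component_score(self._motifs(), "gX") == 0.0
        expect = ((math.log(0.01) + math.log(0.1)) / 2 + 0.0) / 2
        assert bicluster_motif_mean(self._motifs(), ["g1", "gX"]) == pytest.approx(expect)


@pytest.fixture(scope="module")
def ctx_pair(default_pair):
    ds_a, ds_b, fams, truth = default_pair
    return (
        SpeciesContext(ds_a, seed=11, n_draws=200),
        SpeciesContext(ds_b, seed=12, n_draws=200),
        truth,
    )


class TestMembership:
    def test_weight_degeneracy_reduces_to_expression(self, ctx_pair):
        ctx_a, _, truth = ctx_pair
        m = truth.modules[0]
        genes = [p[0] for p in m.pairs]
        state = SpeciesState(ctx_a, genes, list(m.conditions_a))
        w_only = ScoreWeights(w_expr=1.0, w_motif=0.0, w_net=0.0)
        w_net0 = ScoreWeights(w_expr=1.0, w_motif=0.5, w_net=0.0)
        # no motifs attached: motif channel is 0 and the two must agree
        assert member_gene_scores(state, w_only) == pytest.approx(
            member_gene_scores(state, w_net0)
        )

    def test_planted_gene_outscores_random_gene(self, ctx_pair):
        ctx_a, _, truth = ctx_pair
        m = truth.modules[0]
        genes = [p[0] for p in m.pairs]
        state = SpeciesState(ctx_a, genes[:-1], list(m.conditions_a))
        w = ScoreWeights()
        planted = gene_membership_score(genes[-1], state, w)
        random_gene = ctx_a.genes[-1]  # family-less background gene
        assert planted > gene_membership_score(random_gene, state, w)

    def test_score_is_pure(self, ctx_pair):
        ctx_a, _, truth = ctx_pair
        m = truth.modules[0]
        state = SpeciesState(ctx_a, [p[0] for p in m.pairs], list(m.conditions_a))
        w = ScoreWeights()
        gene = ctx_a.genes[100]
        assert gene_membership_score(gene, state, w) == gene_membership_score(gene, state, w)

    def test_unknown_gene_scores_zero_with_warning(self, ctx_pair):
        ctx_a, _, truth = ctx_pair
        state = SpeciesState(ctx_a, ctx_a.genes[:5], ctx_a.conditions[:5])
        with pytest.warns(UserWarning):
            assert gene_membership_score("no_such_gene", state, ScoreWeights()) == 0.0

    def test_pair_score_rules_and_symmetry(self, ctx_pair):
        ctx_a, ctx_b, truth = ctx_pair
        m = truth.modules[0]
        state_a = SpeciesState(ctx_a, [p[0] for p in m.pairs], list(m.conditions_a))
        state_b = SpeciesState(ctx_b, [p[1] for p in m.pairs], list(m.conditions_b))
        ga, gb = m.pairs[0]
        pair = OrthologPair("f", ga, gb)
        w = ScoreWeights()
        sa = gene_membership_score(ga, state_a, w)
        sb = gene_membership_score(gb, state_b, w)
        assert multispecies_pair_score(pair, state_a, state_b, w) == pytest.approx(sa + sb)
        assert multispecies_pair_score(pair, state_a, state_b, w, rule="min") == pytest.approx(
            min(sa, sb)
        )
        swapped = OrthologPair("f", gb, ga)
        assert multispecies_pair_score(swapped, state_b, state_a, w) == pytest.approx(
            multispecies_pair_score(pair, state_a, state_b, w)
        )
        with pytest.raises(ValueError):
            multispecies_pair_score(pair, state_a, state_b, w, rule="median")


class TestNullCalibration:
    def test_channel_z_mean_zero_sd_one_over_null(self, default_pair):
        """Standardizing fresh null draws with the stored grid statistics
        must give mean ~ 0 and sd ~ 1 at 1000 draws."""
        ds_a, *_ = default_pair
        ctx = SpeciesContext(ds_a, seed=99, n_draws=1000)
        rng = np.random.default_rng(1234)
        n, c = ctx.X.shape
        k = int(ctx.nulls.gene_sizes[2])
        kc = int(ctx.nulls.cond_sizes[3])
        em, es = ctx.nulls.expr_stats(k, kc)
        nm, ns = ctx.nulls.net_stats(k)
        from mscm.scoring import profile_misfit

        z_expr, z_net = [], []
        for _ in range(1000):
            rows = rng.choice(n, size=k + 1, replace=False)
            cols = rng.choice(c, size=kc, replace=False)
            raw = -float(profile_misfit(ctx.X, rows[:k], cols, rows[-1:])[0])
            z_expr.append((raw - em) / es)
            z_net.append((ctx.A[rows[-1], rows[:k]].sum() / k - nm) / ns)
        for z in (np.asarray(z_expr), np.asarray(z_net)):
            assert abs(z.mean()) < 0.1
            assert abs(z.std() - 1.0) < 0.15
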