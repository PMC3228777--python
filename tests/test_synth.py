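"""Synthetic-data generator: determinism, planted structure, recovery
scoring arithmetic."""

import numpy as np
import pytest

from mscm.model import Bicluster, BiclusterSide, OrthologPair
from mscm.scoring import residual_matrix
from mscm.synth import (
    GenParams,
    PlantedTruth,
    consensus_identity,
    generate_pair_dataset,
    read_pair_dataset,
    score_recovery,
    write_pair_dataset,
)


class TestGenerator:
    def test_same_seed_identical_datasets(self):
        p = GenParams(n_genes_a=60, n_genes_b=60, n_conditions_a=12, n_conditions_b=12,
                      n_modules=1, module_size=5, n_elab_per_module=1, seed=5)
        a1, b1, f1, t1 = generate_pair_dataset(p)
        a2, b2, f2, t2 = generate_pair_dataset(p)
        assert a1.expression.equals(a2.expression)
        assert b1.expression.equals(b2.expression)
        assert a1.promoters == a2.promoters
        assert set(a1.network.edges) == set(a2.network.edges)
        assert f1 == f2
        assert t1.to_dict() == t2.to_dict()

    def test_different_seed_differs(self):
        p1 = GenParams(n_genes_a=60, n_genes_b=60, n_conditions_a=12, n_conditions_b=12,
                       n_modules=1, module_size=5, n_elab_per_module=1, seed=5)
        p2 = GenParams(**{**p1.__dict__, "seed": 6})
        a1, *_ = generate_pair_dataset(p1)
        a2, *_ = generate_pair_dataset(p2)
        assert not a1.expression.equals(a2.expression)

    def test_zero_modules_gives_pure_noise(self):
        p = GenParams(n_genes_a=50, n_genes_b=50, n_conditions_a=10, n_conditions_b=10,
                      n_modules=0, module_size=5, n_elab_per_module=0, seed=2)
        ds_a, ds_b, fams, truth = generate_pair_dataset(p)
        assert truth.modules == []
        assert abs(ds_a.expression.to_numpy().mean()) < 0.1

    def test_infeasible_sizes_error_before_generation(self):
        with pytest.raises(ValueError, match="infeasible|exceeds"):
            generate_pair_dataset(GenParams(n_genes_a=20, n_genes_b=20,
                                            n_modules=5, module_size=10))
        with pytest.raises(ValueError, match="condition_fraction"):
            generate_pair_dataset(GenParams(condition_fraction=0.0))

    def test_planted_modules_shape_and_motif_instances(self, default_pair):
        """Each planted promoter carries a >= (1 - mutation_rate)-identity
        match to the consensus at the recorded position (string oracle)."""
        ds_a, ds_b, fams, truth = default_pair
        p = truth.params
        assert len(truth.modules) == p.n_modules
        promoters = {ds_a.species_id: ds_a.promoters, ds_b.species_id: ds_b.promoters}
        for module in truth.modules:
            assert len(module.pairs) == p.module_size
            identities = []
            for gene, (pos, instance) in module.motif_positions.items():
                sid = gene.split("_")[0]
                window = promoters[sid][gene][pos:pos + p.motif_width]
                assert window == instance
                identity = sum(a == b for a, b in zip(instance, module.motif_consensus))
                assert identity >= p.motif_width // 2  # loose per-instance floor
                identities.append(identity / p.motif_width)
            # mean identity tracks 1 - mutation_rate up to binomial noise
            assert np.mean(identities) >= 1 - p.motif_mutation_rate - 0.1

    def test_planted_pairs_are_in_emitted_families(self, default_pair):
        ds_a, ds_b, fams, truth = default_pair
        by_pair = set()
        for fam in fams:
            for a in fam.members_a:
                for b in fam.members_b:
                    by_pair.add((a, b))
        for module in truth.modules:
            for pair in module.pairs:
                assert pair in by_pair

    def test_elaboration_genes_have_no_family(self, default_pair):
        ds_a, ds_b, fams, truth = default_pair
        in_family = set()
        for fam in fams:
            in_family |= fam.members_a | fam.members_b
        for module in truth.modules:
            for g in module.elaborated_a + module.elaborated_b:
                assert g not in in_family

    def test_background_mean_shrinks_with_n(self):
        p = GenParams(n_genes_a=200, n_genes_b=200, n_conditions_a=40, n_conditions_b=40,
                      n_modules=0, module_size=5, n_elab_per_module=0, seed=9)
        ds_a, *_ = generate_pair_dataset(p)
        X = ds_a.expression.to_numpy()
        n = X.size
        assert abs(X.mean()) < 4 * p.noise_sigma / np.sqrt(n)

    def test_planted_residual_below_random_submatrices(self, default_pair):
        ds_a, _, _, truth = default_pair
        X = ds_a.expression.to_numpy()
        m = truth.modules[0]
        rows = [ds_a.expression.index.get_loc(p[0]) for p in m.pairs]
        cols = [ds_a.expression.columns.get_loc(c) for c in m.conditions_a]
        planted = residual_matrix(X[np.ix_(rows, cols)])
        rng = np.random.default_rng(0)
        draws = [
            residual_matrix(X[np.ix_(rng.choice(X.shape[0], len(rows), replace=False),
                                     rng.choice(X.shape[1], len(cols), replace=False))])
            for _ in range(100)
        ]
        assert planted < np.mean(draws)

    def test_bundle_round_trip(self, tmp_path, small_pair):
        ds_a, ds_b, fams, truth = small_pair
        write_pair_dataset(ds_a, ds_b, fams, truth, tmp_path / "bundle")
        ra, rb, rf, rt = read_pair_dataset(tmp_path / "bundle")
        assert ra.expression.round(10).equals(ds_a.expression.round(10))
        assert ra.promoters == ds_a.promoters
        assert {frozenset(e) for e in ra.network.edges} == {
            frozenset(e) for e in ds_a.network.edges
        }
        assert sorted(f.family_id for f in rf) == sorted(f.family_id for f in fams)
        assert rt.to_dict() == truth.to_dict()


def _bc(bid, pairs, sid_a="spA", sid_b="spB"):
    return Bicluster(
        bicluster_id=bid,
        sides={
            sid_a: BiclusterSide([a for a, _ in pairs], [], ["c0", "c1"]),
            sid_b: BiclusterSide([b for _, b in pairs], [], ["d0", "d1"]),
        },
        core_pairs=[OrthologPair(f"f{i}", a, b) for i, (a, b) in enumerate(pairs)],
    )


class TestScoreRecovery:
    def _truth(self, pair_lists):
        from mscm.synth import PlantedModule

        modules = [
            PlantedModule(module_id=i, pairs=pairs, conditions_a=["c0"],
                          conditions_b=["d0"], motif_consensus="ACGTACGT",
                          elaborated_a=[], elaborated_b=[])
            for i, pairs in enumerate(pair_lists)
        ]
        return PlantedTruth(modules=modules, params=GenParams())

    def test_exact_prediction_scores_one(self):
        pairs = [(f"spA_g{i:04d}", f"spB_g{i:04d}") for i in range(5)]
        truth = self._truth([pairs])
        out = score_recovery([_bc(1, pairs)], truth, 0.5)
        assert out["recovery_fraction"] == 1.0
        assert out["per_module"][0]["best_jaccard"] == 1.0

    def test_empty_prediction_scores_zero(self):
        truth = self._truth([[("spA_g0000", "spB_g0000")]])
        assert score_recovery([], truth, 0.5)["recovery_fraction"] == 0.0

    def test_partial_overlap_jaccard_arithmetic(self):
        """10 shared of 15 planted plus 2 extras: Jaccard = 10 / 17."""
        planted = [(f"spA_g{i:04d}", f"spB_g{i:04d}") for i in range(15)]
        predicted = planted[:10] + [(f"spA_g{90 + i:04d}", f"spB_g{90 + i:04d}") for i in range(2)]
        truth = self._truth([planted])
        out = score_recovery([_bc(1, predicted)], truth, 0.5)
        assert out["per_module"][0]["best_jaccard"] == pytest.approx(10 / 17)

    def test_species_mismatch_errors(self):
        truth = self._truth([[("spA_g0000", "spB_g0000")]])
        bad = _bc(1, [("x", "y")], sid_a="other", sid_b="spB")
        with pytest.raises(ValueError, match="species mismatch"):
            score_recovery([bad], truth, 0.5)


class TestConsensusIdentity:
    def test_exact_and_revcomp(self):
        assert consensus_identity("TTGATACG", "TTGATACG") == 1.0
        assert consensus_identity("CGTATCAA", "TTGATACG") == 1.0  # reverse complement

    def test_shifted_window(self):
        assert consensus_identity("ATTGATAC", "TTGATACG") >= 7 / 8

    def test_unrelated_is_low(self):
        assert consensus_identity("AAAAAAAA", "CCCCCCCC") <= 0.25
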