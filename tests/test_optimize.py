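"""Optimizer mechanics: acceptance rule, schedules, constraints,
determinism, elaboration's static core, species-specific mode."""

import numpy as np
import pytest

from mscm.model import OrthologPair
from mscm.optimize import (
    AnnealSchedule,
    DetectParams,
    ElaborateParams,
    MotifSearchParams,
    SpecificParams,
    detect_conserved_biclusters,
    elaborate_bicluster,
    metropolis_accept,
    random_bicluster_scores,
    species_specific_biclusters,
)
from mscm.scoring import SpeciesContext

FAST_MOTIFS = MotifSearchParams(n_motifs=1, width_range=(8, 8), n_restarts=1, max_sweeps=50)


def fast_params(**kw):
    defaults = dict(
        n_biclusters=3, init_size=6, iterations=1500, seed=5,
        motif_search=FAST_MOTIFS, motif_refresh_every=100, null_draws=150,
    )
    defaults.update(kw)
    return DetectParams(**defaults)


@pytest.fixture(scope="module")
def small_ctx(small_pair):
    ds_a, ds_b, fams, truth = small_pair
    return (SpeciesContext(ds_a, seed=31, n_draws=150),
            SpeciesContext(ds_b, seed=32, n_draws=150))


class TestAcceptanceRule:
    def test_improving_moves_always_accepted(self):
        rng = np.random.default_rng(0)
        assert all(metropolis_accept(d, 1e-9, rng) for d in (0.0, 0.1, 5.0))

    def test_zero_temperature_rejects_all_worsening(self):
        """As T -> 0+ only score-improving moves pass."""
        rng = np.random.default_rng(0)
        assert not any(metropolis_accept(-1e-6, 1e-12, rng) for _ in range(100))

    def test_acceptance_frequency_tracks_boltzmann(self):
        rng = np.random.default_rng(1)
        delta, temp = -1.0, 2.0
        freq = np.mean([metropolis_accept(delta, temp, rng) for _ in range(4000)])
        assert freq == pytest.approx(np.exp(delta / temp), abs=0.03)


class TestAnnealSchedule:
    def test_geometric_cooling_endpoints(self):
        s = AnnealSchedule(t_start=10.0, t_end=0.1, n_iterations=101)
        assert s.temperature(0) == pytest.approx(10.0)
        assert s.temperature(100) == pytest.approx(0.1)
        temps = [s.temperature(i) for i in range(101)]
        assert all(a >= b for a, b in zip(temps, temps[1:]))

    def test_invalid_schedule_rejected(self):
        with pytest.raises(ValueError):
            AnnealSchedule(t_start=1.0, t_end=2.0, n_iterations=10)
        with pytest.raises(ValueError):
            AnnealSchedule(t_start=1.0, t_end=0.1, n_iterations=0)


class TestDetect:
    def test_too_many_biclusters_rejected(self, small_pair):
        ds_a, ds_b, fams, _ = small_pair
        with pytest.raises(ValueError, match="exceeds"):
            detect_conserved_biclusters(ds_a, ds_b, fams,
                                        fast_params(n_biclusters=len(fams)))

    def test_determinism(self, small_pair, small_ctx):
        ds_a, ds_b, fams, _ = small_pair
        runs = [
            detect_conserved_biclusters(ds_a, ds_b, fams, fast_params(),
                                        contexts=small_ctx)
            for _ in range(2)
        ]
        for b1, b2 in zip(*runs):
            assert b1.core_pairs == b2.core_pairs
            for sid in b1.sides:
                assert b1.sides[sid].conditions == b2.sides[sid].conditions
            assert b1.combined_score == b2.combined_score

    def test_structural_invariants_after_step2(self, small_pair, small_ctx):
        ds_a, ds_b, fams, _ = small_pair
        params = fast_params()
        biclusters = detect_conserved_biclusters(ds_a, ds_b, fams, params,
                                                 contexts=small_ctx)
        core_counts_a, core_counts_b = {}, {}
        for bc in biclusters:
            bc.validate(paired=True)
            assert len(bc.core_pairs) >= 3
            for sid in bc.sides:
                assert len(bc.sides[sid].conditions) >= 2
            for p in bc.core_pairs:
                core_counts_a[p.gene_a] = core_counts_a.get(p.gene_a, 0) + 1
                core_counts_b[p.gene_b] = core_counts_b.get(p.gene_b, 0) + 1
        assert max(core_counts_a.values()) <= params.redundancy_cap
        assert max(core_counts_b.values()) <= params.redundancy_cap

    def test_energy_trace_improves(self, small_pair, small_ctx):
        """Mean total score over the final tenth of the run is above the
        initial tenth (annealing heads downhill in energy)."""
        ds_a, ds_b, fams, _ = small_pair
        trace = []
        detect_conserved_biclusters(ds_a, ds_b, fams, fast_params(iterations=2000),
                                    contexts=small_ctx, trace=trace)
        scores = [s for _, s in trace]
        k = max(1, len(scores) // 10)
        assert np.mean(scores[-k:]) >= np.mean(scores[:k])


@pytest.fixture(scope="module")
def detected(small_pair, small_ctx):
    ds_a, ds_b, fams, _ = small_pair
    return detect_conserved_biclusters(ds_a, ds_b, fams, fast_params(),
                                       contexts=small_ctx)


class TestElaborate:
    def test_core_is_static(self, small_pair, small_ctx, detected):
        ds_a, ds_b, *_ = small_pair
        ctx_a, _ = small_ctx
        for bc in detected:
            before = list(bc.side(ds_a.species_id).core_genes)
            out = elaborate_bicluster(bc, ds_a, ds_a.species_id,
                                      ElaborateParams(iterations=600, seed=3), ctx=ctx_a)
            assert out.side(ds_a.species_id).core_genes == before
            assert not set(out.side(ds_a.species_id).elaborated_genes) & set(before)

    def test_conditions_frozen_by_default(self, small_pair, small_ctx, detected):
        ds_a, *_ = small_pair
        ctx_a, _ = small_ctx
        bc = detected[0]
        out = elaborate_bicluster(bc, ds_a, ds_a.species_id,
                                  ElaborateParams(iterations=600, seed=3), ctx=ctx_a)
        assert out.side(ds_a.species_id).conditions == bc.side(ds_a.species_id).conditions

    def test_empty_core_rejected(self, small_pair, detected):
        ds_a, *_ = small_pair
        bc = detected[0]
        bad = type(bc)(bicluster_id=99,
                       sides={ds_a.species_id: type(bc.side(ds_a.species_id))(
                           core_genes=[], conditions=["x"])},
                       core_pairs=[])
        with pytest.raises(ValueError, match="empty core"):
            elaborate_bicluster(bad, ds_a, ds_a.species_id, ElaborateParams(iterations=10))


class TestSpeciesSpecific:
    def test_all_excluded_gives_empty_with_warning(self, small_pair):
        ds_a, *_ = small_pair
        with pytest.warns(UserWarning, match="excluded"):
            out = species_specific_biclusters(ds_a, set(ds_a.gene_universe),
                                              SpecificParams(iterations=10))
        assert out == []

    def test_never_contains_excluded_genes(self, small_pair, small_ctx):
        ds_a, *_ = small_pair
        ctx_a, _ = small_ctx
        exclusions = set(list(ds_a.gene_universe)[:40])
        out = species_specific_biclusters(
            ds_a, exclusions,
            SpecificParams(n_biclusters=2, iterations=800, seed=4), ctx=ctx_a)
        assert out
        for bc in out:
            genes = set(bc.side(ds_a.species_id).core_genes)
            assert not genes & exclusions

    def test_recovers_single_species_module(self):
        """A clearly separable module available to one species' data only
        (no families supplied) is found by the single-species optimizer."""
        from mscm.synth import GenParams, generate_pair_dataset

        ds_a, _, fams, truth = generate_pair_dataset(GenParams(
            n_genes_a=100, n_genes_b=100, n_conditions_a=30, n_conditions_b=30,
            n_modules=1, module_size=12, signal_mu=3.0,
            n_elab_per_module=0, seed=77,
        ))
        module_genes = {a for a, _ in truth.modules[0].pairs}
        ctx = SpeciesContext(ds_a, seed=9, n_draws=150)
        out = species_specific_biclusters(
            ds_a, set(),
            SpecificParams(n_biclusters=3, seed_candidates=15, iterations=2500, seed=2),
            ctx=ctx)
        best = max(
            len(set(bc.side(ds_a.species_id).core_genes) & module_genes)
            / len(set(bc.side(ds_a.species_id).core_genes) | module_genes)
            for bc in out
        )
        assert best >= 0.5


class TestNullScores:
    def test_random_scores_reproducible(self, small_ctx):
        from mscm.scoring import ScoreWeights

        ctx_a, ctx_b = small_ctx
        s1 = random_bicluster_scores(ctx_a, ctx_b, 6, 10, 10, ScoreWeights(),
                                     n_draws=20, seed=3)
        s2 = random_bicluster_scores(ctx_a, ctx_b, 6, 10, 10, ScoreWeights(),
                                     n_draws=20, seed=3)
        assert np.array_equal(s1, s2)
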