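"""Simulated-annealing bicluster optimization.

Step 2 detects conserved biclusters over ortholog pairs by iterative
Monte Carlo optimization of the joint two-species score; step 3
elaborates each conserved bicluster per species with its core held
static; optional step 4 finds purely species-specific biclusters among
genes not yet used.

Moves are proposed uniformly over {add ortholog family (with lazy
data-driven pair selection), drop pair, add condition, drop condition
(each per species)} on a uniformly chosen bicluster and accepted with the
Metropolis rule min(1, exp(dScore / T)) under a geometric cooling
schedule.  The starting temperature defaults to the standard deviation of
the score change over random probe moves, so no per-dataset hand-tuning
is needed.  Motif re-discovery is amortized: motifs are refreshed every
``motif_refresh_every`` accepted membership changes and score deltas in
between use the stale motifs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from mscm.model import Bicluster, BiclusterSide, Motif, OrthologFamily, OrthologPair, SpeciesDataset
from mscm.motifs import find_motifs
from mscm.orthologs import build_family_index, choose_pair_for_family
from mscm.scoring import (
    ScoreWeights,
    SpeciesContext,
    SpeciesState,
    attach_motifs,
    bicluster_motif_mean,
    candidate_gene_score,
    expression_residual,
    member_condition_scores,
    member_gene_scores,
    network_cohesion_score,
)

MIN_PAIRS = 3
MIN_CONDITIONS = 2


@dataclass
class AnnealSchedule:
    """Geometric cooling from t_start to t_end over n_iterations."""

    t_start: float
    t_end: float
    n_iterations: int

    def __post_init__(self) -> None:
        if not (self.t_start >= self.t_end > 0):
            raise ValueError("need t_start >= t_end > 0")
        if self.n_iterations < 1:
            raise ValueError("need n_iterations >= 1")

    @property
    def cooling_factor(self) -> float:
        if self.n_iterations == 1:
            return 1.0
        return (self.t_end / self.t_start) ** (1.0 / (self.n_iterations - 1))

    def temperature(self, iteration: int) -> float:
        return self.t_start * self.cooling_factor ** iteration


@dataclass
class MotifSearchParams:
    """Motif-discovery settings used inside the optimizer loop (kept
    deliberately lighter than a final post-processing search)."""

    n_motifs: int = 1
    width_range: Tuple[int, int] = (6, 12)
    n_restarts: int = 2
    max_sweeps: int = 120


@dataclass
class DetectParams:
    n_biclusters: int = 6
    init_size: int = 8
    #: uniformly drawn candidate seed pairs per bicluster; the one whose
    #: correlation neighborhood is most co-expressed becomes the seed
    seed_candidates: int = 10
    iterations: int = 20000          # per bicluster-equivalent
    t_start: Optional[float] = None  # None: sd of 200 random probe moves
    t_end: Optional[float] = None    # None: t_start / 100
    weights: ScoreWeights = field(default_factory=ScoreWeights)
    redundancy_cap: int = 2
    motif_refresh_every: int = 50
    pair_rule: str = "sum"
    motif_search: MotifSearchParams = field(default_factory=MotifSearchParams)
    null_draws: int = 300      # random draws per null grid shape
    seed: int = 0


@dataclass
class ElaborateParams:
    iterations: int = 3000
    allow_condition_moves: bool = False
    t_start: Optional[float] = None
    t_end: Optional[float] = None
    weights: ScoreWeights = field(default_factory=ScoreWeights)
    seed: int = 0


def metropolis_accept(delta: float, temperature: float, rng: np.random.Generator) -> bool:
    """Accept with probability min(1, exp(delta / T))."""
    if delta >= 0:
        return True
    if temperature <= 0:
        return False
    arg = delta / temperature
    if arg < -700:
        return False
    return bool(rng.random() < math.exp(arg))


# ---------------------------------------------------------------------------
# internal work unit
# ---------------------------------------------------------------------------

class _Work:
    """Mutable state of one bicluster during optimization."""

    __slots__ = ("pairs", "state_a", "state_b", "motifs_a", "motifs_b",
                 "total", "accepted_changes")

    def __init__(self, pairs: List[OrthologPair], state_a: SpeciesState,
                 state_b: SpeciesState):
        self.pairs = pairs
        self.state_a = state_a
        self.state_b = state_b
        self.motifs_a: List[Motif] = []
        self.motifs_b: List[Motif] = []
        self.total = float("nan")
        self.accepted_changes = 0

    def sync_members(self) -> None:
        self.state_a.members = [p.gene_a for p in self.pairs]
        self.state_b.members = [p.gene_b for p in self.pairs]


def _work_total(work: _Work, weights: ScoreWeights, rule: str) -> float:
    sa = member_gene_scores(work.state_a, weights) - weights.gene_penalty
    sb = member_gene_scores(work.state_b, weights) - weights.gene_penalty
    genes_part = np.minimum(sa, sb).sum() if rule == "min" else sa.sum() + sb.sum()
    # condition terms are Stouffer-normalized per species (see
    # scoring.side_total_score)
    cond_part = 0.0
    for state in (work.state_a, work.state_b):
        terms = member_condition_scores(state, weights) - weights.cond_penalty
        cond_part += terms.sum() / math.sqrt(len(state.conditions))
    return float(genes_part + cond_part)


def _zscored_rows(ctx: SpeciesContext) -> np.ndarray:
    X = ctx.X
    mean = np.nanmean(X, axis=1, keepdims=True)
    sd = np.nanstd(X, axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    Z = (X - mean) / sd
    return np.nan_to_num(Z, nan=0.0)


def _seed_conditions(ctx: SpeciesContext, rows: np.ndarray) -> List[str]:
    """Half the conditions, those where the seed genes deviate most."""
    profile = np.abs(np.nanmean(ctx.X[rows], axis=0))
    profile = np.nan_to_num(profile, nan=0.0)
    n_take = max(MIN_CONDITIONS, len(ctx.conditions) // 2)
    order = np.argsort(-profile, kind="stable")[:n_take]
    return [ctx.conditions[j] for j in sorted(order)]


# ---------------------------------------------------------------------------
# step 2: conserved biclusters
# ---------------------------------------------------------------------------

def detect_conserved_biclusters(
    dataset_a: SpeciesDataset,
    dataset_b: SpeciesDataset,
    families: Sequence[OrthologFamily],
    params: Optional[DetectParams] = None,
    contexts: Optional[Tuple[SpeciesContext, SpeciesContext]] = None,
    trace: Optional[list] = None,
) -> List[Bicluster]:
    """Detect conserved biclusters (cores only); deterministic per seed.

    Raises ``ValueError`` when ``n_biclusters`` exceeds ``len(families) // 3``.
    If ``trace`` is a list, (iteration, mean total score) samples are
    appended to it during the run.
    """
    params = params or DetectParams()
    families = list(families)
    if not families:
        raise ValueError("orthologous core is empty")
    if params.n_biclusters > len(families) // 3:
        raise ValueError(
            f"n_biclusters={params.n_biclusters} exceeds families/3 = {len(families) // 3}"
        )
    ss = np.random.SeedSequence(params.seed)
    seed_ctx_a, seed_ctx_b, seed_main = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3))
    if contexts is not None:
        ctx_a, ctx_b = contexts
    else:
        ctx_a = SpeciesContext(dataset_a, seed=seed_ctx_a, n_draws=params.null_draws)
        ctx_b = SpeciesContext(dataset_b, seed=seed_ctx_b, n_draws=params.null_draws)
    rng = np.random.default_rng(seed_main)
    index = build_family_index(families, dataset_a, dataset_b)
    weights, rule = params.weights, params.pair_rule

    core_count_a: Dict[str, int] = {}
    core_count_b: Dict[str, int] = {}

    def _capped(gene: str, counts: Dict[str, int]) -> bool:
        return counts.get(gene, 0) >= params.redundancy_cap

    # ---- seeding ----------------------------------------------------------
    Za, Zb = _zscored_rows(ctx_a), _zscored_rows(ctx_b)
    n_cond_a, n_cond_b = len(ctx_a.conditions), len(ctx_b.conditions)
    works: List[_Work] = []
    seeded_fams: Set[str] = set()
    fam_ids_sorted = sorted(index.families)
    def _neighborhood(seed_fam: str, available: List[str]) -> Tuple[float, List[OrthologPair]]:
        """Seed pair + its init_size-1 nearest pairs by joint expression
        correlation; returns (mean neighbor correlation, pairs)."""
        sa, sb = index.candidate_pairs[seed_fam][0]
        if _capped(sa, core_count_a) or _capped(sb, core_count_b):
            return (float("-inf"), [])
        row_a, row_b = ctx_a.gene_index[sa], ctx_b.gene_index[sb]
        corr_a = Za @ Za[row_a] / n_cond_a
        corr_b = Zb @ Zb[row_b] / n_cond_b
        pairs = [OrthologPair(seed_fam, sa, sb)]
        used_a, used_b = {sa}, {sb}
        scored: List[Tuple[float, str, str, str]] = []
        for fid in available:
            if fid == seed_fam:
                continue
            best = None
            for a, b in index.candidate_pairs[fid]:
                if a in used_a or b in used_b or _capped(a, core_count_a) or _capped(b, core_count_b):
                    continue
                c = 0.5 * (corr_a[ctx_a.gene_index[a]] + corr_b[ctx_b.gene_index[b]])
                if best is None or c > best[0]:
                    best = (c, a, b)
            if best is not None:
                scored.append((best[0], fid, best[1], best[2]))
        scored.sort(key=lambda t: (-t[0], t[1]))
        kept = []
        for c, fid, a, b in scored[: params.init_size - 1]:
            if a in used_a or b in used_b:
                continue
            pairs.append(OrthologPair(fid, a, b, selection_score=float(c)))
            used_a.add(a)
            used_b.add(b)
            kept.append(c)
        quality = float(np.mean(kept)) if kept else float("-inf")
        return quality, pairs

    for _k in range(params.n_biclusters):
        available = [f for f in fam_ids_sorted if f not in seeded_fams]
        if not available:
            break
        # several uniformly drawn candidate seeds; keep the one whose
        # correlation neighborhood is most strongly co-expressed
        n_cand = min(params.seed_candidates, len(available))
        cand_idx = rng.choice(len(available), size=n_cand, replace=False)
        best_quality, pairs = float("-inf"), []
        for ci in cand_idx:
            quality, cand_pairs = _neighborhood(available[int(ci)], available)
            if quality > best_quality:
                best_quality, pairs = quality, cand_pairs
        if not pairs:
            break
        for p in pairs:
            seeded_fams.add(p.family_id)
            core_count_a[p.gene_a] = core_count_a.get(p.gene_a, 0) + 1
            core_count_b[p.gene_b] = core_count_b.get(p.gene_b, 0) + 1
        rows_a = ctx_a.rows([p.gene_a for p in pairs])
        rows_b = ctx_b.rows([p.gene_b for p in pairs])
        state_a = SpeciesState(ctx_a, [p.gene_a for p in pairs], _seed_conditions(ctx_a, rows_a))
        state_b = SpeciesState(ctx_b, [p.gene_b for p in pairs], _seed_conditions(ctx_b, rows_b))
        work = _Work(pairs, state_a, state_b)
        work.total = _work_total(work, weights, rule)
        works.append(work)

    # ---- proposal machinery ----------------------------------------------
    def _eval_move(work: _Work, pairs=None, conds_a=None, conds_b=None) -> float:
        old = (work.pairs, work.state_a.members, work.state_b.members,
               work.state_a.conditions, work.state_b.conditions)
        try:
            if pairs is not None:
                work.pairs = pairs
                work.sync_members()
            if conds_a is not None:
                work.state_a.conditions = conds_a
            if conds_b is not None:
                work.state_b.conditions = conds_b
            return _work_total(work, weights, rule)
        finally:
            (work.pairs, work.state_a.members, work.state_b.members,
             work.state_a.conditions, work.state_b.conditions) = old

    def _propose(work: _Work):
        """Return (kind, new_total, apply_callable) or None if the move is
        structurally impossible."""
        kind = int(rng.integers(6))
        if kind == 0:  # add ortholog family
            in_work = {p.family_id for p in work.pairs}
            candidates = [f for f in fam_ids_sorted if f not in in_work]
            if not candidates:
                return None
            fid = candidates[int(rng.integers(len(candidates)))]
            used_a = {p.gene_a for p in work.pairs} | {g for g in core_count_a
                                                       if _capped(g, core_count_a)}
            used_b = {p.gene_b for p in work.pairs} | {g for g in core_count_b
                                                       if _capped(g, core_count_b)}
            scorer = lambda a, b: (candidate_gene_score(a, work.state_a, weights)
                                   + candidate_gene_score(b, work.state_b, weights))
            pair = choose_pair_for_family(index.families[fid], used_a, used_b, scorer)
            if pair is None:
                return None
            new_pairs = work.pairs + [pair]
            new_total = _eval_move(work, pairs=new_pairs)

            def apply():
                work.pairs = new_pairs
                work.sync_members()
                core_count_a[pair.gene_a] = core_count_a.get(pair.gene_a, 0) + 1
                core_count_b[pair.gene_b] = core_count_b.get(pair.gene_b, 0) + 1
                work.accepted_changes += 1

            return ("add_pair", new_total, apply)
        if kind == 1:  # drop pair
            if len(work.pairs) <= MIN_PAIRS:
                return None
            i = int(rng.integers(len(work.pairs)))
            pair = work.pairs[i]
            new_pairs = work.pairs[:i] + work.pairs[i + 1:]
            new_total = _eval_move(work, pairs=new_pairs)

            def apply():
                work.pairs = new_pairs
                work.sync_members()
                core_count_a[pair.gene_a] -= 1
                core_count_b[pair.gene_b] -= 1
                work.accepted_changes += 1

            return ("drop_pair", new_total, apply)
        # condition moves
        state = work.state_a if kind in (2, 3) else work.state_b
        which = "conds_a" if kind in (2, 3) else "conds_b"
        all_conds = state.ctx.conditions
        if kind in (2, 4):  # add condition
            candidates = [c for c in all_conds if c not in state.conditions]
            if not candidates:
                return None
            cond = candidates[int(rng.integers(len(candidates)))]
            new_conds = state.conditions + [cond]
        else:  # drop condition
            if len(state.conditions) <= MIN_CONDITIONS:
                return None
            i = int(rng.integers(len(state.conditions)))
            new_conds = state.conditions[:i] + state.conditions[i + 1:]
        new_total = _eval_move(work, **{which: new_conds})

        def apply():
            state.conditions = new_conds

        return ("cond", new_total, apply)

    # ---- temperature calibration ------------------------------------------
    t_start = params.t_start
    if t_start is None:
        # a tenth of the probe-move score sd: hot enough to escape small
        # local traps, cool enough not to scramble the informative seeds
        deltas = []
        for _ in range(200):
            work = works[int(rng.integers(len(works)))]
            prop = _propose(work)
            if prop is not None:
                deltas.append(prop[1] - work.total)
        t_start = float(np.std(deltas)) / 10.0 if len(deltas) >= 2 else 1.0
        t_start = max(t_start, 1e-6)
    t_end = params.t_end if params.t_end is not None else t_start / 100.0
    n_total = params.iterations * max(len(works), 1)
    schedule = AnnealSchedule(t_start=max(t_start, t_end), t_end=t_end,
                              n_iterations=n_total)

    # ---- main loop ---------------------------------------------------------
    use_motifs = weights.w_motif > 0 and params.motif_search.n_motifs > 0
    for it in range(n_total):
        temp = schedule.temperature(it)
        work = works[int(rng.integers(len(works)))]
        prop = _propose(work)
        if prop is None:
            continue
        kind, new_total, apply = prop
        if metropolis_accept(new_total - work.total, temp, rng):
            apply()
            work.total = new_total
            if use_motifs and work.accepted_changes >= params.motif_refresh_every:
                _refresh_motifs(work, params.motif_search, rng)
                work.total = _work_total(work, weights, rule)
                work.accepted_changes = 0
        if trace is not None and it % max(1, n_total // 200) == 0:
            trace.append((it, float(np.mean([w.total for w in works]))))

    # final motif pass for any bicluster never refreshed
    if use_motifs:
        for work in works:
            if not work.motifs_a and not work.motifs_b:
                _refresh_motifs(work, params.motif_search, rng)
                work.total = _work_total(work, weights, rule)

    # ---- package -----------------------------------------------------------
    biclusters = []
    for k, work in enumerate(works):
        bc = _package(work, k + 1, dataset_a, dataset_b, ctx_a, ctx_b)
        bc.validate(paired=True)
        biclusters.append(bc)
    return biclusters


def _refresh_motifs(work: _Work, mp: MotifSearchParams, rng: np.random.Generator) -> None:
    for state, attr in ((work.state_a, "motifs_a"), (work.state_b, "motifs_b")):
        promoters = {
            g: state.ctx.dataset.promoters[g]
            for g in state.members
            if g in state.ctx.dataset.promoters
        }
        seed = int(rng.integers(2**31))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            motifs = find_motifs(
                promoters, n_motifs=mp.n_motifs, width_range=mp.width_range,
                n_restarts=mp.n_restarts, seed=seed, max_sweeps=mp.max_sweeps,
            )
        setattr(work, attr, motifs)
        attach_motifs(state, motifs)


def _package(work: _Work, bicluster_id: int, dataset_a, dataset_b,
             ctx_a: SpeciesContext, ctx_b: SpeciesContext) -> Bicluster:
    sides = {}
    for sid, state, motifs, ds in (
        (dataset_a.species_id, work.state_a, work.motifs_a, dataset_a),
        (dataset_b.species_id, work.state_b, work.motifs_b, dataset_b),
    ):
        genes = list(state.members)
        residual = expression_residual(ds.expression, genes, state.conditions)
        sides[sid] = BiclusterSide(
            core_genes=genes,
            elaborated_genes=[],
            conditions=list(state.conditions),
            motifs=list(motifs),
            score_components={
                "residual": residual,
                "motif_mean_logp": bicluster_motif_mean(motifs, genes),
                "network_score": network_cohesion_score(ds.network, genes),
            },
        )
    return Bicluster(
        bicluster_id=bicluster_id,
        sides=sides,
        core_pairs=list(work.pairs),
        combined_score=work.total,
    )


# ---------------------------------------------------------------------------
# step 3: species-specific elaboration (static core)
# ---------------------------------------------------------------------------

def elaborate_bicluster(
    bicluster: Bicluster,
    dataset: SpeciesDataset,
    species: str,
    params: Optional[ElaborateParams] = None,
    ctx: Optional[SpeciesContext] = None,
) -> Bicluster:
    """Add species-specific genes to one side of a conserved bicluster.

    The core genes are immutable (enforced by assertion); conditions are
    frozen unless ``allow_condition_moves``.  Any gene of the species is
    eligible, including genes in no ortholog family.  Returns a new
    Bicluster with ``elaborated_genes`` filled for ``species``.
    """
    params = params or ElaborateParams()
    side = bicluster.side(species)
    if not side.core_genes:
        raise ValueError(f"bicluster {bicluster.bicluster_id} has an empty core for {species}")
    ss = np.random.SeedSequence([params.seed, bicluster.bicluster_id])
    seed_ctx, seed_main = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))
    if ctx is None:
        ctx = SpeciesContext(dataset, seed=seed_ctx)
    rng = np.random.default_rng(seed_main)
    weights = params.weights

    core = tuple(side.core_genes)
    elaborated = [g for g in side.elaborated_genes if g in ctx.gene_index]
    state = SpeciesState(ctx, list(core) + elaborated, list(side.conditions))
    if side.motifs:
        attach_motifs(state, side.motifs)

    from mscm.scoring import side_total_score

    total = side_total_score(state, weights)
    universe = [g for g in ctx.genes]

    def _propose():
        n_kinds = 4 if params.allow_condition_moves else 2
        kind = int(rng.integers(n_kinds))
        if kind == 0:  # add gene
            member_set = set(state.members)
            candidates = [g for g in universe if g not in member_set]
            if not candidates:
                return None
            gene = candidates[int(rng.integers(len(candidates)))]
            new_members = state.members + [gene]
        elif kind == 1:  # drop an elaborated gene
            extra = state.members[len(core):]
            if not extra:
                return None
            i = int(rng.integers(len(extra)))
            new_members = state.members[: len(core) + i] + state.members[len(core) + i + 1:]
        elif kind == 2:  # add condition
            candidates = [c for c in ctx.conditions if c not in state.conditions]
            if not candidates:
                return None
            cond = candidates[int(rng.integers(len(candidates)))]
            old = state.conditions
            state.conditions = old + [cond]
            new_total = side_total_score(state, weights)
            new_conditions = state.conditions
            state.conditions = old
            return ("cond", new_total, ("conds", new_conditions))
        else:  # drop condition
            if len(state.conditions) <= MIN_CONDITIONS:
                return None
            i = int(rng.integers(len(state.conditions)))
            old = state.conditions
            new_conditions = old[:i] + old[i + 1:]
            state.conditions = new_conditions
            new_total = side_total_score(state, weights)
            state.conditions = old
            return ("cond", new_total, ("conds", new_conditions))
        old_members = state.members
        state.members = new_members
        new_total = side_total_score(state, weights)
        state.members = old_members
        return ("gene", new_total, ("members", new_members))

    t_start = params.t_start
    if t_start is None:
        deltas = []
        for _ in range(50):
            prop = _propose()
            if prop is not None:
                deltas.append(prop[1] - total)
        # tenth of the probe sd, as in detection: keep the informative start
        t_start = max(float(np.std(deltas)) / 10.0 if len(deltas) >= 2 else 1.0, 1e-6)
    t_end = params.t_end if params.t_end is not None else t_start / 100.0
    schedule = AnnealSchedule(max(t_start, t_end), t_end, params.iterations)

    for it in range(params.iterations):
        prop = _propose()
        if prop is None:
            continue
        _kind, new_total, (slot, payload) = prop
        if metropolis_accept(new_total - total, schedule.temperature(it), rng):
            if slot == "members":
                state.members = payload
            else:
                state.conditions = payload
            total = new_total

    assert tuple(state.members[: len(core)]) == core, "core genes were mutated"

    new_side = BiclusterSide(
        core_genes=list(core),
        elaborated_genes=state.members[len(core):],
        conditions=list(state.conditions),
        motifs=list(side.motifs),
        score_components=dict(side.score_components),
    )
    genes = new_side.genes
    new_side.score_components["residual"] = expression_residual(
        dataset.expression, genes, new_side.conditions
    )
    new_side.score_components["network_score"] = network_cohesion_score(
        dataset.network, genes
    )
    new_side.score_components["motif_mean_logp"] = bicluster_motif_mean(
        new_side.motifs, genes
    )
    sides = dict(bicluster.sides)
    sides[species] = new_side
    return Bicluster(
        bicluster_id=bicluster.bicluster_id,
        sides=sides,
        core_pairs=list(bicluster.core_pairs),
        combined_score=bicluster.combined_score,
        stouffer_z=bicluster.stouffer_z,
    )


# ---------------------------------------------------------------------------
# step 4: purely species-specific biclusters (off by default)
# ---------------------------------------------------------------------------

@dataclass
class SpecificParams:
    n_biclusters: int = 2
    init_size: int = 8
    seed_candidates: int = 10
    iterations: int = 5000
    t_start: Optional[float] = None
    t_end: Optional[float] = None
    weights: ScoreWeights = field(default_factory=ScoreWeights)
    seed: int = 0


def species_specific_biclusters(
    dataset: SpeciesDataset,
    exclusions: Set[str],
    params: Optional[SpecificParams] = None,
    ctx: Optional[SpeciesContext] = None,
) -> List[Bicluster]:
    """Single-species biclustering over genes not in any conserved
    bicluster.  Returns single-side Biclusters; empty list (with warning)
    when no genes remain."""
    params = params or SpecificParams()
    ss = np.random.SeedSequence([params.seed, 4])
    seed_ctx, seed_main = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))
    if ctx is None:
        ctx = SpeciesContext(dataset, seed=seed_ctx)
    rng = np.random.default_rng(seed_main)
    weights = params.weights
    universe = [g for g in ctx.genes if g not in exclusions]
    if not universe:
        warnings.warn("all genes excluded; no species-specific biclusters searched")
        return []
    if len(universe) < MIN_PAIRS:
        warnings.warn("too few non-excluded genes; no species-specific biclusters")
        return []

    from mscm.scoring import side_total_score

    Z = _zscored_rows(ctx)
    n_cond = len(ctx.conditions)
    states: List[SpeciesState] = []
    used: Set[str] = set()
    n_biclusters = min(params.n_biclusters, len(universe) // MIN_PAIRS)
    for _k in range(n_biclusters):
        avail = [g for g in universe if g not in used]
        if len(avail) < MIN_PAIRS:
            break
        # several uniform candidate seeds; keep the most co-expressed
        # correlation neighborhood
        n_cand = min(params.seed_candidates, len(avail))
        best_quality, members = float("-inf"), None
        for ci in rng.choice(len(avail), size=n_cand, replace=False):
            seed_gene = avail[int(ci)]
            corr = Z @ Z[ctx.gene_index[seed_gene]] / n_cond
            ranked = sorted(avail, key=lambda g: (-corr[ctx.gene_index[g]], g))
            cand = ranked[: max(MIN_PAIRS, params.init_size)]
            quality = float(np.mean([corr[ctx.gene_index[g]] for g in cand[1:]]))
            if quality > best_quality:
                best_quality, members = quality, cand
        used.update(members)
        rows = ctx.rows(members)
        states.append(SpeciesState(ctx, members, _seed_conditions(ctx, rows)))

    totals = [side_total_score(s, weights) for s in states]

    def _propose(state: SpeciesState, total: float):
        kind = int(rng.integers(4))
        if kind == 0:
            member_set = set(state.members)
            candidates = [g for g in universe if g not in member_set]
            if not candidates:
                return None
            gene = candidates[int(rng.integers(len(candidates)))]
            new = ("members", state.members + [gene])
        elif kind == 1:
            if len(state.members) <= MIN_PAIRS:
                return None
            i = int(rng.integers(len(state.members)))
            new = ("members", state.members[:i] + state.members[i + 1:])
        elif kind == 2:
            candidates = [c for c in ctx.conditions if c not in state.conditions]
            if not candidates:
                return None
            cond = candidates[int(rng.integers(len(candidates)))]
            new = ("conds", state.conditions + [cond])
        else:
            if len(state.conditions) <= MIN_CONDITIONS:
                return None
            i = int(rng.integers(len(state.conditions)))
            new = ("conds", state.conditions[:i] + state.conditions[i + 1:])
        slot, payload = new
        if slot == "members":
            old = state.members
            state.members = payload
            new_total = side_total_score(state, weights)
            state.members = old
        else:
            old = state.conditions
            state.conditions = payload
            new_total = side_total_score(state, weights)
            state.conditions = old
        return (new_total, slot, payload)

    t_start = params.t_start
    if t_start is None:
        deltas = []
        for _ in range(100):
            i = int(rng.integers(len(states)))
            prop = _propose(states[i], totals[i])
            if prop is not None:
                deltas.append(prop[0] - totals[i])
        # tenth of the probe sd, as in detection: keep the informative seeds
        t_start = max(float(np.std(deltas)) / 10.0 if len(deltas) >= 2 else 1.0, 1e-6)
    t_end = params.t_end if params.t_end is not None else t_start / 100.0
    n_total = params.iterations * max(len(states), 1)
    schedule = AnnealSchedule(max(t_start, t_end), t_end, n_total)

    for it in range(n_total):
        i = int(rng.integers(len(states)))
        prop = _propose(states[i], totals[i])
        if prop is None:
            continue
        new_total, slot, payload = prop
        if metropolis_accept(new_total - totals[i], schedule.temperature(it), rng):
            if slot == "members":
                states[i].members = payload
            else:
                states[i].conditions = payload
            totals[i] = new_total

    biclusters = []
    for k, (state, total) in enumerate(zip(states, totals)):
        residual = expression_residual(ctx.dataset.expression, state.members, state.conditions)
        side = BiclusterSide(
            core_genes=list(state.members),
            elaborated_genes=[],
            conditions=list(state.conditions),
            motifs=[],
            score_components={
                "residual": residual,
                "motif_mean_logp": 0.0,
                "network_score": network_cohesion_score(ctx.dataset.network, state.members),
            },
        )
        bc = Bicluster(
            bicluster_id=1000 + k + 1,
            sides={dataset.species_id: side},
            core_pairs=[],
            combined_score=float(total),
        )
        bc.validate(paired=False)
        biclusters.append(bc)
    return biclusters


# ---------------------------------------------------------------------------
# null reference for score sanity checks
# ---------------------------------------------------------------------------

def random_bicluster_scores(
    ctx_a: SpeciesContext,
    ctx_b: SpeciesContext,
    n_pairs: int,
    n_conds_a: int,
    n_conds_b: int,
    weights: ScoreWeights,
    n_draws: int = 100,
    seed: int = 0,
    rule: str = "sum",
) -> np.ndarray:
    """Total scores of random same-shape biclusters: the null that a
    detected bicluster's score is compared against."""
    rng = np.random.default_rng(seed)
    out = np.empty(n_draws)
    for d in range(n_draws):
        rows_a = rng.choice(len(ctx_a.genes), size=n_pairs, replace=False)
        rows_b = rng.choice(len(ctx_b.genes), size=n_pairs, replace=False)
        cols_a = rng.choice(len(ctx_a.conditions), size=n_conds_a, replace=False)
        cols_b = rng.choice(len(ctx_b.conditions), size=n_conds_b, replace=False)
        state_a = SpeciesState(ctx_a, [ctx_a.genes[i] for i in rows_a],
                               [ctx_a.conditions[j] for j in cols_a])
        state_b = SpeciesState(ctx_b, [ctx_b.genes[i] for i in rows_b],
                               [ctx_b.conditions[j] for j in cols_b])
        work = _Work([OrthologPair("null", a, b) for a, b in
                      zip(state_a.members, state_b.members)], state_a, state_b)
        out[d] = _work_total(work, weights, rule)
    return out
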