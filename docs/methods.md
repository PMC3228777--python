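# Methods

## Overview

`mscm` detects condition-specific co-expression modules that are
conserved between two related microbial species and then elaborates each
module per species. The two organisms are coupled through ortholog
families (InParanoid-style: one-to-one, one-to-many, or many-to-many);
a conserved bicluster is a set of ortholog gene *pairs* together with a
condition subset per species. Detection proceeds in steps:

1. **Orthologous core.** Families are indexed; the candidate pairing of
   a family is the Cartesian product of its members. Genes in no family
   are eligible only for elaboration.
2. **Conserved biclusters.** Simulated annealing over moves
   {add ortholog family, drop pair, add condition, drop condition per
   species} maximizes a joint two-species score. When a family is
   proposed, the concrete pair is chosen lazily: the member pair with
   the best joint membership score under the current bicluster state.
3. **Species-specific elaboration.** Each conserved bicluster is split
   into its two single-species halves; genes (including family-less
   ones) are added/dropped per species with the core frozen and, by
   default, the conditions frozen too.
4. **Species-specific biclusters** (optional, off by default): the same
   single-species optimizer over genes not used by any conserved
   bicluster.

Post-processing assigns functional annotations by hypergeometric
enrichment, combines per-bicluster statistics into one Stouffer z,
links related biclusters into a typed network, infers operons from
identical promoter motif patterns, and renders per-bicluster report
cards.

## Evidence channels and the membership score

Each species contributes three evidence channels for a gene `g` against
a bicluster state (members `G`, conditions `C`):

* **Expression — profile misfit.** The bicluster's condition profile is
  the vector of column means of the member submatrix (relative to its
  grand mean). The raw statistic is the negative mean absolute
  deviation of `g`'s row-centered profile from that profile, normalized
  by the member submatrix's value range. We use this fit statistic
  rather than the leave-one-out change in the bicluster residual: for
  any member of a coherent module the leave-one-out residual delta is
  nearly zero (the module stays tight without any single gene), so it
  cannot distinguish genuine members from bystanders.
* **Motif.** The gene's mean best-hit log p-value over the bicluster's
  currently discovered motifs, negated. Best hits come from scanning
  the motif PWMs over every promoter in the dataset.
* **Network.** The density of association-network edges between `g` and
  the current members (edges to members divided by member count).
  Density rather than a raw count keeps the statistic comparable across
  bicluster sizes.

Every channel is standardized against an **empirical null**: seeded
random draws of (member set, condition set, query gene) from the same
dataset. Because the null distribution of each raw statistic depends
strongly on the bicluster shape, nulls are estimated on a grid of
(member count, condition count) shapes — roughly geometric from 3
(respectively 2) up to the dataset size, `null_draws` (default 300)
draws per shape — and interpolated bilinearly between grid points. The
motif channel is standardized against the whole-dataset distribution of
per-gene best-hit log p-values, recomputed at each motif refresh.

The single-species membership score is
`w_expr·z_expr + w_motif·z_motif + w_net·z_net`
(defaults 1.0 / 0.5 / 0.5 — expression is the primary signal; the
relative channel weights are exposed in the run config). The joint
two-species score of an ortholog pair is the sum of the two members'
scores ("sum" rule; a conservative "min" rule is available).

### Bicluster total and activation thresholds

The annealer's objective for one bicluster is

```
total = Σ_pairs (score_a + score_b - 2·λ_gene)
      + Σ_species [ Σ_conds (z_cond - λ_cond) ] / sqrt(|conds|)
```

with `λ_gene = 2.0` and `λ_cond = 0.5` (config keys
`weights.gene_penalty`, `weights.cond_penalty`). The activation
thresholds are essential: without them a sum-of-z objective accretes
chance-positive members indefinitely on structure-free data, because an
optimizer that picks the best of many candidates harvests the upper
tail of the null. A member must therefore be supported beyond roughly
the 97.5th percentile of chance to contribute positively. Condition
terms are additionally Stouffer-normalized by `sqrt(|conds|)`: once a
coherent gene set is in place, every condition's "include me" statistic
is positive and strongly correlated with the others, and summing them
raw would let condition accumulation dominate the gene evidence.

Condition membership itself is scored by the standardized decrease in
the species' bicluster residual when the condition is included. The
residual is the cMonkey-style range-normalized mean absolute deviation
from an additive gene + condition model; note that it is invariant to
any purely additive structure, so condition evidence is intrinsically
weaker than gene evidence — another reason for the damped condition
term.

## Annealing

Moves are proposed uniformly over the six move kinds on a uniformly
chosen bicluster and accepted with probability `min(1, exp(Δ/T))` under
geometric cooling. Constraints: at least 3 pairs and 2 conditions per
species; a gene may sit in at most `redundancy_cap` (default 2)
bicluster cores.

Seeding: for each bicluster, `seed_candidates` (default 10) unused
families are drawn uniformly; for each, the seed pair plus its
`init_size − 1` nearest pairs by joint expression correlation form a
candidate neighborhood, and the most strongly co-expressed neighborhood
wins. Initial conditions are the half of conditions where the seed
genes deviate most from zero. Informative seeding matters: the score
landscape has a barrier between scattered pairs and an assembled module
(a half-module scores near chance), so modules are found by seeding
inside them, not by migration.

Temperature: `t_start` defaults to one tenth of the standard deviation
of the score change over 200 random probe moves, `t_end` to
`t_start/100`. A full-sd start (the classical prescription) re-melts
the informative seeds before cooling and destroys recovery; a tenth is
hot enough to escape small local traps and cold enough to preserve
seeds.

Motif re-discovery dominates cost and is amortized: motifs are
refreshed every `motif_refresh_every` (default 50) accepted membership
changes per bicluster, and score deltas in between use the stale
motifs.

## Motif discovery and scanning

The de novo searcher is a ZOOPS (zero-or-one occurrence per sequence)
Gibbs sampler over both strands: per width in `width_range` and per
restart, sites are resampled to convergence (complete-data
log-likelihood change < 1e-6, capped at `max_sweeps`); the best model
per motif slot minimizes the Fisher combination of per-sequence
best-hit p-values; fixed sites are masked (N) before the next slot.
The E-value surrogate is that Fisher p times the number of
width × restart hypotheses — a monotone ranking statistic, not a
calibrated expectation.

Scanning computes log-odds scores (bits) against the background base
composition at every offset on both strands. Per-hit p-values are
exact for the integerized score: the null score distribution is built
by dynamic-programming convolution over PWM columns with a
discretization step of 0.01 bits. Reverse-strand hits are reported by
the start of the match on the stored (5'→3' toward gene start)
promoter; ties between strands go to "+".

Motif similarity is the maximum over ungapped offsets and both
orientations of the mean per-column Pearson correlation of the
probability vectors, mapped to [0, 1] by (r+1)/2, requiring an overlap
of ≥ 5 columns.

## Post-processing

* **Enrichment**: one-sided hypergeometric upper tail per testable
  term; a bicluster is assigned every term with raw p < 0.05
  (Benjamini–Hochberg q is reported alongside but deliberately not used
  for assignment — the assignment rule is part of the method's
  definition, at a documented cost in false assignments).
* **Bicluster score**: Stouffer's z over (in fixed order) the residual's
  empirical p against shape-matched random draws, the Fisher-combined
  motif best-hit p, the network cohesion p, and the best enrichment p;
  missing components shrink k. For a conserved bicluster the two
  species' z values are averaged.
* **Related biclusters**: per unordered pair, one edge per satisfied
  criterion — gene-overlap Jaccard ≥ 0.1 (per species, then maximized,
  since conserved biclusters have two gene sets), motif similarity
  ≥ 0.8, or a shared assigned term per namespace.
* **Operons**: genes group when their promoters carry the same motif
  ids in the same order and strands with starts within 5 nt after
  aligning on the first shared motif (transitive closure). Hits weaker
  than p = 1e-3 are ignored for pattern building.

## Synthetic data

The generator emulates the structure the method exploits: two species
with deterministic gene-index layout (module cores, elaboration genes,
decoy-paralog pool, family-less genes), 1:1 base families with a
`paralog_family_fraction` of families given a decoy second member on an
alternating side (fresh background expression, no motif), planted
modules with per-species condition subsets, a planted consensus motif
implanted once per member promoter with per-base mutation probability
`motif_mutation_rate`, association networks with Bernoulli background
edges and enriched within-module edges (elaboration genes included in
the module for network purposes), and per-species elaboration genes
that carry the module's signal and motif but belong to no family.

The module expression signal is a shared **condition profile**:
amplitude `signal_mu × U(0.5, 1.5)` per (module, species, condition),
added to every member on the module's conditions. A flat offset would
be absorbed exactly by the additive residual model and would leave the
planted submatrix statistically indistinguishable from noise.

Reference conditions (the generator defaults, used by the acceptance
checks): 240 genes × 50 conditions per species, 3 modules × 15 pairs,
condition fraction 0.5, signal_mu 2, noise_sigma 1, motif width 8 with
10% per-base mutation, promoter length 150, background edge probability
0.01 vs 0.3 within modules, 20% decoy-paralog families, 15% family-less
genes, 3 elaboration genes per module and species. Randomness is split
into fixed sub-streams (expression, promoters, network, families,
annotations) from the single seed.

What the generator does **not** emulate: array-platform noise, probe
effects, missing-value patterns of real compendia, realistic genome
composition or operon structure in promoters, scale (hundreds vs
thousands of genes), or biologically structured annotation ontologies.
Passing recovery tests therefore demonstrates the machinery works under
its own assumptions, not field performance on real compendia.

## Problem sizes and run configurations

The reference detection configuration is 6 biclusters, init size 8,
8 000 iterations per bicluster-equivalent, one in-loop motif of width 8
with one restart, motif refresh every 100 accepted changes. The
spec-level default of 20 000 iterations is exposed in the config; the
recovery checks use 8 000, where recovery has plateaued on the
reference conditions. Pipeline smoke/determinism checks run a reduced
setting (90 genes, 2 modules, 500 iterations). Elaboration replicate
checks use 10 seeds × 3 000 iterations. The null-control dataset is
150 genes × 40 conditions with no modules.

## Known limitations

* On structure-free data the annealer still finds locally coherent
  noise sets: its final objective exceeds the mean of random same-shape
  biclusters by roughly 2–5 null standard deviations. This is inherent
  to comparing an optimized quantity with an unoptimized null; the
  activation thresholds bound the effect (scores stay within a few
  null sd rather than growing without limit) but cannot remove it.
* Condition-subset recovery is weak by design of the residual (additive
  invariance); recovered biclusters are validated by their gene/pair
  content.
* The empirical nulls ignore the optimizer's selection multiplicity;
  the activation thresholds are the compensating control.
* The Gibbs sampler has no phase-shift move, so a recovered PWM may be
  registered a column or two off the planted frame (consensus identity
  is scored over alignments for this reason).
* One-species expression matrices with heavy missingness are handled
  (all statistics are computed over finite cells) but the generator
  never produces them, so that path is covered by unit tests only.
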