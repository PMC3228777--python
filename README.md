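# mscm — two-species integrative biclustering

`mscm` finds **conserved regulatory modules** in paired microbial
datasets: condition-specific groups of orthologous genes that are
co-expressed in *both* of two related species, supported in each
species by three evidence channels — expression coherence, shared
upstream sequence motifs, and connectivity in a functional-association
network. It is aimed at comparative systems biology of bacteria
(e.g. an *E. coli*–*Salmonella*-style pair) where expression compendia,
promoter sequences, association networks and ortholog tables are
available for both organisms.

## Method in brief

Given per-species expression matrices **X**(genes × conditions),
promoters, SIF association networks, GMT annotation sets, and an
InParanoid-style ortholog family table, the algorithm:

1. builds the **orthologous core** — all candidate gene pairings within
   each homology family (1:1, 1:many, many:many);
2. detects **conserved biclusters** by simulated annealing over moves
   {add family / drop pair / add or drop condition per species},
   maximizing a joint score. For a gene *g* and bicluster state, each
   species contributes

   *s(g) = w_e·z_expr + w_m·z_motif + w_n·z_net*,

   where the channels are (i) the fit of *g*'s profile to the
   bicluster's condition profile, (ii) *g*'s best motif-hit log
   p-value under the bicluster's de-novo motifs (ZOOPS Gibbs sampler,
   exact PWM-scan p-values), and (iii) *g*'s edge density to the
   members — each standardized against seeded empirical nulls matched
   to the bicluster shape. A pair's joint score is the sum over the
   two species; within a one-to-many family the best-scoring pair is
   chosen at move time;
3. **elaborates** each bicluster per species (core frozen), adding
   species-specific genes including those with no ortholog;
4. post-processes: hypergeometric annotation enrichment (assignment at
   raw p < 0.05), a per-bicluster meta-analytic score
   *z = Σ Φ⁻¹(1−pᵢ)/√k* (Stouffer), a typed **bicluster network**
   (shared annotations / overlapping members / similar motifs), operon
   inference from identical promoter motif patterns, and a static
   **BiclusterCard** report (JSON + HTML) per bicluster and species.

A synthetic-data generator plants conserved modules, motifs, network
structure, decoy paralogs and elaboration genes with full ground truth,
so the whole pipeline is testable end to end. See `docs/methods.md`
for formulas, defaults and limitations.

## Worked example

Generate a coupled synthetic dataset, run the pipeline, and inspect
recovery against the planted truth:

```bash
mscm simulate --seed 1 --out demo_data
```

```
wrote synthetic bundle to demo_data (240+240 genes, 170 families, 3 planted modules)
```

Then, in Python:

```python
from mscm.synth import read_pair_dataset, score_recovery
from mscm.optimize import detect_conserved_biclusters, DetectParams, MotifSearchParams

ds_a, ds_b, families, truth = read_pair_dataset("demo_data")
biclusters = detect_conserved_biclusters(
    ds_a, ds_b, families,
    DetectParams(n_biclusters=6, iterations=8000, seed=7,
                 motif_search=MotifSearchParams(n_motifs=1, width_range=(8, 8),
                                                n_restarts=1, max_sweeps=60),
                 motif_refresh_every=100),
)
rec = score_recovery(biclusters, truth, match_threshold=0.5)
print(rec["recovery_fraction"], [round(m["best_jaccard"], 2) for m in rec["per_module"]])
```

```
0.6666666666666666 [0.27, 1.0, 1.0]
```

Two of the three planted modules are recovered exactly (some detected
bicluster's core-pair set matches the planted ortholog pairs with
Jaccard 1.0) and the third partially; the recovery fraction counts
modules matched at Jaccard ≥ 0.5. A full file-driven run (`mscm run --config cfg.yaml`)
additionally writes `biclusters.json`, the bicluster network
(GraphML + SIF), rendered cards and a checksum manifest; rerunning
with the same config and seed reproduces every checksum.

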