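"""Coupled two-species synthetic datasets with planted ground truth.

The generator emulates the data model the biclustering operates on: two
organisms with partially overlapping orthologous gene sets (including
decoy paralogs in one-to-many families), planted condition-specific
co-expression modules shared between the species, a planted upstream
motif per module, association networks enriched within modules, and
species-specific elaboration genes that carry the module signal and motif
but have no ortholog partner.

Randomness is split into fixed sub-streams (expression, promoters,
network, families, annotations) spawned from the single seed, so adding a
downstream feature never perturbs the earlier streams.  The gene layout
itself (which genes are module members, elaborations, decoys or
family-less) is deterministic given the sizes, which keeps the truth
stable across streams.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence, Set, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from mscm import io as mscm_io
from mscm.model import (
    AnnotationTerm,
    Bicluster,
    EDGE_TYPES,
    OrthologFamily,
    SpeciesDataset,
)

BASES = np.array(list("ACGT"))


@dataclass
class GenParams:
    """Generation parameters; the defaults are the reference study
    conditions used throughout the test suite."""

    n_genes_a: int = 240
    n_genes_b: int = 240
    n_conditions_a: int = 50
    n_conditions_b: int = 50
    n_modules: int = 3
    module_size: int = 15
    condition_fraction: float = 0.5
    signal_mu: float = 2.0
    noise_sigma: float = 1.0
    motif_width: int = 8
    motif_mutation_rate: float = 0.1
    promoter_length: int = 150
    bg_edge_prob: float = 0.01
    module_edge_prob: float = 0.3
    paralog_family_fraction: float = 0.2
    nonortholog_fraction: float = 0.15
    n_elab_per_module: int = 3
    n_random_terms: int = 10
    random_term_size: int = 10
    species_a: str = "spA"
    species_b: str = "spB"
    seed: int = 0


@dataclass
class PlantedModule:
    module_id: int
    pairs: List[Tuple[str, str]]
    conditions_a: List[str]
    conditions_b: List[str]
    motif_consensus: str
    elaborated_a: List[str]
    elaborated_b: List[str]
    # gene -> (position, implanted instance); strand is always "+"
    motif_positions: Dict[str, Tuple[int, str]] = field(default_factory=dict)


@dataclass
class PlantedTruth:
    """Ground truth of one generated dataset pair, plus a parameter echo."""

    modules: List[PlantedModule]
    params: GenParams
    decoy_genes: Dict[str, List[str]] = field(default_factory=dict)

    def module_pair_sets(self) -> List[Set[Tuple[str, str]]]:
        return [set(m.pairs) for m in self.modules]

    def to_dict(self) -> dict:
        return {
            "params": asdict(self.params),
            "decoy_genes": self.decoy_genes,
            "modules": [
                {
                    "module_id": m.module_id,
                    "pairs": [list(p) for p in m.pairs],
                    "conditions_a": m.conditions_a,
                    "conditions_b": m.conditions_b,
                    "motif_consensus": m.motif_consensus,
                    "elaborated_a": m.elaborated_a,
                    "elaborated_b": m.elaborated_b,
                    "motif_positions": {g: [p, s] for g, (p, s) in m.motif_positions.items()},
                }
                for m in self.modules
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PlantedTruth":
        return cls(
            params=GenParams(**d["params"]),
            decoy_genes={k: list(v) for k, v in d.get("decoy_genes", {}).items()},
            modules=[
                PlantedModule(
                    module_id=int(m["module_id"]),
                    pairs=[tuple(p) for p in m["pairs"]],
                    conditions_a=list(m["conditions_a"]),
                    conditions_b=list(m["conditions_b"]),
                    motif_consensus=m["motif_consensus"],
                    elaborated_a=list(m["elaborated_a"]),
                    elaborated_b=list(m["elaborated_b"]),
                    motif_positions={g: (int(v[0]), v[1]) for g, v in m["motif_positions"].items()},
                )
                for m in d["modules"]
            ],
        )


# ---------------------------------------------------------------------------
# layout arithmetic
# ---------------------------------------------------------------------------

def _layout(p: GenParams) -> dict:
    """Deterministic partition of each species' gene index range."""
    n_module_genes = p.n_modules * p.module_size
    n_elab = p.n_modules * p.n_elab_per_module
    lay = {}
    for side, n_genes in (("a", p.n_genes_a), ("b", p.n_genes_b)):
        n_nofam = max(int(round(p.nonortholog_fraction * n_genes)), n_elab)
        n_eligible = n_genes - n_nofam
        if n_eligible < n_module_genes:
            raise ValueError(
                f"infeasible sizes: species {side} has {n_eligible} family-eligible "
                f"genes but modules need {n_module_genes}"
            )
        lay[side] = {"n_genes": n_genes, "n_nofam": n_nofam, "n_eligible": n_eligible}
    n_fam = int(min(lay["a"]["n_eligible"], lay["b"]["n_eligible"])
                / (1.0 + max(p.paralog_family_fraction, 0.0)))
    if n_fam < n_module_genes:
        raise ValueError("infeasible sizes: too few ortholog families for the modules")
    n_decoy = int(round(p.paralog_family_fraction * n_fam))
    for side in ("a", "b"):
        pool = lay[side]["n_eligible"] - n_fam
        if pool < (n_decoy + 1) // 2:
            raise ValueError("infeasible sizes: decoy pool exhausted")
        lay[side]["decoy_pool"] = pool
    lay["n_fam"] = n_fam
    lay["n_decoy"] = n_decoy
    return lay


def _gene_ids(species: str, n: int) -> List[str]:
    return [f"{species}_g{i:04d}" for i in range(n)]


def _mutate(consensus: str, rate: float, rng: np.random.Generator) -> str:
    out = list(consensus)
    for i, base in enumerate(out):
        if rng.random() < rate:
            choices = [b for b in "ACGT" if b != base]
            out[i] = choices[rng.integers(3)]
    return "".join(out)


# ---------------------------------------------------------------------------
# generator
# ---------------------------------------------------------------------------

def generate_pair_dataset(
    params: GenParams,
) -> Tuple[SpeciesDataset, SpeciesDataset, List[OrthologFamily], PlantedTruth]:
    """Generate the coupled dataset pair, families and ground truth.

    Fully reproducible from ``params.seed``.  Raises ``ValueError`` on
    infeasible sizes before any generation happens.
    """
    p = params
    if not (0.0 < p.condition_fraction <= 1.0):
        raise ValueError("condition_fraction must be in (0, 1]")
    if p.n_modules * p.module_size > min(p.n_genes_a, p.n_genes_b):
        raise ValueError("infeasible sizes: module_size * n_modules exceeds gene count")
    if p.promoter_length < p.motif_width:
        raise ValueError("promoter_length must be >= motif_width")
    lay = _layout(p)

    ss = np.random.SeedSequence(p.seed)
    rng_expr, rng_prom, rng_net, rng_fam, rng_annot = (
        np.random.default_rng(child) for child in ss.spawn(5)
    )

    genes = {"a": _gene_ids(p.species_a, p.n_genes_a), "b": _gene_ids(p.species_b, p.n_genes_b)}
    conds = {
        "a": [f"{p.species_a}_c{j:03d}" for j in range(p.n_conditions_a)],
        "b": [f"{p.species_b}_c{j:03d}" for j in range(p.n_conditions_b)],
    }
    n_module_genes = p.n_modules * p.module_size
    n_elab = p.n_modules * p.n_elab_per_module
    n_fam = lay["n_fam"]

    # index blocks per species: [module genes | other family genes | decoy
    # pool | no-family block (elaborations first)]
    elab_start = {s: lay[s]["n_genes"] - lay[s]["n_nofam"] for s in ("a", "b")}
    module_rows = {
        s: {m: list(range(m * p.module_size, (m + 1) * p.module_size)) for m in range(p.n_modules)}
        for s in ("a", "b")
    }
    elab_rows = {
        s: {
            m: list(range(elab_start[s] + m * p.n_elab_per_module,
                          elab_start[s] + (m + 1) * p.n_elab_per_module))
            for m in range(p.n_modules)
        }
        for s in ("a", "b")
    }

    # --- expression stream: condition subsets, then background + signal
    n_mod_conds = {
        "a": max(1, int(round(p.condition_fraction * p.n_conditions_a))),
        "b": max(1, int(round(p.condition_fraction * p.n_conditions_b))),
    }
    module_conds = {s: {} for s in ("a", "b")}
    for m in range(p.n_modules):
        for s, n_c in (("a", p.n_conditions_a), ("b", p.n_conditions_b)):
            cols = sorted(rng_expr.choice(n_c, size=n_mod_conds[s], replace=False).tolist())
            module_conds[s][m] = cols
    X = {}
    for s, n_c in (("a", p.n_conditions_a), ("b", p.n_conditions_b)):
        mat = rng_expr.normal(0.0, p.noise_sigma, size=(lay[s]["n_genes"], n_c))
        for m in range(p.n_modules):
            cols = module_conds[s][m]
            # condition-specific signal amplitude, mean signal_mu: module
            # genes share a condition profile rather than a flat offset
            amps = p.signal_mu * rng_expr.uniform(0.5, 1.5, size=len(cols))
            mat[np.ix_(module_rows[s][m], cols)] += amps[None, :]
            mat[np.ix_(elab_rows[s][m], cols)] += amps[None, :]
        X[s] = mat

    # --- promoter stream: consensi, then per-gene sequences with implants
    consensi = ["".join(rng_prom.choice(BASES, size=p.motif_width)) for _ in range(p.n_modules)]
    promoters = {"a": {}, "b": {}}
    motif_positions = {"a": {}, "b": {}}
    for s in ("a", "b"):
        planted_of = {}
        for m in range(p.n_modules):
            for row in module_rows[s][m] + elab_rows[s][m]:
                planted_of[row] = m
        for row, gene in enumerate(genes[s]):
            seq = "".join(rng_prom.choice(BASES, size=p.promoter_length))
            if row in planted_of:
                m = planted_of[row]
                instance = _mutate(consensi[m], p.motif_mutation_rate, rng_prom)
                pos = int(rng_prom.integers(0, p.promoter_length - p.motif_width + 1))
                seq = seq[:pos] + instance + seq[pos + p.motif_width:]
                motif_positions[s][gene] = (m, pos, instance)
            promoters[s][gene] = seq

    # --- network stream: Bernoulli background + enriched module edges
    networks = {}
    for s in ("a", "b"):
        g = nx.Graph()
        g.add_nodes_from(genes[s])
        n = lay[s]["n_genes"]
        iu, ju = np.triu_indices(n, k=1)
        mask = rng_net.random(iu.shape[0]) < p.bg_edge_prob
        for i, j in zip(iu[mask], ju[mask]):
            etype = EDGE_TYPES[int(rng_net.integers(len(EDGE_TYPES)))]
            g.add_edge(genes[s][i], genes[s][j], types={etype})
        for m in range(p.n_modules):
            # module membership for the network includes the elaboration
            # genes: they carry the module's association evidence too
            rows = module_rows[s][m] + elab_rows[s][m]
            for ii in range(len(rows)):
                for jj in range(ii + 1, len(rows)):
                    if rng_net.random() < p.module_edge_prob:
                        u, v = genes[s][rows[ii]], genes[s][rows[jj]]
                        etype = EDGE_TYPES[int(rng_net.integers(len(EDGE_TYPES)))]
                        if g.has_edge(u, v):
                            g.edges[u, v]["types"].add(etype)
                        else:
                            g.add_edge(u, v, types={etype})
        networks[s] = g

    # --- family stream: 1:1 base families + decoy paralogs
    families: List[OrthologFamily] = []
    decoy_rows = {s: iter(range(n_fam, lay[s]["n_eligible"])) for s in ("a", "b")}
    n_decoy = lay["n_decoy"]
    decoy_fams = sorted(rng_fam.choice(n_fam, size=n_decoy, replace=False).tolist()) if n_decoy else []
    decoy_side = {fam: ("a" if k % 2 == 0 else "b") for k, fam in enumerate(decoy_fams)}
    decoy_genes: Dict[str, List[str]] = {p.species_a: [], p.species_b: []}
    for f in range(n_fam):
        members = {"a": {genes["a"][f]}, "b": {genes["b"][f]}}
        if f in decoy_side:
            s = decoy_side[f]
            decoy = genes[s][next(decoy_rows[s])]
            members[s].add(decoy)
            decoy_genes[p.species_a if s == "a" else p.species_b].append(decoy)
        families.append(
            OrthologFamily(
                family_id=f"fam{f:04d}",
                members_a=frozenset(members["a"]),
                members_b=frozenset(members["b"]),
            )
        )

    # --- annotation stream: one planted term per module + random terms
    annotations = {"a": {}, "b": {}}
    for s in ("a", "b"):
        for ns in ("GO", "KEGG", "COG"):
            terms: Dict[str, AnnotationTerm] = {}
            for m in range(p.n_modules):
                members = frozenset(
                    genes[s][r] for r in module_rows[s][m] + elab_rows[s][m]
                )
                term = f"{ns}:module{m}"
                terms[term] = AnnotationTerm(term, f"planted module {m}", members, True)
            for t in range(p.n_random_terms):
                size = min(p.random_term_size, lay[s]["n_genes"])
                members = frozenset(
                    genes[s][r] for r in rng_annot.choice(lay[s]["n_genes"], size, replace=False)
                )
                term = f"{ns}:rand{t}"
                terms[term] = AnnotationTerm(term, f"random set {t}", members, len(members) >= 2)
            annotations[s][ns] = terms

    datasets = {}
    for s, sid in (("a", p.species_a), ("b", p.species_b)):
        datasets[s] = SpeciesDataset(
            species_id=sid,
            expression=pd.DataFrame(X[s], index=genes[s], columns=conds[s]),
            promoters=promoters[s],
            network=networks[s],
            annotations=annotations[s],
            gene_universe=tuple(genes[s]),
        )

    modules = []
    for m in range(p.n_modules):
        positions = {}
        for s in ("a", "b"):
            for gene, (mm, pos, instance) in motif_positions[s].items():
                if mm == m:
                    positions[gene] = (pos, instance)
        modules.append(
            PlantedModule(
                module_id=m,
                pairs=[
                    (genes["a"][r], genes["b"][r]) for r in module_rows["a"][m]
                ],
                conditions_a=[conds["a"][j] for j in module_conds["a"][m]],
                conditions_b=[conds["b"][j] for j in module_conds["b"][m]],
                motif_consensus=consensi[m],
                elaborated_a=[genes["a"][r] for r in elab_rows["a"][m]],
                elaborated_b=[genes["b"][r] for r in elab_rows["b"][m]],
                motif_positions=positions,
            )
        )
    truth = PlantedTruth(modules=modules, params=p, decoy_genes=decoy_genes)
    return datasets["a"], datasets["b"], families, truth


# ---------------------------------------------------------------------------
# recovery scoring
# ---------------------------------------------------------------------------

def score_recovery(
    predicted: Sequence[Bicluster],
    truth: PlantedTruth,
    match_threshold: float = 0.5,
) -> dict:
    """Compare predicted biclusters with the planted modules.

    A module counts as recovered when some predicted bicluster's core-pair
    set reaches Jaccard >= ``match_threshold`` against the planted pair
    set.  Elaboration precision/recall is evaluated on the best-matching
    bicluster of each recovered module.  Deterministic.
    """
    sid_a, sid_b = truth.params.species_a, truth.params.species_b
    for bc in predicted:
        if set(bc.sides) - {sid_a, sid_b}:
            raise ValueError(
                f"species mismatch: prediction has {sorted(bc.sides)}, "
                f"truth has {[sid_a, sid_b]}"
            )
    pred_sets = [set(p.key() for p in bc.core_pairs) for bc in predicted]
    per_module = []
    n_recovered = 0
    elab_tp = elab_fp = elab_fn = 0
    for module, planted in zip(truth.modules, truth.module_pair_sets()):
        best_j, best_i = 0.0, None
        for i, ps in enumerate(pred_sets):
            union = len(planted | ps)
            j = len(planted & ps) / union if union else 0.0
            if j > best_j:
                best_j, best_i = j, i
        recovered = best_j >= match_threshold
        n_recovered += recovered
        per_module.append(
            {"module_id": module.module_id, "best_jaccard": best_j,
             "best_bicluster": predicted[best_i].bicluster_id if best_i is not None else None,
             "recovered": bool(recovered)}
        )
        if recovered:
            planted_elab = set(module.elaborated_a) | set(module.elaborated_b)
            pred_elab = set()
            bc = predicted[best_i]
            for sid in bc.sides:
                pred_elab |= set(bc.sides[sid].elaborated_genes)
            elab_tp += len(pred_elab & planted_elab)
            elab_fp += len(pred_elab - planted_elab)
            elab_fn += len(planted_elab - pred_elab)
    n_modules = len(truth.modules)
    return {
        "per_module": per_module,
        "recovery_fraction": (n_recovered / n_modules) if n_modules else 0.0,
        "elaboration_precision": elab_tp / (elab_tp + elab_fp) if (elab_tp + elab_fp) else 0.0,
        "elaboration_recall": elab_tp / (elab_tp + elab_fn) if (elab_tp + elab_fn) else 0.0,
    }


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def consensus_identity(found: str, planted: str) -> float:
    """Best ungapped-alignment identity of ``found`` vs ``planted``.

    Maximum over all offsets and both orientations of (matching positions)
    / len(planted); used to decide whether a discovered motif recovers the
    planted consensus.
    """
    best = 0.0
    for cand in (found, revcomp(found)):
        for off in range(-(len(planted) - 1), len(cand)):
            matches = 0
            for i, base in enumerate(planted):
                j = off + i
                if 0 <= j < len(cand) and cand[j] == base:
                    matches += 1
            best = max(best, matches / len(planted))
    return best


# ---------------------------------------------------------------------------
# file bundle
# ---------------------------------------------------------------------------

def write_pair_dataset(ds_a: SpeciesDataset, ds_b: SpeciesDataset,
                       families: Sequence[OrthologFamily], truth: PlantedTruth,
                       out_dir) -> None:
    """Emit the generated data in exactly the formats the readers consume,
    plus the ground truth as JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for ds in (ds_a, ds_b):
        sid = ds.species_id
        mscm_io.write_expression_matrix(ds.expression, out / f"{sid}.expression.tsv")
        mscm_io.write_promoters_fasta(ds.promoters, out / f"{sid}.promoters.fasta")
        mscm_io.write_network_sif(ds.network, out / f"{sid}.network.sif")
        for ns, terms in ds.annotations.items():
            mscm_io.write_annotation_gmt(terms, out / f"{sid}.{ns}.gmt")
    mscm_io.write_ortholog_families(families, ds_a.species_id, ds_b.species_id,
                                    out / "families.tsv")
    (out / "truth.json").write_text(json.dumps(truth.to_dict(), sort_keys=True, indent=1))


def read_pair_dataset(in_dir) -> Tuple[SpeciesDataset, SpeciesDataset,
                                       List[OrthologFamily], PlantedTruth]:
    """Load a directory written by :func:`write_pair_dataset`."""
    path = Path(in_dir)
    truth = PlantedTruth.from_dict(json.loads((path / "truth.json").read_text()))
    p = truth.params
    datasets = []
    for sid in (p.species_a, p.species_b):
        expr = mscm_io.read_expression_matrix(path / f"{sid}.expression.tsv")
        promoters = mscm_io.read_promoters_fasta(path / f"{sid}.promoters.fasta")
        network = mscm_io.read_network_sif(path / f"{sid}.network.sif")
        annotations = {}
        for gmt in sorted(path.glob(f"{sid}.*.gmt")):
            ns = gmt.name.split(".")[-2]
            annotations[ns] = mscm_io.read_annotation_gmt(gmt)
        datasets.append(
            SpeciesDataset(
                species_id=sid, expression=expr, promoters=promoters,
                network=network, annotations=annotations,
                gene_universe=tuple(expr.index),
            )
        )
    families = mscm_io.read_ortholog_families(
        path / "families.tsv", p.species_a, p.species_b,
        datasets[0].gene_universe, datasets[1].gene_universe,
    )
    return datasets[0], datasets[1], families, truth
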