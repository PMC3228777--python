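"""Post-analytic layer over a detected biclustering.

Combines each bicluster's statistics into one meta-analytic z-score
(Stouffer's method), tests functional-annotation enrichment
(hypergeometric, assignment at raw p < 0.05 with BH q reported for the
record), links related biclusters into a typed network, infers operons
from identical promoter motif patterns, and exports GraphML/SIF files.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from mscm.model import AnnotationTerm, Bicluster, Motif, SpeciesDataset
from mscm.motifs import motif_similarity
from mscm.scoring import SpeciesContext, empirical_residual_p

ASSIGNMENT_P = 0.05


# ---------------------------------------------------------------------------
# Stouffer combination
# ---------------------------------------------------------------------------

def stouffer_bicluster_score(components: Sequence) -> float:
    """Stouffer's z: sum(z_i) / sqrt(k) with z_i = Phi^-1(1 - p_i).

    ``components`` is a sequence of one-sided p-values in (0, 1], each
    oriented so that small p favors a good bicluster; entries may also be
    (p, direction) tuples with direction +1/-1 to flip a component's sign.
    Missing components (None) are skipped, shrinking k.
    """
    zs = []
    for comp in components:
        if comp is None:
            continue
        if isinstance(comp, tuple):
            p, direction = comp
        else:
            p, direction = comp, 1.0
        if not (0.0 < p <= 1.0):
            raise ValueError(f"p-value {p!r} outside (0, 1]")
        zs.append(float(direction) * stats.norm.isf(p))
    if not zs:
        raise ValueError("need at least one component")
    return float(np.sum(zs) / math.sqrt(len(zs)))


def bicluster_component_pvalues(
    bicluster: Bicluster,
    species: str,
    ctx: SpeciesContext,
    best_enrichment_p: Optional[float] = None,
) -> List[Optional[float]]:
    """The fixed-order statistic components entering the Stouffer score:
    residual empirical p, motif mean p (Fisher over genes), network
    cohesion p, best enrichment p.  Unavailable components are None."""
    side = bicluster.side(species)
    residual = side.score_components.get("residual")
    p_resid = (
        empirical_residual_p(ctx, residual, len(side.genes), len(side.conditions))
        if residual is not None else None
    )

    p_motif: Optional[float] = None
    if side.motifs:
        logps = []
        for gene in side.genes:
            vals = [m.hits[gene].logp for m in side.motifs if gene in m.hits]
            if vals:
                logps.append(float(np.mean(vals)))
        if logps:
            chi2 = -2.0 * sum(logps)
            p_motif = float(stats.chi2.sf(chi2, 2 * len(logps)))

    net_score = side.score_components.get("network_score")
    p_net = float(10.0 ** (-net_score)) if net_score is not None else None

    clamp = lambda p: None if p is None else min(max(p, 1e-300), 1.0)
    return [clamp(p_resid), clamp(p_motif), clamp(p_net), clamp(best_enrichment_p)]


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

def annotation_enrichment(
    member_genes: Iterable[str],
    namespace: Dict[str, AnnotationTerm],
    universe: Iterable[str],
) -> Tuple[pd.DataFrame, Set[str]]:
    """One-sided hypergeometric upper-tail enrichment per testable term.

    Returns (table sorted by ascending p, assigned term set).  Assignment
    uses raw p < 0.05; Benjamini-Hochberg q is reported alongside but not
    used for assignment.
    """
    universe = set(universe)
    members = set(member_genes) & universe
    N, n = len(universe), len(members)
    rows = []
    for term in sorted(namespace):
        t = namespace[term]
        if not t.testable:
            continue
        term_genes = t.genes & universe
        K = len(term_genes)
        if K == 0:
            continue
        k = len(term_genes & members)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((term, t.description, p, k, K))
    if not rows:
        return (
            pd.DataFrame(columns=["term", "description", "p", "q", "overlap", "term_size"]),
            set(),
        )
    df = pd.DataFrame(rows, columns=["term", "description", "p", "overlap", "term_size"])
    df["q"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    df = df[["term", "description", "p", "q", "overlap", "term_size"]]
    df = df.sort_values(["p", "term"], kind="stable").reset_index(drop=True)
    assigned = set(df.loc[df["p"] < ASSIGNMENT_P, "term"])
    return df, assigned


# ---------------------------------------------------------------------------
# bicluster network
# ---------------------------------------------------------------------------

@dataclass
class BiclusterNetwork:
    """Graph of biclusters: node size attributes mirror gene/condition
    counts; typed edges mark shared assigned annotations, overlapping
    membership, or similar motifs."""

    graph: nx.MultiGraph = field(default_factory=nx.MultiGraph)

    @property
    def nodes(self):
        return self.graph.nodes

    @property
    def edges(self):
        return self.graph.edges


@dataclass
class RelatedThresholds:
    min_jaccard: float = 0.1
    min_motif_sim: float = 0.8


def _gene_jaccard(bc1: Bicluster, bc2: Bicluster) -> float:
    """Per-species Jaccard of (core + elaborated) gene sets, maximized
    over the species the two biclusters share."""
    best = 0.0
    for sid in set(bc1.sides) & set(bc2.sides):
        g1, g2 = set(bc1.side(sid).genes), set(bc2.side(sid).genes)
        union = g1 | g2
        if union:
            best = max(best, len(g1 & g2) / len(union))
    return best


def related_biclusters(
    biclusters: Sequence[Bicluster],
    assignments: Optional[Dict[int, Dict[str, Set[str]]]] = None,
    thresholds: Optional[RelatedThresholds] = None,
) -> BiclusterNetwork:
    """Build the bicluster network.

    ``assignments`` maps bicluster id -> namespace -> assigned terms (from
    :func:`annotation_enrichment`).  For each unordered pair one edge is
    emitted per satisfied criterion: gene overlap (Jaccard), motif
    similarity, or a shared assigned term per namespace; the edge weight
    is the criterion's statistic.  No self-edges.
    """
    th = thresholds or RelatedThresholds()
    assignments = assignments or {}
    net = BiclusterNetwork()
    for bc in biclusters:
        n_genes = sum(len(side.genes) for side in bc.sides.values())
        n_conds = sum(len(side.conditions) for side in bc.sides.values())
        residual = float(np.mean([
            side.score_components.get("residual", float("nan"))
            for side in bc.sides.values()
        ]))
        top_terms = {}
        for ns, terms in assignments.get(bc.bicluster_id, {}).items():
            if terms:
                top_terms[ns] = sorted(terms)[0]
        net.graph.add_node(
            bc.bicluster_id,
            width_attr=n_genes,
            height_attr=n_conds,
            residual=residual,
            **{f"top_{ns}": term for ns, term in top_terms.items()},
        )
    for bc1, bc2 in itertools.combinations(biclusters, 2):
        i, j = bc1.bicluster_id, bc2.bicluster_id
        jac = _gene_jaccard(bc1, bc2)
        if jac >= th.min_jaccard:
            net.graph.add_edge(i, j, key="gene-overlap", edge_type="gene-overlap",
                               weight=float(jac))
        sims = [
            motif_similarity(m1.pwm, m2.pwm)
            for sid in set(bc1.sides) & set(bc2.sides)
            for m1 in bc1.side(sid).motifs
            for m2 in bc2.side(sid).motifs
        ]
        if sims and max(sims) >= th.min_motif_sim:
            net.graph.add_edge(i, j, key="motif-similarity", edge_type="motif-similarity",
                               weight=float(max(sims)))
        a1, a2 = assignments.get(i, {}), assignments.get(j, {})
        for ns in sorted(set(a1) & set(a2)):
            shared = a1[ns] & a2[ns]
            if shared:
                net.graph.add_edge(i, j, key=f"shared-{ns}", edge_type=f"shared-{ns}",
                                   weight=float(len(shared)))
    return net


# ---------------------------------------------------------------------------
# operon inference from motif patterns
# ---------------------------------------------------------------------------

#: best hits weaker than this natural-log p do not count as pattern members
OPERON_HIT_LOGP = math.log(1e-3)


def _motif_pattern(motifs: Sequence[Motif], gene: str,
                   logp_max: float) -> List[Tuple[int, str, int]]:
    """The ordered, stranded motif arrangement on one promoter:
    [(motif_id, strand, start), ...] sorted along the promoter."""
    events = []
    for motif in motifs:
        hit = motif.hits.get(gene)
        if hit is not None and hit.logp <= logp_max:
            events.append((hit.start, motif.motif_id, hit.strand))
    events.sort()
    return [(mid, strand, start) for start, mid, strand in events]


def _patterns_match(p1, p2, tolerance_nt: int) -> bool:
    if len(p1) != len(p2) or not p1:
        return False
    if [(m, s) for m, s, _ in p1] != [(m, s) for m, s, _ in p2]:
        return False
    off1, off2 = p1[0][2], p2[0][2]
    return all(
        abs((a[2] - off1) - (b[2] - off2)) <= tolerance_nt
        for a, b in zip(p1, p2)
    )


def infer_operons(
    motifs: Sequence[Motif],
    member_genes: Sequence[str],
    tolerance_nt: int = 5,
    hit_logp_max: float = OPERON_HIT_LOGP,
) -> List[Set[str]]:
    """Partition member genes into putative operons by identical promoter
    motif patterns.

    Two genes group together when their promoters carry the same motif
    ids, in the same order and strands, with pairwise start offsets
    within ``tolerance_nt`` after aligning on the first shared motif;
    transitive closure forms the groups.  Genes with no qualifying hits
    are singletons.
    """
    patterns = {g: _motif_pattern(motifs, g, hit_logp_max) for g in member_genes}
    graph = nx.Graph()
    graph.add_nodes_from(member_genes)
    genes = list(member_genes)
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            if _patterns_match(patterns[genes[i]], patterns[genes[j]], tolerance_nt):
                graph.add_edge(genes[i], genes[j])
    return [set(c) for c in sorted(nx.connected_components(graph), key=lambda c: sorted(c)[0])]


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------

def export_bicluster_network(network: BiclusterNetwork, out_prefix) -> List[str]:
    """Write the bicluster network as GraphML and SIF; returns file paths."""
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    graphml_path = out_prefix.with_suffix(".graphml")
    sif_path = out_prefix.with_suffix(".sif")
    export = nx.MultiGraph()
    for node, data in sorted(network.graph.nodes(data=True)):
        export.add_node(node, **{k: v for k, v in sorted(data.items())})
    for u, v, key, data in sorted(network.graph.edges(keys=True, data=True)):
        export.add_edge(u, v, key=key, **{k: v for k, v in sorted(data.items())})
    nx.write_graphml(export, graphml_path, named_key_ids=True)
    with sif_path.open("w") as fh:
        for u, v, key in sorted(network.graph.edges(keys=True)):
            a, b = sorted((u, v))
            fh.write(f"{a}\t{key}\t{b}\n")
    return [str(graphml_path), str(sif_path)]


def export_gene_network(dataset: SpeciesDataset, genes: Iterable[str], out_prefix) -> List[str]:
    """Write the induced association subnetwork on ``genes`` with edge
    types preserved, as GraphML and SIF."""
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    present = [g for g in genes if g in dataset.network]
    sub = nx.Graph()
    sub.add_nodes_from(sorted(present))
    induced = nx.induced_subgraph(dataset.network, present)
    for u, v, data in induced.edges(data=True):
        sub.add_edge(u, v, types="|".join(sorted(data.get("types", {"assoc"}))))
    graphml_path = out_prefix.with_suffix(".graphml")
    sif_path = out_prefix.with_suffix(".sif")
    nx.write_graphml(sub, graphml_path, named_key_ids=True)
    with sif_path.open("w") as fh:
        for u, v, data in sorted(sub.edges(data=True), key=lambda e: (min(e[0], e[1]), max(e[0], e[1]))):
            a, b = (u, v) if u <= v else (v, u)
            for etype in data["types"].split("|"):
                fh.write(f"{a}\t{etype}\t{b}\n")
    return [str(graphml_path), str(sif_path)]


# ---------------------------------------------------------------------------
# whole-run post-processing
# ---------------------------------------------------------------------------

@dataclass
class PostprocessResult:
    #: bicluster id -> species -> namespace -> enrichment table
    enrichment: Dict[int, Dict[str, Dict[str, pd.DataFrame]]]
    #: bicluster id -> namespace -> assigned terms (union over species)
    assignments: Dict[int, Dict[str, Set[str]]]
    #: bicluster id -> species -> operon groups
    operons: Dict[int, Dict[str, List[Set[str]]]]
    network: BiclusterNetwork
    #: bicluster id -> Stouffer z
    stouffer: Dict[int, float]


def postprocess_run(
    biclusters: Sequence[Bicluster],
    datasets: Dict[str, SpeciesDataset],
    contexts: Optional[Dict[str, SpeciesContext]] = None,
    thresholds: Optional[RelatedThresholds] = None,
    seed: int = 0,
) -> PostprocessResult:
    """Enrichment, Stouffer scores, operons and the bicluster network for
    a completed detection/elaboration run.  Sets ``stouffer_z`` on each
    bicluster in place."""
    if contexts is None:
        contexts = {
            sid: SpeciesContext(ds, seed=seed + i)
            for i, (sid, ds) in enumerate(sorted(datasets.items()))
        }
    enrichment: Dict[int, Dict[str, Dict[str, pd.DataFrame]]] = {}
    assignments: Dict[int, Dict[str, Set[str]]] = {}
    operons: Dict[int, Dict[str, List[Set[str]]]] = {}
    stouffer: Dict[int, float] = {}
    for bc in biclusters:
        enrichment[bc.bicluster_id] = {}
        assignments[bc.bicluster_id] = {}
        operons[bc.bicluster_id] = {}
        best_p: Optional[float] = None
        for sid, side in bc.sides.items():
            ds = datasets[sid]
            enrichment[bc.bicluster_id][sid] = {}
            for ns, terms in sorted(ds.annotations.items()):
                table, assigned = annotation_enrichment(side.genes, terms, ds.gene_universe)
                enrichment[bc.bicluster_id][sid][ns] = table
                assignments[bc.bicluster_id].setdefault(ns, set()).update(assigned)
                if len(table):
                    p0 = float(table["p"].iloc[0])
                    best_p = p0 if best_p is None else min(best_p, p0)
            operons[bc.bicluster_id][sid] = infer_operons(side.motifs, side.genes)
        z_parts = []
        for sid in bc.sides:
            comps = bicluster_component_pvalues(bc, sid, contexts[sid], best_p)
            comps = [c for c in comps if c is not None]
            if comps:
                z_parts.append(stouffer_bicluster_score(comps))
        z = float(np.mean(z_parts)) if z_parts else 0.0
        bc.stouffer_z = z
        stouffer[bc.bicluster_id] = z
    network = related_biclusters(biclusters, assignments, thresholds)
    return PostprocessResult(
        enrichment=enrichment,
        assignments=assignments,
        operons=operons,
        network=network,
        stouffer=stouffer,
    )
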