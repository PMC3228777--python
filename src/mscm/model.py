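"""Domain types shared across the package.

The central objects are :class:`SpeciesDataset` (one organism's expression
matrix, promoter sequences, association network and annotation sets),
:class:`OrthologFamily` / :class:`OrthologPair` (putative homology between
the two organisms), :class:`Bicluster` (a conserved module plus its
species-specific elaborations) and :class:`Motif` (a PWM with per-promoter
hits).  All containers are plain dataclasses over pandas / networkx /
numpy objects; serialization helpers live at the bottom of the module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import networkx as nx
import numpy as np
import pandas as pd

PROMOTER_ALPHABET = frozenset("ACGTN")

#: association edge types recognised in SIF inputs (free-form labels are
#: still accepted; these are the conventional ones)
EDGE_TYPES = (
    "operon",
    "metabolic-pathway",
    "phylogenetic-profile",
    "protein-interaction",
    "cog-code",
)


@dataclass(frozen=True)
class AnnotationTerm:
    """One functional-annotation term (GO / KEGG / COG) with its gene set."""

    term: str
    description: str
    genes: frozenset
    #: terms with fewer than 2 member genes are kept but never tested
    testable: bool = True


# namespace -> term -> AnnotationTerm
AnnotationMap = Dict[str, Dict[str, AnnotationTerm]]


@dataclass
class SpeciesDataset:
    """All data for one organism.

    ``expression`` is a genes x conditions DataFrame of log-ratios with NaN
    for missing measurements.  ``promoters`` maps gene id to its upstream
    sequence, stored 5'->3' toward the gene start; coordinates used by the
    motif scanner are 0-based half-open on that stored string.
    """

    species_id: str
    expression: pd.DataFrame
    promoters: Dict[str, str] = field(default_factory=dict)
    network: nx.Graph = field(default_factory=nx.Graph)
    annotations: AnnotationMap = field(default_factory=dict)
    gene_universe: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.gene_universe:
            self.gene_universe = tuple(self.expression.index)

    @property
    def conditions(self) -> Tuple[str, ...]:
        return tuple(self.expression.columns)

    def validate(self) -> List[str]:
        """Check the dataset invariants.

        Hard violations (duplicate gene ids, empty expression, bad promoter
        alphabet) raise ``ValueError``; genes referenced by promoters /
        network / annotations but absent from the gene universe are
        tolerated and returned as warning strings.
        """
        issues: List[str] = []
        universe = set(self.gene_universe)
        if len(universe) != len(self.gene_universe):
            raise ValueError(f"{self.species_id}: duplicate gene ids in gene_universe")
        if len(set(self.expression.index)) != len(self.expression.index):
            dup = self.expression.index[self.expression.index.duplicated()][0]
            raise ValueError(f"{self.species_id}: duplicate gene id in expression: {dup!r}")
        assayed = set(self.expression.index) & universe
        if not assayed:
            raise ValueError(f"{self.species_id}: no assayed gene is in the gene universe")
        for gene, seq in self.promoters.items():
            bad = set(seq) - PROMOTER_ALPHABET
            if bad:
                raise ValueError(
                    f"{self.species_id}: promoter of {gene!r} contains invalid "
                    f"character(s) {sorted(bad)}"
                )
            if gene not in universe:
                issues.append(f"promoter gene {gene!r} not in gene universe")
        for gene in self.network.nodes:
            if gene not in universe:
                issues.append(f"network gene {gene!r} not in gene universe")
        for ns, terms in self.annotations.items():
            for term in terms.values():
                for gene in term.genes - universe:
                    issues.append(f"{ns} term {term.term!r} gene {gene!r} not in gene universe")
        return issues


@dataclass(frozen=True)
class OrthologFamily:
    """A putative homology family spanning species A and B.

    Families may be one-to-one, one-to-many or many-to-many.  ``weights``
    optionally carries per member-pair similarity scores in [0, 1].
    """

    family_id: str
    members_a: frozenset
    members_b: frozenset
    weights: Tuple[Tuple[str, str, float], ...] = ()

    def __post_init__(self) -> None:
        if not self.members_a or not self.members_b:
            raise ValueError(f"family {self.family_id}: empty member set on one side")

    @property
    def candidate_pairs(self) -> List[Tuple[str, str]]:
        return [(a, b) for a in sorted(self.members_a) for b in sorted(self.members_b)]


@dataclass(frozen=True)
class OrthologPair:
    """One gene per species chosen within a family, with the joint
    membership score under which it was selected."""

    family_id: str
    gene_a: str
    gene_b: str
    selection_score: float = 0.0

    def key(self) -> Tuple[str, str]:
        return (self.gene_a, self.gene_b)


@dataclass(frozen=True)
class MotifHit:
    start: int          # 0-based offset of the match on the stored promoter
    strand: str         # "+" or "-"
    logp: float         # natural-log p-value, <= 0


@dataclass
class Motif:
    """A position weight matrix with per-promoter best hits.

    ``pwm`` is a (width, 4) probability matrix in A, C, G, T column order;
    every row sums to 1.  ``hits`` maps gene id to the best hit of this
    motif on that gene's promoter.  ``evalue`` is a monotone surrogate for
    motif unexpectedness: the Fisher combination of per-sequence best-hit
    p-values times the number of width/restart hypotheses searched.
    """

    motif_id: int
    pwm: np.ndarray
    hits: Dict[str, MotifHit] = field(default_factory=dict)
    evalue: float = float("inf")

    @property
    def width(self) -> int:
        return int(self.pwm.shape[0])

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in np.asarray(self.pwm).argmax(axis=1))

    def validate(self, promoters: Optional[Dict[str, str]] = None) -> None:
        pwm = np.asarray(self.pwm, dtype=float)
        if pwm.ndim != 2 or pwm.shape[1] != 4:
            raise ValueError("pwm must be (width, 4)")
        if not np.allclose(pwm.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("pwm rows must each sum to 1")
        for gene, hit in self.hits.items():
            if hit.logp > 0:
                raise ValueError(f"hit logp must be <= 0 (gene {gene!r})")
            if promoters is not None and gene in promoters:
                if hit.start + self.width > len(promoters[gene]):
                    raise ValueError(f"hit on {gene!r} extends past promoter end")


@dataclass
class BiclusterSide:
    """One species' half of a bicluster."""

    core_genes: List[str] = field(default_factory=list)
    elaborated_genes: List[str] = field(default_factory=list)
    conditions: List[str] = field(default_factory=list)
    motifs: List[Motif] = field(default_factory=list)
    # residual >= 0, motif_mean_logp <= 0, network_score >= 0
    score_components: Dict[str, float] = field(default_factory=dict)

    @property
    def genes(self) -> List[str]:
        return list(self.core_genes) + list(self.elaborated_genes)


@dataclass
class Bicluster:
    """A conserved bicluster: paired cores across two species, plus
    per-species elaborations, condition subsets and discovered motifs.

    Species-specific biclusters (optional step 4) use the same container
    with a single side and an empty ``core_pairs`` list.
    """

    bicluster_id: int
    sides: Dict[str, BiclusterSide]
    core_pairs: List[OrthologPair] = field(default_factory=list)
    combined_score: float = float("nan")
    stouffer_z: Optional[float] = None

    @property
    def species_ids(self) -> List[str]:
        return list(self.sides)

    def side(self, species_id: str) -> BiclusterSide:
        return self.sides[species_id]

    def condition_fraction(self, species_id: str, n_total: int) -> float:
        return len(self.sides[species_id].conditions) / float(n_total)

    def validate(self, paired: bool = True) -> None:
        for sid, side in self.sides.items():
            overlap = set(side.core_genes) & set(side.elaborated_genes)
            if overlap:
                raise ValueError(
                    f"bicluster {self.bicluster_id} species {sid}: core and "
                    f"elaborated sets overlap: {sorted(overlap)}"
                )
            if not side.conditions:
                raise ValueError(
                    f"bicluster {self.bicluster_id} species {sid}: empty condition set"
                )
        if paired and self.core_pairs:
            ids = list(self.sides)
            if len(ids) != 2:
                raise ValueError("a paired bicluster needs exactly two sides")
            sid_a, sid_b = ids
            genes_a = [p.gene_a for p in self.core_pairs]
            genes_b = [p.gene_b for p in self.core_pairs]
            if len(set(genes_a)) != len(genes_a) or len(set(genes_b)) != len(genes_b):
                raise ValueError(
                    f"bicluster {self.bicluster_id}: a gene appears in two core pairs"
                )
            if set(genes_a) != set(self.sides[sid_a].core_genes):
                raise ValueError(
                    f"bicluster {self.bicluster_id}: species {sid_a} core does not "
                    "match the paired genes"
                )
            if set(genes_b) != set(self.sides[sid_b].core_genes):
                raise ValueError(
                    f"bicluster {self.bicluster_id}: species {sid_b} core does not "
                    "match the paired genes"
                )


# ---------------------------------------------------------------------------
# serialization (JSON-friendly dicts; used by io.write_result_bundle)
# ---------------------------------------------------------------------------

def motif_to_dict(motif: Motif) -> dict:
    return {
        "motif_id": motif.motif_id,
        "width": motif.width,
        "evalue": motif.evalue,
        "pwm": [[float(v) for v in row] for row in np.asarray(motif.pwm)],
        "hits": {
            gene: {"start": h.start, "strand": h.strand, "logp": h.logp}
            for gene, h in sorted(motif.hits.items())
        },
    }


def motif_from_dict(d: dict) -> Motif:
    return Motif(
        motif_id=int(d["motif_id"]),
        pwm=np.asarray(d["pwm"], dtype=float),
        hits={
            gene: MotifHit(start=int(h["start"]), strand=h["strand"], logp=float(h["logp"]))
            for gene, h in d.get("hits", {}).items()
        },
        evalue=float(d["evalue"]),
    )


def bicluster_to_dict(bc: Bicluster) -> dict:
    return {
        "bicluster_id": bc.bicluster_id,
        "combined_score": bc.combined_score,
        "stouffer_z": bc.stouffer_z,
        "core_pairs": [
            {
                "family_id": p.family_id,
                "gene_a": p.gene_a,
                "gene_b": p.gene_b,
                "selection_score": p.selection_score,
            }
            for p in bc.core_pairs
        ],
        "sides": {
            sid: {
                "core_genes": list(side.core_genes),
                "elaborated_genes": list(side.elaborated_genes),
                "conditions": list(side.conditions),
                "score_components": dict(side.score_components),
                "motifs": [motif_to_dict(m) for m in side.motifs],
            }
            for sid, side in bc.sides.items()
        },
    }


def bicluster_from_dict(d: dict) -> Bicluster:
    return Bicluster(
        bicluster_id=int(d["bicluster_id"]),
        combined_score=float(d["combined_score"]) if d["combined_score"] is not None else float("nan"),
        stouffer_z=d.get("stouffer_z"),
        core_pairs=[
            OrthologPair(
                family_id=p["family_id"],
                gene_a=p["gene_a"],
                gene_b=p["gene_b"],
                selection_score=float(p.get("selection_score", 0.0)),
            )
            for p in d.get("core_pairs", [])
        ],
        sides={
            sid: BiclusterSide(
                core_genes=list(s["core_genes"]),
                elaborated_genes=list(s["elaborated_genes"]),
                conditions=list(s["conditions"]),
                score_components={k: float(v) for k, v in s.get("score_components", {}).items()},
                motifs=[motif_from_dict(m) for m in s.get("motifs", [])],
            )
            for sid, s in d["sides"].items()
        },
    )
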