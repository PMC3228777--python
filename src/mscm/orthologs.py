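"""Ortholog-family resolution: the candidate pairing structure between
the two species, and data-driven selection of one gene pair per family.

Selection is lazy: the best pair within a family is chosen at the moment
the family is proposed for addition to a bicluster, under the joint
membership score of the current bicluster state.  This honors the fact
that the right representative of a one-to-many family depends on which
module is being built.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Sequence, Set, Tuple

from mscm.model import OrthologFamily, OrthologPair, SpeciesDataset


@dataclass
class FamilyIndex:
    families: Dict[str, OrthologFamily]
    by_gene_a: Dict[str, List[str]]          # gene -> family ids containing it
    by_gene_b: Dict[str, List[str]]
    candidate_pairs: Dict[str, List[Tuple[str, str]]]
    overlapping_genes_a: Set[str]            # genes in more than one family
    overlapping_genes_b: Set[str]
    species_specific_a: Set[str]             # genes in no family (elaboration-only)
    species_specific_b: Set[str]

    @property
    def family_ids(self) -> List[str]:
        return list(self.families)


def build_family_index(families: Sequence[OrthologFamily],
                       dataset_a: SpeciesDataset,
                       dataset_b: SpeciesDataset) -> FamilyIndex:
    """Index families by gene and enumerate candidate pairs.

    The candidate pair list of a family is the Cartesian product
    members_a x members_b.  Genes of either species that appear in no
    family are marked species-specific-only: eligible for elaboration,
    never for a conserved core.
    """
    fam_map: Dict[str, OrthologFamily] = {}
    by_a: Dict[str, List[str]] = {}
    by_b: Dict[str, List[str]] = {}
    pairs: Dict[str, List[Tuple[str, str]]] = {}
    for fam in families:
        fam_map[fam.family_id] = fam
        pairs[fam.family_id] = fam.candidate_pairs
        for g in fam.members_a:
            by_a.setdefault(g, []).append(fam.family_id)
        for g in fam.members_b:
            by_b.setdefault(g, []).append(fam.family_id)
    overlap_a = {g for g, fams in by_a.items() if len(fams) > 1}
    overlap_b = {g for g, fams in by_b.items() if len(fams) > 1}
    specific_a = set(dataset_a.gene_universe) - set(by_a)
    specific_b = set(dataset_b.gene_universe) - set(by_b)
    return FamilyIndex(
        families=fam_map, by_gene_a=by_a, by_gene_b=by_b,
        candidate_pairs=pairs,
        overlapping_genes_a=overlap_a, overlapping_genes_b=overlap_b,
        species_specific_a=specific_a, species_specific_b=specific_b,
    )


def choose_pair_for_family(
    family: OrthologFamily,
    used_genes_a: Set[str],
    used_genes_b: Set[str],
    membership_scorer: Callable[[str, str], float],
) -> Optional[OrthologPair]:
    """Select the candidate pair maximizing the joint membership score.

    Candidates whose genes are already used by another family's selected
    pair in this bicluster are excluded; if none remain the family
    contributes no pair.  Bit-identical scores break ties toward the
    lexicographically smaller gene_a, then gene_b.
    """
    candidates = [
        (a, b)
        for a, b in family.candidate_pairs
        if a not in used_genes_a and b not in used_genes_b
    ]
    if not candidates:
        return None
    best: Optional[Tuple[float, str, str]] = None
    for a, b in candidates:  # candidate_pairs is lexicographically sorted
        score = membership_scorer(a, b)
        if best is None or score > best[0]:
            best = (score, a, b)
    return OrthologPair(family_id=family.family_id, gene_a=best[1], gene_b=best[2],
                        selection_score=best[0])
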