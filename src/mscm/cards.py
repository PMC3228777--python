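"""Per-bicluster report cards and the ortholog translation utility.

A BiclusterCard aggregates, for one bicluster in one species, the
statistics, enrichment summary, gene tables, experiments, motifs,
enrichment tables, related biclusters and plot data, mirroring the
expandable-tab report of the original web resource.  Cards are static
artifacts: JSON (schema-versioned) and plain HTML with an embedded
machine-readable metadata block per page.
"""

from __future__ import annotations

import html
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set

import numpy as np

from mscm.model import Bicluster, Motif, OrthologFamily, SpeciesDataset
from mscm.postprocess import PostprocessResult

CARD_SCHEMA_VERSION = "1.0"

SECTIONS = (
    "statistics",
    "enrichment_summary",
    "core_gene_table",
    "elaborated_gene_table",
    "experiments",
    "motifs",
    "enrichment_tables",
    "related",
    "plots_data",
    "coupled_id",
)


@dataclass
class BiclusterCard:
    bicluster_id: int
    species_id: str
    schema_version: str = CARD_SCHEMA_VERSION
    statistics: dict = field(default_factory=dict)
    enrichment_summary: dict = field(default_factory=dict)
    core_gene_table: list = field(default_factory=list)
    elaborated_gene_table: list = field(default_factory=list)
    experiments: dict = field(default_factory=dict)
    motifs: list = field(default_factory=list)
    enrichment_tables: dict = field(default_factory=dict)
    related: list = field(default_factory=list)
    plots_data: dict = field(default_factory=dict)
    coupled_id: Optional[dict] = None

    def to_dict(self) -> dict:
        return {
            "schema_version": self.schema_version,
            "bicluster_id": self.bicluster_id,
            "species_id": self.species_id,
            **{s: getattr(self, s) for s in SECTIONS},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BiclusterCard":
        return cls(
            bicluster_id=int(d["bicluster_id"]),
            species_id=d["species_id"],
            schema_version=d.get("schema_version", CARD_SCHEMA_VERSION),
            **{s: d[s] for s in SECTIONS},
        )


def _gene_row(gene: str, dataset: SpeciesDataset) -> dict:
    def terms_for(ns: str) -> List[str]:
        return sorted(
            t.term for t in dataset.annotations.get(ns, {}).values() if gene in t.genes
        )
    descriptions = [
        t.description
        for ns in dataset.annotations
        for t in dataset.annotations[ns].values()
        if gene in t.genes and t.description
    ]
    return {
        "locus_tag": gene,
        "gene_name": gene,
        "description": descriptions[0] if descriptions else "",
        "GO": terms_for("GO"),
        "KEGG": terms_for("KEGG"),
        "COG": terms_for("COG"),
    }


def build_card(
    bicluster: Bicluster,
    species: str,
    datasets: Dict[str, SpeciesDataset],
    postprocess_results: PostprocessResult,
) -> BiclusterCard:
    """Assemble the card for one (bicluster, species).

    All sections are populated (empty ones explicitly empty); every number
    is copied from the underlying objects, never recomputed.  A missing
    post-processing result raises ``ValueError`` listing absent sections.
    """
    if postprocess_results is None:
        raise ValueError(f"missing post-process results; absent sections: {list(SECTIONS)}")
    bid = bicluster.bicluster_id
    absent = []
    if bid not in postprocess_results.enrichment:
        absent.append("enrichment_tables")
        absent.append("enrichment_summary")
    if bid not in postprocess_results.stouffer:
        absent.append("statistics")
    if absent:
        raise ValueError(f"post-process results missing for bicluster {bid}; "
                         f"absent sections: {absent}")
    dataset = datasets[species]
    side = bicluster.side(species)
    n_total_conds = len(dataset.expression.columns)
    motif_mean_logp = side.score_components.get("motif_mean_logp", 0.0)
    statistics = {
        "n_core": len(side.core_genes),
        "n_elaborated": len(side.elaborated_genes),
        "n_conditions": len(side.conditions),
        "condition_fraction": len(side.conditions) / n_total_conds if n_total_conds else 0.0,
        "score": bicluster.stouffer_z,
        "residual": side.score_components.get("residual"),
        "motif_mean_p": math.exp(motif_mean_logp) if side.motifs else None,
        "motif_evalues": [m.evalue for m in side.motifs],
    }

    enr = postprocess_results.enrichment[bid].get(species, {})
    summary = {}
    for ns, table in sorted(enr.items()):
        sig = table[table["p"] < 0.05]
        summary[ns] = [
            {"term": r.term, "description": r.description, "p": float(r.p)}
            for r in sig.head(3).itertuples()
        ]
    enrichment_tables = {
        ns: [
            {
                "term": r.term,
                "description": r.description,
                "p": float(r.p),
                "q": float(r.q),
                "overlap": int(r.overlap),
                "term_size": int(r.term_size),
            }
            for r in table.itertuples()
        ]
        for ns, table in sorted(enr.items())
    }

    motifs_section = []
    for motif in side.motifs:
        motifs_section.append(
            {
                "motif_id": motif.motif_id,
                "width": motif.width,
                "evalue": motif.evalue,
                "consensus": motif.consensus,
                "locations": {
                    g: {"start": h.start, "strand": h.strand, "logp": h.logp}
                    for g, h in sorted(motif.hits.items())
                    if g in set(side.genes)
                },
            }
        )

    related = []
    graph = postprocess_results.network.graph
    if bid in graph:
        for _u, other, key, data in sorted(graph.edges(bid, keys=True, data=True)):
            related.append(
                {"bicluster_id": int(other), "criterion": data.get("edge_type", key),
                 "weight": float(data.get("weight", 0.0))}
            )

    genes = side.genes
    present = [g for g in genes if g in dataset.expression.index]
    sub = dataset.expression.loc[present, list(side.conditions)]
    matrix = [[None if not np.isfinite(v) else float(v) for v in row] for row in sub.to_numpy()]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean_profile = np.nanmean(sub.to_numpy(), axis=0) if len(present) else np.array([])
    plots_data = {
        "genes": present,
        "conditions": list(side.conditions),
        "matrix": matrix,
        "mean_profile": [None if not np.isfinite(v) else float(v) for v in mean_profile],
    }

    coupled = None
    others = [sid for sid in bicluster.sides if sid != species]
    if others:
        coupled = {"species_id": others[0], "bicluster_id": bid}

    return BiclusterCard(
        bicluster_id=bid,
        species_id=species,
        statistics=statistics,
        enrichment_summary=summary,
        core_gene_table=[_gene_row(g, dataset) for g in side.core_genes],
        elaborated_gene_table=[_gene_row(g, dataset) for g in side.elaborated_genes],
        experiments={"conditions": list(side.conditions), "metadata": {}},
        motifs=motifs_section,
        enrichment_tables=enrichment_tables,
        related=related,
        plots_data=plots_data,
        coupled_id=coupled,
    )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _card_filename(card: BiclusterCard, ext: str) -> str:
    return f"card_{card.species_id}_{card.bicluster_id:04d}.{ext}"


def _render_html(card: BiclusterCard) -> str:
    meta = {
        "bicluster_id": card.bicluster_id,
        "species_id": card.species_id,
        "gene_names": [r["locus_tag"] for r in card.core_gene_table + card.elaborated_gene_table],
        "condition_names": card.experiments["conditions"],
    }
    def table(rows: List[dict]) -> str:
        if not rows:
            return "<p><em>empty</em></p>"
        head = "".join(f"<th>{html.escape(str(k))}</th>" for k in rows[0])
        body = "".join(
            "<tr>" + "".join(f"<td>{html.escape(str(v))}</td>" for v in r.values()) + "</tr>"
            for r in rows
        )
        return f"<table><tr>{head}</tr>{body}</table>"

    stats_rows = [{"property": k, "value": v} for k, v in card.statistics.items()]
    parts = [
        "<!DOCTYPE html><html><head><meta charset='utf-8'>",
        f"<title>Bicluster {card.bicluster_id} ({card.species_id})</title></head><body>",
        f"<h1>Bicluster {card.bicluster_id} — {html.escape(card.species_id)}</h1>",
        f"<script type='application/json' id='bicluster-metadata'>{json.dumps(meta)}</script>",
        "<h2>Statistics</h2>", table(stats_rows),
        "<h2>Enrichment Summary</h2>",
        table([
            {"namespace": ns, **entry}
            for ns, entries in card.enrichment_summary.items()
            for entry in entries
        ]),
        "<h2>Core Genes</h2>", table(card.core_gene_table),
        "<h2>Elaborated Genes</h2>", table(card.elaborated_gene_table),
        "<h2>Experiments</h2>",
        table([{"condition": c} for c in card.experiments["conditions"]]),
        "<h2>Bicluster Motifs</h2>",
        table([
            {"motif": m["motif_id"], "width": m["width"], "evalue": m["evalue"],
             "consensus": m["consensus"], "n_locations": len(m["locations"])}
            for m in card.motifs
        ]),
        "<h2>Enrichment Analysis</h2>",
        table([
            {"namespace": ns, **row}
            for ns, rows in card.enrichment_tables.items()
            for row in rows
        ]),
        "<h2>Related Biclusters</h2>", table(card.related),
        "</body></html>",
    ]
    return "\n".join(parts)


def render_cards(cards: Sequence[BiclusterCard], out_dir, format: str = "json") -> Dict[str, str]:
    """Write one file per card plus a score-sorted index.

    ``format`` is "json" or "html"; returns {file name: sha256}.
    """
    if format not in ("json", "html"):
        raise ValueError(f"unknown format {format!r}")
    from mscm.io import file_checksum

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: Dict[str, str] = {}
    ranked = sorted(
        cards,
        key=lambda c: (-(c.statistics.get("score") if c.statistics.get("score") is not None else float("-inf")),
                       c.species_id, c.bicluster_id),
    )
    for card in cards:
        name = _card_filename(card, format)
        if format == "json":
            (out / name).write_text(json.dumps(card.to_dict(), sort_keys=True, indent=1))
        else:
            (out / name).write_text(_render_html(card))
        manifest[name] = file_checksum(out / name)
    if format == "json":
        index = [
            {"bicluster_id": c.bicluster_id, "species_id": c.species_id,
             "score": c.statistics.get("score"), "file": _card_filename(c, format)}
            for c in ranked
        ]
        (out / "index.json").write_text(json.dumps(index, indent=1))
        manifest["index.json"] = file_checksum(out / "index.json")
    else:
        rows = "".join(
            f"<tr><td><a href='{_card_filename(c, format)}'>{c.bicluster_id}</a></td>"
            f"<td>{html.escape(c.species_id)}</td><td>{c.statistics.get('score')}</td></tr>"
            for c in ranked
        )
        (out / "index.html").write_text(
            "<!DOCTYPE html><html><head><meta charset='utf-8'><title>Biclusters</title>"
            "</head><body><h1>Biclusters ranked by score</h1>"
            f"<table><tr><th>bicluster</th><th>species</th><th>score</th></tr>{rows}</table>"
            "</body></html>"
        )
        manifest["index.html"] = file_checksum(out / "index.html")
    return manifest


# ---------------------------------------------------------------------------
# ortholog translation
# ---------------------------------------------------------------------------

def translate_orthologs(
    genes: Sequence[str],
    direction: str,
    families: Sequence[OrthologFamily],
) -> Dict[str, List[str]]:
    """Map genes of one species to their ortholog partners in the other.

    ``direction`` is "a_to_b" or "b_to_a".  For each input gene the union
    of partner-side members over all families containing it is returned,
    sorted; genes in no family map to an empty list (with a warning).
    Output preserves input order.
    """
    if direction not in ("a_to_b", "b_to_a"):
        raise ValueError(f"direction must be 'a_to_b' or 'b_to_a', got {direction!r}")
    forward = direction == "a_to_b"
    out: Dict[str, List[str]] = {}
    for gene in genes:
        partners: Set[str] = set()
        found = False
        for fam in families:
            members = fam.members_a if forward else fam.members_b
            if gene in members:
                found = True
                partners |= fam.members_b if forward else fam.members_a
        if not found:
            warnings.warn(f"gene {gene!r} is in no ortholog family")
        out[gene] = sorted(partners)
    return out
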