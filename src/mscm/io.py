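"""Readers and writers for the standard input/output formats.

Inputs: expression TSV (genes x conditions, ``NA`` missing token), promoter
FASTA, SIF association networks, GMT annotation sets, and an
InParanoid-style ortholog family TSV.  Outputs: a result bundle of JSON
biclusters, TSV pair lists, PWM text blocks, SIF/GraphML networks and a
checksummed manifest.

Gene ids are matched case-sensitively after whitespace trimming; no
synonym resolution happens here.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd
from Bio import SeqIO

from mscm.model import (
    AnnotationTerm,
    Bicluster,
    Motif,
    OrthologFamily,
    OrthologPair,
    PROMOTER_ALPHABET,
    bicluster_from_dict,
    bicluster_to_dict,
)

DEFAULT_MISSING_TOKEN = "NA"


class FormatError(ValueError):
    """Malformed input file."""


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_expression_matrix(path, missing_token: str = DEFAULT_MISSING_TOKEN) -> pd.DataFrame:
    """Read a genes x conditions TSV of log-ratios.

    First row holds condition ids, first column gene ids.  Cells are
    decimal reals or ``missing_token`` (stored as NaN, never as zero).
    Duplicate gene ids and ragged rows are hard errors.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    lines = [ln for ln in lines if ln.strip() != ""]
    if not lines:
        raise FormatError(f"{path}: no conditions (empty file)")
    header = lines[0].rstrip("\n").split("\t")
    conditions = [c.strip() for c in header[1:]]
    if not conditions:
        raise FormatError(f"{path}: no conditions")
    n_fields = len(header)
    genes: List[str] = []
    rows: List[List[float]] = []
    seen = set()
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != n_fields:
            raise FormatError(
                f"{path}:{lineno}: ragged row ({len(fields)} fields, expected {n_fields})"
            )
        gene = fields[0].strip()
        if gene in seen:
            raise FormatError(f"{path}:{lineno}: duplicate gene id {gene!r}")
        seen.add(gene)
        values = []
        for cell in fields[1:]:
            cell = cell.strip()
            if cell == missing_token or cell == "":
                values.append(np.nan)
            else:
                try:
                    values.append(float(cell))
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: bad value {cell!r}") from exc
        genes.append(gene)
        rows.append(values)
    return pd.DataFrame(rows, index=genes, columns=conditions, dtype=float)


def read_promoters_fasta(path) -> Dict[str, str]:
    """Read upstream promoter sequences.

    The record id (token before the first whitespace) is the gene id.
    Sequences are upper-cased, U is mapped to T; characters outside
    A/C/G/T/N are errors.  Zero-length records are dropped with a warning.
    """
    path = Path(path)
    promoters: Dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        gene = record.id.strip()
        seq = str(record.seq).upper().replace("U", "T")
        if gene in promoters:
            raise FormatError(f"{path}: duplicate promoter record id {gene!r}")
        if not seq:
            warnings.warn(f"{path}: zero-length promoter record {gene!r} dropped")
            continue
        bad = set(seq) - PROMOTER_ALPHABET
        if bad:
            raise FormatError(
                f"{path}: promoter {gene!r} contains invalid character(s) {sorted(bad)}"
            )
        promoters[gene] = seq
    return promoters


def read_network_sif(path) -> nx.Graph:
    """Read a SIF association network into an undirected labeled graph.

    Lines are ``geneA <sep> type <sep> geneB [geneC ...]``; multi-target
    lines are expanded to one edge per target.  One undirected edge is kept
    per unordered gene pair; its ``types`` attribute accumulates every edge
    type seen for that pair.  Self-loops are dropped with a warning.
    """
    path = Path(path)
    graph = nx.Graph()
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        fields = [f.strip() for f in fields if f.strip()]
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: SIF line has fewer than 3 fields")
        src, etype = fields[0], fields[1]
        graph.add_node(src)
        for dst in fields[2:]:
            if dst == src:
                warnings.warn(f"{path}:{lineno}: self-loop on {src!r} dropped")
                continue
            if graph.has_edge(src, dst):
                graph.edges[src, dst]["types"].add(etype)
            else:
                graph.add_edge(src, dst, types={etype})
    return graph


def read_ortholog_families(
    path,
    species_a: str,
    species_b: str,
    universe_a: Optional[Iterable[str]] = None,
    universe_b: Optional[Iterable[str]] = None,
) -> List[OrthologFamily]:
    """Read an InParanoid-like family table.

    Columns: family_id, species tag, gene id, optional confidence in [0,1].
    Members absent from the corresponding gene universe are dropped with a
    warning; families left empty on either side are discarded with a
    warning.  A species tag other than the two configured ids is an error.
    """
    path = Path(path)
    uni_a = set(universe_a) if universe_a is not None else None
    uni_b = set(universe_b) if universe_b is not None else None
    raw: Dict[str, Dict[str, list]] = {}
    order: List[str] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = [f.strip() for f in line.split("\t")]
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: expected >= 3 fields")
        fam_id, tag, gene = fields[0], fields[1], fields[2]
        conf = float(fields[3]) if len(fields) > 3 and fields[3] != "" else None
        if tag not in (species_a, species_b):
            raise FormatError(
                f"{path}:{lineno}: unknown species tag {tag!r} "
                f"(configured: {species_a!r}, {species_b!r})"
            )
        if fam_id not in raw:
            raw[fam_id] = {"a": [], "b": [], "w": []}
            order.append(fam_id)
        side = "a" if tag == species_a else "b"
        raw[fam_id][side].append(gene)
        if conf is not None:
            raw[fam_id]["w"].append((side, gene, conf))
    families: List[OrthologFamily] = []
    for fam_id in order:
        entry = raw[fam_id]
        members_a, members_b = set(entry["a"]), set(entry["b"])
        if uni_a is not None:
            for g in sorted(members_a - uni_a):
                warnings.warn(f"family {fam_id}: {species_a} member {g!r} unknown, dropped")
            members_a &= uni_a
        if uni_b is not None:
            for g in sorted(members_b - uni_b):
                warnings.warn(f"family {fam_id}: {species_b} member {g!r} unknown, dropped")
            members_b &= uni_b
        if not members_a or not members_b:
            warnings.warn(f"family {fam_id}: empty on one side after filtering, discarded")
            continue
        weights = tuple(
            (g, "", w) if side == "a" else ("", g, w) for side, g, w in entry["w"]
        )
        families.append(
            OrthologFamily(
                family_id=fam_id,
                members_a=frozenset(members_a),
                members_b=frozenset(members_b),
                weights=weights,
            )
        )
    return families


def read_annotation_gmt(path) -> Dict[str, AnnotationTerm]:
    """Read one GMT annotation namespace: term, description, gene list."""
    path = Path(path)
    terms: Dict[str, AnnotationTerm] = {}
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        warnings.warn(f"{path}: empty annotation file")
        return terms
    for lineno, line in enumerate(lines, start=1):
        fields = line.split("\t") if "\t" in line else line.split()
        if not fields or not fields[0].strip():
            raise FormatError(f"{path}:{lineno}: blank term")
        term = fields[0].strip()
        description = fields[1].strip() if len(fields) > 1 else ""
        genes = frozenset(g.strip() for g in fields[2:] if g.strip())
        terms[term] = AnnotationTerm(
            term=term, description=description, genes=genes, testable=len(genes) >= 2
        )
    return terms


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def _canonical_json(obj) -> str:
    return json.dumps(obj, sort_keys=True, indent=1, allow_nan=True)


def write_expression_matrix(expr: pd.DataFrame, path,
                            missing_token: str = DEFAULT_MISSING_TOKEN) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("gene\t" + "\t".join(map(str, expr.columns)) + "\n")
        for gene, row in expr.iterrows():
            cells = [missing_token if pd.isna(v) else repr(float(v)) for v in row]
            fh.write(str(gene) + "\t" + "\t".join(cells) + "\n")


def write_promoters_fasta(promoters: Dict[str, str], path) -> None:
    with Path(path).open("w") as fh:
        for gene in promoters:
            fh.write(f">{gene}\n{promoters[gene]}\n")


def write_network_sif(graph: nx.Graph, path) -> None:
    with Path(path).open("w") as fh:
        # SIF carries edges only; isolated genes are implied by the gene universe
        for u, v, data in sorted(graph.edges(data=True), key=lambda e: (min(e[0], e[1]), max(e[0], e[1]))):
            a, b = (u, v) if u <= v else (v, u)
            for etype in sorted(data.get("types", {"assoc"})):
                fh.write(f"{a}\t{etype}\t{b}\n")


def write_annotation_gmt(terms: Dict[str, AnnotationTerm], path) -> None:
    with Path(path).open("w") as fh:
        for term in sorted(terms):
            t = terms[term]
            fh.write("\t".join([t.term, t.description] + sorted(t.genes)) + "\n")


def write_ortholog_families(families: Sequence[OrthologFamily], species_a: str,
                            species_b: str, path) -> None:
    with Path(path).open("w") as fh:
        for fam in families:
            for g in sorted(fam.members_a):
                fh.write(f"{fam.family_id}\t{species_a}\t{g}\n")
            for g in sorted(fam.members_b):
                fh.write(f"{fam.family_id}\t{species_b}\t{g}\n")


def write_motifs_text(motifs: Sequence[Motif], path) -> None:
    """PWM text format: per motif a header ``MOTIF id width evalue`` then
    ``width`` rows of 4 tab-separated probabilities (A C G T order)."""
    with Path(path).open("w") as fh:
        for motif in motifs:
            fh.write(f"MOTIF\t{motif.motif_id}\t{motif.width}\t{motif.evalue!r}\n")
            for row in np.asarray(motif.pwm):
                fh.write("\t".join(repr(float(v)) for v in row) + "\n")


def read_motifs_text(path) -> List[Motif]:
    motifs: List[Motif] = []
    rows: List[List[float]] = []
    header: Optional[Tuple[int, float]] = None

    def flush():
        if header is not None:
            motifs.append(Motif(motif_id=header[0], pwm=np.asarray(rows, dtype=float),
                                evalue=header[1]))

    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        if line.startswith("MOTIF"):
            flush()
            fields = line.split("\t")
            header = (int(fields[1]), float(fields[3]))
            rows = []
        else:
            rows.append([float(v) for v in line.split("\t")])
    flush()
    return motifs


def write_biclusters_json(biclusters: Sequence[Bicluster], path) -> None:
    Path(path).write_text(_canonical_json([bicluster_to_dict(b) for b in biclusters]))


def read_biclusters_json(path) -> List[Bicluster]:
    return [bicluster_from_dict(d) for d in json.loads(Path(path).read_text())]


def write_pairs_tsv(pairs: Sequence[OrthologPair], path) -> None:
    with Path(path).open("w") as fh:
        fh.write("family_id\tgene_a\tgene_b\tselection_score\n")
        for p in pairs:
            fh.write(f"{p.family_id}\t{p.gene_a}\t{p.gene_b}\t{p.selection_score!r}\n")


def file_checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_result_bundle(run_result, out_dir) -> Dict[str, str]:
    """Write a completed run to ``out_dir`` and return the manifest
    (relative file name -> sha256).

    ``run_result`` is a :class:`mscm.pipeline.RunResult`; reruns with
    identical inputs and seed produce byte-identical files and therefore
    identical checksums.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise FormatError(f"output directory {out_dir} is not writable: {exc}") from exc

    manifest: Dict[str, str] = {}

    def emit(name: str, writer) -> None:
        writer(out_dir / name)
        manifest[name] = file_checksum(out_dir / name)

    emit("biclusters.json", lambda p: write_biclusters_json(run_result.biclusters, p))
    all_pairs = [p for bc in run_result.biclusters for p in bc.core_pairs]
    emit("ortholog_pairs.tsv", lambda p: write_pairs_tsv(all_pairs, p))
    all_motifs = [
        m for bc in run_result.biclusters for side in bc.sides.values() for m in side.motifs
    ]
    emit("motifs.txt", lambda p: write_motifs_text(all_motifs, p))
    if run_result.bicluster_network is not None:
        from mscm.postprocess import export_bicluster_network

        files = export_bicluster_network(run_result.bicluster_network, out_dir / "bicluster_network")
        for f in files:
            manifest[Path(f).name] = file_checksum(f)
    if run_result.config is not None:
        emit("run_config.json", lambda p: Path(p).write_text(_canonical_json(run_result.config)))

    (out_dir / "manifest.json").write_text(_canonical_json(manifest))
    return manifest
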