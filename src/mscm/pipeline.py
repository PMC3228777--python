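"""End-to-end orchestration: load -> detect -> elaborate -> (step 4) ->
postprocess -> cards -> result bundle on disk.

Every random decision derives from the single config seed, so a rerun
with an identical config produces byte-identical output checksums.
"""

from __future__ import annotations

import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np

from mscm import io as mscm_io
from mscm.cards import BiclusterCard, build_card, render_cards
from mscm.config import RunConfig
from mscm.model import Bicluster, OrthologFamily, SpeciesDataset
from mscm.motifs import find_motifs
from mscm.optimize import (
    detect_conserved_biclusters,
    elaborate_bicluster,
    species_specific_biclusters,
)
from mscm.postprocess import PostprocessResult, RelatedThresholds, postprocess_run
from mscm.scoring import SpeciesContext, bicluster_motif_mean

log = logging.getLogger("mscm")


@dataclass
class RunResult:
    biclusters: List[Bicluster]
    species_ids: List[str]
    bicluster_network: Optional[object] = None
    post: Optional[PostprocessResult] = None
    cards: List[BiclusterCard] = field(default_factory=list)
    config: Optional[dict] = None
    manifest: Dict[str, str] = field(default_factory=dict)
    timings: Dict[str, float] = field(default_factory=dict)


def load_species(paths, species_id: Optional[str] = None) -> SpeciesDataset:
    sid = species_id or paths.id
    expr = mscm_io.read_expression_matrix(paths.expression)
    promoters = mscm_io.read_promoters_fasta(paths.promoters) if paths.promoters else {}
    network = mscm_io.read_network_sif(paths.network) if paths.network else None
    annotations = {
        ns: mscm_io.read_annotation_gmt(path) for ns, path in sorted(paths.annotations.items())
    }
    import networkx as nx

    ds = SpeciesDataset(
        species_id=sid,
        expression=expr,
        promoters=promoters,
        network=network if network is not None else nx.Graph(),
        annotations=annotations,
        gene_universe=tuple(expr.index),
    )
    for issue in ds.validate():
        log.warning("%s: %s", sid, issue)
    return ds


def run_pipeline(
    config: RunConfig,
    datasets: Optional[Dict[str, SpeciesDataset]] = None,
    families: Optional[List[OrthologFamily]] = None,
    write_bundle: bool = True,
) -> RunResult:
    """Execute detection, elaboration, optional step 4, post-processing
    and card rendering; returns the in-memory result and (by default)
    writes the output bundle with a checksum manifest."""
    t0 = time.time()
    timings: Dict[str, float] = {}

    if datasets is None or families is None:
        ds_a = load_species(config.species_a)
        ds_b = load_species(config.species_b)
        families = mscm_io.read_ortholog_families(
            config.families, ds_a.species_id, ds_b.species_id,
            ds_a.gene_universe, ds_b.gene_universe,
        )
        datasets = {ds_a.species_id: ds_a, ds_b.species_id: ds_b}
    else:
        ids = list(datasets)
        ds_a, ds_b = datasets[ids[0]], datasets[ids[1]]
    timings["load"] = time.time() - t0
    log.info("loaded %d + %d genes, %d families",
             len(ds_a.gene_universe), len(ds_b.gene_universe), len(families))

    # shared contexts so detection/elaboration/postprocess use one null
    ss = np.random.SeedSequence(config.seed)
    ctx_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2)]
    stage = time.time()
    ctx_a = SpeciesContext(ds_a, seed=ctx_seeds[0], n_draws=config.null_draws)
    ctx_b = SpeciesContext(ds_b, seed=ctx_seeds[1], n_draws=config.null_draws)
    contexts = {ds_a.species_id: ctx_a, ds_b.species_id: ctx_b}
    timings["contexts"] = time.time() - stage

    stage = time.time()
    biclusters = detect_conserved_biclusters(
        ds_a, ds_b, families, config.detect_params(), contexts=(ctx_a, ctx_b)
    )
    timings["detect"] = time.time() - stage
    log.info("detected %d conserved biclusters in %.1fs", len(biclusters), timings["detect"])

    stage = time.time()
    elaborated = []
    for bc in biclusters:
        for sid in list(bc.sides):
            bc = elaborate_bicluster(bc, datasets[sid], sid, config.elaborate_params(),
                                     ctx=contexts[sid])
        elaborated.append(bc)
    biclusters = elaborated
    timings["elaborate"] = time.time() - stage

    # final motif discovery over full member sets
    stage = time.time()
    rng = np.random.default_rng(int(ss.generate_state(2)[1] % (2**31)))
    for bc in biclusters:
        for sid in bc.sides:
            side = bc.side(sid)
            promoters = {
                g: datasets[sid].promoters[g]
                for g in side.genes if g in datasets[sid].promoters
            }
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                motifs = find_motifs(
                    promoters,
                    n_motifs=config.motif.final_n_motifs,
                    width_range=(config.motif.width_min, config.motif.width_max),
                    n_restarts=config.motif.final_n_restarts,
                    seed=int(rng.integers(2**31)),
                    max_sweeps=config.motif.max_sweeps,
                )
            side.motifs = motifs
            side.score_components["motif_mean_logp"] = bicluster_motif_mean(motifs, side.genes)
    timings["motifs"] = time.time() - stage

    if config.step4.enabled:
        stage = time.time()
        for sid, ds in datasets.items():
            used = {
                g for bc in biclusters if sid in bc.sides for g in bc.side(sid).genes
            }
            biclusters.extend(
                species_specific_biclusters(ds, used, config.step4_params(),
                                            ctx=contexts[sid])
            )
        timings["step4"] = time.time() - stage

    stage = time.time()
    post = postprocess_run(
        biclusters, datasets, contexts=contexts,
        thresholds=RelatedThresholds(
            min_jaccard=config.postprocess.min_jaccard,
            min_motif_sim=config.postprocess.min_motif_sim,
        ),
    )
    timings["postprocess"] = time.time() - stage

    stage = time.time()
    cards = [
        build_card(bc, sid, datasets, post)
        for bc in biclusters
        for sid in sorted(bc.sides)
    ]
    timings["cards"] = time.time() - stage

    result = RunResult(
        biclusters=biclusters,
        species_ids=[ds_a.species_id, ds_b.species_id],
        post=post,
        cards=cards,
        config=config.to_dict(),
    )
    result.bicluster_network = post.network
    result.timings = timings

    if write_bundle:
        out_dir = Path(config.out_dir)
        manifest = mscm_io.write_result_bundle(result, out_dir)
        for fmt in config.report_formats:
            card_manifest = render_cards(cards, out_dir / f"cards_{fmt}", format=fmt)
            manifest.update({f"cards_{fmt}/{k}": v for k, v in card_manifest.items()})
        (out_dir / "manifest.json").write_text(
            json.dumps(manifest, sort_keys=True, indent=1)
        )
        (out_dir / "timings.json").write_text(json.dumps(timings, indent=1))
        result.manifest = manifest
    log.info("pipeline complete in %.1fs", time.time() - t0)
    return result
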