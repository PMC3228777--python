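"""Shared fixtures: tiny hand-built datasets and a session-scoped
synthetic pair used by the slower integration tests."""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

# reproducible property tests regardless of the invoking environment
settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from mscm.model import AnnotationTerm, SpeciesDataset
from mscm.synth import GenParams, generate_pair_dataset


@pytest.fixture()
def tiny_dataset() -> SpeciesDataset:
    """Six genes, four conditions, a small network and one GO namespace."""
    rng = np.random.default_rng(0)
    genes = [f"g{i}" for i in range(6)]
    conds = [f"c{j}" for j in range(4)]
    expr = pd.DataFrame(rng.normal(size=(6, 4)), index=genes, columns=conds)
    net = nx.Graph()
    net.add_nodes_from(genes)
    net.add_edge("g0", "g1", types={"operon"})
    net.add_edge("g1", "g2", types={"metabolic-pathway"})
    promoters = {g: "".join(rng.choice(list("ACGT"), size=40)) for g in genes}
    annotations = {
        "GO": {
            "GO:1": AnnotationTerm("GO:1", "first", frozenset({"g0", "g1", "g2"}), True),
            "GO:2": AnnotationTerm("GO:2", "second", frozenset({"g3"}), False),
        }
    }
    return SpeciesDataset(
        species_id="tiny",
        expression=expr,
        promoters=promoters,
        network=net,
        annotations=annotations,
        gene_universe=tuple(genes),
    )


@pytest.fixture(scope="session")
def small_pair():
    """A reduced synthetic two-species pair for integration tests:
    2 modules x 10 pairs on 120-gene datasets."""
    params = GenParams(
        n_genes_a=120, n_genes_b=120,
        n_conditions_a=30, n_conditions_b=30,
        n_modules=2, module_size=10,
        n_elab_per_module=2, seed=123,
    )
    return generate_pair_dataset(params)


@pytest.fixture(scope="session")
def default_pair():
    """The reference study conditions: 3 modules x 15 pairs."""
    return generate_pair_dataset(GenParams(seed=1))
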