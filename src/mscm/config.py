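"""Run configuration: defaults, YAML loading, strict key validation."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Dict, List, Optional

import yaml

from mscm.optimize import DetectParams, ElaborateParams, MotifSearchParams, SpecificParams
from mscm.scoring import ScoreWeights


@dataclass
class SpeciesPaths:
    id: str = ""
    expression: str = ""
    promoters: str = ""
    network: str = ""
    #: namespace -> GMT path
    annotations: Dict[str, str] = field(default_factory=dict)


@dataclass
class Step4Config:
    enabled: bool = False
    n_biclusters: int = 2
    iterations: int = 5000


@dataclass
class PostprocessConfig:
    min_jaccard: float = 0.1
    min_motif_sim: float = 0.8


@dataclass
class MotifConfig:
    # in-loop search (amortized inside the optimizer)
    n_motifs: int = 1
    width_min: int = 6
    width_max: int = 12
    n_restarts: int = 2
    max_sweeps: int = 120
    # final per-bicluster search after elaboration
    final_n_motifs: int = 2
    final_n_restarts: int = 2


@dataclass
class WeightsConfig:
    expr: float = 1.0
    motif: float = 0.5
    net: float = 0.5
    gene_penalty: float = 2.0
    cond_penalty: float = 0.5

    def to_weights(self) -> ScoreWeights:
        return ScoreWeights(w_expr=self.expr, w_motif=self.motif, w_net=self.net,
                            gene_penalty=self.gene_penalty,
                            cond_penalty=self.cond_penalty)


@dataclass
class ElaborateConfig:
    iterations: int = 3000
    allow_condition_moves: bool = False


@dataclass
class RunConfig:
    species_a: SpeciesPaths = field(default_factory=SpeciesPaths)
    species_b: SpeciesPaths = field(default_factory=SpeciesPaths)
    families: str = ""
    n_biclusters: int = 6
    init_size: int = 8
    seed_candidates: int = 10
    iterations: int = 20000
    t_start: Optional[float] = None
    t_end: Optional[float] = None
    weights: WeightsConfig = field(default_factory=WeightsConfig)
    redundancy_cap: int = 2
    motif_refresh_every: int = 50
    motif: MotifConfig = field(default_factory=MotifConfig)
    elaborate: ElaborateConfig = field(default_factory=ElaborateConfig)
    step4: Step4Config = field(default_factory=Step4Config)
    postprocess: PostprocessConfig = field(default_factory=PostprocessConfig)
    report_formats: List[str] = field(default_factory=lambda: ["json", "html"])
    null_draws: int = 300
    seed: int = 0
    out_dir: str = "mscm_out"

    def detect_params(self) -> DetectParams:
        return DetectParams(
            n_biclusters=self.n_biclusters,
            init_size=self.init_size,
            seed_candidates=self.seed_candidates,
            iterations=self.iterations,
            t_start=self.t_start,
            t_end=self.t_end,
            weights=self.weights.to_weights(),
            redundancy_cap=self.redundancy_cap,
            motif_refresh_every=self.motif_refresh_every,
            motif_search=MotifSearchParams(
                n_motifs=self.motif.n_motifs,
                width_range=(self.motif.width_min, self.motif.width_max),
                n_restarts=self.motif.n_restarts,
                max_sweeps=self.motif.max_sweeps,
            ),
            null_draws=self.null_draws,
            seed=self.seed,
        )

    def elaborate_params(self) -> ElaborateParams:
        return ElaborateParams(
            iterations=self.elaborate.iterations,
            allow_condition_moves=self.elaborate.allow_condition_moves,
            weights=self.weights.to_weights(),
            seed=self.seed,
        )

    def step4_params(self) -> SpecificParams:
        return SpecificParams(
            n_biclusters=self.step4.n_biclusters,
            iterations=self.step4.iterations,
            weights=self.weights.to_weights(),
            seed=self.seed,
        )

    def to_dict(self) -> dict:
        return asdict(self)


def _build(cls, data: dict, path: str = ""):
    """Instantiate a config dataclass tree, rejecting unknown keys."""
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        where = path or cls.__name__
        raise ValueError(f"unknown config key(s) in {where}: {sorted(unknown)}")
    kwargs = {}
    nested = {
        "species_a": SpeciesPaths, "species_b": SpeciesPaths,
        "weights": WeightsConfig, "motif": MotifConfig,
        "elaborate": ElaborateConfig, "step4": Step4Config,
        "postprocess": PostprocessConfig,
    }
    for key, value in data.items():
        if key in nested and isinstance(value, dict):
            kwargs[key] = _build(nested[key], value, path=f"{path}.{key}" if path else key)
        else:
            kwargs[key] = value
    return cls(**kwargs)


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration; unknown keys are
    rejected before any compute."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return _build(RunConfig, data)


def config_from_dict(data: dict) -> RunConfig:
    return _build(RunConfig, dict(data))
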