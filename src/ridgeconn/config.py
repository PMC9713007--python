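"""Structured run configuration for the end-to-end pipeline."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .classifier import ClassifierConfig
from .graph_metrics import ReferenceConfig
from .synthetic_cohort import ClinicalSpec, CohortConfig, CovariateSpec, PlantedEdge

__all__ = ["RunConfig", "load_config"]


@dataclass(frozen=True)
class RunConfig:
    out_dir: str = "ridgeconn_run"
    in_dir: str | None = None  # existing cohort directory; None => simulate
    seed: int = 0
    paper_convention: bool = False

    # simulation
    cohort: CohortConfig = field(default_factory=CohortConfig)

    # connectome
    alpha: float = 0.1
    grid_lo: float = 0.05
    grid_hi: float = 0.40
    grid_step: float = 0.01

    # graph metrics
    reference: ReferenceConfig = field(default_factory=ReferenceConfig)
    include_e_loc: bool = False

    # nbs
    nbs_p_primary: float = 0.001
    nbs_n_perm: int = 5000
    nbs_directions: tuple[str, ...] = ("positive", "negative")
    nbs_covariates: tuple[str, ...] = ()

    # group stats
    stats_n_perm_global: int = 10000
    stats_n_perm_local: int = 5000
    clinical_vars: tuple[str, ...] = ("hama", "bprs")
    control_covariates: tuple[str, ...] = ("age", "education", "ftnd")

    # classification
    classify: ClassifierConfig = field(default_factory=ClassifierConfig)

    def to_dict(self) -> dict:
        return asdict(self)


def _cohort_from_dict(d: dict) -> CohortConfig:
    d = dict(d)
    if "planted_edges" in d:
        d["planted_edges"] = tuple(
            PlantedEdge(int(e[0]), int(e[1]), float(e[2])) if not isinstance(e, dict)
            else PlantedEdge(int(e["i"]), int(e["j"]), float(e["delta"]))
            for e in d["planted_edges"]
        )
    if "covariate_spec" in d:
        d["covariate_spec"] = CovariateSpec(
            {k: tuple(v) for k, v in d["covariate_spec"].items()}
        )
    if "clinical_spec" in d:
        spec = dict(d["clinical_spec"])
        alpha = spec.pop("summary_alpha", 0.1)
        d["clinical_spec"] = ClinicalSpec(
            {k: tuple(v) for k, v in spec.items()}, summary_alpha=alpha
        )
    return CohortConfig(**d)


def load_config(path: str | Path, **overrides) -> RunConfig:
    """Read a YAML run configuration, applying keyword overrides."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    raw.update(overrides)
    if "cohort" in raw and isinstance(raw["cohort"], dict):
        raw["cohort"] = _cohort_from_dict(raw["cohort"])
    if "reference" in raw and isinstance(raw["reference"], dict):
        raw["reference"] = ReferenceConfig(**raw["reference"])
    if "classify" in raw and isinstance(raw["classify"], dict):
        raw["classify"] = ClassifierConfig(**raw["classify"])
    for key in ("nbs_directions", "nbs_covariates", "clinical_vars", "control_covariates"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    return RunConfig(**raw)
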