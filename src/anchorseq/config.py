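"""JSON pipeline configuration: schema, validation, defaults.

One configuration file drives the whole pipeline.  Validation is strict:
unknown keys are rejected by name, every violation is reported (not just
the first), and referenced paths must exist at load time.  Anchor-search
defaults are precision threshold 0.9, delta 0.3, tau 0.3.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .samples import ContractViolation


class ConfigError(ValueError):
    """Configuration file violates the schema; message lists all problems."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SyntheticSection(_Strict):
    """Generate the benchmark repertoire instead of loading data."""

    n_samples: int = Field(default=1000, gt=0)
    frame_length: int = Field(default=20, gt=0)
    n_seed_sequences: int = Field(default=4, gt=0)
    mutation_rate: float = Field(default=0.05, ge=0.0, le=1.0)
    n_rules: int = Field(default=2, ge=0)
    label_noise: float = Field(default=0.0, ge=0.0, lt=0.5)


class DataSection(_Strict):
    table: Optional[str] = None
    fasta: Optional[str] = None
    regions: Optional[str] = None
    frame_length: Optional[int] = Field(default=None, gt=0)
    synthetic: Optional[SyntheticSection] = None

    @model_validator(mode="after")
    def _one_source(self) -> "DataSection":
        sources = [s is not None for s in (self.table, self.fasta, self.synthetic)]
        if sum(sources) != 1:
            raise ValueError("exactly one of table, fasta or synthetic is required")
        if self.fasta is not None and self.frame_length is None:
            raise ValueError("fasta input requires an explicit frame_length")
        return self


class ModelSection(_Strict):
    kind: Literal["planted", "constant", "import"] = "planted"
    #: planted rules as [[position, symbol], ...] lists; empty → use the
    #: synthetic benchmark's own planted rules
    rules: Optional[list[list]] = None
    label_noise: float = Field(default=0.0, ge=0.0, lt=0.5)
    constant_label: Literal["binding", "non-binding"] = "binding"
    #: "package.module:attribute" resolving to a model or zero-arg factory
    import_path: Optional[str] = None

    @model_validator(mode="after")
    def _kind_args(self) -> "ModelSection":
        if self.kind == "import" and not self.import_path:
            raise ValueError("model kind 'import' requires import_path")
        return self


class ClusteringSection(_Strict):
    algorithm: Literal["k-medoids", "agglomerative", "optics", "birch"] = "agglomerative"
    metric: str = "levenshtein"
    linkage: Literal["average", "complete", "single"] = "average"
    k: Optional[int] = Field(default=None, gt=0)
    k_grid: Optional[list[int]] = None
    eps: Optional[float] = Field(default=None, gt=0)
    eps_grid: Optional[list[float]] = None
    criterion: Literal["silhouette", "davies-bouldin"] = "silhouette"
    min_samples: int = Field(default=2, gt=0)

    @model_validator(mode="after")
    def _params_for_algorithm(self) -> "ClusteringSection":
        if self.algorithm == "optics":
            if self.eps is None and not self.eps_grid:
                raise ValueError("optics requires eps or eps_grid")
        elif self.k is None and not self.k_grid:
            raise ValueError(f"{self.algorithm} requires k or k_grid")
        return self


class AnchorsSection(_Strict):
    precision_threshold: float = Field(default=0.9, gt=0.0, le=1.0)
    delta: float = Field(default=0.3, gt=0.0, lt=1.0)
    tau: float = Field(default=0.3, gt=0.0, lt=1.0)
    beam_width: int = Field(default=1, gt=0)
    batch_size: int = Field(default=100, gt=0)
    max_predicates: Optional[int] = Field(default=None, gt=0)
    max_pulls: int = Field(default=2000, gt=0)


class EvaluationSection(_Strict):
    #: CL true positives must fulfill *only* their own rule (the strict
    #: reading); False switches to the inclusive variant
    cl_exclusive: bool = True
    region_mode: Literal["predicate", "rule"] = "predicate"


class PipelineConfig(_Strict):
    seed: int = 0
    output_dir: str = "anchorseq_out"
    data: DataSection
    model: ModelSection = ModelSection()
    clustering: ClusteringSection = ClusteringSection(k=4)
    anchors: AnchorsSection = AnchorsSection()
    evaluation: EvaluationSection = EvaluationSection()
    figures: bool = True

    def check_paths(self, base: Path) -> None:
        for candidate in (self.data.table, self.data.fasta, self.data.regions):
            if candidate is not None and not (base / candidate).exists():
                raise ConfigError(f"referenced path does not exist: {candidate}")


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a JSON configuration file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"configuration file not found: {path}")
    with open(path) as fh:
        try:
            raw = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ConfigError(f"not valid JSON: {exc}") from exc
    try:
        config = PipelineConfig.model_validate(raw)
    except ValidationError as exc:
        problems = []
        for err in exc.errors():
            loc = ".".join(str(p) for p in err["loc"]) or "<root>"
            problems.append(f"{loc}: {err['msg']}")
        raise ConfigError(
            "invalid configuration:\n  " + "\n  ".join(problems)) from exc
    config.check_paths(path.parent)
    return config
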