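"""Validated YAML configuration for the screen pipeline.

The schema is strict: unknown keys are rejected with a message naming the
offending key, and every threshold has the pipeline's documented default
(mean read quality 30, minimum mutation count 10, class prior 0.25, droplet
occupancy 10%, smoothing window 9).
"""

from __future__ import annotations

import math
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

SCHEMA_VERSION = 1


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class ScreenSection(_Strict):
    occupancy: float = Field(0.10, gt=0, lt=1,
                             description="P(droplet holds >= 1 cell)")
    incubation_min: float = Field(3.0, ge=0)
    gate_threshold: float = 70.0
    active_rate_mean: float = Field(100.0, ge=0)
    inactive_rate_mean: float = Field(10.0, ge=0)
    expression_noise_cv: float = Field(0.3, ge=0)
    autofluorescence_sd: float = Field(30.0, ge=0)
    prior_pi: float = Field(0.25, gt=0, lt=1)
    n_droplets: int = Field(100_000, ge=1)

    @property
    def occupancy_lambda(self) -> float:
        # occupancy reported as P(>=1 cell) => Poisson mean -ln(1 - occupancy)
        return -math.log(1.0 - self.occupancy)


class LibrarySection(_Strict):
    n_variants: int = Field(2000, ge=1)
    mean_nt_mutations: float = Field(4.5, ge=0)
    gene_codons: int = Field(100, ge=2,
                             description="toy gene length when no FASTA is given")
    numbering_offset: int = 0
    truth_beta_sd: float = Field(1.5, ge=0,
                                 description="sd of simulated true coefficients")
    shuffled_replicates: list[int] = Field(
        default_factory=list,
        description="replicates whose activity labels are permuted (QC testing)",
    )


class SequencingSection(_Strict):
    depth: int = Field(20_000, ge=1)
    error_rate: float = Field(0.001, ge=0, lt=0.1)
    n_replicates: int = Field(3, ge=1)


class PipelineSection(_Strict):
    min_read_quality: float = Field(30.0, ge=0)
    min_mutation_count: int = Field(10, ge=0)


class FitSection(_Strict):
    l2_penalty: float = Field(1e-4, ge=0)
    tol: float = Field(1e-8, gt=0)
    max_iter: int = Field(500, ge=1)
    exclusion_threshold: float = Field(0.5, ge=-1, le=1)


class ProfilesSection(_Strict):
    window: int = Field(9, ge=1)


class Config(_Strict):
    schema_version: int = SCHEMA_VERSION
    simulate: bool = True
    reference_fasta: str | None = None
    seed: int = 0
    screen: ScreenSection = Field(default_factory=ScreenSection)
    library: LibrarySection = Field(default_factory=LibrarySection)
    sequencing: SequencingSection = Field(default_factory=SequencingSection)
    pipeline: PipelineSection = Field(default_factory=PipelineSection)
    fit: FitSection = Field(default_factory=FitSection)
    profiles: ProfilesSection = Field(default_factory=ProfilesSection)

    def dump(self) -> dict:
        return self.model_dump()

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.dump(), sort_keys=True))


class ConfigError(ValueError):
    """Raised for unreadable or schema-violating configuration files."""


def load_config(path_or_dict) -> Config:
    """Load and validate a pipeline configuration.

    Accepts a YAML path or an already-parsed mapping. An empty file yields
    all defaults; schema violations raise :class:`ConfigError` naming the
    offending key.
    """
    if isinstance(path_or_dict, dict):
        raw = path_or_dict
    else:
        text = Path(path_or_dict).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    try:
        return Config(**raw)
    except ValidationError as exc:
        msgs = []
        for err in exc.errors():
            key = ".".join(str(p) for p in err["loc"]) or "<root>"
            msgs.append(f"{key}: {err['msg']}")
        raise ConfigError("invalid configuration: " + "; ".join(msgs)) from exc
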