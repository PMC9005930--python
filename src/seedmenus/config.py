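"""Run configuration: schema, validation and YAML loading."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator


class SimulateConfig(BaseModel):
    """Synthetic-input generation settings (demo / validation profile)."""

    nrows: int = Field(64, ge=8)
    ncols: int = Field(64, ge=8)
    cell_km: float = Field(1.0, gt=0)
    n_covariates: int = Field(8, ge=2, le=14)
    autocorrelation_range: float = Field(4.0, gt=0)
    n_species: int = Field(3, ge=1)
    n_occurrences: int = Field(300, ge=10)
    intercept: float = -8.0
    beta_low: float = 2.0
    beta_high: float = 3.0
    n_causal: int = Field(2, ge=1)
    access_bias_strength: float = Field(0.0, ge=0)
    n_roads: int = Field(3, ge=1)


class ModelSpaceConfig(BaseModel):
    max_terms: int = Field(6, ge=1, le=14)
    r_cut: float = Field(0.7, gt=0, le=1)
    spec_cap: int | None = Field(None, ge=1)


class CVConfig(BaseModel):
    n_runs: int = Field(50, ge=1)
    holdout: float = Field(0.2, gt=0, lt=1)
    thin_block_km: float = Field(10.0, gt=0)
    thin_max_per_block: int = Field(3, ge=1)


class FitConfig(BaseModel):
    n_trees: int = Field(1000, ge=1)
    maxent_regularization: float = Field(1.0, gt=0)
    gam_nbasis: int = Field(10, ge=4)
    min_presences: int = Field(20, ge=5)
    families: list[str] = Field(
        default=["smooth_additive", "tree_ensemble", "maxent_like"])

    @field_validator("families")
    @classmethod
    def _known_families(cls, v):
        known = {"smooth_additive", "tree_ensemble", "maxent_like"}
        bad = set(v) - known
        if bad:
            raise ValueError(f"unknown families {sorted(bad)}")
        return v


class EnsembleConfig(BaseModel):
    n_keep: int = Field(10, ge=1)
    se_mode: str = Field("se", pattern="^(se|sd)$")


class ThresholdConfig(BaseModel):
    kind: str = Field("fixed", pattern="^(fixed|max_sss|sens_eq_spec)$")
    fixed_value: float = Field(0.0, ge=0, le=1)


class RunConfig(BaseModel):
    """Top-level pipeline configuration.

    The master seed fans out deterministically to per-species, per-run
    and per-draw child seeds (documented counter scheme in
    :func:`seedmenus.metrics.derive_seed`), and is recorded in output
    metadata.
    """

    output_dir: str = "seedmenus_out"
    stack_path: str | None = None
    occurrences_path: str | None = None
    traits_path: str | None = None
    sites_path: str | None = None
    master_seed: int = Field(0, ge=0, lt=2 ** 31)
    lifespans: dict[str, str] = Field(default_factory=dict)
    simulate: SimulateConfig = SimulateConfig()
    model_space: ModelSpaceConfig = ModelSpaceConfig()
    cv: CVConfig = CVConfig()
    fit: FitConfig = FitConfig()
    ensemble: EnsembleConfig = EnsembleConfig()
    threshold: ThresholdConfig = ThresholdConfig()

    @field_validator("lifespans")
    @classmethod
    def _known_lifespans(cls, v):
        bad = {k: s for k, s in v.items() if s not in ("annual", "perennial")}
        if bad:
            raise ValueError(f"lifespans must be annual/perennial, got {bad}")
        return v

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=False))


def demo_config(output_dir: str = "seedmenus_demo", seed: int = 1) -> RunConfig:
    """Desk-scale profile: 8 covariates, <=4 terms, 10 runs, 5 candidates.

    Completes in minutes on one CPU while exercising every pipeline
    stage; the full-scale defaults mirror the regional study design
    (14 covariates, <=6 terms, 50 runs, ~10 candidates per family).
    """
    return RunConfig(
        output_dir=output_dir, master_seed=seed,
        simulate=SimulateConfig(),
        model_space=ModelSpaceConfig(max_terms=4, spec_cap=24),
        cv=CVConfig(n_runs=10),
        fit=FitConfig(n_trees=200),
        ensemble=EnsembleConfig(n_keep=5),
        threshold=ThresholdConfig(kind="fixed", fixed_value=0.4),
    )
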