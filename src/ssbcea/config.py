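"""Run configuration: validated settings for a full pipeline run."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from .effects import SUBSTITUTION_SCOPES, load_scenarios

PIF_METHODS = ("mean_shift", "integral")


class RunConfig(BaseModel):
    """Validated configuration for :func:`ssbcea.run.run`.

    Defaults mirror the published analysis settings: 3% discounting, an
    AUD 50,000/HALY willingness-to-pay threshold, 2000 Monte Carlo
    iterations and a 100 kJ/day-per-kg adult steady-state coefficient.
    """

    scenarios: list[str] = Field(default_factory=lambda: ["A1"])
    bundle_dir: Path | None = None
    synthetic_seed: int | None = 1
    calibrate_to_published: bool = True
    discount_rate: float = 0.03
    wtp: float = 50_000.0
    n_iterations: int = 2000
    seed: int = 42
    pif_method: str = "mean_shift"
    substitution_scope: str = "all_ssb"
    rho_adult: float = 100.0
    sample_effects: bool = False
    effect_sd: float = 0.2
    max_age: int = 100
    out_dir: Path | None = None

    @field_validator("discount_rate")
    @classmethod
    def _rate_non_negative(cls, v: float) -> float:
        if v < 0:
            raise ValueError("discount_rate must be non-negative")
        return v

    @field_validator("n_iterations")
    @classmethod
    def _iterations_positive(cls, v: int) -> int:
        if v < 1:
            raise ValueError("n_iterations must be at least 1")
        return v

    @field_validator("wtp")
    @classmethod
    def _wtp_positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("wtp must be positive")
        return v

    @field_validator("pif_method")
    @classmethod
    def _pif_method_known(cls, v: str) -> str:
        if v not in PIF_METHODS:
            raise ValueError(f"pif_method must be one of {PIF_METHODS}")
        return v

    @field_validator("substitution_scope")
    @classmethod
    def _scope_known(cls, v: str) -> str:
        if v not in SUBSTITUTION_SCOPES:
            raise ValueError(f"substitution_scope must be one of {SUBSTITUTION_SCOPES}")
        return v

    @field_validator("scenarios")
    @classmethod
    def _scenarios_known(cls, v: list[str]) -> list[str]:
        known = set(load_scenarios())
        unknown = [s for s in v if s not in known]
        if unknown:
            raise ValueError(f"unknown scenario ids {unknown}; known: {sorted(known)}")
        if not v:
            raise ValueError("at least one scenario required")
        return v

    @model_validator(mode="after")
    def _inputs_specified(self) -> "RunConfig":
        if self.bundle_dir is None and self.synthetic_seed is None:
            raise ValueError("either bundle_dir or synthetic_seed is required")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))
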