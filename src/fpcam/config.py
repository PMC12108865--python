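"""Run configuration: defaults, YAML loading, and override precedence."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import yaml

from .errors import ValidationError


@dataclass(frozen=True)
class RunConfig:
    """Flat configuration shared by the pipeline and the CLI.

    Precedence when assembling a run: command-line flags > config file >
    these defaults.  Unknown keys are rejected so typos fail loudly.
    """

    epsilon: float = 1e-5
    value_column: str = "avg_log2FC"
    p_adj_threshold: float = 0.05
    normalize_axis: str = "gene"        # or "cluster"
    lambda2_trigger: str = "secmax"     # or "median"
    match_mode: str = "either"          # or "primary"
    case_fold: bool = True
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValidationError("epsilon must be positive")
        if self.normalize_axis not in ("gene", "cluster"):
            raise ValidationError(f"normalize_axis: {self.normalize_axis!r}")
        if self.lambda2_trigger not in ("secmax", "median"):
            raise ValidationError(f"lambda2_trigger: {self.lambda2_trigger!r}")
        if self.match_mode not in ("either", "primary"):
            raise ValidationError(f"match_mode: {self.match_mode!r}")
        if not 0 <= self.p_adj_threshold <= 1:
            raise ValidationError("p_adj_threshold must lie in [0, 1]")

    def replace(self, **overrides) -> "RunConfig":
        """Return a copy with the given fields replaced; unknown keys raise."""
        known = {f.name for f in dataclasses.fields(self)}
        unknown = set(overrides) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        clean = {k: v for k, v in overrides.items() if v is not None}
        return dataclasses.replace(self, **clean)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        """Load a flat key/value YAML file, rejecting unknown keys."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValidationError(f"config file {path} must be a flat mapping")
        return cls().replace(**raw)
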