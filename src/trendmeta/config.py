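"""Run configuration.

A flat key/value document (YAML or JSON syntax — YAML is a superset) holds
every analysis knob; CLI flags override file values.  The seed is part of
the config so that any stochastic stage is replayable.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

DEFAULT_STAGE_ORDER = ("HC", "D1", "D2", "D3", "ESRD")

__all__ = ["AnalysisConfig", "DEFAULT_STAGE_ORDER"]


@dataclass
class AnalysisConfig:
    """Thresholds and rules shared across pipeline stages.

    alpha_trend
        Per-direction significance level of the ordered-trend screen
        (raw p, unadjusted — BH-adjusted columns are emitted for
        information only).
    z_threshold
        Absolute combined-Z cutoff of the meta-analysis screen.
    weight_scheme
        ``sqrt_n`` (Stouffer sample-size weights) or ``equal``.
    probe_collapse_rule
        ``max_abs_z`` or ``median_z``.
    trend_stage_set
        Ordered stage labels entering the trend ranking.
    fdr_limit
        BH q cutoff for over-representation analysis.
    """

    alpha_trend: float = 0.05
    z_threshold: float = 5.0
    weight_scheme: str = "sqrt_n"
    probe_collapse_rule: str = "max_abs_z"
    trend_stage_set: tuple[str, ...] = ("D1", "D2", "D3")
    fdr_limit: float = 0.05
    loess_span: float = 0.3
    pca_threshold_sd: float = 4.0
    anova_alpha: float = 0.05
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha_trend < 1.0:
            raise ValueError(f"alpha_trend must be in (0,1), got {self.alpha_trend}")
        if self.z_threshold <= 0:
            raise ValueError(f"z_threshold must be > 0, got {self.z_threshold}")
        if self.weight_scheme not in ("sqrt_n", "equal"):
            raise ValueError(f"unknown weight_scheme {self.weight_scheme!r}")
        if self.probe_collapse_rule not in ("max_abs_z", "median_z"):
            raise ValueError(f"unknown probe_collapse_rule {self.probe_collapse_rule!r}")
        if not 0.0 < self.fdr_limit <= 1.0:
            raise ValueError(f"fdr_limit must be in (0,1], got {self.fdr_limit}")
        self.trend_stage_set = tuple(self.trend_stage_set)

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "AnalysisConfig":
        """Load a flat YAML/JSON config; keyword overrides win."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} must hold a flat mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["trend_stage_set"] = list(self.trend_stage_set)
        return d

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")
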