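"""Run configuration: one serializable object describing an analysis."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .cohort import ConfigError
from .engine import AnalysisWindow
from .standardize import ICSS1_WEIGHTS, StandardWeights


@dataclass
class RunConfig:
    """Paths, schema maps, analysis windows, and model settings for a run.

    Every run writes its resolved configuration next to its outputs so the
    analysis is reproducible from the output directory alone.
    """

    cases: str | None = None
    lifetable: str | None = None
    output_dir: str = "periodsurv_out"
    case_schema: dict = field(default_factory=dict)
    lifetable_schema: dict = field(default_factory=dict)
    #: list of {mode, start, end, k}
    windows: list[dict] = field(default_factory=lambda: [
        {"mode": "period", "start": 2004, "end": 2008, "k": 5},
        {"mode": "period", "start": 2009, "end": 2013, "k": 5},
        {"mode": "period", "start": 2014, "end": 2018, "k": 5},
    ])
    stratifiers: list[str] = field(default_factory=lambda: ["sex"])
    #: age-group label -> weight; None selects the shipped ICSS-1 default
    weights: dict[str, float] | None = None
    standardize: bool = False
    projection_link: str = "cloglog"
    project_ahead: int = 1  # number of future periods to project
    seed: int = 0

    def analysis_windows(self) -> list[AnalysisWindow]:
        if not self.windows:
            raise ConfigError("no analysis windows configured")
        return [AnalysisWindow(**w) for w in self.windows]

    def standard_weights(self) -> StandardWeights:
        if self.weights is None:
            return ICSS1_WEIGHTS
        return StandardWeights(dict(self.weights))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))
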