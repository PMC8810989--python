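"""Run configuration shared by the CLI and the end-to-end driver."""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

import yaml

from .changepoint import Metric
from .estimator import ERA_END, ERA_START

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    """All tunable parameters of the end-to-end workflow.

    Attributes
    ----------
    threshold
        Bright-value cleaning cutoff (scaled reflectance).
    filter_window
        Odd moving-average window (1 disables smoothing).
    metric
        Changepoint cost metric; change-in-mean is the default, the
        mean-and-variance variant is retained behind this switch.
    era_start, era_end
        Calendar window over which a conversion year is considered reliably
        detectable.
    tolerance_years
        Validation tolerance (+/- years).
    min_area_km2
        Area filter for polygon water features.
    alpha
        Significance level for the trend test.
    seed
        Root seed; all randomness in a run derives from it.
    """

    threshold: float = 10_000.0
    filter_window: int = 3
    metric: Metric = Metric.MEAN
    era_start: int = ERA_START
    era_end: int = ERA_END
    tolerance_years: int = 1
    min_area_km2: float = 0.05
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "metric", Metric(self.metric))
        if self.filter_window < 1 or self.filter_window % 2 == 0:
            raise ValueError("filter_window must be an odd integer >= 1")
        if not self.era_start < self.era_end:
            raise ValueError("era_start must precede era_end")
        if self.tolerance_years < 0:
            raise ValueError("tolerance_years must be >= 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.min_area_km2 < 0:
            raise ValueError("min_area_km2 must be >= 0")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load from a flat YAML key-value file; unknown keys are an error."""
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a flat key-value mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)

    def to_file(self, path: str | Path) -> None:
        data = {f.name: getattr(self, f.name) for f in fields(self)}
        data["metric"] = self.metric.value
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
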