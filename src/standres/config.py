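"""Run configuration: defaults, YAML round-tripping, validation.

The defaults reproduce the framework's reference study conditions: 1000
Monte-Carlo runs of 2000 simulated years in 5-year steps, a 1000-year
discounting horizon, annual discount rates of 1.5 % (net revenues) and
0.5 % (carbon), a rotation age of 85 years and the 5 x 3 gap-cut regime
grid (sizes 0.10-0.30, ages 20/40/60).  Every field can be overridden, e.g.
for scaled-down test runs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    seed: int = 1
    n_runs: int = 1000
    series_years: int = 2000
    step_years: int = 5
    horizon_years: int = 1000
    rate_financial: float = 0.015
    rate_carbon: float = 0.005
    rotation_years: int = 85
    gap_sizes: list[float] = field(default_factory=lambda: [0.1, 0.15, 0.2, 0.25, 0.3])
    gap_ages: list[int] = field(default_factory=lambda: [20, 40, 60])
    min_state_samples: int = 30
    # Parameter-table paths; None means "use the shipped synthetic defaults".
    growth_table_csv: Optional[str] = None
    survival_yaml: Optional[str] = None
    valuation_yaml: Optional[str] = None
    output_dir: str = "standres_output"

    def __post_init__(self) -> None:
        if self.series_years < self.horizon_years:
            raise ValueError("series must be at least as long as the horizon")
        if self.series_years % self.step_years or self.horizon_years % self.step_years:
            raise ValueError("series and horizon must be multiples of the step")
        if self.rotation_years % self.step_years:
            raise ValueError("rotation must be a multiple of the step")
        if any(a >= self.rotation_years for a in self.gap_ages):
            raise ValueError("gap ages must lie below the rotation age")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)
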