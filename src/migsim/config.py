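"""Run configuration (YAML/JSON) shared by the CLI entry points."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import yaml

from .calibration import CalibrationConfig
from .domain import PartitionScheme

__all__ = ["RunConfig", "load_yaml"]


def load_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


@dataclass(frozen=True)
class RunConfig:
    """Settings for a simulation run.

    ``n_samples`` defaults to a desk-scale ensemble; production hindcasts of
    the published kind use much larger ensembles (the reference setup is
    100,000 samples over 1990-2020).
    """

    start_year: int = 1990
    end_year: int = 2020
    n_samples: int = 1000
    seed: int = 0
    mode: str = "stochastic"
    max_rejection_rounds: int = 1000
    scheme: PartitionScheme = field(default_factory=PartitionScheme)
    calibration: CalibrationConfig = field(default_factory=CalibrationConfig)

    @property
    def horizon(self) -> int:
        return self.end_year - self.start_year

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        d.pop("synthetic", None)  # consumed by the synth command
        if "scheme" in d:
            d["scheme"] = PartitionScheme.from_dict(d["scheme"])
        if "calibration" in d:
            d["calibration"] = CalibrationConfig.from_dict(d["calibration"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(load_yaml(path))
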