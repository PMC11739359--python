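"""Pipeline configuration: stage thresholds, paths and the run seed.

Serializes to/from YAML losslessly; every CLI run logs the fully resolved
configuration so a run can be reproduced from its log alone.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .synthetic import CohortConfig

log = logging.getLogger("sepsisratio")


@dataclass
class PipelineConfig:
    """Thresholds and knobs of every pipeline stage, with their defaults."""

    fc_log2_min: float = 0.6
    q_max: float = 0.1
    b_posterior_min: float = 0.75
    linear_fc_min: float = 1.5
    p_de: float = 0.01
    n_bootstrap: int = 2000
    lactate_cutoff: float = 2.0
    ratio_cutoff: float | None = None  # None = recompute by Youden; value = frozen
    censor_day: float = 30.0
    efficiency_corrected: bool = True
    protect_outcome: bool = False  # pass outcome as ComBat covariate
    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    paths: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "cohort" in d and isinstance(d["cohort"], dict):
            d["cohort"] = CohortConfig(**d["cohort"])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def log_resolved(self) -> None:
        log.info("resolved configuration: %s", self.to_dict())


def setup_logging(verbose: bool = False) -> None:
    logging.basicConfig(
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
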