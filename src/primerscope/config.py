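"""Run configuration: every threshold in one serializable object.

All thresholds that shape a run are collected here so they can be loaded
from a single YAML file, overridden from the command line, echoed to the
log, and written back next to the outputs for provenance.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .genome_io import DEFAULT_SSU_DIALECTS

logger = logging.getLogger(__name__)

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Thresholds and knobs for the excise/design/screen workflows."""

    # gene excision / validation
    dialects: list[str] = field(default_factory=lambda: list(DEFAULT_SSU_DIALECTS))
    min_gene_len: int = 300
    max_gene_len: int = 2500
    max_ambiguous_frac: float = 0.10
    # conserved-region detection / primer design
    min_region_length: int = 20
    min_majority_freq: float = 0.75
    max_gap_fraction: float = 0.10
    include_freq: float = 0.10
    # screening / reporting
    flag_threshold: float = 0.35
    band_lo: int = 400
    band_hi: int = 600
    rank_depth: int = -1
    # general
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def log_thresholds(self) -> None:
        for f in dataclasses.fields(self):
            logger.info("config %s = %r", f.name, getattr(self, f.name))
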