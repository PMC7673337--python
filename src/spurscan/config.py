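"""Pipeline configuration.

Every numeric default mirrors the screening protocol: 7-20 aa spacers
(21-60 bp of DNA), 7-20 aa ab initio repeat units, 6 aa minimum indexed
peptide (the shortest stop-free frame of a 20 bp repeat), 500 kb minimum
genome, a 10 kb cas search window on each side, and RPS-BLAST hit
thresholds E <= 1e-5, identity >= 25%, coverage >= 70%.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import Optional

from .errors import ConfigError


@dataclass
class ScanConfig:
    spacer_min: int = 7  # aa
    spacer_max: int = 20  # aa
    unit_min: int = 7  # aa
    unit_max: int = 20  # aa
    min_peptide_len: int = 6  # aa
    min_genome_len: int = 500_000  # bp, inclusive
    window_bp: int = 10_000  # bp each side, inclusive
    max_evalue: float = 1e-5
    min_identity: float = 25.0  # percent
    min_coverage: float = 0.70  # fraction
    subtypes_json: Optional[str] = None  # None -> packaged catalog
    domain_map_json: Optional[str] = None  # None -> packaged mapping

    def validate(self) -> "ScanConfig":
        if self.spacer_min > self.spacer_max:
            raise ConfigError(
                f"spacer_min {self.spacer_min} > spacer_max {self.spacer_max}"
            )
        if self.unit_min > self.unit_max:
            raise ConfigError(f"unit_min {self.unit_min} > unit_max {self.unit_max}")
        for name in (
            "spacer_min",
            "unit_min",
            "min_peptide_len",
            "min_genome_len",
            "window_bp",
            "max_evalue",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if not 0 <= self.min_identity <= 100:
            raise ConfigError("min_identity must be in [0, 100]")
        if not 0 <= self.min_coverage <= 1:
            raise ConfigError("min_coverage must be in [0, 1]")
        return self

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "ScanConfig":
        with open(path) as fh:
            raw = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        return cls(**raw).validate()
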