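"""Pipeline configuration: defaults, YAML loading and validation.

Collects every tunable constant of the mining and pharmacology stages: the
motif, the E-value significance threshold, the minimum aligned overlap with
the mature dyn A 1-17 segment, substitution matrix and gap penalties, the
Karlin-Altschul parameters, the radioligand parameters and the BRET
quantification window. Unknown keys in a config file are rejected.
Precedence is CLI flag > config file > defaults.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from blennymine.exceptions import ConfigError


@dataclass
class PipelineConfig:
    motif: str = "YGGF"
    evalue_threshold: float = 1e-6
    min_dynA_overlap: int = 8
    matrix: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    karlin_lambda: float = 0.267
    karlin_k: float = 0.041
    dynA_interval: tuple[int, int] = (207, 223)
    radioligand_conc: float = 1.0  # [L], nM
    radioligand_kd: float = 0.87  # nM
    bret_window: tuple[float, float] = (311.0, 2411.0)
    cpm_per_fmol: float = 38.4  # stored conversion constant; unused by defaults
    seed: int = 0
    small_sample_correction: bool = False

    def __post_init__(self) -> None:
        if not self.motif:
            raise ConfigError("motif must be non-empty")
        if not 0 < self.evalue_threshold:
            raise ConfigError("evalue_threshold must be positive")
        if self.min_dynA_overlap < 1 or self.min_dynA_overlap > 17:
            raise ConfigError("min_dynA_overlap must be in 1..17")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ConfigError("gap penalties must be non-negative")
        if self.karlin_lambda <= 0 or self.karlin_k <= 0:
            raise ConfigError("Karlin-Altschul parameters must be positive")
        if self.radioligand_conc <= 0 or self.radioligand_kd <= 0:
            raise ConfigError("radioligand parameters must be positive")
        self.dynA_interval = tuple(self.dynA_interval)  # type: ignore[assignment]
        self.bret_window = tuple(self.bret_window)  # type: ignore[assignment]
        if self.dynA_interval[1] - self.dynA_interval[0] + 1 != 17:
            raise ConfigError("dynA_interval must span 17 residues")
        if self.bret_window[1] <= self.bret_window[0]:
            raise ConfigError("bret_window must be a non-empty interval")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load a YAML config; unknown keys are rejected, overrides win."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["dynA_interval"] = list(self.dynA_interval)
        out["bret_window"] = list(self.bret_window)
        return out

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]
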