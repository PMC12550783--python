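"""Run configuration: every stage parameter with its default, YAML round-trip,
and a content hash stamped onto every output table for reproducibility."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError
from .reference import (
    CONTACT_CUTOFF_ANGSTROM,
    DISSOCIATION_THRESHOLD_ANGSTROM,
    DISTANCE_THRESHOLD,
    DRS_RESIDUES,
    DSITE_RESIDUES,
    PLDDT_DISORDER_MAX,
    PLDDT_ORDER_MIN,
)

__version__ = "0.1.0"


@dataclass(frozen=True)
class RunConfig:
    """All pipeline parameters, pre-filled with the analysis defaults so a
    zero-config run reproduces the standard docking-interface analysis."""

    seed: int = 17
    gap_policy: str = "exclude"
    distance_threshold: float = DISTANCE_THRESHOLD
    k: str | int = "auto"
    k_range: tuple[int, int] = (2, 8)
    contact_cutoff: float = CONTACT_CUTOFF_ANGSTROM
    dissociation_threshold: float = DISSOCIATION_THRESHOLD_ANGSTROM
    plddt_disorder_max: float = PLDDT_DISORDER_MAX
    plddt_order_min: float = PLDDT_ORDER_MIN
    hydrophobic_class: str = "LIVM"
    dsite_residues: tuple[int, ...] = DSITE_RESIDUES
    drs_residues: tuple[int, ...] = DRS_RESIDUES
    n_trajectories_per_mode: int = 4
    version: str = __version__

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["k_range"] = list(self.k_range)
        d["dsite_residues"] = list(self.dsite_residues)
        d["drs_residues"] = list(self.drs_residues)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("k_range", "dsite_residues", "drs_residues"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"no such config file: {path}")
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} is not a mapping")
        return cls.from_dict(data)

    @property
    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]
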