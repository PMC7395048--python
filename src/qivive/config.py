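"""Pipeline configuration: schema-validated YAML/JSON with provenance hash."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml

__all__ = ["PipelineConfig", "config_hash"]


def config_hash(obj) -> str:
    """Stable sha256 of a JSON-serializable configuration object."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings.

    ``pbk_overrides`` uses the flat parameter symbols (BW, ka, Vmaxc, ...);
    ``scenarios`` lists plasma-binding scenarios as mappings with keys
    label, fu_m, fu_p, BPr (defaults: the four methadone fu_p scenarios).
    Unknown keys in a config file are rejected.
    """

    seed: int = 0
    output_dir: str = "qivive_out"
    dose_mg_per_day: float = 70.0
    bw: float = 70.0
    n_days: int = 30
    pbk_overrides: dict = field(default_factory=dict)
    scenarios: list = field(default_factory=list)
    bmr: float = 0.10
    n_bootstrap: int = 200
    mea: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}; "
                             f"expected a subset of {sorted(known)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def hash(self) -> str:
        return config_hash(self.to_dict())
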