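"""Run configuration: one serializable object drives every pipeline stage."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .errors import ParameterError

RESPONSES = ("CEE", "CE150", "NPP", "T100")


@dataclass
class RunConfig:
    """Paths, thresholds and the seed for a reproducible run.

    Any field can be set from a YAML config file and overridden by a CLI
    flag. The configuration hash (first 12 hex digits of the SHA-256 of the
    canonical JSON form) is embedded in every output file header.
    """

    # input paths (produced by `simulate` or supplied by the user)
    abundance: str | None = None
    metadata: str | None = None
    tree: str | None = None
    edges: str | None = None
    taxonomy: str | None = None
    traits: str | None = None
    out_dir: str = "viroflux_out"

    # responses and filter thresholds
    responses: tuple[str, ...] = ("CEE",)
    min_samples: int = 5
    presence_reads: int = 2
    rho_threshold: float = 0.2

    # regression settings
    n_components: int = 2
    n_perm: int = 10_000
    vip_threshold: float = 2.0

    # host-prediction settings
    min_leaves: int = 3
    alpha: float = 0.05
    test_direction: str = "greater"

    # trait settings
    trait_contrast: tuple[str, str] = ("positive", "non_vip")
    partner_mode: str = "any"

    # simulation scenario overrides
    scenario: dict = field(default_factory=dict)

    seed: int = 0

    def __post_init__(self) -> None:
        for resp in self.responses:
            if resp not in RESPONSES:
                raise ParameterError(
                    f"unknown response {resp!r}; choose from {RESPONSES}"
                )
        if self.n_perm < 0:
            raise ParameterError("n_perm must be non-negative")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        for key in ("responses", "trait_contrast"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def config_hash(self) -> str:
        """Hash of the result-determining fields (output location excluded)."""
        fields_dict = self.to_dict()
        fields_dict.pop("out_dir", None)
        canonical = json.dumps(fields_dict, sort_keys=True, default=str)
        return hashlib.sha256(canonical.encode()).hexdigest()[:12]

    def header(self) -> dict:
        return {"config_hash": self.config_hash, "seed": self.seed}

    def ensure_out_dir(self) -> Path:
        path = Path(self.out_dir)
        path.mkdir(parents=True, exist_ok=True)
        return path
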