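"""Structured run configuration with validation and lossless round-tripping."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

from .ct import CTConfig
from .errors import ValidationError
from .geometry import AnthropometricParams

MOTIONS = ("flexion", "extension", "lateral_bending", "twisting")

_RANGES = {
    "noise_sd": (0.0, 200.0),
    "edge_vert": (0.5, 6.0),
    "edge_ivd": (0.25, 3.0),
    "max_disp_fraction": (0.001, 0.2),
    "n_steps_compression": (10, 500),
    "knockdown": (1e-4, 1.0),
    "peak_moment": (0.1, 50.0),
    "n_steps_rom": (2, 200),
    "roi_erosion_mm": (0.0, 10.0),
}


@dataclass
class RunConfig:
    """Every tunable of the pipeline, with documented ranges.

    All randomness of a run flows from ``seed``; re-running with the same
    config and seed reproduces results bit-for-bit.
    """

    seed: int = 0
    anthropometry: AnthropometricParams = field(default_factory=AnthropometricParams)
    ct: CTConfig = field(default_factory=CTConfig)
    noise_sd: float = 30.0  # HU
    edge_vert: float = 3.0  # mm
    edge_ivd: float = 1.5  # mm
    hu_sampling: str = "centroid"  # or "volume"
    max_disp: float | None = None  # mm; None -> fraction of model height
    max_disp_fraction: float = 0.04
    n_steps_compression: int = 40
    knockdown: float = 0.01
    peak_moment: float = 7.5  # N*m
    n_steps_rom: int = 8
    motions: tuple[str, ...] = MOTIONS
    tension_only: bool = True
    roi_erosion_mm: float = 2.0
    out_dir: str | None = None

    def __post_init__(self):
        for name, (lo, hi) in _RANGES.items():
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValidationError(
                    f"config field '{name}' = {v!r} outside [{lo}, {hi}]"
                )
        if self.hu_sampling not in ("centroid", "volume"):
            raise ValidationError(
                f"config field 'hu_sampling' must be 'centroid' or 'volume', "
                f"got {self.hu_sampling!r}"
            )
        bad = [m for m in self.motions if m not in MOTIONS]
        if bad:
            raise ValidationError(f"unknown motion(s) {bad}; valid: {MOTIONS}")
        self.motions = tuple(self.motions)

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "anthropometry" in d and isinstance(d["anthropometry"], dict):
            d["anthropometry"] = AnthropometricParams(**d["anthropometry"])
        if "ct" in d and isinstance(d["ct"], dict):
            d["ct"] = CTConfig(**d["ct"])
        if "motions" in d:
            d["motions"] = tuple(d["motions"])
        return cls(**d)

    def save(self, path) -> None:
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            import yaml

            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    @classmethod
    def load(cls, path) -> "RunConfig":
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            import yaml

            return cls.from_dict(yaml.safe_load(path.read_text()))
        return cls.from_dict(json.loads(path.read_text()))

    def digest(self) -> str:
        """Short stable hash of the configuration, for provenance logs."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
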