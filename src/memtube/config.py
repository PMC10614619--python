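"""Pipeline configuration and run manifests."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from memtube.pixelclass import DEFAULT_SCALES, ShapeCriteria

__all__ = ["PipelineConfig", "RunManifest", "config_hash", "file_hash"]


@dataclass
class PipelineConfig:
    """Validated configuration for the end-to-end pipeline.

    Unknown keys in a YAML config are rejected at load time, before any
    computation starts.
    """

    pixel_size_nm: float = 100.0
    channels: dict = field(default_factory=lambda: {"lipid": "lipid", "protein": "protein"})
    scales: tuple[float, ...] = DEFAULT_SCALES
    criteria: ShapeCriteria = field(default_factory=ShapeCriteria)
    calibration_path: str | None = None
    seed: int = 0
    output_dir: str = "memtube_out"
    n_train_scenes: int = 6
    train_target_ratios: tuple[float, ...] = (0.2, 0.5, 0.8)

    def __post_init__(self) -> None:
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be > 0")
        if len(set(self.channels.values())) != len(self.channels):
            raise ValueError("channel names must be distinct")
        self.scales = tuple(float(s) for s in self.scales)
        if isinstance(self.criteria, dict):
            self.criteria = ShapeCriteria(**self.criteria)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        allowed = set(cls.__dataclass_fields__)
        unknown = set(data) - allowed
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["scales"] = list(self.scales)
        d["train_target_ratios"] = list(self.train_target_ratios)
        return d


def config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def file_hash(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


@dataclass
class RunManifest:
    """Provenance record: equal manifest inputs imply byte-identical result CSVs."""

    tool_version: str
    config_hash: str
    input_hashes: dict
    seed: int
    timestamp: str

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")
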