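"""Run configuration: one serializable object controlling a full run."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    # inputs
    he_image: str = ""
    cycif_image: str = ""
    cell_table: str = ""
    panel_file: str = ""
    slide_id: str = "slide"
    out_dir: str = "run_out"
    # tiling
    tile_size_px: int = 256
    min_tissue_frac: float = 0.1
    aggregation: str = "mean_log1p"
    # registration
    metric: str = "mattes"
    max_displacement_px: int = 32
    # features / model
    provider: str = "randproj"
    provider_dim: int = 384
    architecture: str = "mlp"
    hidden_sizes: tuple[int, ...] = (256, 256, 256)
    learning_rate: float = 1e-3
    batch_size: int = 256
    max_epochs: int = 300
    patience: int = 10
    dropout: float = 0.1
    augment: bool = False
    # evaluation / gating
    x_values: tuple[float, ...] = (5.0, 10.0, 20.0)
    gate_on: str = "z"
    # misc
    seed: int = 0
    model_path: str = ""  # when set, skip training and load this model

    def to_dict(self) -> dict:
        d = asdict(self)
        d["hidden_sizes"] = list(self.hidden_sizes)
        d["x_values"] = list(self.x_values)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "hidden_sizes" in d:
            d["hidden_sizes"] = tuple(d["hidden_sizes"])
        if "x_values" in d:
            d["x_values"] = tuple(d["x_values"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))
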