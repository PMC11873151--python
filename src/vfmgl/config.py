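"""Experiment configuration: presets, YAML round-trip, seeding.

The four use-case presets carry the published training hyperparameters
verbatim (uc1: 20 epochs, lr 1e-4, weight decay 1e-4, batch 25, SGD with
momentum 0.9; uc2: 10 / 0.01 / 0.001 / 32; uc3: Dice loss + Adam, 100 /
1e-4 / 1e-4 / 3; uc4: Dice loss + SGD, 100 / 0.001 / 1e-4 / 2; the
meta-network always uses SGD with learning rate and weight decay 0.001).
The toy presets shrink images, widths and epochs to desk scale.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml

from .ddbl_kd import Stage2Config
from .hgkt import Stage1Config

__all__ = ["ExperimentConfig", "PRESETS", "load_config", "save_config"]


@dataclass
class ExperimentConfig:
    name: str = "toy-classification"
    task: str = "classification"
    n_centers: int = 3
    n_samples: int = 48
    image_size: int = 32
    student_width: int = 4
    teacher_family: str = "tiny-vit"
    prevalence: float = 0.5
    effect_strength: float = 1.0
    artifact_prob: float = 0.1
    rounds: int = 10
    top_fraction: float = 0.5
    split_ratios: tuple[float, ...] = (0.6, 0.4)
    stage1: Stage1Config = field(default_factory=Stage1Config)
    stage2: Stage2Config = field(default_factory=Stage2Config)
    seed: int = 42
    out_dir: str = "results"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["split_ratios"] = list(self.split_ratios)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        d["stage1"] = Stage1Config(**d.get("stage1", {}))
        d["stage2"] = Stage2Config(**d.get("stage2", {}))
        d["split_ratios"] = tuple(d.get("split_ratios", (0.6, 0.4)))
        return cls(**d)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:12]


def _uc(name, task, epochs, lr, wd, batch, optimizer="sgd", size=224):
    return ExperimentConfig(
        name=name, task=task, image_size=size, student_width=64,
        teacher_family="vit-b-14", n_samples=200, rounds=10,
        split_ratios=(0.6, 0.4) if name == "uc1" else (0.64, 0.16, 0.2),
        stage1=Stage1Config(epochs=epochs, lr=lr, weight_decay=wd,
                            batch_size=batch, optimizer=optimizer,
                            lr_meta=0.001),
        stage2=Stage2Config(epochs=1, lr=lr, weight_decay=wd,
                            batch_size=batch, optimizer=optimizer))


PRESETS: dict[str, ExperimentConfig] = {
    # published per-use-case training settings
    "uc1": _uc("uc1", "classification", 20, 1e-4, 1e-4, 25),
    "uc2": _uc("uc2", "classification", 10, 1e-2, 1e-3, 32, size=96),
    "uc3": _uc("uc3", "segmentation", 100, 1e-4, 1e-4, 3, "adam", size=384),
    "uc4": _uc("uc4", "segmentation", 100, 1e-3, 1e-4, 2, size=256),
    # desk-scale
    "toy-classification": ExperimentConfig(),
    "toy-segmentation": ExperimentConfig(
        name="toy-segmentation", task="segmentation", image_size=32,
        n_samples=24, student_width=2, rounds=2,
        stage1=Stage1Config(epochs=2, lr=0.01, batch_size=4),
        stage2=Stage2Config(epochs=1, lr=0.01, batch_size=4)),
}


def save_config(config: ExperimentConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def load_config(path) -> ExperimentConfig:
    with open(path) as fh:
        return ExperimentConfig.from_dict(yaml.safe_load(fh))
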