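"""Run configuration: one strict, serializable record per experiment.

Defaults mirror the reference training protocol (100 epochs, batch size 16,
learning rate 0.001, Adam, cross-entropy, beta1 = 0.2, 224 x 224 inputs);
smoke-scale experiments override them.  Unknown keys in a config file are an
error so typos never silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses

import yaml

VOTING_MODES = ("average", "standard", "individual", "group", "mixed")


@dataclasses.dataclass
class RunConfig:
    seed: int = 0
    epochs: int = 100
    batch_size: int = 16
    learning_rate: float = 0.001
    beta1: float = 0.2
    voting_mode: str = "mixed"
    use_csae: bool = True
    backbones: tuple[str, ...] = ("tiny_cnn", "tiny_cnn_wide")
    image_size: int = 224
    restarts: int = 32
    temperature: float = 1.0
    csae_kernel: int = 3
    rescale_attention: bool = False
    primary_mass: float = 0.55
    augment: bool = False
    copies_per_image: int = 7
    synth_n_per_class: int = 0  # > 0: generate a synthetic dataset
    noise_level: float = 0.03
    manifest: str | None = None  # path to an existing manifest CSV
    out_dir: str = "runs"

    def __post_init__(self):
        if self.voting_mode not in VOTING_MODES:
            raise ValueError(
                f"voting_mode must be one of {VOTING_MODES}, got {self.voting_mode!r}"
            )
        if not 0.0 <= self.beta1 <= 1.0:
            raise ValueError(f"beta1 must be in [0, 1], got {self.beta1}")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        self.backbones = tuple(self.backbones)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(d) - known)
        if unknown:
            raise ValueError(f"unknown config keys: {unknown}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)  # YAML errors carry line/column info
        if not isinstance(d, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        return cls.from_dict(d)

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["backbones"] = list(self.backbones)
        return d
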