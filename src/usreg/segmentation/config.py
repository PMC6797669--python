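"""Training configuration and dataset splits for the segmentation network."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

__all__ = ["UNetConfig", "DatasetSplit"]


@dataclass
class UNetConfig:
    """Hyperparameters of the 3D U-Net and its patch-based training.

    The defaults are the published operating point of the method: two
    resolution steps, dropout 0.4 on the synthesis path, a (30,30,30) core
    patch with an (8,8,8) per-side context border (46^3 network input),
    batches of 15 samples, learning rate 1e-3, and model selection by the
    best validation Jaccard computed on 75 samples every 100 iterations.
    """

    resolution_steps: int = 2
    dropout_rate: float = 0.4
    base_channels: int = 16
    patch_size: tuple[int, int, int] = (30, 30, 30)
    padding: tuple[int, int, int] = (8, 8, 8)
    batch_size: int = 15
    learning_rate: float = 1e-3
    val_samples: int = 75
    val_interval: int = 100
    max_iterations: int = 1000
    seed: int = 0
    loss: str = "bce"  # or "dice"
    balanced_fraction: float = 0.5
    threshold: float = 0.5
    stop_at_val_jaccard: float | None = None

    def __post_init__(self):
        self.patch_size = tuple(int(p) for p in self.patch_size)
        self.padding = tuple(int(p) for p in self.padding)
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if any(p < 1 for p in self.patch_size):
            raise ValueError("patch_size entries must be positive")
        if self.loss not in ("bce", "dice"):
            raise ValueError("loss must be 'bce' or 'dice'")

    @property
    def tile_shape(self) -> tuple[int, int, int]:
        """Network input shape: core plus context border on every side."""
        return tuple(p + 2 * b for p, b in zip(self.patch_size, self.padding))

    def to_yaml(self, path):
        d = asdict(self)
        d["patch_size"] = list(self.patch_size)
        d["padding"] = list(self.padding)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "UNetConfig":
        with open(path, encoding="utf-8") as fh:
            d = yaml.safe_load(fh)
        return cls(**d)


@dataclass
class DatasetSplit:
    """Pairwise-disjoint train/validation/test case lists."""

    train: list = field(default_factory=list)
    validation: list = field(default_factory=list)
    test: list = field(default_factory=list)

    def __post_init__(self):
        ids = [id(c) for part in (self.train, self.validation, self.test) for c in part]
        if len(ids) != len(set(ids)):
            raise ValueError("train/validation/test lists must be pairwise disjoint")
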