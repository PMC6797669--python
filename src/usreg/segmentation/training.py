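"""Patch sampling, training with Jaccard model selection, tiled inference."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ..core import Mask3D, Volume3D, require_same_geometry
from ..errors import SizeError, TrainingError
from .config import DatasetSplit, UNetConfig
from .layers import bce_with_logits, soft_dice_loss
from .unet import UNet3D

__all__ = ["Patch", "TrainedModel", "sample_patches", "train", "predict_mask", "jaccard"]


@dataclass
class Patch:
    """One training sample: context-padded input tile and core label tile."""

    input: np.ndarray  # (tile_shape,) z-scored intensities
    label: np.ndarray  # (patch_size,) binary core
    origin: tuple[int, int, int]  # core origin in volume voxel indices


def _case_arrays(case) -> tuple[np.ndarray, np.ndarray]:
    """Accept a PhantomCase or a (Volume3D, Mask3D) pair."""
    if hasattr(case, "volume") and hasattr(case, "mask"):
        vol, mask = case.volume, case.mask
    else:
        vol, mask = case
    v = np.asarray(vol.data, dtype=np.float32)
    m = (np.asarray(mask.data) > 0.5).astype(np.float32)
    # z-score per volume; plain intensity units would swamp the first layers
    std = v.std()
    v = (v - v.mean()) / (std if std > 0 else 1.0)
    return v, m


def sample_patches(case, cfg: UNetConfig, n: int, rng: np.random.Generator | None = None,
                   balanced: bool | None = None) -> list[Patch]:
    """Draw ``n`` seed-deterministic patches from one case.

    Each input tile is the core (``cfg.patch_size``) plus a context border of
    ``cfg.padding`` voxels per side, mirror-extended at volume boundaries;
    the label tile is the core of the mask.  With balanced sampling (the
    default), half of the core centers land on mask voxels — sheets occupy
    only a few percent of the volume, so uniform sampling would rarely see
    foreground.
    """
    if n <= 0:
        raise ValueError("number of patches must be positive")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    if balanced is None:
        balanced = cfg.balanced_fraction > 0
    v, m = _case_arrays(case)
    core = np.asarray(cfg.patch_size)
    pad = np.asarray(cfg.padding)
    shape = np.asarray(v.shape)
    if np.any(shape < core):
        raise SizeError(f"volume {v.shape} smaller than one core tile {cfg.patch_size}")
    vp = np.pad(v, [(p, p) for p in pad], mode="reflect")

    fg = np.argwhere(m > 0.5)
    max_origin = shape - core
    patches = []
    for _ in range(n):
        if balanced and len(fg) > 0 and rng.random() < cfg.balanced_fraction:
            center = fg[rng.integers(len(fg))]
            origin = np.clip(center - core // 2, 0, max_origin)
        else:
            origin = np.array([rng.integers(0, mo + 1) for mo in max_origin])
        o = origin
        tile = vp[o[0] : o[0] + core[0] + 2 * pad[0],
                  o[1] : o[1] + core[1] + 2 * pad[1],
                  o[2] : o[2] + core[2] + 2 * pad[2]]
        label = m[o[0] : o[0] + core[0], o[1] : o[1] + core[1], o[2] : o[2] + core[2]]
        patches.append(Patch(input=tile.copy(), label=label.copy(), origin=tuple(int(x) for x in o)))
    return patches


@dataclass
class TrainedModel:
    """Weights of the best checkpoint plus the full training history."""

    config: UNetConfig
    state: dict
    history: list = field(default_factory=list)  # (iteration, val_jaccard)
    selected_checkpoint: int = 0

    def build_network(self) -> UNet3D:
        net = UNet3D(
            steps=self.config.resolution_steps,
            base_channels=self.config.base_channels,
            dropout=self.config.dropout_rate,
            seed=self.config.seed,
        )
        net.load_state_dict(self.state)
        return net

    def save(self, directory):
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        np.savez(d / "weights.npz", **self.state)
        self.config.to_yaml(d / "config.yaml")
        pd.DataFrame(self.history, columns=["iteration", "val_jaccard"]).to_csv(
            d / "history.csv", index=False
        )
        (d / "selected.txt").write_text(str(self.selected_checkpoint), encoding="utf-8")

    @classmethod
    def load(cls, directory) -> "TrainedModel":
        d = Path(directory)
        cfg = UNetConfig.from_yaml(d / "config.yaml")
        with np.load(d / "weights.npz") as z:
            state = {k: z[k] for k in z.files}
        hist = pd.read_csv(d / "history.csv").values.tolist()
        sel = int((d / "selected.txt").read_text())
        return cls(config=cfg, state=state, history=hist, selected_checkpoint=sel)


def _batch(patches: list[Patch]) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([p.input for p in patches])[:, None]
    y = np.stack([p.label for p in patches])[:, None]
    return x, y


def _core_slice(cfg: UNetConfig):
    return tuple(slice(p, p + c) for p, c in zip(cfg.padding, cfg.patch_size))


def _patch_jaccard(pred: np.ndarray, truth: np.ndarray) -> float:
    inter = float(np.logical_and(pred, truth).sum())
    union = float(np.logical_or(pred, truth).sum())
    return 1.0 if union == 0 else inter / union


def train(split: DatasetSplit, cfg: UNetConfig) -> TrainedModel:
    """Optimize the U-Net on sampled patches with Jaccard model selection.

    Every ``cfg.val_interval`` iterations the mean Jaccard over a fixed set
    of ``cfg.val_samples`` validation patches is recorded and the weights
    checkpointed if it improves; the returned model carries the best
    checkpoint and the full history.
    """
    if not split.train or not split.validation:
        raise ValueError("train and validation case lists must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    net = UNet3D(
        steps=cfg.resolution_steps,
        base_channels=cfg.base_channels,
        dropout=cfg.dropout_rate,
        seed=cfg.seed,
    )
    opt = net.make_optimizer(cfg.learning_rate)
    loss_fn = bce_with_logits if cfg.loss == "bce" else soft_dice_loss
    core = _core_slice(cfg)

    # fixed validation patch set, sampled once
    val_rng = np.random.default_rng(cfg.seed + 10_000)
    per_case = int(np.ceil(cfg.val_samples / len(split.validation)))
    val_patches = []
    for case in split.validation:
        val_patches += sample_patches(case, cfg, per_case, rng=val_rng)
    val_patches = val_patches[: cfg.val_samples]

    def validate() -> float:
        scores = []
        for i in range(0, len(val_patches), max(1, cfg.batch_size)):
            chunk = val_patches[i : i + max(1, cfg.batch_size)]
            x, y = _batch(chunk)
            prob = net.predict_proba(x)[(slice(None), slice(None), *core)]
            pred = prob >= cfg.threshold
            for b in range(len(chunk)):
                scores.append(_patch_jaccard(pred[b, 0], y[b, 0] > 0.5))
        return float(np.mean(scores))

    history: list[tuple[int, float]] = []
    best_state, best_jac, best_iter = net.state_dict(), -1.0, 0
    for it in range(1, cfg.max_iterations + 1):
        case = split.train[rng.integers(len(split.train))]
        batch = sample_patches(case, cfg, cfg.batch_size, rng=rng)
        x, y = _batch(batch)
        logits = net.forward(x, training=True)
        loss, dlog_core = loss_fn(logits[(slice(None), slice(None), *core)], y)
        if not np.isfinite(loss):
            raise TrainingError(f"non-finite loss at iteration {it}", iteration=it)
        dlogits = np.zeros_like(logits)
        dlogits[(slice(None), slice(None), *core)] = dlog_core
        opt.zero_grad()
        net.backward(dlogits)
        opt.step()

        if it % cfg.val_interval == 0:
            jac = validate()
            history.append((it, jac))
            if jac > best_jac:
                best_jac, best_state, best_iter = jac, net.state_dict(), it
            if cfg.stop_at_val_jaccard is not None and best_jac >= cfg.stop_at_val_jaccard:
                break

    return TrainedModel(
        config=cfg, state=best_state, history=history, selected_checkpoint=best_iter
    )


def predict_mask(model: TrainedModel, v: Volume3D, threshold: float | None = None):
    """Tile-and-stitch inference; returns (binary mask, probability mask).

    The volume is tiled into non-overlapping cores with a mirror-padded
    context border; only each tile's core is written to the output, so the
    stitched map has no seams from border effects.
    """
    cfg = model.config
    threshold = cfg.threshold if threshold is None else threshold
    core = np.asarray(cfg.patch_size)
    pad = np.asarray(cfg.padding)
    shape = np.asarray(v.shape)
    if np.any(shape < core):
        raise SizeError(f"volume {v.shape} smaller than one core tile {cfg.patch_size}")

    data = np.asarray(v.data, dtype=np.float32)
    std = data.std()
    data = (data - data.mean()) / (std if std > 0 else 1.0)
    vp = np.pad(data, [(p, p) for p in pad], mode="reflect")
    net = model.build_network()

    prob = np.zeros(v.shape, dtype=np.float32)
    starts = [sorted({min(s, int(shape[a]) - int(core[a])) for s in range(0, int(shape[a]), int(core[a]))})
              for a in range(3)]
    for o0 in starts[0]:
        for o1 in starts[1]:
            for o2 in starts[2]:
                tile = vp[o0 : o0 + core[0] + 2 * pad[0],
                          o1 : o1 + core[1] + 2 * pad[1],
                          o2 : o2 + core[2] + 2 * pad[2]]
                p = net.predict_proba(tile[None, None])[0, 0]
                cs = tuple(slice(pp, pp + cc) for pp, cc in zip(pad, core))
                prob[o0 : o0 + core[0], o1 : o1 + core[1], o2 : o2 + core[2]] = p[cs]

    prob_mask = Mask3D.like(v, np.clip(prob, 0, 1), kind="probability")
    return prob_mask.binarize(threshold), prob_mask


def jaccard(a: Mask3D, b: Mask3D) -> float:
    """|A ∩ B| / |A ∪ B| over binary masks; 1.0 when both are empty."""
    require_same_geometry(a, b, "jaccard operands")
    am = np.asarray(a.data) > 0.5
    bm = np.asarray(b.data) > 0.5
    union = float(np.logical_or(am, bm).sum())
    if union == 0:
        return 1.0
    return float(np.logical_and(am, bm).sum()) / union
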