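"""Evaluation suite: landmark TRE, Dice variants, mask statistics, capture range.

Target registration error (TRE) is the Euclidean distance, in mm, between a
reference landmark mapped through the computed transform chain and its
annotated counterpart in the other volume.  Dice is reported both plainly
and in a correspondence-restricted variant that discards predicted connected
components with no counterpart in the manual annotation — the fair score
when the manual annotation is sparse.  The capture range is the largest
initial misalignment (as mean TRE) from which registration still converges
for at least 80% of trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import LandmarkSet, Mask3D, Volume3D, require_paired, require_same_geometry
from .errors import UndefinedStatisticError
from .transforms import RigidTransform, TransformChain

__all__ = [
    "TREReport",
    "tre",
    "dice",
    "dice_correspondence_restricted",
    "MaskStats",
    "mask_stats",
    "pearson",
    "CaptureRangeProtocol",
    "CaptureRangeResult",
    "capture_range_from_table",
    "capture_range",
    "mean_tre",
]


@dataclass
class TREReport:
    """Per-landmark distances (mm) with summary statistics."""

    distances: np.ndarray
    mean: float
    std: float
    min: float
    max: float
    n_landmarks: int

    @classmethod
    def from_distances(cls, d) -> "TREReport":
        d = np.asarray(d, dtype=float)
        return cls(
            distances=d,
            mean=float(d.mean()),
            std=float(d.std()),
            min=float(d.min()),
            max=float(d.max()),
            n_landmarks=len(d),
        )

    def as_dict(self) -> dict:
        return {
            "mean": self.mean,
            "std": self.std,
            "min": self.min,
            "max": self.max,
            "n_landmarks": self.n_landmarks,
        }


def tre(ref_lm: LandmarkSet, other_lm: LandmarkSet, chain: TransformChain | None = None) -> TREReport:
    """distances_i = || chain(ref_i) - other_i || in mm."""
    require_paired(ref_lm, other_lm)
    chain = chain if chain is not None else TransformChain()
    mapped = chain.apply(ref_lm.points)
    d = np.linalg.norm(mapped - other_lm.points, axis=1)
    return TREReport.from_distances(d)


def mean_tre(ref_lm: LandmarkSet, other_lm: LandmarkSet, chain: TransformChain | None = None) -> float:
    return tre(ref_lm, other_lm, chain).mean


def dice(a: Mask3D, b: Mask3D) -> float:
    """2|A ∩ B| / (|A| + |B|); 1.0 when both masks are empty."""
    require_same_geometry(a, b, "dice operands")
    am = np.asarray(a.data) > 0.5
    bm = np.asarray(b.data) > 0.5
    denom = float(am.sum() + bm.sum())
    if denom == 0:
        return 1.0
    return 2.0 * float(np.logical_and(am, bm).sum()) / denom


_CONN26 = np.ones((3, 3, 3), dtype=int)


def dice_correspondence_restricted(pred: Mask3D, manual: Mask3D) -> float:
    """Dice after discarding predicted components with no manual counterpart.

    Predicted 26-connected components with zero overlap against the manual
    mask are removed before computing Dice; a component "corresponds" as
    soon as it shares one voxel.
    """
    require_same_geometry(pred, manual, "dice operands")
    pm = np.asarray(pred.data) > 0.5
    mm = np.asarray(manual.data) > 0.5
    labels, n = ndimage.label(pm, structure=_CONN26)
    if n > 0:
        overlap = ndimage.sum_labels(mm.astype(np.int64), labels, index=np.arange(1, n + 1))
        keep = np.zeros(n + 1, dtype=bool)
        keep[1:] = overlap > 0
        pm = keep[labels]
    kept = Mask3D.like(pred, pm.astype(np.uint8), kind="binary")
    return dice(kept, manual)


@dataclass
class MaskStats:
    """Mean intensity inside/outside a mask, plus mask volume in mm^3."""

    mean_inside: float | None
    mean_outside: float | None
    volume_mm3: float


def mask_stats(v: Volume3D, m: Mask3D) -> MaskStats:
    """Inside/outside intensity means; an empty region reports None."""
    require_same_geometry(v, m, "mask_stats operands")
    data = np.asarray(v.data, dtype=float)
    inside = np.asarray(m.data) > 0.5
    n_in = int(inside.sum())
    n_out = int(inside.size - n_in)
    return MaskStats(
        mean_inside=float(data[inside].mean()) if n_in else None,
        mean_outside=float(data[~inside].mean()) if n_out else None,
        volume_mm3=n_in * v.voxel_volume,
    )


def pearson(x, y) -> float:
    """Sample Pearson correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("pearson expects two equally long 1D sequences")
    if len(x) < 3:
        raise ValueError("pearson needs at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedStatisticError("pearson undefined for zero-variance input")
    return float(np.corrcoef(x, y)[0, 1])


# ---------------------------------------------------------------------------
# Capture range
# ---------------------------------------------------------------------------

@dataclass
class CaptureRangeProtocol:
    """Misalignment magnitudes to probe, trials per offset, success rule.

    ``success_threshold_mm = None`` applies the default rule: a trial
    succeeds when its final mean TRE is at most
    ``max(1 voxel, 1.5 x the unperturbed run's final mean TRE)``.
    """

    offsets_mm: tuple = (1.0, 2.0, 3.0, 4.0, 5.0)
    trials_per_offset: int = 10
    success_threshold_mm: float | None = None
    success_fraction: float = 0.80

    def __post_init__(self):
        offs = tuple(float(o) for o in self.offsets_mm)
        if any(b <= a for a, b in zip(offs, offs[1:])):
            raise ValueError("offsets must be strictly increasing")
        if not 0 < self.success_fraction <= 1:
            raise ValueError("success fraction must lie in (0, 1]")
        self.offsets_mm = offs


@dataclass
class CaptureRangeResult:
    range_mm: float
    censored: bool  # True when every tested offset passed
    table: dict = field(default_factory=dict)  # offset -> (successes, trials)
    diagnostic: str = ""


def capture_range_from_table(table: dict, success_fraction: float = 0.80) -> CaptureRangeResult:
    """Largest offset whose success fraction passes, with first-failure cut.

    ``table`` maps offset (mm) to ``(successes, trials)``.  Offsets beyond
    the first failing one do not count even if they pass.
    """
    best = 0.0
    censored = True
    for off in sorted(table):
        succ, tot = table[off]
        if tot > 0 and succ / tot >= success_fraction:
            best = float(off)
        else:
            censored = False
            break
    diag = "" if best > 0 else "no offset reached the required success fraction"
    return CaptureRangeResult(range_mm=best, censored=censored, table=dict(table), diagnostic=diag)


def capture_range(
    ref_mask: Mask3D,
    tmpl_mask: Mask3D,
    ref_lm: LandmarkSet,
    tmpl_lm: LandmarkSet,
    protocol: CaptureRangeProtocol,
    seed: int = 0,
    register_fn=None,
    config=None,
) -> CaptureRangeResult:
    """Probe convergence from random rigid misalignments of growing size.

    For each offset magnitude, ``trials_per_offset`` registrations start
    from random pure translations of that magnitude (so the initial mean TRE
    equals the offset); a trial succeeds when the final mean TRE passes the
    protocol's rule.  Returns the largest offset at which at least
    ``success_fraction`` of trials succeed, cut at the first failure.
    """
    from .registration import register_parametric

    if register_fn is None:
        def register_fn(ref, tmpl, init):
            rigid, _ = register_parametric(ref, tmpl, init=init, config=config)
            return TransformChain([rigid])

    rng = np.random.default_rng(seed)

    # unperturbed baseline defines the default success threshold
    base_chain = register_fn(ref_mask, tmpl_mask, RigidTransform.identity())
    base_mtre = mean_tre(ref_lm, tmpl_lm, base_chain)
    if protocol.success_threshold_mm is not None:
        thr = protocol.success_threshold_mm
    else:
        thr = max(float(np.max(ref_mask.spacing)), 1.5 * base_mtre)

    table: dict[float, tuple[int, int]] = {}
    for off in protocol.offsets_mm:
        succ = 0
        for _ in range(protocol.trials_per_offset):
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            init = RigidTransform(translation=direction * off)
            chain = register_fn(ref_mask, tmpl_mask, init)
            if mean_tre(ref_lm, tmpl_lm, chain) <= thr:
                succ += 1
        table[off] = (succ, protocol.trials_per_offset)
        if succ / protocol.trials_per_offset < protocol.success_fraction:
            break  # first failure: larger offsets cannot count anyway
    return capture_range_from_table(table, protocol.success_fraction)
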