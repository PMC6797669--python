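"""Coarse-to-fine image pyramids (smooth, then subsample by 2)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from ..core import Mask3D, Volume3D
from ..errors import SizeError

__all__ = ["PyramidLevel", "build_pyramid"]


@dataclass
class PyramidLevel:
    """One pyramid level; index 0 is the native grid."""

    index: int
    image: Volume3D


def _halve(img: Volume3D) -> Volume3D:
    """Gaussian smoothing (sigma = 1 fine voxel) then factor-2 subsampling.

    Node-centered subsampling keeps node 0 at the origin, so world geometry
    is preserved; spacing doubles exactly.
    """
    data = gaussian_filter(np.asarray(img.data, dtype=np.float32), sigma=1.0, mode="nearest")
    data = data[::2, ::2, ::2]
    kwargs = dict(
        data=data,
        spacing=img.spacing * 2,
        origin=img.origin,
        direction=img.direction,
    )
    if isinstance(img, Mask3D):
        return Mask3D(kind="probability", **{**kwargs, "data": np.clip(data, 0.0, 1.0)})
    return Volume3D(**kwargs)


def build_pyramid(x: Volume3D, levels: int) -> list[PyramidLevel]:
    """Levels 0..``levels``; level L has spacing ``native * 2**L``."""
    if min(x.shape) < 2**levels + 1:
        raise SizeError(
            f"grid {x.shape} too small for {levels} pyramid levels "
            f"(needs >= {2**levels + 1} samples per axis)"
        )
    out = [PyramidLevel(0, x)]
    cur = x
    for lv in range(1, levels + 1):
        cur = _halve(cur)
        out.append(PyramidLevel(lv, cur))
    return out
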