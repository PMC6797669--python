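"""Pull-back resampling of volumes and masks through transform chains."""

from __future__ import annotations

import numpy as np
from scipy.ndimage import map_coordinates

from .core import Mask3D, Volume3D
from .transforms import TransformChain

__all__ = ["resample"]


def resample(x: Volume3D, chain: TransformChain, target: Volume3D | None = None):
    """Resample ``x`` onto ``target``'s grid through ``chain`` (pull-back).

    The output value at each target voxel p is ``x(chain(p))`` with trilinear
    interpolation; reads outside ``x``'s grid return 0 (background).  Returns
    the same kind as ``x`` (a mask input yields a probability-kind mask; the
    caller re-binarizes if needed).
    """
    if target is None:
        target = x
    pts = target.grid_world_points()
    mapped = chain.apply(pts)
    idx = x.world_to_index(mapped).T  # (3, N)
    data = np.asarray(x.data, dtype=float)
    out = map_coordinates(data, idx, order=1, mode="grid-constant", cval=0.0)
    out = out.reshape(target.shape)
    if isinstance(x, Mask3D):
        out = np.clip(out, 0.0, 1.0)
        return Mask3D(
            data=out.astype(np.float32),
            spacing=target.spacing,
            origin=target.origin,
            direction=target.direction,
            kind="probability",
        )
    return Volume3D(
        data=out.astype(np.float32),
        spacing=target.spacing,
        origin=target.origin,
        direction=target.direction,
    )
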