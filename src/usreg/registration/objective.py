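"""Distance and regularity terms of the variational objective.

The registration functional is J(phi) = D(R, T∘phi) + alpha·S(u): an SSD
distance between the reference mask and the deformed template mask, plus a
linear-elastic penalty on the nonparametric part u of the displacement.
Both terms are discretized on the voxel grid (discretize-then-optimize) and
scaled by the voxel volume so values are comparable across pyramid levels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..core import Volume3D, require_same_geometry
from ..transforms import DeformationField

__all__ = ["ssd", "elastic_energy", "elastic_energy_and_grad", "ObjectiveValue"]


@dataclass
class ObjectiveValue:
    """One evaluation of J = D + alpha * S."""

    distance: float
    regularity: float
    alpha: float

    @property
    def total(self) -> float:
        return self.distance + self.alpha * self.regularity


def ssd(ref: Volume3D, def_tmpl: Volume3D) -> float:
    """Sum of squared differences, D = 1/2 * sum (T - R)^2 * voxel volume."""
    require_same_geometry(ref, def_tmpl, "ssd operands")
    diff = np.asarray(def_tmpl.data, dtype=float) - np.asarray(ref.data, dtype=float)
    return 0.5 * float(np.sum(diff**2)) * ref.voxel_volume


# -- finite-difference machinery -------------------------------------------
# np.gradient's stencil (central interior, one-sided at the boundary); the
# adjoint below is its exact transpose, verified by inner-product tests.

def _grad_axis(f: np.ndarray, h: float, axis: int) -> np.ndarray:
    return np.gradient(f, h, axis=axis)


def _grad_axis_adjoint(y: np.ndarray, h: float, axis: int) -> np.ndarray:
    out = np.zeros_like(y)
    ym = np.moveaxis(y, axis, 0)
    om = np.moveaxis(out, axis, 0)
    n = ym.shape[0]
    if n >= 3:
        om[2:] += ym[1:-1] / (2 * h)
        om[:-2] -= ym[1:-1] / (2 * h)
    om[0] -= ym[0] / h
    om[1] += ym[0] / h
    om[-1] += ym[-1] / h
    om[-2] -= ym[-1] / h
    return out


def elastic_energy_and_grad(
    disp: np.ndarray, spacing, mu: float, lam: float
) -> tuple[float, np.ndarray]:
    """Linear-elastic potential of a displacement array (3, n0, n1, n2).

    S(u) = sum over nodes of [ mu/4 * sum_{j,k} (d_j u_k + d_k u_j)^2
                               + lam/2 * (div u)^2 ] * voxel volume,
    with mm-scaled central differences and Neumann (one-sided) boundaries.
    Returns (S, dS/du) with the gradient in the same array layout.
    """
    spacing = np.asarray(spacing, dtype=float)
    hvol = float(np.prod(spacing))
    D = [[_grad_axis(disp[k], spacing[j], axis=j) for k in range(3)] for j in range(3)]
    E = [[D[j][k] + D[k][j] for k in range(3)] for j in range(3)]
    div = D[0][0] + D[1][1] + D[2][2]

    s = 0.0
    for j in range(3):
        for k in range(3):
            s += float(np.sum(E[j][k] ** 2))
    energy = hvol * (mu / 4.0 * s + lam / 2.0 * float(np.sum(div**2)))

    grad = np.zeros_like(disp)
    for k in range(3):
        acc = np.zeros_like(disp[k])
        for j in range(3):
            acc += _grad_axis_adjoint(E[j][k], spacing[j], axis=j)
        grad[k] = hvol * (mu * acc + lam * _grad_axis_adjoint(div, spacing[k], axis=k))
    return energy, grad


def elastic_energy(u: DeformationField, mu: float = 1.0, lam: float = 0.0) -> float:
    """Elastic potential of a :class:`DeformationField` (see above)."""
    energy, _ = elastic_energy_and_grad(u.displacements, u.spacing, mu, lam)
    return energy
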