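"""Mask-driven parametric and nonparametric registration stages.

The pipeline mirrors standard variational registration practice:

1. *Parametric pre-registration*, one pyramid level coarser than native:
   translation-only (3 parameters), then full rigid (6 parameters), both
   minimizing SSD between the softened masks by l-BFGS, starting from the
   tracker-provided initial guess.
2. *Nonparametric elastic stage* on three scales (pyramid levels 3 → 2 → 1):
   minimizes SSD + alpha * elastic(u) over a dense displacement u added on
   top of the rigid map, prolongating u trilinearly between levels.

Hard binary masks have an almost-everywhere-zero SSD gradient, so both
stages consume Gaussian-softened masks (sigma = 1 voxel by default) or the
network's probability output directly.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates, zoom

from ..core import Mask3D, Volume3D
from ..errors import DegenerateInputError
from ..resample import resample
from ..transforms import (
    DeformationField,
    RigidTransform,
    TransformChain,
    euler_matrix_derivatives,
    euler_to_matrix,
)
from .lbfgs import OptimizationLog, StoppingCriteria, lbfgs_optimize
from .objective import elastic_energy_and_grad
from .pyramid import build_pyramid

__all__ = [
    "RegistrationConfig",
    "RegistrationResult",
    "soften_mask",
    "register_parametric",
    "register_nonparametric",
    "register",
]


@dataclass
class RegistrationConfig:
    """Tunables of the variational engine.

    alpha weighs the elastic penalty against SSD; mu and lam are the Lamé
    parameters of the elastic potential; sigma_soften (voxels) controls mask
    softening; the parametric stage runs at ``parametric_level`` and the
    nonparametric stage sweeps ``coarsest_level`` down to ``finest_level``.
    """

    alpha: float = 0.03
    mu: float = 1.0
    lam: float = 0.0
    sigma_soften: float = 1.5
    parametric_level: int = 1
    coarsest_level: int = 3
    finest_level: int = 1
    stopping: StoppingCriteria = dc_field(default_factory=StoppingCriteria)


@dataclass
class RegistrationResult:
    """Transform chain, deformed template, per-stage logs, convergence."""

    chain: TransformChain
    deformed_template: Volume3D | Mask3D
    log: dict
    converged: bool
    stop_reasons: dict
    timings: dict = dc_field(default_factory=dict)


def soften_mask(mask: Mask3D, sigma_vox: float = 1.0) -> Mask3D:
    """Gaussian-soften a mask so SSD has usable gradients."""
    data = np.asarray(mask.data, dtype=np.float32)
    if sigma_vox > 0 and mask.kind == "binary":
        data = gaussian_filter(data, sigma=sigma_vox, mode="nearest")
    return Mask3D.like(mask, np.clip(data, 0.0, 1.0), kind="probability")


def _world_gradient(img: Volume3D) -> np.ndarray:
    """Spatial gradient in world (mm) coordinates, shape (3, n0, n1, n2)."""
    g_idx = np.stack(np.gradient(np.asarray(img.data, dtype=float), *img.spacing))
    # rotate index-axis derivatives into the world frame
    return np.einsum("ab,b...->a...", img.direction, g_idx)


class _TemplateSampler:
    """Interpolates a template level and its world gradient at world points."""

    def __init__(self, tmpl: Volume3D):
        self.tmpl = tmpl
        self.data = np.asarray(tmpl.data, dtype=float)
        self.grad = _world_gradient(tmpl)

    def __call__(self, pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        idx = self.tmpl.world_to_index(pts).T
        val = map_coordinates(self.data, idx, order=1, mode="grid-constant", cval=0.0)
        g = np.stack(
            [map_coordinates(self.grad[c], idx, order=1, mode="grid-constant", cval=0.0) for c in range(3)],
            axis=-1,
        )
        return val, g


def _check_nonempty(mask: Mask3D, name: str):
    if float(np.sum(mask.data)) <= 0:
        raise DegenerateInputError(f"{name} mask is empty")


def _world_center(vol: Volume3D) -> np.ndarray:
    last = np.asarray(vol.shape, dtype=float) - 1
    return (vol.index_to_world([0.0, 0.0, 0.0]) + vol.index_to_world(last)) / 2


def register_parametric(
    ref: Mask3D,
    tmpl: Mask3D,
    init: RigidTransform | None = None,
    config: RegistrationConfig | None = None,
) -> tuple[RigidTransform, dict]:
    """Translation then full rigid alignment, one level coarser than native.

    SSD-only (no regularizer applies to parametric maps).  Returns the rigid
    transform expressed at native resolution (world units are level-free)
    and a per-stage log.
    """
    config = config or RegistrationConfig()
    _check_nonempty(ref, "reference")
    _check_nonempty(tmpl, "template")
    init = init or RigidTransform.identity()

    lv = config.parametric_level
    ref_l = build_pyramid(soften_mask(ref, config.sigma_soften), lv)[lv].image
    tmpl_l = build_pyramid(soften_mask(tmpl, config.sigma_soften), lv)[lv].image

    sampler = _TemplateSampler(tmpl_l)
    P = ref_l.grid_world_points()
    R_data = np.asarray(ref_l.data, dtype=float).reshape(-1)
    hvol = ref_l.voxel_volume
    center = _world_center(ref)
    # scale the angle parameters by a lever arm so translation (mm) and
    # rotation parameters see comparable gradients in the line search
    arm = float(np.linalg.norm(_world_center(ref) - ref.index_to_world([0, 0, 0])))
    arm = max(arm, 1.0)

    def objective(params, with_rotation: bool):
        t = params[:3]
        angles = params[3:6] / arm if with_rotation else init.rotation
        R = euler_to_matrix(angles)
        pc = P - center
        phi = center + pc @ R.T + t
        val, g = sampler(phi)
        r = val - R_data
        D = 0.5 * float(np.sum(r**2)) * hvol
        grad_t = (r[:, None] * g).sum(axis=0) * hvol
        if not with_rotation:
            return D, grad_t
        dRs = euler_matrix_derivatives(angles)
        grad_a = np.array(
            [float(np.sum(r * np.sum(g * (pc @ dR.T), axis=1))) * hvol for dR in dRs]
        )
        return D, np.concatenate([grad_t, grad_a / arm])

    log: dict[str, OptimizationLog] = {}
    # stage 1: translation only, from the tracker initial guess
    x0 = init.translation.astype(float).copy()
    x_t, log["translation"] = lbfgs_optimize(
        lambda p: objective(p, with_rotation=False), x0, config.stopping
    )
    # stage 2: all six rigid parameters
    x0 = np.concatenate([x_t, init.rotation * arm])
    x_r, log["rigid"] = lbfgs_optimize(
        lambda p: objective(p, with_rotation=True), x0, config.stopping
    )
    result = RigidTransform(translation=x_r[:3], rotation=x_r[3:6] / arm, center=center)
    return result, log


def _prolong(disp: np.ndarray, target_shape: tuple[int, int, int]) -> np.ndarray:
    """Trilinear prolongation of a (3, ...) displacement array (values in mm
    are level-free, so no rescaling)."""
    factors = [t / s for t, s in zip(target_shape, disp.shape[1:])]
    return np.stack([zoom(disp[c], factors, order=1, mode="nearest") for c in range(3)])


def register_nonparametric(
    ref: Mask3D,
    tmpl: Mask3D,
    init: RigidTransform | None = None,
    config: RegistrationConfig | None = None,
) -> tuple[DeformationField, dict]:
    """Multilevel elastic registration on top of a rigid initializer.

    Solves min_u SSD(ref, tmpl∘(phi_init + u)) + alpha * S(u) by l-BFGS at
    pyramid levels coarsest → finest, prolongating u between levels.  Only
    the correction u is regularized, so the rigid bulk motion carries no
    penalty.  The returned field holds u resampled to the native grid.
    """
    config = config or RegistrationConfig()
    _check_nonempty(ref, "reference")
    _check_nonempty(tmpl, "template")
    init = init or RigidTransform.identity()

    levels = list(range(config.coarsest_level, config.finest_level - 1, -1))
    ref_pyr = build_pyramid(soften_mask(ref, config.sigma_soften), config.coarsest_level)
    tmpl_pyr = build_pyramid(soften_mask(tmpl, config.sigma_soften), config.coarsest_level)

    log: dict[str, OptimizationLog] = {}
    disp = None
    for lv in levels:
        ref_l = ref_pyr[lv].image
        tmpl_l = tmpl_pyr[lv].image
        sampler = _TemplateSampler(tmpl_l)
        P = ref_l.grid_world_points()
        phi0 = init.apply(P)
        R_data = np.asarray(ref_l.data, dtype=float).reshape(-1)
        hvol = ref_l.voxel_volume
        shape_l = ref_l.shape
        spacing_l = ref_l.spacing
        n = P.shape[0]

        if disp is None:
            disp = np.zeros((3, *shape_l))
        else:
            disp = _prolong(disp, shape_l)

        def objective(u_flat, _sampler=sampler, _phi0=phi0, _R=R_data, _h=hvol,
                      _shape=shape_l, _sp=spacing_l, _n=n):
            u = u_flat.reshape(3, *_shape)
            u_pts = u.reshape(3, -1).T
            val, g = _sampler(_phi0 + u_pts)
            r = val - _R
            D = 0.5 * float(np.sum(r**2)) * _h
            dD = (r[:, None] * g * _h).T.reshape(3, *_shape)
            S, dS = elastic_energy_and_grad(u, _sp, config.mu, config.lam)
            J = D + config.alpha * S
            return J, (dD + config.alpha * dS).reshape(-1)

        u_opt, log[f"level{lv}"] = lbfgs_optimize(objective, disp.reshape(-1), config.stopping)
        disp = u_opt.reshape(3, *shape_l)

    if config.finest_level > 0:
        disp = _prolong(disp, ref.shape)
    field = DeformationField(
        displacements=disp, spacing=ref.spacing, origin=ref.origin, direction=ref.direction
    )
    return field, log


def _warp_field_through(field: DeformationField, rigid: RigidTransform, grid: Volume3D) -> DeformationField:
    """Re-index u so that [rigid, field'] reproduces phi(p) = rigid(p) + u(p).

    field'(q) = u(rigid^-1(q)) sampled on ``grid``; exact at grid nodes up to
    interpolation of u.
    """
    pts = grid.grid_world_points()
    back = rigid.inverse().apply(pts)
    u = field.displacement_at(back)
    disp = u.T.reshape(3, *grid.shape)
    return DeformationField(
        displacements=disp, spacing=grid.spacing, origin=grid.origin, direction=grid.direction
    )


def register(
    ref: Mask3D,
    tmpl: Mask3D,
    init: RigidTransform | None = None,
    config: RegistrationConfig | None = None,
) -> RegistrationResult:
    """Full engine: parametric pre-registration then elastic refinement.

    The output chain is [rigid, field] with the field re-indexed so that
    applying the chain reproduces the optimized map; the stored deformed
    template is produced by ``resample(tmpl, chain)`` itself.
    """
    config = config or RegistrationConfig()
    timings = {}
    t0 = time.perf_counter()
    rigid, log_p = register_parametric(ref, tmpl, init=init, config=config)
    timings["parametric_s"] = time.perf_counter() - t0
    t0 = time.perf_counter()
    field, log_n = register_nonparametric(ref, tmpl, init=rigid, config=config)
    timings["nonparametric_s"] = time.perf_counter() - t0

    chain = TransformChain([rigid])
    if rigid.is_identity(atol=1e-15):
        chain = TransformChain([rigid, field])
    else:
        chain = TransformChain([rigid, _warp_field_through(field, rigid, ref)])
    deformed = resample(tmpl, chain, ref)

    log = {"parametric": log_p, "nonparametric": log_n}
    reasons = {f"parametric/{k}": v.stop_reason for k, v in log_p.items()}
    reasons.update({f"nonparametric/{k}": v.stop_reason for k, v in log_n.items()})
    converged = all(
        v.converged for v in list(log_p.values()) + list(log_n.values())
    )
    return RegistrationResult(
        chain=chain,
        deformed_template=deformed,
        log=log,
        converged=converged,
        stop_reasons=reasons,
        timings=timings,
    )
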