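"""Synthetic ultrasound phantoms with ground-truth masks and landmarks.

The generator emulates what matters for mask-driven registration of B-mode
brain ultrasound: bright sheet-like structures (sulci / falx analogues) on a
speckled hypoechogenic background.  Sheets are smooth curved 2D manifolds
(graphs of random low-order trigonometric height functions) thickened to a
physical thickness; intensities are structure/background means modulated by
multiplicative right-skewed speckle; landmarks sit on mask voxels,
preferentially at high-curvature points, mirroring how real landmark sets
cluster at deep grooves and corners of sulci.

Resection is simulated as a sphere whose interior drops to background level
while a thin bright rim appears around it.  The rim is deliberately *not*
added to the ground-truth mask: it is the confounder that resection cavities
pose for mask-based registration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .core import LandmarkSet, Mask3D, Volume3D
from .errors import CapacityError, CoverageError, GeometryError
from .resample import resample
from .transforms import DeformationField, RigidTransform, TransformChain

__all__ = [
    "PhantomSpec",
    "PhantomCase",
    "CavitySpec",
    "generate_phantom",
    "deform_phantom",
    "simulate_resection",
    "random_smooth_field",
    "random_rigid",
]


@dataclass
class PhantomSpec:
    """Parameters of one synthetic case.

    Defaults describe a desk-scale case: a 64^3 grid at 0.5 mm isotropic
    spacing (32 mm field of view) with three curved bright sheets of 1.5 mm
    thickness, a 3:1 structure/background intensity contrast and moderate
    multiplicative speckle.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (0.5, 0.5, 0.5)
    n_sheets: int = 3
    sheet_thickness: float = 1.5
    sheet_intensity_mean: float = 180.0
    background_intensity_mean: float = 60.0
    speckle_scale: float = 0.3
    n_landmarks: int = 15
    landmark_margin_mm: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if self.n_sheets < 1:
            raise ValueError("n_sheets must be >= 1")
        if self.sheet_intensity_mean <= self.background_intensity_mean:
            raise ValueError("sheet intensity mean must exceed background mean")
        if self.n_landmarks < 4:
            raise ValueError("n_landmarks must be >= 4")


@dataclass
class PhantomCase:
    """A generated case: intensity volume, ground-truth mask, landmarks."""

    volume: Volume3D
    mask: Mask3D
    landmarks: LandmarkSet
    spec: PhantomSpec | None = None

    def landmarks_on_mask(self) -> bool:
        """True when every landmark's nearest voxel lies inside the mask."""
        idx = np.rint(self.mask.world_to_index(self.landmarks.points)).astype(int)
        idx = np.clip(idx, 0, np.array(self.mask.shape) - 1)
        return bool(np.all(self.mask.data[idx[:, 0], idx[:, 1], idx[:, 2]] > 0.5))


@dataclass
class CavitySpec:
    """A spherical resection cavity: dark interior, bright rim."""

    center: tuple[float, float, float]
    radius: float
    rim_intensity_mean: float = 180.0
    rim_thickness: float = 1.5

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("cavity radius must be positive")


def _sheet_height_function(rng: np.random.Generator, extent_uv, extent_w, base_frac):
    """Random smooth height h(u, v) in mm for one sheet."""
    lu, lv = extent_uv
    base = base_frac * extent_w
    n_terms = 3
    amps = rng.uniform(0.04, 0.10, n_terms) * extent_w
    fu = rng.uniform(0.4, 1.4, n_terms)
    fv = rng.uniform(0.4, 1.4, n_terms)
    ph = rng.uniform(0, 2 * np.pi, n_terms)
    tilt_u, tilt_v = rng.uniform(-0.15, 0.15, 2)

    def h(u, v):
        out = base + tilt_u * (u - lu / 2) + tilt_v * (v - lv / 2)
        for m in range(n_terms):
            out = out + amps[m] * np.sin(2 * np.pi * (fu[m] * u / lu + fv[m] * v / lv) + ph[m])
        return out

    return h


def generate_phantom(spec: PhantomSpec) -> PhantomCase:
    """Generate a deterministic case from ``spec`` (seeded RNG)."""
    rng = np.random.default_rng(spec.seed)
    shape = tuple(int(s) for s in spec.shape)
    spacing = np.asarray(spec.spacing, dtype=float)
    extent = (np.asarray(shape) - 1) * spacing

    # voxel-center coordinates in mm along each axis
    coords = [np.arange(n) * sp for n, sp in zip(shape, spacing)]

    mask = np.zeros(shape, dtype=bool)
    for s in range(spec.n_sheets):
        axis = s % 3
        others = [a for a in range(3) if a != axis]
        base_frac = (s + 1) / (spec.n_sheets + 1) + rng.uniform(-0.05, 0.05)
        h = _sheet_height_function(
            rng, (extent[others[0]], extent[others[1]]), extent[axis], base_frac
        )
        u, v = np.meshgrid(coords[others[0]], coords[others[1]], indexing="ij")
        hv = h(u, v)  # (n_u, n_v) height along `axis`
        w = coords[axis].reshape([-1 if a == axis else 1 for a in range(3)])
        hv3 = np.expand_dims(hv, axis=axis)
        mask |= np.abs(w - hv3) <= spec.sheet_thickness / 2

    base = np.where(mask, spec.sheet_intensity_mean, spec.background_intensity_mean)
    base = gaussian_filter(base.astype(np.float32), sigma=0.6)
    speckle = (1.0 - spec.speckle_scale) + spec.speckle_scale * rng.exponential(1.0, shape)
    intensity = np.clip(base * speckle, 0.0, 2.5 * spec.sheet_intensity_mean).astype(np.float32)

    volume = Volume3D(data=intensity, spacing=spacing, origin=np.zeros(3))
    mask3d = Mask3D.like(volume, mask.astype(np.uint8), kind="binary")

    landmarks = _sample_landmarks(mask3d, spec.n_landmarks, rng, spec.landmark_margin_mm)
    return PhantomCase(volume=volume, mask=mask3d, landmarks=landmarks, spec=spec)


def _sample_landmarks(
    mask: Mask3D, n: int, rng: np.random.Generator, margin_mm: float = 0.0
) -> LandmarkSet:
    """Sample mask voxels without replacement, weighted toward high curvature.

    Candidates keep a ``margin_mm`` distance from the volume boundary:
    annotated landmarks on real acquisitions lie inside the well-imaged
    overlap of the two volumes, never at the reconstruction margin.
    """
    vox = np.argwhere(mask.data > 0.5)
    if margin_mm > 0:
        lo = np.ceil(margin_mm / mask.spacing)
        hi = np.asarray(mask.shape) - 1 - lo
        inside = np.all((vox >= lo) & (vox <= hi), axis=1)
        if inside.sum() >= n:
            vox = vox[inside]
    if len(vox) < n:
        raise CapacityError(f"requested {n} landmarks but mask has {len(vox)} voxels")
    smooth = gaussian_filter(mask.data.astype(np.float32), sigma=1.5)
    grads = np.gradient(smooth)
    hess_sq = np.zeros(mask.shape, dtype=np.float32)
    for g in grads:
        for gg in np.gradient(g):
            hess_sq += gg**2
    w = np.sqrt(hess_sq)[vox[:, 0], vox[:, 1], vox[:, 2]]
    # restrict to the top-decile curvature voxels: annotators pick distinctive
    # corners and groove junctions, where correspondence is locally
    # unambiguous — a landmark on a featureless flat sheet patch would have
    # no identifiable counterpart
    thr = np.quantile(w, 0.9)
    cand = np.flatnonzero(w >= thr)
    if len(cand) < n:
        cand = np.argsort(w)[-max(n, 1) :]
    wc = w[cand] + 1e-12
    chosen = cand[rng.choice(len(cand), size=n, replace=False, p=wc / wc.sum())]
    pts = mask.index_to_world(vox[chosen])
    return LandmarkSet(points=pts, labels=[f"L{i + 1}" for i in range(n)])


def _world_bounds(vol: Volume3D) -> tuple[np.ndarray, np.ndarray]:
    corners = np.array(
        [[i, j, k] for i in (0, vol.shape[0] - 1) for j in (0, vol.shape[1] - 1) for k in (0, vol.shape[2] - 1)]
    )
    w = vol.index_to_world(corners)
    return w.min(axis=0), w.max(axis=0)


def deform_phantom(case: PhantomCase, motion) -> PhantomCase:
    """Apply a known motion; returned landmarks are the exact correspondence.

    Landmarks are mapped through the analytic ``motion``; the volume and mask
    are pushed forward consistently, i.e. resampled through the motion's
    inverse (closed form for rigid motions, fixed-point inversion for dense
    fields), so that image features travel with the landmarks.
    """
    if isinstance(motion, RigidTransform):
        inverse = motion.inverse()
    elif isinstance(motion, DeformationField):
        inverse = motion.approximate_inverse()
    else:
        raise TypeError(f"unsupported motion type {type(motion)}")

    # coverage check: fraction of mask mass moved outside the field of view
    vox = np.argwhere(case.mask.data > 0.5)
    if len(vox) > 4000:
        vox = vox[:: len(vox) // 4000]
    moved = motion.apply(case.mask.index_to_world(vox))
    lo, hi = _world_bounds(case.volume)
    outside = np.any((moved < lo) | (moved > hi), axis=1)
    if outside.mean() > 0.5:
        raise CoverageError(
            f"motion moves {100 * outside.mean():.0f}% of the mask outside the field of view"
        )

    inv_chain = TransformChain([inverse])
    new_volume = resample(case.volume, inv_chain, case.volume)
    new_mask = resample(case.mask, inv_chain, case.mask).binarize(0.5)
    new_lm = LandmarkSet(points=motion.apply(case.landmarks.points), labels=case.landmarks.labels)
    return PhantomCase(volume=new_volume, mask=new_mask, landmarks=new_lm, spec=case.spec)


def simulate_resection(case: PhantomCase, cavity: CavitySpec, seed: int = 0) -> PhantomCase:
    """Carve a cavity: dark interior, bright rim, mask voxels removed.

    The bright rim mimics how resection cavities appear hyperechogenic; it is
    not added to the ground-truth mask, so any segmentation or registration
    that picks it up is being confounded exactly as on real data.  Landmark
    positions are left untouched (they remain valid world points even where
    the underlying sheet was resected).
    """
    vol, mask = case.volume, case.mask
    lo, hi = _world_bounds(vol)
    c = np.asarray(cavity.center, dtype=float)
    if np.any(c + cavity.radius < lo) or np.any(c - cavity.radius > hi):
        raise GeometryError("cavity sphere does not intersect the volume")

    pts = vol.grid_world_points()
    dist = np.linalg.norm(pts - c, axis=1).reshape(vol.shape)
    interior = dist <= cavity.radius
    rim = (dist > cavity.radius) & (dist <= cavity.radius + cavity.rim_thickness)

    spec = case.spec
    bg = spec.background_intensity_mean if spec is not None else float(
        np.asarray(vol.data)[np.asarray(mask.data) < 0.5].mean()
    )
    sscale = spec.speckle_scale if spec is not None else 0.3
    rng = np.random.default_rng(seed)
    speckle = (1.0 - sscale) + sscale * rng.exponential(1.0, vol.shape)

    data = np.asarray(vol.data).copy()
    data[interior] = (bg * speckle)[interior]
    data[rim] = (cavity.rim_intensity_mean * speckle)[rim]
    new_vol = Volume3D(data=data.astype(np.float32), spacing=vol.spacing, origin=vol.origin, direction=vol.direction)

    new_mask_data = np.asarray(mask.data).copy()
    new_mask_data[interior] = 0
    new_mask = Mask3D.like(vol, new_mask_data.astype(np.uint8), kind="binary")
    return PhantomCase(volume=new_vol, mask=new_mask, landmarks=case.landmarks, spec=spec)


def random_smooth_field(vol: Volume3D, max_mm: float, seed: int = 0) -> DeformationField:
    """A smooth random displacement field with peak magnitude ``max_mm``.

    Brain shift within a small field of view is coherent at the organ scale
    (a gravity-driven sag plus gentle local strain), so the field is built
    from low-order global modes — constant, linear, bilinear and half-period
    sine terms in normalized coordinates — with random coefficients, then
    scaled so the largest displacement magnitude equals ``max_mm``.
    """
    rng = np.random.default_rng(seed)
    axes = [np.linspace(-1.0, 1.0, n) for n in vol.shape]
    X = list(np.meshgrid(*axes, indexing="ij"))
    basis = (
        [np.ones(vol.shape)]
        + X
        + [np.sin(np.pi * x / 2) for x in X]
        + [X[0] * X[1], X[1] * X[2], X[0] * X[2]]
    )
    disp = np.zeros((3, *vol.shape))
    for c in range(3):
        coef = rng.standard_normal(len(basis))
        for b, co in zip(basis, coef):
            disp[c] += co * b
    mag = np.sqrt((disp**2).sum(axis=0)).max()
    if mag > 0:
        disp *= max_mm / mag
    return DeformationField(
        displacements=disp, spacing=vol.spacing, origin=vol.origin, direction=vol.direction
    )


def random_rigid(vol: Volume3D, max_translation_mm: float, max_angle_rad: float, seed: int = 0) -> RigidTransform:
    """A random rigid motion about the volume's world center."""
    rng = np.random.default_rng(seed)
    direction = rng.standard_normal(3)
    direction /= np.linalg.norm(direction)
    t = direction * rng.uniform(0.5, 1.0) * max_translation_mm
    angles = rng.uniform(-max_angle_rad, max_angle_rad, 3)
    lo, hi = _world_bounds(vol)
    return RigidTransform(translation=t, rotation=angles, center=(lo + hi) / 2)
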