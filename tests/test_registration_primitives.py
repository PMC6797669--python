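"""SSD, elastic energy, pyramids, resampling and the l-BFGS core."""

import numpy as np
import pytest
from scipy.optimize import minimize

from usreg import (
    DeformationField,
    Mask3D,
    RigidTransform,
    StoppingCriteria,
    TransformChain,
    Volume3D,
    build_pyramid,
    elastic_energy,
    lbfgs_optimize,
    resample,
    ssd,
)
from usreg.errors import GeometryError, OptimizationError, SizeError
from usreg.registration.objective import (
    _grad_axis,
    _grad_axis_adjoint,
    elastic_energy_and_grad,
)

from conftest import assert_descending


def _vol(data, spacing=(1, 1, 1), origin=(0, 0, 0)):
    return Volume3D(data=np.asarray(data, dtype=np.float32), spacing=spacing, origin=origin)


class TestPyramid:
    def test_constant_volume_stays_constant(self):
        v = _vol(np.full((17, 17, 17), 7.0))
        for level in build_pyramid(v, 3):
            np.testing.assert_allclose(level.image.data, 7.0, rtol=1e-6)

    def test_level_zero_is_input(self, small_case):
        pyr = build_pyramid(small_case.volume, 2)
        assert pyr[0].image is small_case.volume

    def test_spacing_doubles(self, small_case):
        pyr = build_pyramid(small_case.volume, 3)
        for lv in range(4):
            np.testing.assert_allclose(pyr[lv].image.spacing, small_case.volume.spacing * 2**lv)

    def test_mass_preserved_within_two_percent(self, small_case):
        pyr = build_pyramid(small_case.volume, 2)
        native = float(np.sum(np.asarray(pyr[0].image.data, float))) * pyr[0].image.voxel_volume
        for level in pyr[1:]:
            mass = float(np.sum(np.asarray(level.image.data, float))) * level.image.voxel_volume
            assert abs(mass - native) / native < 0.02

    def test_too_small_grid_rejected(self):
        with pytest.raises(SizeError):
            build_pyramid(_vol(np.zeros((4, 4, 4))), 2)


class TestResample:
    def test_identity_reproduces_grid_values(self, small_case):
        out = resample(small_case.volume, TransformChain())
        np.testing.assert_allclose(out.data, small_case.volume.data, atol=1e-5)

    def test_one_voxel_translation_shifts_grid(self, small_case):
        sp = small_case.volume.spacing
        chain = TransformChain([RigidTransform(translation=[sp[0], 0, 0])])
        out = resample(small_case.volume, chain)
        np.testing.assert_allclose(
            np.asarray(out.data)[:-1], np.asarray(small_case.volume.data)[1:], atol=1e-4
        )

    def test_rigid_map_matches_per_voxel_oracle(self, rng):
        from scipy.ndimage import map_coordinates

        v = _vol(rng.random((10, 10, 10)), spacing=(0.7, 0.9, 1.1), origin=(1, 2, 3))
        t = RigidTransform(translation=[0.5, -0.3, 0.2], rotation=[0.05, -0.03, 0.08],
                           center=[4, 5, 6])
        out = resample(v, TransformChain([t]))
        # independent per-voxel check on a random subset
        for _ in range(30):
            idx = tuple(rng.integers(0, 10, 3))
            p = v.index_to_world(np.array(idx, dtype=float))
            q = v.world_to_index(t.apply(p))
            expected = map_coordinates(
                np.asarray(v.data, float), q.reshape(3, 1), order=1,
                mode="grid-constant", cval=0.0,
            )[0]
            assert abs(np.asarray(out.data)[idx] - expected) < 1e-6


class TestSSD:
    def test_identical_masks_zero(self, small_case):
        assert ssd(small_case.mask, small_case.mask) == 0.0

    def test_single_voxel_half(self):
        ref = _vol(np.zeros((4, 4, 4)))
        tm = np.zeros((4, 4, 4))
        tm[1, 2, 3] = 1.0
        assert ssd(_vol(tm), ref) == pytest.approx(0.5)

    def test_matches_triple_loop_oracle(self, rng):
        a = rng.random((6, 7, 8))
        b = rng.random((6, 7, 8))
        sp = (0.5, 0.7, 1.3)
        acc = 0.0
        for i in range(6):
            for j in range(7):
                for k in range(8):
                    acc += (b[i, j, k] - a[i, j, k]) ** 2
        expected = 0.5 * acc * np.prod(sp)
        got = ssd(_vol(a, spacing=sp), _vol(b, spacing=sp))
        assert abs(got - expected) < 1e-9 * max(1.0, expected)

    def test_geometry_mismatch_rejected(self, rng):
        with pytest.raises(GeometryError):
            ssd(_vol(rng.random((4, 4, 4))), _vol(rng.random((4, 4, 4)), spacing=(2, 2, 2)))


class TestElasticEnergy:
    def test_zero_and_constant_fields(self):
        z = DeformationField(displacements=np.zeros((3, 5, 5, 5)), spacing=(1, 1, 1), origin=(0, 0, 0))
        assert elastic_energy(z, 1.0, 1.0) == 0.0
        c = DeformationField(displacements=np.ones((3, 5, 5, 5)) * 4.2, spacing=(1, 1, 1), origin=(0, 0, 0))
        assert elastic_energy(c, 1.0, 1.0) == pytest.approx(0.0, abs=1e-12)

    def test_difference_adjoint_is_exact(self, rng):
        f = rng.standard_normal((6, 7, 8))
        y = rng.standard_normal((6, 7, 8))
        for axis, h in [(0, 0.5), (1, 1.0), (2, 2.5)]:
            lhs = np.sum(_grad_axis(f, h, axis) * y)
            rhs = np.sum(f * _grad_axis_adjoint(y, h, axis))
            assert abs(lhs - rhs) < 1e-10

    def test_gradient_matches_finite_differences(self, rng):
        disp = rng.standard_normal((3, 5, 6, 7)) * 0.1
        sp = (0.5, 0.7, 1.0)
        S, g = elastic_energy_and_grad(disp, sp, mu=1.3, lam=0.7)
        eps = 1e-6
        for _ in range(8):
            i = tuple(rng.integers(s) for s in disp.shape)
            d2 = disp.copy()
            d2[i] += eps
            S2, _ = elastic_energy_and_grad(d2, sp, mu=1.3, lam=0.7)
            assert abs((S2 - S) / eps - g[i]) < 1e-4

    def test_shear_converges_to_closed_form(self):
        # u = (gamma x, 0, 0) on the unit cube with mu=1, lam=0:
        # S -> gamma^2 * volume under grid refinement
        gamma = 0.37
        errors = []
        for n in (9, 17, 33):
            h = 1.0 / (n - 1)
            x = np.arange(n) * h
            disp = np.zeros((3, n, n, n))
            disp[0] = gamma * x[:, None, None]
            f = DeformationField(displacements=disp, spacing=(h, h, h), origin=(0, 0, 0))
            # node-sum quadrature covers (n*h)^3; normalize to the unit cube
            S = elastic_energy(f, 1.0, 0.0) / (n * h) ** 3
            errors.append(abs(S - gamma**2))
        # central differences are exact for a linear field, so the error is
        # already ~0 at every resolution; it must not grow under refinement
        assert errors[-1] <= errors[0] + 1e-12
        assert errors[-1] < 0.02 * gamma**2


class TestLBFGS:
    TIGHT = StoppingCriteria(min_progress=1e-12, min_gradient=1e-9,
                             rel_gradient=1e-10, min_step=1e-10, max_iterations=100)

    def test_convex_quadratic_reaches_minimizer(self):
        c = np.array([1.0, -2.0, 3.0])
        x, log = lbfgs_optimize(lambda x: (np.sum((x - c) ** 2), 2 * (x - c)),
                                np.zeros(3), self.TIGHT)
        np.testing.assert_allclose(x, c, atol=1e-6)
        assert log.converged

    def test_objective_log_non_increasing(self, rng):
        A = rng.standard_normal((8, 8))
        A = A @ A.T + 8 * np.eye(8)
        b = rng.standard_normal(8)
        x, log = lbfgs_optimize(lambda x: (0.5 * x @ A @ x - b @ x, A @ x - b),
                                rng.standard_normal(8), self.TIGHT)
        assert_descending(log)

    def test_rosenbrock_matches_independent_optimizer(self):
        def rosen(x):
            a, b = x
            J = (1 - a) ** 2 + 100 * (b - a * a) ** 2
            g = np.array([-2 * (1 - a) - 400 * a * (b - a * a), 200 * (b - a * a)])
            return J, g

        x0 = np.array([-1.2, 1.0])
        x, log = lbfgs_optimize(rosen, x0, self.TIGHT)
        assert log.objective[-1] < 1e-4
        ref = minimize(lambda x: rosen(x)[0], x0, jac=lambda x: rosen(x)[1], method="L-BFGS-B")
        np.testing.assert_allclose(x, ref.x, atol=1e-4)

    def test_default_stopping_values(self):
        s = StoppingCriteria()
        assert (s.min_progress, s.min_gradient, s.rel_gradient, s.min_step) == (1e-3,) * 4
        assert s.max_iterations == 100

    def test_non_finite_start_raises(self):
        with pytest.raises(OptimizationError):
            lbfgs_optimize(lambda x: (np.inf, x), np.zeros(2))
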