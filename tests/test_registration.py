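"""Two-stage registration: SSD cost, localized MI, transforms, label fusion."""

import numpy as np
import pytest
from scipy import ndimage

import coroseg as cs
from coroseg.registration import (AffineTransform, RegistrationOptions,
                                  affine_register, bspline_register,
                                  gaussian_pyramid, localized_mi,
                                  majority_vote, segment_heart, ssd_cost,
                                  warp_labels)
from coroseg.volumes import (GeometryError, Grid, GridPoint,
                             OptimizationError, indices_to_world)


def _vol(arr, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)):
    arr = np.asarray(arr, float)
    return cs.Volume3D(arr, Grid(arr.shape, spacing, origin))


def _points(idx):
    return [GridPoint(tuple(i)) for i in idx]


class TestSSD:
    def test_self_cost_is_zero_under_identity(self):
        rng = np.random.default_rng(0)
        vol = _vol(rng.normal(size=(8, 8, 8)) * 100)
        pts = _points([(2, 3, 4), (5, 5, 5), (0, 0, 0)])
        assert ssd_cost(vol, vol, AffineTransform.identity(), pts) == 0.0

    def test_constant_offset_gives_squared_offset(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(8, 8, 8)) * 50
        pts = _points([(k, j, i) for k in (2, 4) for j in (2, 4) for i in (2, 4)])
        cost = ssd_cost(_vol(a), _vol(a + 7.0), AffineTransform.identity(), pts)
        assert cost == pytest.approx(49.0)

    def test_single_sample_residual(self):
        a = np.zeros((4, 4, 4)); a[1, 1, 1] = 100.0
        b = np.zeros((4, 4, 4)); b[1, 1, 1] = 90.0
        cost = ssd_cost(_vol(a), _vol(b), AffineTransform.identity(),
                        _points([(1, 1, 1)]))
        assert cost == pytest.approx(100.0)

    def test_all_samples_outside_moving_domain_is_an_error(self):
        a = _vol(np.zeros((4, 4, 4)))
        t = AffineTransform(np.eye(3), np.array([1000.0, 0, 0]))
        with pytest.raises(OptimizationError):
            ssd_cost(a, a, t, _points([(1, 1, 1)]))


class TestPyramid:
    def test_single_level_is_the_original(self):
        vol = _vol(np.random.default_rng(0).normal(size=(16, 16, 16)))
        pyr = gaussian_pyramid(vol, 1)
        assert len(pyr) == 1 and pyr[0] is vol

    def test_shapes_and_spacings_halve(self):
        vol = _vol(np.zeros((64, 64, 64)))
        pyr = gaussian_pyramid(vol, 3)
        assert [p.shape for p in pyr] == [(64,) * 3, (32,) * 3, (16,) * 3]
        assert [p.spacing[0] for p in pyr] == [1.0, 2.0, 4.0]

    def test_constant_volume_stays_constant(self):
        pyr = gaussian_pyramid(_vol(np.full((32, 32, 32), 5.0)), 3)
        for p in pyr:
            assert np.allclose(p.data, 5.0)

    def test_truncation_below_minimum_size_warns(self):
        with pytest.warns(UserWarning):
            pyr = gaussian_pyramid(_vol(np.zeros((16, 16, 16))), 4)
        assert len(pyr) == 2


class TestWarpLabels:
    def _label(self):
        m = np.zeros((10, 10, 10), bool)
        m[3:6, 3:6, 3:6] = True
        return cs.BinaryMask3D(m, Grid((10, 10, 10), (1, 1, 1)))

    def test_identity_preserves_label(self):
        lbl = self._label()
        out = warp_labels(lbl, AffineTransform.identity(), lbl.grid)
        assert np.array_equal(out.data, lbl.data)

    def test_integer_translation_shifts_exactly(self):
        lbl = self._label()
        # T maps target world x to source x + 2mm(x axis): content shifts -x
        t = AffineTransform(np.eye(3), np.array([2.0, 0.0, 0.0]))
        out = warp_labels(lbl, t, lbl.grid)
        assert np.array_equal(out.data, np.roll(lbl.data, -2, axis=2))

    def test_output_strictly_binary(self):
        lbl = self._label()
        t = AffineTransform(np.eye(3) * 1.31, np.array([0.4, -0.7, 0.2]))
        out = warp_labels(lbl, t, lbl.grid)
        assert out.data.dtype == np.bool_


class TestMajorityVote:
    def _m(self, arr):
        arr = np.asarray(arr, bool)
        return cs.BinaryMask3D(arr, Grid(arr.shape, (1, 1, 1)))

    def test_two_of_three_wins(self):
        one = np.ones((2, 2, 2)); zero = np.zeros((2, 2, 2))
        out = majority_vote([self._m(one), self._m(one), self._m(zero)])
        assert out.data.all()

    def test_tie_resolves_to_background(self):
        one = np.ones((2, 2, 2)); zero = np.zeros((2, 2, 2))
        out = majority_vote([self._m(one), self._m(zero)])
        assert not out.data.any()

    def test_unanimous_vote_is_identity(self):
        rng = np.random.default_rng(0)
        m = self._m(rng.random((4, 4, 4)) > 0.5)
        out = majority_vote([m, m, m])
        assert np.array_equal(out.data, m.data)

    def test_vote_bounded_by_union_and_intersection(self):
        rng = np.random.default_rng(1)
        ms = [self._m(rng.random((5, 5, 5)) > 0.5) for _ in range(5)]
        out = majority_vote(ms)
        union = np.logical_or.reduce([m.data for m in ms])
        inter = np.logical_and.reduce([m.data for m in ms])
        assert not np.any(out.data & ~union)
        assert np.all(out.data[inter])

    def test_grid_mismatch_rejected(self):
        a = self._m(np.ones((3, 3, 3)))
        b = cs.BinaryMask3D(np.ones((3, 3, 3), bool), Grid((3, 3, 3), (2, 2, 2)))
        with pytest.raises(GeometryError):
            majority_vote([a, b])


class TestLocalizedMI:
    def test_two_equal_bins_give_exactly_one_bit(self):
        # half the voxels at one level, half at another, fixed == moving:
        # the joint histogram is diagonal with two equal entries
        data = np.zeros((8, 8, 8))
        data[:, :, 4:] = 100.0
        vol = _vol(data)
        opts = RegistrationOptions(n_histogram_bins=2)
        mi = localized_mi(vol, vol, AffineTransform.identity(),
                          GridPoint((4, 4, 4)), opts)
        assert mi == pytest.approx(1.0, abs=1e-9)

    def test_independent_patches_give_near_zero(self):
        rng = np.random.default_rng(0)
        a = _vol(rng.normal(size=(16, 16, 16)))
        b = _vol(rng.normal(size=(16, 16, 16)))
        mi = localized_mi(a, b, AffineTransform.identity(), GridPoint((8, 8, 8)),
                          RegistrationOptions(n_histogram_bins=8))
        assert 0.0 <= mi < 0.1

    def test_nonnegative_and_bounded_by_marginal_entropy(self):
        rng = np.random.default_rng(2)
        a = _vol(ndimage.gaussian_filter(rng.normal(size=(16, 16, 16)), 2))
        b = _vol(ndimage.gaussian_filter(rng.normal(size=(16, 16, 16)), 2))
        opts = RegistrationOptions(n_histogram_bins=16)
        mi = localized_mi(a, b, AffineTransform.identity(), GridPoint((8, 8, 8)),
                          opts)
        assert mi >= 0.0
        assert mi <= np.log2(opts.n_histogram_bins)

    def test_symmetry_under_argument_swap(self):
        rng = np.random.default_rng(3)
        a = _vol(ndimage.gaussian_filter(rng.normal(size=(16, 16, 16)), 2) * 100)
        b = _vol(a.data + rng.normal(size=(16, 16, 16)) * 10)
        opts = RegistrationOptions(n_histogram_bins=16)
        ab = localized_mi(a, b, AffineTransform.identity(), GridPoint((8, 8, 8)), opts)
        ba = localized_mi(b, a, AffineTransform.identity(), GridPoint((8, 8, 8)), opts)
        assert ab == pytest.approx(ba, abs=0.05)

    def test_degenerate_histogram_returns_zero_with_warning(self):
        flat = _vol(np.zeros((8, 8, 8)))
        with pytest.warns(UserWarning):
            mi = localized_mi(flat, flat, AffineTransform.identity(),
                              GridPoint((4, 4, 4)), RegistrationOptions())
        assert mi == 0.0


class TestAffineRegister:
    def test_self_registration_near_identity_and_cost_reduced(
            self, registration_phantom):
        vol, _, _ = registration_phantom
        opts = RegistrationOptions(rng_seed=5, n_affine_iterations=60)
        t = affine_register(vol, vol, opts)
        assert np.abs(t.matrix - np.eye(3)).max() < 0.02
        assert np.abs(t.translation).max() < 0.5
        rng = np.random.default_rng(0)
        pts = _points(np.stack([rng.integers(0, 64, 500)] * 3, axis=1))
        assert ssd_cost(vol, vol, t, pts) <= ssd_cost(
            vol, vol, AffineTransform.identity(t.center), pts) + 1e-9

    def test_recovers_three_voxel_translation(self, registration_phantom):
        vol, _, _ = registration_phantom
        shifted = ndimage.shift(vol.data, (0, 0, 3), order=1,
                                cval=float(vol.data.min()))
        moving = cs.Volume3D(shifted, vol.grid)
        t = affine_register(vol, moving, RegistrationOptions(rng_seed=7))
        # content shifted +x by 3 voxels (3 mm): T must map x -> x + 3 x̂
        assert np.linalg.norm(t.translation - [3.0, 0.0, 0.0]) < 0.5
        assert np.abs(t.matrix - np.eye(3)).max() < 0.05

    def test_deterministic_given_seed(self, registration_phantom):
        vol, _, _ = registration_phantom
        moving = cs.Volume3D(np.roll(vol.data, 2, axis=1), vol.grid)
        opts = RegistrationOptions(rng_seed=13, n_affine_iterations=40)
        a = affine_register(vol, moving, opts)
        b = affine_register(vol, moving, opts)
        assert np.array_equal(a.matrix, b.matrix)
        assert np.array_equal(a.translation, b.translation)


class TestBSplineRegister:
    def test_zero_iterations_embeds_the_affine_init(self, registration_phantom):
        vol, _, _ = registration_phantom
        init = AffineTransform(np.eye(3), np.array([1.0, -2.0, 0.5]))
        opts = RegistrationOptions(n_bspline_iterations=0)
        tr = bspline_register(vol, vol, init, opts)
        assert np.all(tr.coefficients == 0.0)
        pts = np.array([[10.0, 20.0, 30.0], [5.0, 5.0, 5.0]])
        assert np.allclose(tr.apply(pts), init.apply(pts))

    def test_self_registration_displacement_stays_small(self,
                                                        registration_phantom):
        vol, heart, _ = registration_phantom
        opts = RegistrationOptions(rng_seed=3, n_bspline_iterations=60)
        tr = bspline_register(vol, vol, AffineTransform.identity(), opts)
        pts = indices_to_world(vol.grid, np.argwhere(heart.data)[::97])
        disp = np.linalg.norm(tr.displacement(pts), axis=1)
        assert np.median(disp) <= 1.0  # <= 1 voxel at 1 mm spacing

    def test_halves_landmark_error_of_smooth_warp(self, registration_spec,
                                                  registration_phantom):
        from coroseg.phantom import apply_synthetic_warp

        base, heart, _ = registration_phantom
        warp = cs.SyntheticWarp(
            np.eye(3), np.zeros(3), registration_spec.center_mm(),
            sin_amplitude=np.array([[2.0, 1.5, 1.2], [1.0, 1.4, 1.0]]),
            sin_frequency=np.array([[1 / 70, 1 / 90, 1 / 60],
                                    [1 / 50, 1 / 80, 1 / 100]]),
            sin_phase=np.array([[0.3, 1.1, 2.0], [2.5, 0.7, 1.6]]))
        atlas = apply_synthetic_warp(base, heart, warp)
        rng = np.random.default_rng(0)
        pts = indices_to_world(
            base.grid, np.argwhere(heart.data)[
                rng.choice(heart.count(), 300, replace=False)])
        opts = RegistrationOptions(rng_seed=7)
        aff = affine_register(base, atlas.image, opts)
        err_aff = np.median(np.linalg.norm(warp.apply(aff.apply(pts)) - pts,
                                           axis=1))
        bsp = bspline_register(base, atlas.image, aff, opts)
        err_bsp = np.median(np.linalg.norm(warp.apply(bsp.apply(pts)) - pts,
                                           axis=1))
        assert err_bsp <= 0.5 * err_aff


class TestSegmentHeart:
    def test_zero_deformation_atlases_reproduce_gold(self, registration_spec,
                                                     registration_phantom):
        vol, heart, _ = registration_phantom
        atlases = cs.make_atlas_set(registration_spec, 3, 0.0, rng_seed=1)
        opts = RegistrationOptions(rng_seed=5, n_affine_iterations=60,
                                   n_bspline_iterations=60)
        fused = segment_heart(vol, atlases, opts)
        assert cs.dice(fused, heart) >= 0.995

    def test_single_atlas_vote_of_one(self, registration_spec,
                                      registration_phantom):
        vol, heart, _ = registration_phantom
        atlases = cs.make_atlas_set(registration_spec, 1, 0.0, rng_seed=1)
        opts = RegistrationOptions(rng_seed=5, n_affine_iterations=30,
                                   n_bspline_iterations=0)
        fused = segment_heart(vol, atlases, opts)
        assert cs.dice(fused, heart) >= 0.99

    def test_no_atlases_is_an_error(self, registration_phantom):
        vol, _, _ = registration_phantom
        with pytest.raises(cs.PipelineError):
            segment_heart(vol, [], RegistrationOptions())
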