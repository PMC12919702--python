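"""Filtering, padding, backprojection and the full FBP pipeline."""

import math
from dataclasses import replace

import numpy as np
import pytest

from fovxtend.geometry import (
    SystemGeometry,
    derive_geometry,
    view_vectors,
)
from fovxtend.recon import (
    GridSpec,
    ProjectionSet,
    apply_redundancy_weights,
    backproject,
    conjugate_pad,
    pad_for_filtering,
    ramp_filter,
    ramp_kernel,
    reconstruct,
    weight_profile,
    _ramp_filter_rows,
)
from fovxtend.simulate import Phantom, Primitive, analytic_sinogram


class TestPadding:
    def test_mirror_and_edge_rule(self):
        padded, rec = pad_for_filtering(np.array([1.0, 2.0, 3.0]), "low_x", 3)
        np.testing.assert_array_equal(padded[:3], [3.0, 2.0, 1.0])
        np.testing.assert_array_equal(padded[rec], [1.0, 2.0, 3.0])
        # everything right of the data is the edge value
        assert np.all(padded[6:] == 3.0)

    def test_high_x_mirrors_right(self):
        padded, rec = pad_for_filtering(np.array([1.0, 2.0, 3.0]), "high_x", 3)
        assert np.all(padded[:3] == 1.0)
        np.testing.assert_array_equal(padded[rec], [1.0, 2.0, 3.0])
        np.testing.assert_array_equal(padded[6:9], [3.0, 2.0, 1.0])

    def test_constant_row_filters_to_near_zero(self):
        # the band-limited kernel keeps a 4/(pi^2 N) DC response (needed
        # for quantitative reconstruction), so DC is annihilated only to
        # that level, improving as the padded length grows
        for n, bound in [(64, 5e-3), (512, 7e-4)]:
            row = np.full(n, 3.7)
            padded, rec = pad_for_filtering(row, "low_x", n)
            filtered = _ramp_filter_rows(padded, 1.0)[rec]
            assert np.abs(filtered).max() < bound * 3.7

    def test_recovery_slice_shape(self):
        row = np.arange(50, dtype=float)
        padded, rec = pad_for_filtering(row, "none", 17)
        assert padded[rec].shape == row.shape

    def test_short_row_rejected(self):
        with pytest.raises(ValueError):
            pad_for_filtering(np.array([1.0]), "low_x", 4)

    def test_conjugate_pad_completes_truncated_disk(self, g_offset,
                                                    disk_phantom):
        # the reversed copy aligned on the COR ray reproduces the rays
        # lost to truncation: compare against a wider detector
        dg = derive_geometry(g_offset)
        proj = analytic_sinogram(disk_phantom, g_offset, np.array([0.0]),
                                 "attenuation")
        padded, rec = conjugate_pad(proj.data, g_offset, dg, 64)
        pad_vals = padded[0, 0, rec.start - 20: rec.start]
        # ground truth at the padded coordinates from the exact phantom
        x_pad = (np.arange(-20, 0) - (g_offset.n_col - 1) / 2) * g_offset.p
        from fovxtend.simulate import _detector_rays
        view = view_vectors(dg, g_offset, [0.0])[0]
        S, d = _detector_rays(view, g_offset, x_pad)
        truth = disk_phantom.line_integrals(S, d, "mu")
        np.testing.assert_allclose(pad_vals, truth, atol=5e-3 * truth.max())


class TestRampFilter:
    def test_impulse_response_is_discrete_kernel(self, g_centered):
        """Closed-form band-limited Ram-Lak kernel values."""
        dx = g_centered.p
        n = 64
        data = np.zeros((1, 1, n))
        data[0, 0, 0] = 1.0
        proj = ProjectionSet(data, [0.0], "attenuation",
                             replace_cols(g_centered, n))
        out = ramp_filter(proj).data[0, 0]
        assert out[0] == pytest.approx(1.0 / (4 * dx * dx), rel=1e-12)
        for k in (2, 4, 6):
            assert out[k] == pytest.approx(0.0, abs=1e-9 / dx**2)
        for k in (1, 3, 5):
            assert out[k] == pytest.approx(-1.0 / (np.pi * k * dx) ** 2,
                                           rel=1e-9)

    def test_linearity(self, g_centered):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(2, 1, g_centered.n_col))
        b = rng.normal(size=(2, 1, g_centered.n_col))
        mk = lambda d: ProjectionSet(d, [0.0, 1.0], "attenuation", g_centered)
        fa = ramp_filter(mk(a)).data
        fb = ramp_filter(mk(b)).data
        fab = ramp_filter(mk(a + b)).data
        np.testing.assert_allclose(fab, fa + fb, atol=1e-10)

    def test_non_finite_rejected(self, g_centered):
        data = np.zeros((1, 1, g_centered.n_col))
        data[0, 0, 5] = np.nan
        proj = ProjectionSet(data, [0.0], "attenuation", g_centered)
        with pytest.raises(ValueError):
            ramp_filter(proj)


def replace_cols(g: SystemGeometry, n: int) -> SystemGeometry:
    return SystemGeometry(zsm=g.zsm, zmo=g.zmo, zod=g.zod, p=g.p, n_col=n,
                          n_row=g.n_row, delta_cor=g.delta_cor)


class TestWeightApplication:
    def test_flat_weights_are_identity(self, g_centered):
        dg = derive_geometry(g_centered)
        wp = weight_profile(dg, g_centered)
        rng = np.random.default_rng(0)
        proj = ProjectionSet(rng.normal(size=(3, 1, g_centered.n_col)),
                             [0.0, 1.0, 2.0], "attenuation", g_centered)
        out = apply_redundancy_weights(proj, wp)
        np.testing.assert_array_equal(out.data, proj.data)

    def test_zero_weight_columns_vanish(self, g_offset):
        dg = derive_geometry(g_offset)
        wp = weight_profile(dg, g_offset)
        proj = ProjectionSet(np.ones((1, 1, g_offset.n_col)), [0.0],
                             "attenuation", g_offset)
        out = apply_redundancy_weights(proj, wp)
        assert np.all(out.data[..., wp.w == 0.0] == 0.0)

    def test_shape_mismatch_rejected(self, g_offset, g_centered):
        dg = derive_geometry(g_offset)
        wp = weight_profile(dg, g_offset)
        proj = ProjectionSet(np.ones((1, 1, 128)), [0.0], "attenuation",
                             replace_cols(g_centered, 128))
        with pytest.raises(ValueError):
            apply_redundancy_weights(proj, wp)


class TestBackprojection:
    def test_zero_stack_gives_zero_volume(self, g_centered):
        dg = derive_geometry(g_centered)
        proj = ProjectionSet(np.zeros((4, 1, g_centered.n_col)),
                             np.linspace(0, 2 * np.pi, 4, endpoint=False),
                             "attenuation", g_centered)
        views = view_vectors(dg, g_centered, proj.angles)
        vol = backproject(proj, views, GridSpec(16, 16, 1e-4))
        assert np.all(vol.values == 0.0)

    def test_nan_rejected(self, g_centered):
        dg = derive_geometry(g_centered)
        data = np.zeros((1, 1, g_centered.n_col))
        data[0, 0, 0] = np.nan
        proj = ProjectionSet(data, [0.0], "attenuation", g_centered)
        views = view_vectors(dg, g_centered, [0.0])
        with pytest.raises(ValueError):
            backproject(proj, views, GridSpec(4, 4, 1e-4))

    def test_single_view_matches_hand_traced_rays(self, g_offset):
        """One view, 3x3 grid: accumulate (U0/U)^2 * interp by hand."""
        g = g_offset
        dg = derive_geometry(g)
        rng = np.random.default_rng(11)
        row = rng.normal(size=g.n_col)
        proj = ProjectionSet(row[None, None, :], [0.3], "attenuation", g)
        (view,) = view_vectors(dg, g, [0.3])
        grid = GridSpec(3, 3, 5e-4)
        vol = backproject(proj, [view], grid)
        s_pitch = g.p * g.z_so / g.R
        cols = (np.arange(g.n_col) - (g.n_col - 1) / 2) * s_pitch
        for iy, y in enumerate(grid.y):
            for ix, x in enumerate(grid.x):
                d = np.array([x, y]) - view.source[:2]
                U = d @ view.central_axis[:2]
                t = d @ view.col_axis[:2]
                U0 = -(view.source[:2] @ view.central_axis[:2])
                s_star = U0 * t / U
                expected = (np.pi / 1) * (U0 / U) ** 2 * np.interp(
                    s_star, cols, row)
                assert vol.values[0, iy, ix] == pytest.approx(expected,
                                                              rel=1e-9)

    def test_shift_equivariance(self, g_centered):
        """Translating the phantom translates the reconstruction."""
        voxel = 1e-4
        grid = GridSpec(96, 96, voxel)
        angles = np.arange(180) * 2 * np.pi / 180
        ph0 = Phantom([Primitive.disk((0.0, 0.0), 2e-3, mu=10.0)])
        ph1 = Phantom([Primitive.disk((voxel, 0.0), 2e-3, mu=10.0)])
        v0 = reconstruct(analytic_sinogram(ph0, g_centered, angles,
                                           "attenuation"),
                         g_centered, grid).values[0]
        v1 = reconstruct(analytic_sinogram(ph1, g_centered, angles,
                                           "attenuation"),
                         g_centered, grid).values[0]
        shifted = np.roll(v0, 1, axis=1)
        core = np.s_[8:-8, 8:-8]
        assert np.sqrt(np.mean((v1[core] - shifted[core]) ** 2)) < 0.03 * 10.0


class TestReconstructPipeline:
    def test_air_scan_reconstructs_to_zero(self, g_centered):
        proj = ProjectionSet(np.zeros((8, 1, g_centered.n_col)),
                             np.arange(8) * np.pi / 4, "attenuation",
                             g_centered)
        vol = reconstruct(proj, g_centered, GridSpec(32, 32, 1e-4))
        assert np.abs(vol.values).max() < 1e-12

    def test_intensity_channel_rejected(self, g_centered):
        proj = ProjectionSet(np.zeros((1, 1, g_centered.n_col)), [0.0],
                             "intensity", g_centered)
        with pytest.raises(ValueError):
            reconstruct(proj, g_centered, GridSpec(8, 8, 1e-4))

    def test_weighting_applied_after_filtering(self, g_offset, disk_phantom,
                                               angles_360):
        """Pipeline order: pad -> ramp -> unpad -> weight -> backproject.

        The alternative order (weight before filter) is a different
        operator on a truncated sinogram; the pipeline must match the
        weight-after-filter composition exactly.
        """
        g = g_offset
        dg = derive_geometry(g)
        grid = GridSpec(64, 64, 3e-4)
        proj = analytic_sinogram(disk_phantom, g, angles_360, "attenuation")
        vol = reconstruct(proj, g, grid).values

        x = g.detector_columns()
        cosw = g.R / np.sqrt(g.R**2 + x**2)
        wp = weight_profile(dg, g)
        views = view_vectors(dg, g, angles_360)
        s_pitch = g.p * g.z_so / g.R

        def run(order):
            data = proj.data * cosw
            if order == "before":
                data = data * wp.w
            padded, rec = conjugate_pad(data, g, dg, g.n_col)
            filt = _ramp_filter_rows(padded, s_pitch)[..., rec] * s_pitch
            if order == "after":
                filt = filt * wp.w
            return backproject(replace(proj, data=filt), views, grid).values

        np.testing.assert_allclose(vol, run("after"), rtol=1e-12, atol=1e-12)
        assert np.abs(vol - run("before")).max() > 1e-6

    def test_zero_offset_equals_plain_fbp(self, g_centered, angles_360):
        """At tau=0 the pipeline is ordinary full-scan fan-beam FBP."""
        ph = Phantom([Primitive.disk((1e-3, -0.5e-3), 2e-3, mu=10.0)])
        grid = GridSpec(96, 96, 1.2e-4)
        proj = analytic_sinogram(ph, g_centered, angles_360, "attenuation")
        vol = reconstruct(proj, g_centered, grid).values

        # independent plain FBP: cosine weight, edge-padded Ram-Lak,
        # no redundancy weighting
        g = g_centered
        dg = derive_geometry(g)
        x = g.detector_columns()
        data = proj.data * (g.R / np.sqrt(g.R**2 + x**2))
        padded, rec = pad_for_filtering(data, "none", g.n_col)
        s_pitch = g.p * g.z_so / g.R
        filt = _ramp_filter_rows(padded, s_pitch)[..., rec] * s_pitch
        views = view_vectors(dg, g, angles_360)
        ref = backproject(replace(proj, data=filt), views, grid).values
        np.testing.assert_allclose(vol, ref, rtol=1e-6, atol=1e-6 * 10.0)
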