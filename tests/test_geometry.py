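"""Unwrapping module: rasterization oracle, unwrap fidelity, stacking, segments."""

import numpy as np
import pytest

from t1tex.geometry import (
    Contour,
    ContourError,
    UnwrapConfig,
    UnwrapError,
    global_and_segmental_t1,
    rasterize_myocardium,
    stack_subject,
    unwrap_slice,
    unwrap_subject,
)

from conftest import make_annulus_slice, subject_from_slice


def _circle(cx, cy, r, n=96):
    phis = 2 * np.pi * np.arange(n) / n
    return Contour(np.column_stack([cx + r * np.cos(phis), cy + r * np.sin(phis)]))


class TestRasterize:
    # geometry chosen so no pixel center lies within 0.05 px of either circle,
    # far above the 96-gon's sagitta (~0.005 px): polygon and true-circle
    # classifications agree exactly.
    CX, CY, R1, R2 = 16.0, 16.976, 4.766, 9.776

    def test_matches_point_in_annulus_oracle(self):
        mask = rasterize_myocardium(
            _circle(self.CX, self.CY, self.R1), _circle(self.CX, self.CY, self.R2), (32, 32)
        )
        ys, xs = np.mgrid[0:32, 0:32]
        d = np.hypot(xs - self.CX, ys - self.CY)
        oracle = (d > self.R1) & (d < self.R2)
        assert np.array_equal(mask, oracle)

    def test_translation_equivariance(self):
        endo, epi = _circle(12.3, 12.8, 4.2), _circle(12.3, 12.8, 8.1)
        base = rasterize_myocardium(endo, epi, (40, 40))
        moved = rasterize_myocardium(endo.translated(3, 3), epi.translated(3, 3), (40, 40))
        assert np.array_equal(np.roll(np.roll(base, 3, 0), 3, 1)[4:-4, 4:-4], moved[4:-4, 4:-4])

    def test_degenerate_equal_contours_give_empty_mask_then_unwrap_error(self):
        c = _circle(16, 16, 6.0)
        mask = rasterize_myocardium(c, c, (32, 32))
        assert not mask.any()
        sl = make_annulus_slice()
        degenerate = type(sl)(sl.pixel_grid, sl.pixel_size, c, c, np.array([22.0, 16.0]), 0)
        with pytest.raises(UnwrapError):
            unwrap_slice(degenerate)

    def test_crossing_contours_rejected(self):
        endo = _circle(16, 16, 8.0)   # pokes outside the "epi" circle
        epi = _circle(20, 16, 6.0)
        with pytest.raises(ContourError, match="crossing"):
            rasterize_myocardium(endo, epi, (32, 32))


class TestUnwrap:
    def test_constant_annulus_is_exact(self):
        sl = make_annulus_slice(field=1100.0)
        out = unwrap_slice(sl).values
        assert out.shape == (32, 192)
        assert np.allclose(out, 1100.0, atol=1e-9)

    def test_angular_ramp_recovered_per_column(self):
        """T1 = 1000 + clockwise angle (deg) from landmark -> linear column means."""
        theta0 = 2.0
        cx, cy = 31.6, 32.3

        def ramp(xx, yy):
            ang = (np.arctan2(yy - cy, xx - cx) - theta0) % (2 * np.pi)
            return 1000.0 + np.degrees(ang)

        sl = make_annulus_slice(field=ramp, landmark_angle=theta0)
        out = unwrap_slice(sl).values
        cols = out.shape[1]
        expected = 1000.0 + 360.0 * (np.arange(cols) + 0.5) / cols
        # columns nearest the wrap discontinuity interpolate across it:
        # 1 px at the endocardial radius spans ~4 columns
        inner = slice(4, cols - 4)
        assert np.allclose(out.mean(axis=0)[inner], expected[inner], atol=5.0)
        # each column approximately constant across depths
        assert out.std(axis=0)[inner].max() < 5.0

    def test_mean_preserved_on_smooth_phantom(self):
        def smooth(xx, yy):
            return 1100.0 + 40 * np.sin(xx / 9.0) + 30 * np.cos(yy / 7.0)

        sl = make_annulus_slice(field=smooth)
        out = unwrap_slice(sl).values
        mask = rasterize_myocardium(sl.endo, sl.epi, sl.pixel_grid.shape)
        mask_mean = sl.pixel_grid[mask].mean()
        assert abs(out.mean() - mask_mean) / mask_mean < 0.01

    def test_landmark_shift_circularly_shifts_columns(self):
        def smooth(xx, yy):
            return 1100.0 + 40 * np.sin(xx / 9.0) + 30 * np.cos(yy / 7.0)

        theta0, cx, cy, r_epi = 2.0, 31.6, 32.3, 15.6
        sl = make_annulus_slice(field=smooth, landmark_angle=theta0)
        base = unwrap_slice(sl).values
        k = 17
        theta1 = theta0 + 2 * np.pi * k / base.shape[1]
        lm = np.array([cx + r_epi * np.cos(theta1), cy + r_epi * np.sin(theta1)])
        shifted = unwrap_slice(type(sl)(sl.pixel_grid, sl.pixel_size, sl.endo, sl.epi, lm, 0))
        assert np.allclose(shifted.values, np.roll(base, -k, axis=1), atol=1e-9)

    def test_monotone_depth_on_radial_gradient(self):
        cx, cy = 31.6, 32.3

        def radial(xx, yy):
            return 1000.0 + 20.0 * np.hypot(xx - cx, yy - cy)

        out = unwrap_slice(make_annulus_slice(field=radial)).values
        assert np.all(np.diff(out, axis=0) >= -1e-9)  # row 0 = endo, increasing outward

    def test_r64_downaveraged_approximates_r32(self):
        def smooth(xx, yy):
            return 1100.0 + 40 * np.sin(xx / 9.0) + 30 * np.cos(yy / 7.0)

        sl = make_annulus_slice(field=smooth)
        r32 = unwrap_slice(sl, UnwrapConfig.from_preset("R32")).values
        r64 = unwrap_slice(sl, UnwrapConfig.from_preset("R64")).values
        down = r64.reshape(32, 2, 192, 2).mean(axis=(1, 3))
        assert np.abs(down - r32).mean() < 1.0

    def test_config_validation(self):
        with pytest.raises(ValueError, match="6"):
            UnwrapConfig(rows=32, cols=100)
        with pytest.raises(ValueError, match="preset"):
            UnwrapConfig.from_preset("R128")


class TestStack:
    def test_stack_shapes_and_identity(self):
        sl = make_annulus_slice(field=1100.0)
        subj = subject_from_slice(sl)
        stacked = unwrap_subject(subj)
        assert stacked.values.shape == (160, 192)
        assert np.array_equal(stacked.values[:32], unwrap_slice(sl).values)
        r16 = unwrap_subject(subj, UnwrapConfig.from_preset("R16"))
        assert r16.values.shape == (80, 96)

    def test_wrong_count_or_mixed_shapes_rejected(self):
        sl = make_annulus_slice()
        m32 = unwrap_slice(sl, UnwrapConfig.from_preset("R32"))
        m16 = unwrap_slice(sl, UnwrapConfig.from_preset("R16"))
        with pytest.raises(ValueError, match="5"):
            stack_subject([m32] * 4)
        with pytest.raises(ValueError, match="shape"):
            stack_subject([m32] * 4 + [m16])


class TestGlobalSegmental:
    def test_constant_phantom(self):
        subj = subject_from_slice(make_annulus_slice(field=1100.0))
        g, seg = global_and_segmental_t1(subj)
        assert abs(g - 1100.0) < 1e-9
        assert seg.shape == (30,)
        assert np.allclose(seg, 1100.0, atol=1e-9)

    def test_elevated_sextant_maps_to_first_segment(self):
        """+100 ms in the first clockwise sextant from the landmark."""
        theta0, cx, cy = 2.0, 31.6, 32.3

        def sector(xx, yy):
            ang = (np.arctan2(yy - cy, xx - cx) - theta0) % (2 * np.pi)
            return 1100.0 + 100.0 * (ang < np.pi / 3)

        subj = subject_from_slice(make_annulus_slice(field=sector, landmark_angle=theta0))
        _, seg = global_and_segmental_t1(subj)
        seg = seg.reshape(5, 6)
        assert np.all(seg[:, 0] > 1180)
        assert np.all(seg[:, 2:5] < 1120)  # remote segments unaffected
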