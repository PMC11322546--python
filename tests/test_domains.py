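import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from samquant import synthetic
from samquant.domains import (CropRect, crop_substack, domain_dimensions,
                              isocline_ellipse, orthogonal_projections,
                              periphery_metrics)
from samquant.paraboloid import ProjectionImage
from samquant.stack_io import IsotropicStack

HALF_MAX_FACTOR = 2 * np.sqrt(2 * np.log(2))  # full width of a Gaussian at half max


def gaussian_projection(sigma_x_um, sigma_z_um, px_um, amplitude=1000.0,
                        half_extent_um=None):
    """Analytic 2D Gaussian sum-projection image (rows=z, cols=x)."""
    if half_extent_um is None:
        half_extent_um = 4 * max(sigma_x_um, sigma_z_um)
    n = int(2 * half_extent_um / px_um) + 1
    c = (n - 1) / 2 * px_um
    z = np.arange(n)[:, None] * px_um
    x = np.arange(n)[None, :] * px_um
    img = amplitude * np.exp(-((x - c) ** 2) / (2 * sigma_x_um**2)
                             - ((z - c) ** 2) / (2 * sigma_z_um**2))
    return ProjectionImage(img, "xz", px_um)


class TestCrop:
    def test_full_frame_identity(self, uniform_iso_stack):
        st = uniform_iso_stack
        nz, ny, nx = st.shape_zyx
        out = crop_substack(st, CropRect(0, nx, 0, ny))
        np.testing.assert_array_equal(out.data, st.data)

    def test_small_rect_shape(self, uniform_iso_stack):
        out = crop_substack(uniform_iso_stack, CropRect(3, 13, 5, 15))
        assert out.shape_zyx == (30, 10, 10)

    def test_empty_rect_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            CropRect(5, 5, 0, 4)

    def test_crop_excludes_flank_primordium_signal(self):
        # a dome with flank bumps: cropping to the centre removes their
        # contribution to the projections entirely
        dome = synthetic.DomeSpec(apex_um=(12.8, 12.8, 2.0), a1=0.05, a2=0.05,
                                  n_primordia=4, primordium_offset_um=9.0,
                                  primordium_amplitude=500.0)
        clean = synthetic.DomeSpec(apex_um=(12.8, 12.8, 2.0), a1=0.05, a2=0.05)
        kw = dict(shape_zyx=(40, 64, 64), voxel_size_xy=0.4, voxel_size_z=0.4,
                  seed=0)
        with_bumps, _ = synthetic.make_dome_stack(dome, [], **kw)
        without, _ = synthetic.make_dome_stack(clean, [], **kw)
        rect = CropRect(24, 40, 24, 40)  # central 6.4 um window
        a = crop_substack(IsotropicStack(with_bumps.data, 0.4, 0.4, ["wall"]), rect)
        b = crop_substack(IsotropicStack(without.data, 0.4, 0.4, ["wall"]), rect)
        pa, _ = orthogonal_projections(a, "wall")
        pb, _ = orthogonal_projections(b, "wall")
        np.testing.assert_allclose(pa.image, pb.image, atol=1e-6)


class TestProjections:
    def test_single_voxel(self):
        data = np.zeros((1, 8, 9, 10))
        data[0, 3, 4, 5] = 7.0
        iso = IsotropicStack(data, 0.4, 0.4, ["r"])
        xz, yz = orthogonal_projections(iso, "r")
        assert (xz.image != 0).sum() == 1 and xz.image[3, 5] == 7.0
        assert (yz.image != 0).sum() == 1 and yz.image[3, 4] == 7.0

    def test_blobs_aligned_in_y_merge_in_xz_only(self):
        data = np.zeros((1, 10, 20, 20))
        data[0, 5, 4, 10] = 5.0
        data[0, 5, 15, 10] = 5.0  # same x, different y
        iso = IsotropicStack(data, 0.4, 0.4, ["r"])
        xz, yz = orthogonal_projections(iso, "r")
        assert (xz.image != 0).sum() == 1  # merged
        assert (yz.image != 0).sum() == 2  # separated

    def test_projection_conserves_total_intensity(self):
        rng = np.random.default_rng(4)
        data = rng.random((1, 6, 7, 8))
        iso = IsotropicStack(data, 0.4, 0.4, ["r"])
        xz, yz = orthogonal_projections(iso, "r")
        assert xz.image.sum() == pytest.approx(data.sum())
        assert yz.image.sum() == pytest.approx(data.sum())


class TestIsoclineEllipse:
    def test_gaussian_half_max_width(self):
        e = isocline_ellipse(gaussian_projection(8.0, 5.0, 0.25))
        assert e.width_um == pytest.approx(8.0 * HALF_MAX_FACTOR, rel=0.05)
        assert e.height_um == pytest.approx(5.0 * HALF_MAX_FACTOR, rel=0.05)

    def test_isotropic_gaussian_is_circular(self):
        e = isocline_ellipse(gaussian_projection(6.0, 6.0, 0.25))
        assert e.height_um == pytest.approx(e.width_um, rel=0.02)

    def test_intensity_scaling_invariance(self):
        proj = gaussian_projection(6.0, 4.0, 0.5)
        e1 = isocline_ellipse(proj)
        e2 = isocline_ellipse(ProjectionImage(proj.image * 7.3, "xz", 0.5))
        assert e2.height_um == pytest.approx(e1.height_um, rel=1e-9)
        assert e2.width_um == pytest.approx(e1.width_um, rel=1e-9)

    def test_translation_invariance_within_crop(self):
        base = gaussian_projection(4.0, 4.0, 0.5, half_extent_um=24.0)
        shifted = ProjectionImage(np.roll(base.image, (8, -6), axis=(0, 1)),
                                  "xz", 0.5)
        e1 = isocline_ellipse(base)
        e2 = isocline_ellipse(shifted)
        assert e2.height_um == pytest.approx(e1.height_um, rel=1e-6)

    def test_axis_converges_with_resolution(self):
        # analytic limit: full axis -> 2*sigma*sqrt(2 ln 2) as px -> 0
        target = 6.0 * HALF_MAX_FACTOR
        errs = [abs(isocline_ellipse(gaussian_projection(6.0, 6.0, px)).width_um
                    - target) for px in (1.0, 0.25)]
        assert errs[1] < errs[0]

    def test_border_touching_region_flagged(self):
        img = np.full((20, 20), 10.0)  # above-threshold region touches border
        with pytest.raises(ValueError, match="border"):
            isocline_ellipse(ProjectionImage(img, "xz", 0.5))

    def test_no_signal_rejected(self):
        with pytest.raises(ValueError, match="no positive signal"):
            isocline_ellipse(ProjectionImage(np.zeros((10, 10)), "xz", 0.5))


class TestDomainDimensions:
    def _ellipse(self, h, w):
        from samquant.domains import DomainEllipse

        return DomainEllipse((0, 0), h, w, 0.0, 0.5, "xz")

    def test_identical_views_pass_through(self):
        h, w = domain_dimensions(self._ellipse(20, 10), self._ellipse(20, 10))
        assert (h, w) == (20, 10)

    def test_views_are_averaged(self):
        h, w = domain_dimensions(self._ellipse(20, 8), self._ellipse(22, 12))
        assert h == pytest.approx(21.0)
        assert w == pytest.approx(10.0)

    def test_axisymmetric_synthetic_domain_recovered(self):
        # nuclear-gaussian reporter inside a dome; both views agree with truth
        dome = synthetic.DomeSpec(apex_um=(32.0, 32.0, 2.0), a1=0.02, a2=0.02)
        rep = synthetic.ReporterSpec(mode="nuclear-gaussian", value=500.0,
                                     center_um=(32.0, 32.0, 20.0),
                                     sigma_um=(8.0, 8.0, 6.0), name="wus")
        stack, _ = synthetic.make_dome_stack(dome, [rep], shape_zyx=(64, 128, 128),
                                             voxel_size_xy=0.5, voxel_size_z=1.0,
                                             seed=0)
        from samquant.stack_io import resample_isotropic

        iso = resample_isotropic(stack)
        xz, yz = orthogonal_projections(iso, "wus")
        h, w = domain_dimensions(isocline_ellipse(xz), isocline_ellipse(yz))
        assert w == pytest.approx(8.0 * HALF_MAX_FACTOR, rel=0.05)
        assert h == pytest.approx(6.0 * HALF_MAX_FACTOR, rel=0.05)


class TestPeriphery:
    def test_worked_example(self):
        dw = periphery_metrics(100.0, 40.0)
        assert dw.periphery_um == pytest.approx(30.0)
        assert dw.pz_oc_ratio == pytest.approx(0.75)

    def test_equal_widths_give_zero_periphery(self):
        assert periphery_metrics(50.0, 50.0).periphery_um == 0.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            periphery_metrics(30.0, 40.0)
        with pytest.raises(ValueError):
            periphery_metrics(30.0, 0.0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(w=st.floats(1.0, 500.0),
           frac=st.floats(0.01, 1.0))
    def test_exact_arithmetic_property(self, w, frac):
        oc = w * frac
        dw = periphery_metrics(w, oc)
        assert dw.periphery_um == (w - oc) / 2
        assert dw.pz_oc_ratio == dw.periphery_um / oc
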