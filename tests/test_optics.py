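"""Forward-model contracts: PSF normalization, projector linearity and
adjointness, and the view decomposition bijection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lfrecon.optics import (ConfigurationError, LightField, OpticalConfig,
                            Volume, build_psf, decompose_views, project,
                            project_adjoint, recompose_views)


class TestOpticalConfig:
    def test_na_must_be_below_medium_index(self):
        with pytest.raises(ConfigurationError):
            OpticalConfig(numerical_aperture=1.6, medium_index=1.518)

    def test_z_planes_must_increase(self):
        with pytest.raises(ConfigurationError):
            OpticalConfig(z_planes=(0.0, -1.0, 1.0))

    def test_unknown_psf_model_rejected(self):
        with pytest.raises(ConfigurationError):
            OpticalConfig(psf_model="raytrace")


class TestBuildPsf:
    def test_kernels_nonnegative_and_unit_mass(self, toy_psf):
        assert np.all(toy_psf.kernels >= 0)
        assert np.all(np.isfinite(toy_psf.kernels))
        # every (depth, phase) kernel carries unit mass -> projection
        # conserves the energy of every point source
        mass = toy_psf.kernels.sum(axis=(-2, -1))
        np.testing.assert_allclose(mass, 1.0, atol=1e-6)
        for d in range(toy_psf.config.n_depths):
            assert toy_psf.depth_mass(d) == pytest.approx(1.0, abs=1e-6)

    def test_gaussian_zero_defocus_concentrated_under_central_lenslet(self):
        cfg = OpticalConfig(pixels_per_lenslet=5, z_planes=(-1.0, 0.0, 1.0),
                            kernel_halfwidth=1, lenslet_pitch=1.0,
                            numerical_aperture=1.0, medium_index=1.33)
        psf = build_psf(cfg)
        n = 5
        k = psf.kernels[1, n // 2, n // 2]  # z = 0, on-axis source
        central = k[n:2 * n, n:2 * n].sum()
        assert central / k.sum() >= 0.9

    def test_wave_optics_width_grows_with_defocus(self):
        cfg = OpticalConfig(
            pixels_per_lenslet=5, z_planes=(0.0, 6.0), kernel_halfwidth=2,
            numerical_aperture=1.4, medium_index=1.518, wavelength=525.0,
            lenslet_pitch=1.3, psf_model="wave_optics")
        psf = build_psf(cfg)
        assert psf.lateral_rms_width(1) > psf.lateral_rms_width(0)

    def test_gaussian_far_defocus_wider_than_focus(self, toy_psf):
        # the surrogate's blur width grows with |z|; near focus the angular
        # fine structure dominates the second moment, so only the far
        # defocus comparison is a sharp contract
        w = [toy_psf.lateral_rms_width(d) for d in range(5)]
        assert w[0] > w[2] and w[4] > w[2]  # z = 0 at index 2


class TestProject:
    def test_zero_volume_projects_to_zero(self, toy_psf):
        lf = project(Volume(np.zeros((5, 16, 16))), toy_psf)
        assert np.all(lf.data == 0)

    def test_unit_voxel_stamps_its_kernel(self, toy_psf):
        n, kh = 4, 1
        vol = np.zeros((5, 16, 16))
        d, i, j, ly, lx = 2, 1, 3, 2, 1
        vol[d, ly * n + i, lx * n + j] = 1.0
        lf = project(Volume(vol), toy_psf)
        k = toy_psf.kernels[d, i, j]
        expected = np.zeros((16, 16))
        s = k.shape[0]
        for a in range(s):
            for b in range(s):
                y, x = ly * n - kh * n + a, lx * n - kh * n + b
                if 0 <= y < 16 and 0 <= x < 16:
                    expected[y, x] += k[a, b]
        np.testing.assert_allclose(lf.data, expected, atol=1e-12)

    def test_linearity(self, toy_psf, rng):
        v1 = Volume(rng.random((5, 16, 16)))
        v2 = Volume(rng.random((5, 16, 16)))
        a, b = 0.37, 2.1
        combined = project(Volume(a * v1.data + b * v2.data), toy_psf)
        separate = a * project(v1, toy_psf).data + b * project(v2, toy_psf).data
        np.testing.assert_allclose(combined.data, separate, rtol=1e-6,
                                   atol=1e-9)

    def test_energy_conserved_for_interior_support(self, toy_psf, rng):
        # sources at least kernel_halfwidth lenslets from the border lose
        # nothing off the sensor edge
        vol = np.zeros((5, 24, 24))
        vol[:, 8:16, 8:16] = rng.random((5, 8, 8))
        lf = project(Volume(vol), toy_psf)
        assert lf.data.sum() == pytest.approx(vol.sum(), rel=1e-5)

    def test_pitch_translation_equivariance(self, toy_psf):
        n = 4
        v1 = np.zeros((5, 24, 24))
        v1[2, 9, 10] = 1.0
        v2 = np.zeros((5, 24, 24))
        v2[2, 9 + n, 10 + n] = 1.0  # moved by exactly one pitch
        lf1 = project(Volume(v1), toy_psf).data
        lf2 = project(Volume(v2), toy_psf).data
        np.testing.assert_allclose(lf2[n:, n:], lf1[:-n, :-n], atol=1e-12)

    def test_shape_mismatch_raises_with_both_shapes(self, toy_psf):
        with pytest.raises(ValueError, match="depth"):
            project(Volume(np.zeros((3, 16, 16))), toy_psf)

    def test_adjoint_identity(self, toy_psf, rng):
        v = Volume(rng.random((5, 16, 16)))
        lf = LightField(rng.random((16, 16)), 4)
        lhs = float((project(v, toy_psf).data * lf.data).sum())
        rhs = float((v.data * project_adjoint(lf, toy_psf).data).sum())
        assert lhs == pytest.approx(rhs, rel=1e-6)


class TestViews:
    def test_two_by_two_lenslet_example(self):
        lf = LightField(np.arange(16.0).reshape(4, 4), 2)
        views = decompose_views(lf)
        np.testing.assert_array_equal(views.data[0],
                                      [[0.0, 2.0], [8.0, 10.0]])
        np.testing.assert_array_equal(views.data[3],
                                      [[5.0, 7.0], [13.0, 15.0]])

    def test_full_scale_geometry_gives_169_views_of_16(self):
        lf = LightField(np.zeros((208, 208)), 13)
        views = decompose_views(lf)
        assert views.data.shape == (169, 16, 16)

    @settings(deadline=None, max_examples=25)
    @given(n=st.integers(1, 5), gy=st.integers(1, 6), gx=st.integers(1, 6),
           seed=st.integers(0, 2 ** 16))
    def test_roundtrip_bit_exact(self, n, gy, gx, seed):
        r = np.random.default_rng(seed)
        lf = LightField(r.integers(0, 1000, (gy * n, gx * n)).astype(float), n)
        back = recompose_views(decompose_views(lf))
        assert np.array_equal(back.data, lf.data)

    def test_single_view_recomposes_onto_one_phase(self):
        views = np.zeros((4, 3, 3))
        views[1] = 7.0  # phase (0, 1)
        lf = recompose_views(
            decompose_views(LightField(np.zeros((6, 6)), 2)))
        from lfrecon.optics import ViewStack
        lf = recompose_views(ViewStack(views, 2))
        nz = np.nonzero(lf.data)
        assert np.all(nz[0] % 2 == 0) and np.all(nz[1] % 2 == 1)

    def test_non_divisible_shape_rejected(self):
        with pytest.raises(ValueError):
            LightField(np.zeros((9, 8)), 2)
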