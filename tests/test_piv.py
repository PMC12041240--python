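"""PIV stage: localization, position-error tensor, and 3D optical flow."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from lfrecon.phantoms import (FlowField, ParticleSet, PhantomSpec,
                              _rasterize_beads, make_beads,
                              make_particle_pair)
from lfrecon.piv import (FlowParams, fit_solid_rotation, localize_particles,
                         optical_flow_3d, position_error, velocity_error)


class TestLocalization:
    def test_single_bead_detected_subvoxel(self):
        truth = np.array([[4.3, 20.6, 17.2]])
        vol = _rasterize_beads((9, 40, 40), truth, np.full((1, 3), 1.2))
        det = localize_particles(vol, threshold=0.3, min_distance=3)
        assert len(det) == 1
        assert np.linalg.norm(det.positions[0] - truth[0]) < 0.5

    def test_zero_volume_empty_set(self):
        assert len(localize_particles(np.zeros((4, 8, 8)))) == 0

    def test_two_separated_beads_detected(self):
        pos = np.array([[3.0, 10.0, 10.0], [3.0, 10.0, 26.0]])
        vol = _rasterize_beads((7, 36, 36), pos, np.full((2, 3), 1.2))
        det = localize_particles(vol, threshold=0.3, min_distance=4)
        assert len(det) == 2

    def test_threshold_validated(self):
        with pytest.raises(ValueError):
            localize_particles(np.zeros((2, 2, 2)), threshold=1.5)


class TestPositionError:
    def test_identical_sets_zero(self):
        p = ParticleSet(np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]]),
                        np.zeros(2))
        res = position_error(p, p)
        np.testing.assert_allclose(res.errors, 0.0)
        assert res.mean_error == 0.0

    def test_three_four_five(self):
        det = ParticleSet(np.array([[3.0, 4.0, 0.0]]), np.zeros(1))
        ide = ParticleSet(np.array([[0.0, 0.0, 0.0]]), np.zeros(1))
        assert position_error(det, ide).errors[0] == pytest.approx(5.0)

    def test_mean_of_zero_and_five(self):
        det = ParticleSet(np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 15.0]]),
                          np.zeros(2))
        ide = ParticleSet(np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 10.0]]),
                          np.zeros(2))
        assert position_error(det, ide).mean_error == pytest.approx(2.5)

    def test_cardinality_mismatch_reported(self):
        det = ParticleSet(np.array([[0.0, 0.0, 0.0], [9.0, 9.0, 9.0]]),
                          np.zeros(2))
        ide = ParticleSet(np.array([[0.1, 0.0, 0.0]]), np.zeros(1))
        res = position_error(det, ide)
        assert res.n_unmatched_detected == 1 and res.n_unmatched_ideal == 0

    def test_physical_scale_applied(self):
        det = ParticleSet(np.array([[1.0, 0.0, 0.0]]), np.zeros(1))
        ide = ParticleSet(np.array([[0.0, 0.0, 0.0]]), np.zeros(1))
        res = position_error(det, ide, scale=np.array([2.0, 1.0, 1.0]))
        assert res.errors[0] == pytest.approx(2.0)


class TestOpticalFlow:
    def test_identical_volumes_zero_flow(self):
        vol, _ = make_beads(PhantomSpec(shape=(8, 24, 24), voxel_size=(1, 1, 1),
                                        seed=1, n_beads=3, bead_diameter=3.0,
                                        min_separation=5))
        f = optical_flow_3d(vol, vol)
        assert np.abs(f.vectors).max() == 0.0

    def test_unit_shift_recovered_within_ten_percent(self):
        vol, _ = make_beads(PhantomSpec(shape=(16, 48, 48), voxel_size=(1, 1, 1),
                                        seed=7, n_beads=25, bead_diameter=4.0,
                                        min_separation=4))
        a = ndi.gaussian_filter(vol.data, 0.5)
        b = np.roll(a, 1, axis=0)
        f = optical_flow_3d(a, b)
        interior = np.s_[3:-3, 3:-3, 3:-3]
        w = a[interior] > 0.05
        mean_flow = np.array([f.vectors[c][interior][w].mean()
                              for c in range(3)])
        assert mean_flow[0] == pytest.approx(1.0, rel=0.10)
        assert abs(mean_flow[1]) < 0.1 and abs(mean_flow[2]) < 0.1

    def test_vortex_angular_speed_within_fifteen_percent(self):
        spec = PhantomSpec(shape=(24, 24, 48), voxel_size=(1, 1, 1), seed=9,
                           particles_per_lenslet=0.4, pixels_per_lenslet=4,
                           particle_diameter=4.0, flow="vortex",
                           vortex_omega=0.08)
        v1, v2, _, _, truth = make_particle_pair(spec)
        f = optical_flow_3d(v1, v2)
        d, h, w = spec.shape
        zz, _, xx = np.meshgrid(np.arange(d, dtype=float),
                                np.arange(h, dtype=float),
                                np.arange(w, dtype=float), indexing="ij")
        r = np.sqrt((zz - (d - 1) / 2) ** 2 + (xx - (w - 1) / 2) ** 2)
        mask = (v1.data > 0.05) & (r > 2) & (r < 10)
        omega = fit_solid_rotation(f, mask=mask)
        assert omega == pytest.approx(0.08, rel=0.15)

    def test_axis_permutation_equivariance(self):
        vol, _ = make_beads(PhantomSpec(shape=(12, 16, 20), voxel_size=(1, 1, 1),
                                        seed=3, n_beads=6, bead_diameter=3.0,
                                        min_separation=4))
        a = ndi.gaussian_filter(vol.data, 0.5)
        b = np.roll(a, 1, axis=0)
        f = optical_flow_3d(a, b, FlowParams(n_iterations=50))
        perm = (1, 0, 2)
        fp = optical_flow_3d(a.transpose(perm), b.transpose(perm),
                             FlowParams(n_iterations=50))
        np.testing.assert_allclose(fp.vectors[1], f.vectors[0].transpose(perm),
                                   atol=1e-10)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            optical_flow_3d(np.zeros((4, 8, 8)), np.zeros((4, 8, 9)))

    def test_agrees_with_independent_tvl1_solver(self):
        """Cross-check against scikit-image's TV-L1 flow (a different
        variational formulation) on a dense smooth displacement."""
        from skimage.registration import optical_flow_tvl1
        vol, _ = make_beads(PhantomSpec(shape=(16, 32, 32), voxel_size=(1, 1, 1),
                                        seed=11, n_beads=20, bead_diameter=5.0,
                                        min_separation=3))
        a = ndi.gaussian_filter(vol.data, 1.0)
        b = np.roll(a, 1, axis=0)
        mine = optical_flow_3d(a, b)
        ref = optical_flow_tvl1(a, b)
        interior = np.s_[3:-3, 3:-3, 3:-3]
        w = a[interior] > 0.05
        assert mine.vectors[0][interior][w].mean() == pytest.approx(
            ref[0][interior][w].mean(), abs=0.15)


class TestVelocityError:
    def _flow(self, arr):
        return FlowField(np.asarray(arr, float))

    def test_identical_flows_zero_error(self):
        f = self._flow(np.random.default_rng(0).random((3, 4, 5, 6)))
        assert velocity_error(f, f)["mean"] == 0.0

    def test_constant_offset_unit_error(self):
        t = self._flow(np.zeros((3, 4, 5, 6)))
        e = np.zeros((3, 4, 5, 6))
        e[2] = 1.0
        res = velocity_error(self._flow(e), t)
        assert res["mean"] == pytest.approx(1.0)

    def test_n_equals_mask_count(self):
        t = self._flow(np.zeros((3, 4, 5, 6)))
        mask = np.zeros((4, 5, 6), bool)
        mask[1, 2, :4] = True
        assert velocity_error(t, t, mask)["n"] == 4

    def test_empty_mask_rejected(self):
        t = self._flow(np.zeros((3, 2, 2, 2)))
        with pytest.raises(ValueError, match="mask"):
            velocity_error(t, t, np.zeros((2, 2, 2), bool))
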