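"""Phantom generators: determinism, geometric fidelity of the rendered
structures, and correctness of the returned ground truth."""

import numpy as np
import pytest
from scipy.ndimage import center_of_mass

from lfrecon.metrics import dff_traces, fwhm_profile, pearson, roi_means_from_frames
from lfrecon.phantoms import (PhantomSpec, make_beads, make_neuro_volume,
                              make_particle_pair, make_tubulins,
                              render_neuro_frames)


class TestTubulins:
    spec = PhantomSpec(shape=(5, 64, 64), voxel_size=(1.0, 0.1, 0.1), seed=3,
                       n_filaments=8, filament_diameter=1.0)

    def test_deterministic(self):
        a = make_tubulins(self.spec)
        b = make_tubulins(self.spec)
        assert np.array_equal(a.data, b.data)

    def test_normalized_to_unit(self):
        v = make_tubulins(self.spec)
        assert v.data.min() >= 0 and v.data.max() == pytest.approx(1.0)

    def test_cross_section_fwhm_matches_diameter(self):
        # planar phantom (one z-slice): the y- and x-profiles through a point
        # on the filament are oblique cuts of a Gaussian tube of width w with
        # 1/w² = 1/w_y² + 1/w_x², which recovers the perpendicular FWHM
        spec = PhantomSpec(shape=(1, 96, 96), voxel_size=(1.0, 0.1, 0.1),
                           seed=11, n_filaments=1, filament_diameter=1.0)
        v = make_tubulins(spec)
        _, y, x = np.unravel_index(np.argmax(v.data), v.data.shape)
        wy = fwhm_profile(v.data[0, :, x])
        wx = fwhm_profile(v.data[0, y, :])
        width_vox = 1.0 / np.sqrt(1.0 / wy ** 2 + 1.0 / wx ** 2)
        assert width_vox == pytest.approx(10.0, abs=1.0)  # 1 μm / 0.1 μm

    def test_occupancy_monotone_in_filament_count(self):
        occ = []
        for n in (5, 10, 20):
            spec = PhantomSpec(shape=(5, 64, 64), voxel_size=(1, 0.1, 0.1),
                               seed=3, n_filaments=n)
            occ.append((make_tubulins(spec).data > 0.05).mean())
        assert occ[0] < occ[1] < occ[2]

    def test_oversized_diameter_rejected(self):
        with pytest.raises(ValueError, match="diameter"):
            make_tubulins(PhantomSpec(shape=(3, 16, 16),
                                      voxel_size=(1, 0.1, 0.1),
                                      filament_diameter=100.0))


class TestBeads:
    def test_centroids_match_returned_positions(self):
        spec = PhantomSpec(shape=(9, 48, 48), voxel_size=(1, 1, 1), seed=1,
                           n_beads=4, bead_diameter=2.0, min_separation=12)
        vol, truth = make_beads(spec)
        for p in truth.positions:
            lo = np.maximum((p - 4).astype(int), 0)
            hi = np.minimum((p + 5).astype(int), vol.data.shape)
            sub = vol.data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
            com = np.array(center_of_mass(sub)) + lo
            assert np.linalg.norm(com - p) < 0.5

    def test_min_separation_respected(self):
        spec = PhantomSpec(shape=(9, 64, 64), voxel_size=(1, 1, 1), seed=2,
                           n_beads=8, bead_diameter=2.0, min_separation=10)
        _, truth = make_beads(spec)
        d = np.linalg.norm(
            truth.positions[:, None] - truth.positions[None], axis=2)
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 10

    def test_zero_count_gives_empty(self):
        vol, truth = make_beads(PhantomSpec(n_beads=0))
        assert np.all(vol.data == 0) and len(truth) == 0

    def test_infeasible_packing_raises(self):
        with pytest.raises(RuntimeError, match="min_separation"):
            make_beads(PhantomSpec(shape=(5, 16, 16), voxel_size=(1, 1, 1),
                                   n_beads=50, min_separation=30))


class TestNeuro:
    spec = PhantomSpec(shape=(5, 48, 48), voxel_size=(2.0, 2.0, 2.0), seed=4,
                       n_somata=4, soma_radius=5.0, n_frames=60,
                       with_background=False)

    def test_background_free_support_is_union_of_somata(self):
        vol, centers, _ = make_neuro_volume(self.spec)
        support = vol.data > 0
        r_vox = 5.0 / 2.0
        zz, yy, xx = np.meshgrid(*map(np.arange, vol.data.shape), indexing="ij")
        union = np.zeros_like(support)
        for c in centers.positions:
            union |= (((zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2)
                      <= r_vox ** 2 * 1.0 + 1e-9)
        assert not np.any(support & ~union)

    def test_single_spike_trace_decays_exponentially(self):
        from lfrecon.phantoms import ActivityTrace
        spec = PhantomSpec(seed=9, n_frames=50, frame_rate=10.0, decay_tau=1.0,
                           spike_rate=0.0)
        # construct directly: a single spike convolved with exp kernel
        t = np.arange(50) / 10.0
        f = 0.2 + np.where(t >= 1.0, np.exp(-(t - 1.0) / 1.0), 0.0)
        tr = ActivityTrace(values=f, frame_rate=10.0, spike_times=np.array([1.0]))
        peak = np.argmax(tr.values)
        assert t[peak] == pytest.approx(1.0)
        decay = tr.values[peak:] - 0.2
        np.testing.assert_allclose(decay, decay[0] * np.exp(-(t[: len(decay)])),
                                   atol=1e-6)

    def test_rendered_dff_tracks_generating_trace(self):
        frames, centers, traces = render_neuro_frames(self.spec)
        base, _, _ = make_neuro_volume(self.spec)
        masks = base._soma_masks
        roi = roi_means_from_frames(frames, masks)
        dff = dff_traces(roi)
        for tr, d in zip(traces, dff):
            assert pearson(d, tr.values) >= 0.99


class TestParticlePair:
    def test_zero_flow_keeps_frames_identical(self):
        spec = PhantomSpec(shape=(8, 32, 32), voxel_size=(1, 1, 1), seed=5,
                           particles_per_lenslet=0.2, pixels_per_lenslet=4,
                           flow="uniform", flow_speed=0.0)
        v1, v2, p1, p2, _ = make_particle_pair(spec)
        assert np.array_equal(v1.data, v2.data)
        assert np.array_equal(p1.positions, p2.positions)

    def test_uniform_flow_advects_exactly(self):
        spec = PhantomSpec(shape=(8, 32, 32), voxel_size=(1, 1, 1), seed=6,
                           particles_per_lenslet=0.2, pixels_per_lenslet=4,
                           flow="uniform", flow_speed=1.5)
        _, _, p1, p2, flow = make_particle_pair(spec)
        np.testing.assert_allclose(p2.positions - p1.positions,
                                   np.tile([0, 0, 1.5], (len(p1), 1)))
        assert flow.vectors[2].mean() == pytest.approx(1.5)

    def test_ppm_seeding_density(self):
        # 0.03 particles per microlens over a 100x100 lenslet grid
        spec = PhantomSpec(shape=(5, 400, 400), voxel_size=(1, 1, 1), seed=7,
                           particles_per_lenslet=0.03, pixels_per_lenslet=4,
                           particle_diameter=2.0, flow="uniform")
        _, _, p1, _, _ = make_particle_pair(spec)
        expected = 0.03 * 100 * 100
        assert abs(len(p1) - expected) <= 4 * np.sqrt(expected)

    def test_unknown_flow_rejected(self):
        with pytest.raises(ValueError, match="flow"):
            make_particle_pair(PhantomSpec(flow="turbulent"))
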