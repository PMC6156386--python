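"""Registration core: image sampling, energy, gradient, optimizer contracts."""

import dataclasses

import numpy as np
import pytest

from cardiowarp import (
    ImageSeries,
    PhantomSpec,
    WarpConfig,
    basal_displacement,
    cycle_phase,
    neo_hookean_energy_density,
    normalize_series,
    register_frame,
    render_image_series,
    sample_image,
    similarity_penalty,
    track_cycle,
    warping_energy,
)
from cardiowarp.warping import WarpError, template_intensities


def _flat_series(vols, spacing=(1.0, 1.0, 1.0)):
    A = np.eye(4)
    A[:3, :3] = np.diag(spacing)
    return ImageSeries(
        frames=np.asarray(vols, float),
        affine=A,
        frame_times=np.arange(len(vols)) * 0.03,
        es_index=0,
        ed_index=1,
    )


class TestCyclePhase:
    def test_anchors(self):
        assert cycle_phase(0, 30, 15) == pytest.approx(0.0)
        assert cycle_phase(15, 30, 15) == pytest.approx(1.0)

    def test_symmetric_case_is_sin_squared(self):
        t = np.arange(30)
        assert np.allclose(cycle_phase(t, 30, 15), np.sin(np.pi * t / 30) ** 2)

    def test_asymmetric_es_still_peaks_at_es(self):
        p = cycle_phase(np.arange(30), 30, 12)
        assert np.argmax(p) == 12
        assert p[0] == pytest.approx(0.0)


class TestNormalize:
    def test_scale_invariance(self, rng):
        vols = rng.uniform(0, 1, (3, 8, 8, 4))
        a = normalize_series(vols, np.eye(4), np.arange(3) * 0.03, 1, 0)
        b = normalize_series(10 * vols, np.eye(4), np.arange(3) * 0.03, 1, 0)
        assert np.allclose(a.frames, b.frames)

    def test_output_range(self, rng):
        vols = rng.normal(100, 30, (3, 8, 8, 4))
        s = normalize_series(vols, np.eye(4), np.arange(3) * 0.03, 1, 0)
        assert s.frames.min() >= 0.0 and s.frames.max() <= 1.0
        assert s.normalization["hi"] > s.normalization["lo"]

    def test_constant_series_rejected(self):
        with pytest.raises(WarpError):
            normalize_series(np.ones((2, 4, 4, 4)), np.eye(4), [0, 0.03], 1, 0)

    def test_constant_frame_among_normal_frames_is_fine(self, rng):
        vols = rng.uniform(0, 1, (3, 6, 6, 4))
        vols[1] = 0.5
        s = normalize_series(vols, np.eye(4), np.arange(3) * 0.03, 2, 0)
        assert s.n_frames == 3


class TestSampleImage:
    def test_voxel_center_returns_stored_intensity(self, rng):
        vols = rng.uniform(0, 1, (2, 6, 6, 6))
        s = _flat_series(vols)
        pts = np.array([[2.0, 3.0, 4.0], [1.0, 1.0, 1.0]])
        val, _ = sample_image(s, 0, pts)
        assert val[0] == pytest.approx(vols[0, 2, 3, 4])
        assert val[1] == pytest.approx(vols[0, 1, 1, 1])

    def test_linear_ramp_gradient_recovered(self):
        # f = a.x + b sampled without smoothing: the interpolant is exact
        # and its gradient must be a (away from the border)
        n = 8
        idx = np.stack(np.meshgrid(*[np.arange(n)] * 3, indexing="ij"), -1)
        a = np.array([0.02, -0.01, 0.03])
        vol = idx @ a + 0.4
        s = _flat_series([vol, vol])
        pts = np.array([[3.3, 4.7, 2.2], [2.1, 2.9, 4.4]])
        val, grad = sample_image(s, 0, pts)
        assert np.abs(grad - a).max() < 1e-6
        assert val == pytest.approx(pts @ a + 0.4, abs=1e-12)

    def test_far_outside_returns_zero(self, rng):
        s = _flat_series(rng.uniform(0, 1, (2, 5, 5, 5)))
        val, grad = sample_image(s, 0, np.array([[100.0, 100.0, 100.0]]))
        assert val[0] == 0.0
        assert np.all(grad[0] == 0.0)

    def test_nonfinite_points_rejected(self, rng):
        s = _flat_series(rng.uniform(0, 1, (2, 5, 5, 5)))
        with pytest.raises(WarpError):
            sample_image(s, 0, np.array([[np.nan, 0, 0]]))


class TestEnergyDensities:
    def test_neo_hookean_zero_at_identity(self):
        assert neo_hookean_energy_density(np.eye(3), 1.0) == 0.0

    def test_neo_hookean_direct_arithmetic(self):
        F = np.diag([2.0, 2**-0.5, 2**-0.5])
        C = F.T @ F
        assert neo_hookean_energy_density(C, 1.0) == pytest.approx(2.0)

    def test_neo_hookean_rotation_invariant(self, rng):
        th = 0.9
        Q = np.array(
            [[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]]
        )
        C = Q.T @ Q
        assert neo_hookean_energy_density(C, 3.0) == pytest.approx(0.0, abs=1e-12)

    def test_non_spd_rejected(self):
        with pytest.raises(WarpError):
            neo_hookean_energy_density(np.diag([1.0, -0.5, 1.0]), 1.0)

    def test_similarity_penalty_values(self):
        assert similarity_penalty(0.5, 0.5, 0.005) == 0.0
        # gamma = 0.005 and unit mismatch: U = gamma/2 = 0.0025
        assert similarity_penalty(1.0, 0.0, 0.005) == pytest.approx(0.0025)
        assert similarity_penalty(0.2, 0.9, 0.005) == similarity_penalty(0.9, 0.2, 0.005)


class TestBasalDisplacement:
    def _series(self, n=10, es=5):
        return ImageSeries(
            frames=np.tile(np.arange(n)[:, None, None, None] / n, (1, 4, 4, 4)),
            affine=np.eye(4),
            frame_times=np.arange(n) * 0.03,
            es_index=es,
            ed_index=0,
        )

    def test_zero_at_es(self):
        cfg = WarpConfig(mapse=10.0)
        assert basal_displacement(5, cfg, self._series()) == pytest.approx(0.0)

    def test_full_excursion_at_ed(self):
        cfg = WarpConfig(mapse=10.0)
        # ES-referenced: at ED the base sits a full MAPSE away
        assert abs(basal_displacement(0, cfg, self._series())) == pytest.approx(10.0)

    def test_zero_mapse_everywhere(self):
        cfg = WarpConfig(mapse=0.0)
        s = self._series()
        assert all(basal_displacement(t, cfg, s) == 0.0 for t in range(10))


class TestWarpingEnergy:
    def test_zero_displacement_matched_images(self, small_mesh_es, small_series):
        cfg = WarpConfig()
        E, g, ok = warping_energy(
            small_mesh_es, np.zeros((small_mesh_es.n_nodes, 3)), small_series,
            small_series.es_index, cfg,
        )
        assert ok
        assert E == pytest.approx(0.0, abs=1e-12)
        assert np.abs(g).max() < 1e-12

    def test_zero_displacement_differing_images_is_pure_penalty(
        self, small_mesh_es, small_series
    ):
        cfg = WarpConfig()
        t = 1
        E, _, _ = warping_energy(
            small_mesh_es, np.zeros((small_mesh_es.n_nodes, 3)), small_series, t, cfg
        )
        # elastic part vanishes at u = 0, so E equals the image integral
        from cardiowarp.warping import QUAD_RULES

        B, w = QUAD_RULES[cfg.quadrature]
        tmpl = template_intensities(small_mesh_es, small_series, cfg)
        Xq = np.einsum("qa,mak->mqk", B, small_mesh_es.cell_coords())
        tv, _ = sample_image(small_series, t, Xq.reshape(-1, 3), cfg.smoothing_sd)
        V = small_mesh_es.cell_volumes()
        expected = np.sum(
            0.5 * cfg.gamma * (tmpl - tv.reshape(tmpl.shape)) ** 2 * w * V[:, None]
        )
        assert E == pytest.approx(expected, rel=1e-12)

    def test_gradient_matches_finite_differences(self, small_mesh_es, small_series, rng):
        cfg = WarpConfig()
        # smooth random feasible state: low-frequency displacement field
        X = small_mesh_es.nodes
        k = rng.normal(0, 0.05, (3, 3))
        u = 0.5 * np.sin(X @ k.T / 20.0)
        E, g, ok = warping_energy(small_mesh_es, u, small_series, 1, cfg)
        assert ok
        h = 1e-5
        for _ in range(5):
            v = rng.normal(size=u.shape)
            v /= np.linalg.norm(v)
            Ep, _, _ = warping_energy(small_mesh_es, u + h * v, small_series, 1, cfg)
            Em, _, _ = warping_energy(small_mesh_es, u - h * v, small_series, 1, cfg)
            fd = (Ep - Em) / (2 * h)
            dd = float(np.sum(g * v))
            assert abs(fd - dd) / max(abs(fd), abs(dd)) < 1e-5

    def test_inverted_element_flagged(self, small_mesh_es, small_series):
        cfg = WarpConfig()
        u = np.zeros((small_mesh_es.n_nodes, 3))
        # collapse one cell by swapping two of its nodes' positions
        c = small_mesh_es.cells[0]
        u[c[0]] = small_mesh_es.nodes[c[1]] - small_mesh_es.nodes[c[0]]
        u[c[1]] = small_mesh_es.nodes[c[0]] - small_mesh_es.nodes[c[1]]
        E, _, ok = warping_energy(small_mesh_es, u, small_series, 1, cfg)
        assert not ok
        assert np.isinf(E)


class TestRegisterFrame:
    def test_matched_target_zero_bc_stays_put(self, small_mesh_es, small_series):
        cfg = WarpConfig(mapse=0.0, max_iter=50)
        u, log = register_frame(
            small_mesh_es, np.zeros((small_mesh_es.n_nodes, 3)), small_series,
            small_series.es_index, 0.0, cfg,
        )
        assert np.abs(u).max() < 1e-6

    def test_energy_monotone_within_frame(self, small_mesh_es, small_series):
        cfg = WarpConfig(mapse=0.0, max_iter=40)
        _, log = register_frame(
            small_mesh_es, np.zeros((small_mesh_es.n_nodes, 3)), small_series, 1, 0.0, cfg
        )
        e = np.array(log["energies"])
        assert np.all(np.diff(e) <= 1e-12)

    def test_known_in_plane_shift_recovered(self, small_spec, small_mesh_es):
        # target = template shifted by 2 voxels in x: the mean recovered
        # in-plane displacement must match the shift within 10%
        series = render_image_series(small_spec)
        shift_vox = 2
        shifted = np.roll(series.frames[small_spec.es_frame], shift_vox, axis=0)
        frames = np.stack([series.frames[small_spec.es_frame], shifted])
        s2 = ImageSeries(
            frames=frames, affine=series.affine, frame_times=np.array([0.0, 0.03]),
            es_index=0, ed_index=1,
        )
        cfg = WarpConfig(mapse=0.0, max_iter=300, c1=1e-4)
        u, log = register_frame(
            small_mesh_es, np.zeros((small_mesh_es.n_nodes, 3)), s2, 1, 0.0, cfg
        )
        shift_mm = shift_vox * small_spec.grid_spacing[0]
        assert u[:, 0].mean() == pytest.approx(shift_mm, rel=0.10)


class TestTrackCycle:
    def test_static_series_zero_mapse_keeps_mesh_still(self, small_mesh_es, small_series):
        frames = np.tile(small_series.frames[small_series.es_index], (4, 1, 1, 1))
        s = ImageSeries(
            frames=frames, affine=small_series.affine,
            frame_times=np.arange(4) * 0.03, es_index=2, ed_index=0,
        )
        cfg = WarpConfig(mapse=0.0, max_iter=50)
        sol = track_cycle(small_mesh_es, s, cfg)
        assert np.abs(sol.u).max() < 1e-6
        assert np.all(sol.jacobians() > 0)

    def test_es_displacement_exactly_zero(self, small_mesh_es, small_series):
        cfg = WarpConfig(mapse=10.0, max_iter=20)
        sol = track_cycle(small_mesh_es, small_series, cfg)
        assert np.all(sol.u[small_series.es_index] == 0.0)

    def test_mismatch_energy_reduced_vs_rest(self, small_mesh_es, small_series, small_spec):
        cfg = WarpConfig(mapse=small_spec.mapse, max_iter=200)
        sol = track_cycle(small_mesh_es, small_series, cfg)
        t = 1  # well away from ES
        E0, _, _ = warping_energy(
            small_mesh_es, np.zeros((small_mesh_es.n_nodes, 3)), small_series, t, cfg
        )
        assert sol.energies[t] < 0.5 * E0

    def test_solution_tensors_consistent(self, small_mesh_es, small_series):
        cfg = WarpConfig(mapse=0.0, max_iter=10)
        sol = track_cycle(small_mesh_es, small_series, cfg)
        C = sol.cauchy_green()
        I1 = sol.first_invariant()
        assert np.allclose(I1, np.einsum("tmii->tm", C))
        assert np.allclose(sol.jacobians(), np.linalg.det(sol.F))
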