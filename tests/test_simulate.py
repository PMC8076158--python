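"""Brownian dynamics and rendering of the synthetic-movie generator."""

import numpy as np
import pytest

from sgddm.simulate import (
    SimulationConfig,
    TrajectorySet,
    density_to_particle_count,
    generate_movie,
    render_frame,
    simulate_trajectories,
    step_positions,
    step_orientations,
)


def small_config(**overrides):
    base = dict(
        n_particles=8,
        n_frames=5,
        image_shape=(64, 64),
        D_T=0.24,
        D_R=0.30,
        noise_sigma=0.0,
        seed=3,
    )
    base.update(overrides)
    return SimulationConfig(**base)


class TestStepPositions:
    def test_zero_diffusivity_leaves_positions_unchanged(self, rng):
        pos = rng.uniform(0, 10, size=(50, 2))
        new = step_positions(pos, 0.0, 0.04, rng, box_um=(10, 10))
        assert np.array_equal(new, pos)

    def test_single_step_variance(self, rng):
        n = 200_000
        pos = np.zeros((n, 2))
        new = step_positions(pos, 0.25, 0.04, rng)
        var = new[:, 0].var()
        expected = 2 * 0.25 * 0.04
        se = expected * np.sqrt(2.0 / n)
        assert abs(var - expected) < 3 * se

    def test_ensemble_msd_slope(self, rng):
        # <dr^2> = 4 D_T tau for free 2D Brownian motion
        n, steps, D, dt = 10_000, 100, 0.25, 0.04
        pos = np.zeros((n, 2))
        for _ in range(steps):
            pos = step_positions(pos, D, dt, rng)
        msd = (pos**2).sum(axis=1).mean()
        expected = 4 * D * dt * steps
        se = expected * np.sqrt(2.0 / n)
        assert abs(msd - expected) < 3 * se

    def test_boundary_rules_keep_positions_in_box(self, rng):
        pos = rng.uniform(0, 5, size=(100, 2))
        for boundary in ("periodic", "reflecting"):
            p = pos.copy()
            for _ in range(50):
                p = step_positions(p, 1.0, 0.1, rng, box_um=(5, 5), boundary=boundary)
            assert np.all((p >= 0) & (p <= 5))

    def test_invalid_parameters_raise(self, rng):
        with pytest.raises(ValueError):
            step_positions(np.zeros((2, 2)), -1.0, 0.04, rng)
        with pytest.raises(ValueError):
            step_positions(np.zeros((2, 2)), 1.0, 0.0, rng)


class TestStepOrientations:
    def test_zero_rotation_leaves_orientations_unchanged(self, rng):
        u = rng.normal(size=(40, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        assert np.array_equal(step_orientations(u, 0.0, 0.04, rng), u)

    def test_unit_norm_preserved(self, rng):
        u = rng.normal(size=(500, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        for _ in range(20):
            u = step_orientations(u, 0.5, 0.04, rng)
            assert np.allclose(np.linalg.norm(u, axis=1), 1.0, atol=1e-9)

    def test_coarse_step_warns(self, rng):
        u = np.array([[0.0, 0.0, 1.0]])
        with pytest.warns(UserWarning, match="too coarse"):
            step_orientations(u, 2.0, 0.04, rng)

    @pytest.mark.parametrize("order,rate_factor", [(1, 2.0), (2, 6.0)])
    def test_orientation_correlators_decay_at_legendre_rates(self, rng, order, rate_factor):
        # <P_l(u(t).u(0))> = exp(-l(l+1) D_R t); l=2 is the 6 D_R of the
        # roto-translational ISF
        n, D, dt, steps = 20_000, 0.30, 0.04, 25
        u0 = rng.normal(size=(n, 3))
        u0 /= np.linalg.norm(u0, axis=1, keepdims=True)
        u = u0.copy()
        for _ in range(steps):
            u = step_orientations(u, D, dt, rng)
        c = (u * u0).sum(axis=1)
        p = c if order == 1 else (3 * c**2 - 1) / 2
        expected = np.exp(-rate_factor * D * dt * steps)
        se = p.std(ddof=1) / np.sqrt(n)
        assert abs(p.mean() - expected) < 3 * se


class TestRendering:
    def test_axis_along_optical_axis_gives_circular_blob(self):
        cfg = small_config(n_particles=1)
        centre = 32.5 * cfg.pixel_size  # exactly on a pixel centre
        img_pole = render_frame(
            np.array([[centre, centre]]), np.array([[0.0, 0.0, 1.0]]), cfg
        )
        # circular blob: symmetric under transpose about the centre
        blob = img_pole - cfg.background
        assert np.allclose(blob, blob.T, atol=1e-4 * blob.max())
        # peak height corresponds to sigma_a = sigma_b = sigma_perp
        expected_peak = cfg.amplitude / (2 * np.pi * cfg.sigma_perp**2)
        assert blob.max() == pytest.approx(expected_peak, rel=0.02)

    def test_in_plane_rotation_by_90_degrees_transposes_image(self):
        cfg = small_config(n_particles=1)
        centre = 32 * cfg.pixel_size  # exact image centre
        pos = np.array([[centre, centre]])
        img_x = render_frame(pos, np.array([[1.0, 0.0, 0.0]]), cfg)
        img_y = render_frame(pos, np.array([[0.0, 1.0, 0.0]]), cfg)
        assert np.allclose(img_y, img_x.T, atol=1e-4 * img_x.max())

    def test_integrated_intensity_conserved(self, rng):
        cfg = small_config(n_particles=10, image_shape=(128, 128), noise_sigma=0.0)
        u = rng.normal(size=(10, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        pos = rng.uniform(2, 128 * cfg.pixel_size - 2, size=(10, 2))
        img = render_frame(pos, u, cfg)
        total = (img.astype(float).sum() - cfg.background * 128 * 128) * cfg.pixel_size**2
        assert total == pytest.approx(10 * cfg.amplitude, rel=0.01)

    def test_undersampled_blob_warns(self):
        cfg = small_config(pixel_size=0.8, sigma_parallel=0.5, sigma_perp=0.3)
        with pytest.warns(UserWarning, match="undersampled"):
            render_frame(np.array([[5.0, 5.0]]), np.array([[1.0, 0.0, 0.0]]), cfg)

    def test_image_too_small_raises(self):
        cfg = small_config(image_shape=(16, 16))
        with pytest.raises(ValueError, match="too small"):
            render_frame(np.array([[1.0, 1.0]]), np.array([[1.0, 0.0, 0.0]]), cfg)


class TestGenerateMovie:
    def test_seed_reproducibility_bit_identical(self):
        cfg = small_config(noise_sigma=3.0, n_frames=4)
        seq1, traj1 = generate_movie(cfg)
        seq2, traj2 = generate_movie(cfg)
        assert np.array_equal(seq1.frames, seq2.frames)
        assert np.array_equal(traj1.positions, traj2.positions)
        assert np.array_equal(traj1.orientations, traj2.orientations)

    def test_zero_noise_zero_diffusivities_static_movie(self):
        cfg = small_config(D_T=0.0, D_R=0.0, n_frames=4)
        seq, _ = generate_movie(cfg)
        assert np.array_equal(seq.frames[0], seq.frames[-1])

    def test_trajectories_respect_invariants(self):
        cfg = small_config(n_frames=20)
        _, traj = generate_movie(cfg)
        assert traj.n_frames == 20 and traj.n_particles == 8
        norms = np.linalg.norm(traj.orientations, axis=-1)
        assert np.allclose(norms, 1.0, atol=1e-9)
        Ly, Lx = cfg.box_um
        assert np.all(traj.positions[..., 0] >= 0) and np.all(traj.positions[..., 0] <= Lx)

    def test_ground_truth_dataframe_round_trip(self):
        cfg = small_config(n_frames=3)
        _, traj = generate_movie(cfg)
        df = traj.to_dataframe()
        assert len(df) == 3 * 8
        assert set(df.columns) == {"frame", "particle_id", "x_um", "y_um", "ux", "uy", "uz"}


def test_paper_density_gives_35_particles_on_40x_field():
    # 5e3 particles per mm^2 on the 6.9e3 µm^2 field of view
    assert density_to_particle_count(5e3, 6.9e3) == 35


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(sigma_parallel=0.2, sigma_perp=0.3)
    with pytest.raises(ValueError):
        SimulationConfig(D_T=-0.1)
    with pytest.raises(ValueError):
        SimulationConfig(boundary="open")
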