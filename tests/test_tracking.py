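"""Detection, linking, shape fitting and the SPT dynamical estimators."""

import numpy as np
import pandas as pd
import pytest

from sgddm.simulate import SimulationConfig, render_frame
from sgddm import tracking as trk


def blob_frame(positions_px, orientations, shape=(96, 96), noise=0.0, seed=0):
    """Render isolated blobs at given pixel positions (helper)."""
    cfg = SimulationConfig(
        n_particles=len(positions_px),
        n_frames=1,
        image_shape=shape,
        noise_sigma=noise,
        seed=seed,
    )
    pos_um = (np.asarray(positions_px, dtype=float) + 0.5) * cfg.pixel_size
    rng = np.random.default_rng(seed) if noise > 0 else None
    return cfg, render_frame(pos_um, np.asarray(orientations, dtype=float), cfg, rng)


class TestDetection:
    def test_blank_frame_gives_empty_list(self, rng):
        img = 100 + rng.normal(0, 1, size=(64, 64))
        det = trk.detect_particles(img, min_separation=9)
        assert len(det) == 0

    def test_single_blob_subpixel_localization(self):
        true = np.array([[47.3, 52.8]])  # (x, y) px
        _, img = blob_frame(true, [[1.0, 0.0, 0.0]])
        det = trk.detect_particles(img, min_separation=9)
        assert len(det) == 1
        err = np.hypot(det["x_px"][0] - true[0, 0], det["y_px"][0] - true[0, 1])
        assert err < 0.05

    def test_well_separated_field_gives_exact_count(self, rng):
        n = 35
        gx, gy = np.meshgrid(np.arange(6), np.arange(6))
        pts = np.stack([gx.ravel(), gy.ravel()], 1)[:n] * 40.0 + 20.0
        pts = pts + rng.uniform(-3, 3, size=pts.shape)
        u = rng.normal(size=(n, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        _, img = blob_frame(pts, u, shape=(256, 256), noise=2.0)
        det = trk.detect_particles(img, min_separation=9)
        assert len(det) == n

    def test_min_separation_enforced_pairwise(self):
        # two blobs 6 px apart with 9 px separation: only the brighter kept
        _, img = blob_frame([[40, 40], [46, 40]], [[0, 0, 1], [1, 0, 0]])
        det = trk.detect_particles(img, min_separation=9)
        assert len(det) == 1


class TestLinking:
    def frames_from(self, tracks):
        """tracks: dict id -> list of (frame, y, x)."""
        rows = []
        for _, obs in tracks.items():
            for f, y, x in obs:
                rows.append({"frame": f, "y_px": y, "x_px": x, "mass": 1.0})
        return pd.DataFrame(rows)

    def test_single_particle_full_length(self):
        det = self.frames_from({0: [(f, 10 + 0.1 * f, 20.0) for f in range(30)]})
        linked = trk.link(det, max_disp=3.0)
        assert linked["particle"].nunique() == 1
        assert len(linked) == 30

    def test_two_distant_particles_never_swap(self):
        det = self.frames_from(
            {
                0: [(f, 10.0 + 0.2 * f, 10.0) for f in range(20)],
                1: [(f, 60.0 - 0.2 * f, 60.0) for f in range(20)],
            }
        )
        linked = trk.link(det, max_disp=3.0)
        assert linked["particle"].nunique() == 2
        for _, g in linked.groupby("particle"):
            assert g["x_px"].std() < 1e-9  # each trajectory stays on its column

    def test_jump_beyond_max_disp_starts_new_trajectory(self):
        obs = [(0, 10.0, 10.0), (1, 10.5, 10.0), (2, 30.0, 30.0), (3, 30.5, 30.0)]
        det = self.frames_from({0: obs})
        linked = trk.link(det, max_disp=3.0)
        assert linked["particle"].nunique() == 2

    def test_tie_resolved_to_lowest_particle_id(self):
        # two previous endpoints equidistant from one detection
        det = pd.DataFrame(
            [
                {"frame": 0, "y_px": 10.0, "x_px": 9.0, "mass": 1.0},
                {"frame": 0, "y_px": 10.0, "x_px": 11.0, "mass": 1.0},
                {"frame": 1, "y_px": 10.0, "x_px": 10.0, "mass": 1.0},
            ]
        )
        linked = trk.link(det, max_disp=3.0)
        survivor = linked[linked["frame"] == 1]["particle"].iloc[0]
        assert survivor == 0


class TestBivariateGaussianFit:
    def test_recovery_of_axes_and_angle(self):
        # a = 0.5 µm, b = 0.3 µm at 30 degrees, noiseless
        phi = np.deg2rad(30)
        u = [np.cos(phi), np.sin(phi), 0.0]
        cfg, img = blob_frame([[48.0, 48.0]], [u])
        res = trk.fit_bivariate_gaussian(img, (48.0, 48.0), 10)
        assert res["ok"]
        assert res["a_px"] * cfg.pixel_size == pytest.approx(0.5, rel=0.01)
        assert res["b_px"] * cfg.pixel_size == pytest.approx(0.3, rel=0.01)
        assert np.rad2deg(res["phi"]) == pytest.approx(30.0, abs=1.0)
        assert res["epsilon"] == pytest.approx(0.36, rel=0.03)

    def test_circular_blob_eps_one_and_angle_undefined(self):
        cfg, img = blob_frame([[48.0, 48.0]], [[0.0, 0.0, 1.0]], noise=1.0)
        res = trk.fit_bivariate_gaussian(img, (48.0, 48.0), 10)
        assert res["ok"]
        assert res["epsilon"] == pytest.approx(1.0, abs=0.05)
        assert not res["phi_defined"]

    def test_roi_clipping_at_border_reports_failure(self):
        _, img = blob_frame([[3.0, 48.0]], [[1.0, 0.0, 0.0]])
        res = trk.fit_bivariate_gaussian(img, (48.0, 3.0), 10)
        assert res["ok"] is False


def gt_observation_table(n_particles, n_frames, D_R, dt=0.04, seed=0,
                         sp=0.5, sq=0.3, pin_in_plane=False, frozen=False):
    """Observation table from simulated orientations only (no imaging).

    The pinned (in-plane) variant accumulates the angle directly, which is
    exact 1D angular diffusion; the 3D variant uses the simulator's
    substepped sphere update."""
    from sgddm.simulate import step_orientations

    rng = np.random.default_rng(seed)
    us = np.empty((n_frames, n_particles, 3))
    if pin_in_plane:
        ang = rng.uniform(0, 2 * np.pi, size=n_particles)
        for t in range(n_frames):
            if not frozen and D_R > 0:
                ang = ang + rng.normal(0, np.sqrt(2 * D_R * dt), size=n_particles)
            us[t] = np.stack([np.cos(ang), np.sin(ang), np.zeros_like(ang)], 1)
    else:
        u = rng.normal(size=(n_particles, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        for t in range(n_frames):
            if not frozen and D_R > 0:
                u = step_orientations(u, D_R, dt, rng)
            us[t] = u
    sin2 = us[..., 0] ** 2 + us[..., 1] ** 2
    a = np.sqrt(sp**2 * sin2 + sq**2 * (1 - sin2))
    phi = np.arctan2(us[..., 1], us[..., 0]) % np.pi
    eps = sq**2 / a**2
    T, N = n_frames, n_particles
    return pd.DataFrame(
        {
            "particle": np.tile(np.arange(N), T),
            "frame": np.repeat(np.arange(T), N),
            "x_um": 0.0,
            "y_um": 0.0,
            "a_um": a.ravel(),
            "b_um": sq,
            "phi": phi.ravel(),
            "epsilon": eps.ravel(),
            "phi_defined": True,
        }
    )


class TestMSD:
    def test_ballistic_motion_flagged_nonlinear(self):
        rows = []
        for p in range(12):
            for f in range(40):
                rows.append({"particle": p, "frame": f, "x_um": 0.3 * f, "y_um": 0.0})
        _, fit = trk.msd(pd.DataFrame(rows), dt=0.04)
        assert fit["nonlinear"]
        assert fit["exponent"] == pytest.approx(2.0, abs=0.05)

    def test_pure_brownian_recovery(self, rng):
        D, dt = 0.23, 0.04
        rows = []
        for p in range(40):
            xy = np.cumsum(rng.normal(0, np.sqrt(2 * D * dt), size=(300, 2)), axis=0)
            for f in range(300):
                rows.append(
                    {"particle": p, "frame": f, "x_um": xy[f, 0], "y_um": xy[f, 1]}
                )
        _, fit = trk.msd(pd.DataFrame(rows), dt=dt)
        assert fit["D_T"] == pytest.approx(D, rel=0.1)
        assert not fit["nonlinear"]

    def test_insufficient_statistics_raise(self):
        df = pd.DataFrame(
            {"particle": [0] * 5, "frame": range(5), "x_um": range(5), "y_um": 0.0}
        )
        with pytest.raises(ValueError, match="insufficient"):
            trk.msd(df, dt=0.04)


class TestAngularMSD:
    def test_in_plane_rotation_rate_recovered(self):
        # axis pinned to the image plane: the nematic angle is exactly
        # diffusive with <dphi^2> = 2 D tau
        D = 0.3
        traj = gt_observation_table(300, 400, D, pin_in_plane=True, seed=2)
        _, fit = trk.angular_msd(traj, dt=0.04)
        assert fit["D_R"] == pytest.approx(D, rel=0.05)

    def test_full_3d_rotation_recovered_within_tolerance(self):
        D = 0.28
        traj = gt_observation_table(400, 500, D, seed=3)
        _, fit = trk.angular_msd(traj, dt=0.04)
        assert fit["D_R"] == pytest.approx(D, rel=0.2)

    def test_statistics_invariant_under_nematic_shift(self):
        D = 0.3
        traj = gt_observation_table(100, 200, D, pin_in_plane=True, seed=4)
        shifted = traj.copy()
        half = shifted.index[: len(shifted) // 2]
        shifted.loc[half, "phi"] = (shifted.loc[half, "phi"] + np.pi) % np.pi
        _, f1 = trk.angular_msd(traj, dt=0.04)
        _, f2 = trk.angular_msd(shifted, dt=0.04)
        assert f2["D_R"] == pytest.approx(f1["D_R"], rel=1e-9)

    def test_frozen_orientations_give_zero_slope(self):
        traj = gt_observation_table(50, 100, 0.3, frozen=True, seed=5)
        # frozen axes in-plane keep phi measurable but static
        traj["a_um"] = 0.5
        _, fit = trk.angular_msd(traj, dt=0.04)
        assert abs(fit["D_R"]) < 1e-9


class TestAspectRatioAutocorrelation:
    def test_rate_is_six_D_R(self):
        D = 0.29
        traj = gt_observation_table(60, 2500, D, seed=6)
        _, fit = trk.aspect_ratio_autocorrelation(traj, dt=0.04)
        assert fit["gamma"] == pytest.approx(6 * D, rel=0.15)

    def test_normalization_at_zero_lag(self):
        traj = gt_observation_table(20, 400, 0.3, seed=7)
        curve, _ = trk.aspect_ratio_autocorrelation(traj, dt=0.04)
        assert curve["C_eps"].iloc[0] == pytest.approx(1.0)

    def test_frozen_orientations_raise_inapplicable(self):
        traj = gt_observation_table(20, 200, 0.3, frozen=True, seed=8)
        with pytest.raises(ValueError, match="inapplicable"):
            trk.aspect_ratio_autocorrelation(traj, dt=0.04)
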