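"""Single-particle-tracking validation path.

Locates particles frame by frame (Crocker–Grier-style bandpass, local-maximum
candidates, centroid refinement), links them into trajectories with a greedy
nearest-neighbour assignment, measures the apparent shape of each particle by
a bivariate Gaussian fit, and derives three independent dynamical estimators:

* translational: the centre-of-mass MSD, <dr^2(tau)> = 4 D_T tau;
* rotational, in-plane: the angular MSD of the nematic image angle,
  <dphi^2(tau)> = 2 D_R tau.  The in-plane angle of a 3D rotational diffuser
  is only diffusive with coefficient D_R while the particle axis lies near
  the image plane (the azimuth step variance is 2 D_R dt / sin^2 theta), so
  angular steps are measured only between frames whose apparent aspect ratio
  indicates sin^2 theta above a threshold — without this restriction the
  estimator is severalfold biased;
* rotational, out-of-plane: the autocorrelation of the apparent aspect ratio
  eps = b^2/a^2, which relaxes as C_eps(tau) = exp(-6 D_R tau) (the l = 2
  correlator of isotropic rotational diffusion).

Observations and trajectories are tidy pandas DataFrames with a fixed
schema; ``Trajectories`` below documents the columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import least_squares

from .ddm import ImageSequence

__all__ = [
    "detect_particles",
    "link",
    "fit_bivariate_gaussian",
    "measure_trajectories",
    "msd",
    "angular_msd",
    "aspect_ratio_autocorrelation",
]

#: observation schema: frame, particle, x_um, y_um, a_um, b_um, phi, epsilon, ok


def _bandpass(image: np.ndarray, noise_size: float, feature_size: float) -> np.ndarray:
    img = np.asarray(image, dtype=np.float32)
    low = ndimage.gaussian_filter(img, noise_size, truncate=3.0)
    bg = ndimage.gaussian_filter(img, feature_size, truncate=2.5)
    return low - bg


def detect_particles(
    image: np.ndarray,
    min_separation: int = 9,
    threshold: float | None = None,
    noise_size: float = 1.0,
    feature_size: float | None = None,
    invert: bool = False,
) -> pd.DataFrame:
    """Locate bright particle candidates in one frame.

    Difference-of-Gaussians bandpass, local maxima above ``threshold`` with
    ``min_separation`` (pixels) enforced, then intensity-weighted centroid
    refinement.  ``threshold`` defaults to 5 robust standard deviations of
    the bandpassed image.  Returns a DataFrame with columns y_px, x_px, mass
    (possibly empty — zero detections are not an error).
    """
    img = np.asarray(image, dtype=float)
    if invert:
        img = -img
    if feature_size is None:
        feature_size = max(2.0, min_separation / 2.0)
    bp = _bandpass(img, noise_size, feature_size)
    if threshold is None:
        sub = bp[::4, ::4]
        mad = np.median(np.abs(sub - np.median(sub)))
        threshold = 5.0 * 1.4826 * mad
    size = max(3, int(min_separation) | 1)
    maxima = (bp == ndimage.maximum_filter(bp, size=size)) & (bp > threshold)
    ys, xs = np.nonzero(maxima)
    # enforce the separation pairwise: keep the brighter of close peaks
    if ys.size > 1:
        order = np.argsort(bp[ys, xs])[::-1]
        ys, xs = ys[order], xs[order]
        keep = np.ones(ys.size, dtype=bool)
        for i in range(ys.size):
            if not keep[i]:
                continue
            d2 = (ys[i + 1 :] - ys[i]) ** 2 + (xs[i + 1 :] - xs[i]) ** 2
            keep[i + 1 :] &= d2 >= min_separation**2
        ys, xs = ys[keep], xs[keep]
    # refinement window must cover the feature's tails, otherwise the
    # truncation biases sub-pixel positions toward the window centre
    half = max(4, int(min_separation) // 2 + 2)
    H, W = bp.shape
    rows = []
    pos = np.clip(bp, 0, None)
    for y, x in zip(ys, xs):
        # intensity-weighted centroid, re-centred iteratively so the window
        # truncation does not bias sub-pixel positions
        cy, cx = float(y), float(x)
        m = 0.0
        for _ in range(3):
            yc, xc = int(round(cy)), int(round(cx))
            y0, y1 = max(0, yc - half), min(H, yc + half + 1)
            x0, x1 = max(0, xc - half), min(W, xc + half + 1)
            patch = pos[y0:y1, x0:x1]
            m = patch.sum()
            if m <= 0:
                break
            yy, xx = np.mgrid[y0:y1, x0:x1]
            cy = float((yy * patch).sum() / m)
            cx = float((xx * patch).sum() / m)
        if m <= 0:
            continue
        rows.append({"y_px": cy, "x_px": cx, "mass": float(m)})
    return pd.DataFrame(rows, columns=["y_px", "x_px", "mass"])


def link(
    detections: list[pd.DataFrame] | pd.DataFrame,
    max_disp: float,
) -> pd.DataFrame:
    """Greedy nearest-neighbour frame-to-frame linking (no gap closing).

    ``detections`` is either a list of per-frame DataFrames (y_px, x_px) or
    one DataFrame with a ``frame`` column.  Candidate links within
    ``max_disp`` pixels are assigned one-to-one in order of increasing
    displacement; ties resolve to the lowest particle id.  Unmatched
    detections start new trajectories.  Returns the concatenated detections
    with ``frame`` and ``particle`` columns.
    """
    if isinstance(detections, pd.DataFrame):
        per_frame = [
            g.reset_index(drop=True) for _, g in detections.groupby("frame", sort=True)
        ]
        frame_ids = sorted(detections["frame"].unique())
    else:
        per_frame = [d.reset_index(drop=True) for d in detections]
        frame_ids = list(range(len(per_frame)))

    out = []
    next_id = 0
    prev_xy = np.empty((0, 2))
    prev_ids: list[int] = []
    for f_idx, det in zip(frame_ids, per_frame):
        cur_xy = det[["y_px", "x_px"]].to_numpy(dtype=float) if len(det) else np.empty((0, 2))
        ids = np.full(len(det), -1, dtype=int)
        if len(prev_ids) and len(det):
            d2 = ((prev_xy[:, None, :] - cur_xy[None, :, :]) ** 2).sum(-1)
            cand = np.argwhere(d2 <= max_disp**2)
            # sort by displacement, then by previous particle id (tie-break)
            order = np.lexsort((np.array([prev_ids[i] for i in cand[:, 0]]), d2[cand[:, 0], cand[:, 1]]))
            used_prev, used_cur = set(), set()
            for k in order:
                i, j = cand[k]
                if i in used_prev or j in used_cur:
                    continue
                used_prev.add(i)
                used_cur.add(j)
                ids[j] = prev_ids[i]
        for j in range(len(det)):
            if ids[j] < 0:
                ids[j] = next_id
                next_id += 1
        rec = det.copy()
        rec["frame"] = f_idx
        rec["particle"] = ids
        out.append(rec)
        prev_xy = cur_xy
        prev_ids = list(ids)
    if not out:
        return pd.DataFrame(columns=["y_px", "x_px", "mass", "frame", "particle"])
    return pd.concat(out, ignore_index=True)


def _gauss2d_residuals(p, yy, xx, z):
    off, height, y0, x0, sa, sb, phi = p
    c, s = np.cos(phi), np.sin(phi)
    dy = yy - y0
    dx = xx - x0
    # rotate into the (a, b) frame; a along phi measured from +x toward +y
    ra = c * dx + s * dy
    rb = -s * dx + c * dy
    model = off + height * np.exp(-0.5 * ((ra / sa) ** 2 + (rb / sb) ** 2))
    return (model - z).ravel()


def _gauss2d_jac(p, yy, xx, z):
    off, height, y0, x0, sa, sb, phi = p
    c, s = np.cos(phi), np.sin(phi)
    dy = (yy - y0).ravel()
    dx = (xx - x0).ravel()
    ra = c * dx + s * dy
    rb = -s * dx + c * dy
    E = np.exp(-0.5 * ((ra / sa) ** 2 + (rb / sb) ** 2))
    hE = height * E
    J = np.empty((E.size, 7))
    J[:, 0] = 1.0
    J[:, 1] = E
    J[:, 2] = hE * (ra * s / sa**2 + rb * c / sb**2)
    J[:, 3] = hE * (ra * c / sa**2 - rb * s / sb**2)
    J[:, 4] = hE * ra**2 / sa**3
    J[:, 5] = hE * rb**2 / sb**3
    J[:, 6] = hE * ra * rb * (1.0 / sb**2 - 1.0 / sa**2)
    return J


def fit_bivariate_gaussian(
    image: np.ndarray,
    roi_center: tuple[float, float],
    roi_halfwidth: int,
) -> dict:
    """Elliptical Gaussian + constant offset fit inside a square ROI.

    ``roi_center`` is (y_px, x_px); the ROI must contain exactly one
    particle.  Returns a dict with axis stds a >= b (pixels), nematic angle
    phi in [0, pi) measured from the +x axis, epsilon = b^2/a^2, the refined
    centre, and ``ok``/``phi_defined`` flags (phi is undefined when a and b
    agree within their uncertainty — a circular image carries no angle).
    """
    img = np.asarray(image, dtype=float)
    H, W = img.shape
    cy, cx = roi_center
    y0 = int(round(cy)) - roi_halfwidth
    x0 = int(round(cx)) - roi_halfwidth
    y1, x1 = y0 + 2 * roi_halfwidth + 1, x0 + 2 * roi_halfwidth + 1
    if y0 < 0 or x0 < 0 or y1 > H or x1 > W:
        return {"ok": False}
    z = img[y0:y1, x0:x1]
    yy, xx = np.mgrid[y0:y1, x0:x1].astype(float)

    # moment-based initialisation on the offset-subtracted patch
    edge = np.concatenate([z[0], z[-1], z[:, 0], z[:, -1]])
    off0 = float(np.median(edge))
    w = np.clip(z - off0, 0, None)
    m = w.sum()
    if m <= 0:
        return {"ok": False}
    ybar = (yy * w).sum() / m
    xbar = (xx * w).sum() / m
    cyy = ((yy - ybar) ** 2 * w).sum() / m
    cxx = ((xx - xbar) ** 2 * w).sum() / m
    cxy = ((yy - ybar) * (xx - xbar) * w).sum() / m
    cov = np.array([[cxx, cxy], [cxy, cyy]])
    evals, evecs = np.linalg.eigh(cov)
    sa0 = float(np.sqrt(max(evals[1], 0.25)))
    sb0 = float(np.sqrt(max(evals[0], 0.25)))
    phi0 = float(np.arctan2(evecs[1, 1], evecs[0, 1]))
    h0 = float(z.max() - off0)

    # the centre is a sub-pixel refinement of the detection: keep it local so
    # the fit cannot migrate onto a neighbouring particle inside the ROI
    wiggle = min(3.0, roi_halfwidth / 2.0)
    ybar = float(np.clip(ybar, cy - wiggle + 0.1, cy + wiggle - 0.1))
    xbar = float(np.clip(xbar, cx - wiggle + 0.1, cx + wiggle - 0.1))
    p0 = [off0, h0, ybar, xbar, sa0, sb0, phi0]
    lo = [-np.inf, 0.0, cy - wiggle, cx - wiggle, 0.2, 0.2, -np.inf]
    hi = [np.inf, np.inf, cy + wiggle, cx + wiggle, roi_halfwidth * 2.0, roi_halfwidth * 2.0, np.inf]
    try:
        sol = least_squares(
            _gauss2d_residuals,
            p0,
            jac=_gauss2d_jac,
            args=(yy, xx, z),
            bounds=(lo, hi),
            xtol=1e-8,
            max_nfev=400,
        )
    except ValueError:
        return {"ok": False}
    off, height, yc, xc, sa, sb, phi = sol.x
    if sa < sb:
        sa, sb = sb, sa
        phi += np.pi / 2.0
    phi = phi % np.pi

    # rough parameter uncertainties from the Jacobian
    try:
        J = sol.jac
        dof = max(z.size - 7, 1)
        s2 = 2.0 * sol.cost / dof
        cov_p = s2 * np.linalg.inv(J.T @ J)
        sa_err = float(np.sqrt(max(cov_p[4, 4], 0)))
        sb_err = float(np.sqrt(max(cov_p[5, 5], 0)))
    except np.linalg.LinAlgError:
        sa_err = sb_err = np.inf
    # on a circular image the fitted a >= b split is a positively biased
    # order statistic, so demand both statistical and absolute ellipticity
    phi_defined = bool((sa - sb) > 3.0 * np.hypot(sa_err, sb_err) and (1 - sb / sa) > 0.01)

    return {
        "ok": bool(sol.success and height > 0),
        "y_px": float(yc),
        "x_px": float(xc),
        "a_px": float(sa),
        "b_px": float(sb),
        "phi": float(phi),
        "epsilon": float(sb**2 / sa**2),
        "height": float(height),
        "offset": float(off),
        "phi_defined": bool(phi_defined),
        "resid_rms": float(np.sqrt(2.0 * sol.cost / z.size)),
    }


def measure_trajectories(
    sequence: ImageSequence,
    linked: pd.DataFrame,
    roi_halfwidth: int = 12,
    min_length: int = 10,
) -> pd.DataFrame:
    """Bivariate-Gaussian shape measurement along linked trajectories.

    Returns the tidy observation table (one row per particle per frame):
    particle, frame, x_um, y_um, a_um, b_um, phi, epsilon, phi_defined.
    Trajectories shorter than ``min_length`` frames and failed fits are
    dropped.
    """
    px = sequence.pixel_size
    lengths = linked.groupby("particle")["frame"].size()
    keep = set(lengths[lengths >= min_length].index)
    rows = []
    for _, r in linked.iterrows():
        if r["particle"] not in keep:
            continue
        res = fit_bivariate_gaussian(
            sequence.frames[int(r["frame"])], (r["y_px"], r["x_px"]), roi_halfwidth
        )
        if not res.get("ok", False):
            continue
        rows.append(
            {
                "particle": int(r["particle"]),
                "frame": int(r["frame"]),
                # pixel index i spans [i, i+1): continuous coordinate i + 0.5
                "x_um": (res["x_px"] + 0.5) * px,
                "y_um": (res["y_px"] + 0.5) * px,
                "a_um": res["a_px"] * px,
                "b_um": res["b_px"] * px,
                "phi": res["phi"],
                "epsilon": res["epsilon"],
                "phi_defined": res["phi_defined"],
            }
        )
    return pd.DataFrame(rows)


def _pooled_msd(series: list[np.ndarray], max_lag: int) -> tuple[np.ndarray, np.ndarray]:
    """Time- and ensemble-averaged MSD of 1D or 2D series (list of (T,) or
    (T, d) arrays, NaN rows marking missing frames); returns (msd, n_pairs)
    for lags 1..max_lag.  Lags are frame lags: series must be laid out on a
    contiguous frame grid."""
    sums = np.zeros(max_lag)
    ns = np.zeros(max_lag, dtype=int)
    for s in series:
        s = np.atleast_2d(np.asarray(s, dtype=float).T).T  # (T, d)
        T = s.shape[0]
        fin = np.all(np.isfinite(s), axis=1)
        for lag in range(1, min(max_lag, T - 1) + 1):
            both = fin[lag:] & fin[:-lag]
            if not both.any():
                continue
            d = s[lag:][both] - s[:-lag][both]
            sums[lag - 1] += (d**2).sum()
            ns[lag - 1] += d.shape[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(ns > 0, sums / np.maximum(ns, 1), np.nan)
    return out, ns


def _on_frame_grid(g: pd.DataFrame, columns: list[str]) -> np.ndarray:
    """Trajectory columns laid out on the contiguous frame range, NaN where
    the particle was not observed (gap-aware lag bookkeeping)."""
    g = g.sort_values("frame")
    frames = g["frame"].to_numpy(dtype=int)
    span = frames[-1] - frames[0] + 1
    out = np.full((span, len(columns)), np.nan)
    out[frames - frames[0]] = g[columns].to_numpy(dtype=float)
    return out


def msd(
    traj: pd.DataFrame,
    dt: float,
    max_lag: int | None = None,
    fit_lags: int = 10,
) -> tuple[pd.DataFrame, dict]:
    """Ensemble MSD of the centre of mass and D_T from <dr^2> = 4 D_T tau.

    The linear fit runs through the origin over the first decade of lags,
    weighted by pair counts.  A log-log slope far from 1 flags the curve as
    nonlinear (e.g. ballistic drift).  Requires >= 10 trajectories spanning
    >= 10 lags.
    """
    groups = [
        _on_frame_grid(g, ["x_um", "y_um"])
        for _, g in traj.groupby("particle")
        if len(g) >= fit_lags + 1
    ]
    if len(groups) < 10:
        raise ValueError(
            f"insufficient statistics: {len(groups)} trajectories with > {fit_lags} points (need >= 10)"
        )
    if max_lag is None:
        max_lag = max(fit_lags * 10, 20)
    curve, ns = _pooled_msd(groups, max_lag)
    lags_s = dt * np.arange(1, max_lag + 1)
    sel = np.arange(min(fit_lags, max_lag))
    x, y, w = lags_s[sel], curve[sel], ns[sel].astype(float)
    good = np.isfinite(y) & (w > 0)
    x, y, w = x[good], y[good], w[good]
    slope = np.sum(w * x * y) / np.sum(w * x * x)
    resid = y - slope * x
    se = np.sqrt(np.sum(w * resid**2) / max(len(x) - 1, 1) / np.sum(w * x * x))
    # log-log exponent as a linearity diagnostic
    pos = y > 0
    expo = np.polyfit(np.log(x[pos]), np.log(y[pos]), 1)[0] if pos.sum() >= 3 else 1.0
    fit = {
        "D_T": slope / 4.0,
        "D_T_se": se / 4.0,
        "slope": slope,
        "exponent": float(expo),
        "nonlinear": bool(abs(expo - 1.0) > 0.3),
        "n_trajectories": len(groups),
    }
    return pd.DataFrame({"tau": lags_s, "msd": curve, "n": ns}), fit


def _nematic_unwrap(phi: np.ndarray) -> np.ndarray:
    """Cumulative angle from a nematic series: each step mapped to
    (-pi/2, pi/2], head–tail symmetric."""
    steps = np.diff(phi)
    steps = (steps + np.pi / 2) % np.pi - np.pi / 2
    return np.concatenate([[phi[0]], phi[0] + np.cumsum(steps)])


def _shape_quality(traj: pd.DataFrame) -> pd.Series:
    """Plausible single-particle shapes: short axis near its ensemble median
    and long axis not a gross outlier (guards against overlap artefacts)."""
    b_med = traj["b_um"].median()
    a_med = traj["a_um"].median()
    return traj["b_um"].between(0.5 * b_med, 2.0 * b_med) & (traj["a_um"] < 2.5 * a_med)


def _in_plane_mask(traj: pd.DataFrame, threshold: float) -> pd.Series:
    """Frames whose apparent shape implies sin^2(theta) >= threshold.

    sin^2 theta = (a^2/b^2 - 1)/(r - 1) with r the fully-in-plane axis ratio
    (sigma_par/sigma_perp)^2.  For an isotropically tumbling axis the 85th
    percentile of sin^2 theta is 0.98, so r is estimated robustly as the 85th
    percentile of a^2/b^2 over quality-filtered observations (a high quantile
    would be corrupted by overlap outliers).
    """
    good = _shape_quality(traj)
    ratio = (traj["a_um"] / traj["b_um"]) ** 2
    r_hat = np.quantile(ratio[good], 0.85) / 0.98
    if r_hat <= 1.0 + 1e-6:
        return pd.Series(False, index=traj.index)
    sin2 = (ratio - 1.0) / (r_hat - 1.0)
    return (sin2 >= threshold) & good & traj.get("phi_defined", True)


def angular_msd(
    traj: pd.DataFrame,
    dt: float,
    in_plane_threshold: float = 0.75,
    fit_span: float = 0.2,
    max_lag: int | None = None,
) -> tuple[pd.DataFrame, dict]:
    """In-plane angular MSD and D_R from <dphi^2(tau)> = 2 D_R tau.

    The nematic image angle is unwrapped with minimal steps inside runs of
    consecutive frames where the particle lies near the image plane
    (``in_plane_threshold`` on the estimated sin^2 of the polar angle); the
    short-lag linear fit (tau <= ``fit_span``/D_R, iterated once) carries a
    free intercept that absorbs static angle noise; D_R = slope/2.
    """
    mask = _in_plane_mask(traj, in_plane_threshold)
    runs: list[np.ndarray] = []
    med_steps = []
    for _, g in traj.groupby("particle"):
        g = g.sort_values("frame")
        ok = mask.loc[g.index].to_numpy()
        frames = g["frame"].to_numpy()
        phi = g["phi"].to_numpy()
        consecutive = np.concatenate([[False], (np.diff(frames) == 1)])
        start = 0
        n = len(g)
        i = 0
        while i < n:
            if not ok[i]:
                i += 1
                continue
            j = i
            while j + 1 < n and ok[j + 1] and consecutive[j + 1]:
                j += 1
            if j > i:
                seg = _nematic_unwrap(phi[i : j + 1])
                runs.append(seg)
                med_steps.append(np.abs(np.diff(seg)))
            i = j + 1
    if not runs:
        raise ValueError("no in-plane runs: cannot measure the image angle")
    all_steps = np.concatenate(med_steps)
    if np.median(all_steps) >= np.pi / 6:
        raise ValueError(
            "frame-to-frame rotation too large for nematic unwrapping; "
            "a higher frame rate is required"
        )
    if max_lag is None:
        max_lag = 50
    curve, ns = _pooled_msd(runs, max_lag)
    lags_s = dt * np.arange(1, max_lag + 1)

    def _fit(tau_max):
        sel = (lags_s <= tau_max) & np.isfinite(curve) & (ns > 0)
        if sel.sum() < 3:
            sel = np.isfinite(curve) & (ns > 0)
            sel[np.cumsum(sel) > 3] = False
        x, y, w = lags_s[sel], curve[sel], ns[sel].astype(float)
        X = np.stack([np.ones_like(x), x], axis=1)
        beta, cov, _ = _wls(X, y, w)
        return beta, cov, int(sel.sum())

    # first pass from the shortest lag, then restrict to tau <= fit_span/D_R
    d0 = max(curve[0] / (2 * dt), 1e-12)
    beta, cov, _ = _fit(fit_span / d0)
    d1 = max(beta[1] / 2.0, 1e-12)
    beta, cov, n_used = _fit(fit_span / d1)
    fit = {
        "D_R": beta[1] / 2.0,
        "D_R_se": float(np.sqrt(max(cov[1, 1], 0)) / 2.0),
        "intercept": float(beta[0]),
        "n_lags_used": n_used,
        "n_runs": len(runs),
    }
    return pd.DataFrame({"tau": lags_s, "angular_msd": curve, "n": ns}), fit


def _wls(X, y, w):
    W = np.sqrt(w)
    beta, *_ = np.linalg.lstsq(X * W[:, None], y * W, rcond=None)
    resid = y - X @ beta
    s2 = np.sum(w * resid**2) / max(len(y) - X.shape[1], 1)
    cov = s2 * np.linalg.inv((X * w[:, None]).T @ X)
    return beta, cov, resid


def aspect_ratio_autocorrelation(
    traj: pd.DataFrame,
    dt: float,
    min_length: int = 50,
    max_lag: int | None = None,
    fit_floor: float = 0.1,
) -> tuple[pd.DataFrame, dict]:
    """Normalized autocorrelation of the apparent aspect ratio and its rate.

    C_eps(tau) = <delta_eps(t) delta_eps(t+tau)> / <delta_eps^2> with
    delta_eps the deviation of eps = b^2/a^2 from its per-trajectory mean,
    pooled over reference times and trajectories.  An exponential
    C = exp(-gamma tau) is fitted over the range where C_eps > ``fit_floor``;
    for isotropic 3D rotational diffusion gamma = 6 D_R.  Raises when eps
    carries no variance (no out-of-plane motion, or circular particles).
    """
    good = _shape_quality(traj)
    masked = traj.copy()
    # overlap artefacts masked out; gaps stay NaN on the frame grid
    masked.loc[~good, "epsilon"] = np.nan
    series = []
    for _, g in masked.groupby("particle"):
        if len(g) < min_length:
            continue
        eps = _on_frame_grid(g, ["epsilon"])[:, 0]
        if np.isfinite(eps).sum() >= min_length:
            series.append(eps)
    if len(series) < 10:
        raise ValueError(
            f"insufficient statistics: {len(series)} trajectories of length >= {min_length}"
        )
    centered = [s - np.nanmean(s) for s in series]
    var = np.mean([np.nanmean(c**2) for c in centered])
    mean_eps2 = np.mean([np.nanmean(s**2) for s in series])
    if var < 1e-6 * mean_eps2:
        raise ValueError(
            "apparent aspect ratio carries no variance: the estimator is "
            "inapplicable (no out-of-plane motion or circular particles)"
        )
    if max_lag is None:
        max_lag = min(200, max(len(s) for s in series) - 1)
    num = np.zeros(max_lag)
    ns = np.zeros(max_lag, dtype=int)
    den_sum = 0.0
    den_n = 0
    for c in centered:
        fin = np.isfinite(c)
        den_sum += np.nansum(c**2)
        den_n += int(fin.sum())
        for lag in range(1, min(max_lag, c.size - 1) + 1):
            both = fin[lag:] & fin[:-lag]
            num[lag - 1] += np.nansum(np.where(both, c[lag:] * c[:-lag], 0.0))
            ns[lag - 1] += int(both.sum())
    den = den_sum / den_n
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.where(ns > 0, num / np.maximum(ns, 1) / den, np.nan)
    lags_s = dt * np.arange(1, max_lag + 1)

    # fit over the contiguous range where C stays above the floor
    above = np.nonzero(~((C > fit_floor) & np.isfinite(C)))[0]
    stop = above[0] if above.size else max_lag
    if stop < 3:
        raise ValueError("correlation decays below the fit floor within 3 lags")
    x, y = lags_s[:stop], C[:stop]
    coef = np.polyfit(x, np.log(np.clip(y, 1e-12, None)), 1)
    from scipy.optimize import curve_fit

    # the free offset absorbs the negative bias that per-trajectory mean
    # subtraction introduces on records of finitely many correlation times
    popt, pcov = curve_fit(
        lambda t, amp, g, c0: amp * np.exp(-g * t) + c0,
        x,
        y,
        p0=[float(np.exp(coef[1])), float(-coef[0]), 0.0],
        maxfev=10_000,
    )
    gamma = float(popt[1])
    gamma_se = float(np.sqrt(pcov[1, 1]))
    fit = {
        "gamma": gamma,
        "gamma_se": gamma_se,
        "amplitude": float(popt[0]),
        "D_R": gamma / 6.0,
        "D_R_se": gamma_se / 6.0,
        "n_lags_used": int(stop),
        "n_trajectories": len(series),
    }
    curve_df = pd.DataFrame({"tau": np.concatenate([[0.0], lags_s]),
                             "C_eps": np.concatenate([[1.0], C]),
                             "n": np.concatenate([[den_n], ns])})
    return curve_df, fit
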