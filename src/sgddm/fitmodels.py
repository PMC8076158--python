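"""Intermediate-scattering-function models fitted to structure functions.

The structure function of a dilute Brownian suspension follows

    D(q, tau) = A(q) [1 - f(q, tau)] + B(q),

where B(q) is the camera-noise baseline and A(q) the signal amplitude.  For
standard DDM of diffusing particles the ISF is a single exponential,
f = exp(-Gamma(q) tau) with Gamma = D_T q^2.  For SG-DDM of anisotropic
particles the ISF carries two branches,

    f(q, tau) = alpha(q) f_RT + (1 - alpha(q)) f_T,
    f_T  = exp(-D_T q^2 tau),
    f_RT = exp(-6 D_R tau - D_T q^2 tau),

so a double-exponential fit yields a fast roto-translational rate
Gamma_1 = 6 D_R + D_T q^2 and a slow translational rate Gamma_2 = D_T q^2.
Rate-versus-q regressions then give the diffusion coefficients: D_T from the
quadratic law through the origin, D_R from one sixth of the intercept of the
affine-in-q^2 law.  Above the q where the two rates approach each other the
branches cannot be separated reliably; fits there are flagged unresolved and
excluded from the regressions.

`StructureFunctionFit` wraps the per-q fits as a model object whose
``fit()`` returns a results object carrying the per-q parameter table,
diffusion estimates with uncertainties, a text summary and plots.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .ddm import StructureFunctionTable

__all__ = [
    "SingleExpFit",
    "DoubleExpFit",
    "DiffusionEstimate",
    "fit_single_exponential",
    "fit_double_exponential",
    "extract_DT",
    "extract_DR",
    "isf_from_structure_function",
    "rates_consistent",
    "StructureFunctionFit",
    "StructureFunctionFitResults",
]

#: fitted fractional decay within the lag window required to trust a rate
_PLATEAU_GAMMA_TAU = 1.6
#: rate ratio below which two exponentials are declared unresolvable
_SEPARABILITY_RATIO = 2.0


@dataclass
class SingleExpFit:
    A: float
    B: float
    gamma: float
    A_err: float = np.nan
    B_err: float = np.nan
    gamma_err: float = np.nan
    converged: bool = False


@dataclass
class DoubleExpFit:
    A: float
    B: float
    alpha: float
    gamma1: float  # fast branch (roto-translational)
    gamma2: float  # slow branch (translational)
    A_err: float = np.nan
    B_err: float = np.nan
    alpha_err: float = np.nan
    gamma1_err: float = np.nan
    gamma2_err: float = np.nan
    converged: bool = False
    resolved: bool = False


@dataclass
class DiffusionEstimate:
    """Diffusion coefficients from a rate-versus-q regression."""

    D_T: float | None = None
    D_T_se: float | None = None
    D_R: float | None = None
    D_R_se: float | None = None
    q_max_used: float = np.nan
    n_points: int = 0
    source: str = ""
    non_physical: bool = False
    non_quadratic: bool = False
    covariance: np.ndarray | None = None

    def __str__(self) -> str:
        parts = [f"[{self.source}]"]
        if self.D_T is not None:
            parts.append(f"D_T = {self.D_T:.4g} ± {self.D_T_se:.2g} µm²/s")
        if self.D_R is not None:
            parts.append(f"D_R = {self.D_R:.4g} ± {self.D_R_se:.2g} 1/s")
        parts.append(f"(q ≤ {self.q_max_used:.3g} µm⁻¹, n = {self.n_points})")
        if self.non_physical:
            parts.append("NON-PHYSICAL")
        return " ".join(parts)


def _single_model(tau, A, B, g):
    return A * (1.0 - np.exp(-g * tau)) + B


def _double_model(tau, A, B, alpha, g1, g2):
    return A * (1.0 - (alpha * np.exp(-g1 * tau) + (1 - alpha) * np.exp(-g2 * tau))) + B


def _clean(d_values, lags, sigma):
    d = np.asarray(d_values, dtype=float)
    tau = np.asarray(lags, dtype=float)
    ok = np.isfinite(d) & np.isfinite(tau)
    if sigma is not None:
        sigma = np.asarray(sigma, dtype=float)[ok]
    return d[ok], tau[ok], sigma


def fit_single_exponential(
    d_values: np.ndarray,
    lags: np.ndarray,
    sigma: np.ndarray | None = None,
) -> SingleExpFit:
    """Least-squares fit of D(tau) = A (1 - exp(-Gamma tau)) + B.

    Initialisation: B from the smallest value, A from the plateau, Gamma from
    the lag where the rise reaches (1 - 1/e) of A.  The fit is flagged
    unconverged when no plateau lies within the lag range (the decay is not
    resolved), when the rise happens entirely below the first lag, or when
    the amplitude is indistinguishable from zero.
    """
    d, tau, sigma = _clean(d_values, lags, sigma)
    if d.size < 6:
        raise ValueError("need at least 6 lag points spanning the decay")
    b0 = float(d.min())
    a0 = max(float(d.max()) - b0, 1e-12 + 0.1 * abs(float(d.max())))
    target = b0 + (1.0 - 1.0 / np.e) * a0
    above = np.nonzero(d >= target)[0]
    g0 = 1.0 / tau[above[0]] if above.size else 1.0 / tau[-1]
    try:
        popt, pcov = curve_fit(
            _single_model,
            tau,
            d,
            p0=[a0, b0, g0],
            sigma=sigma,
            bounds=([0, 0, 1e-12], [np.inf, np.inf, np.inf]),
            maxfev=10_000,
        )
        perr = np.sqrt(np.diag(pcov))
        success = np.all(np.isfinite(popt))
    except RuntimeError:
        popt, perr, success = np.array([a0, b0, g0]), np.full(3, np.nan), False
    A, B, g = popt
    converged = bool(
        success
        and g * tau[-1] >= _PLATEAU_GAMMA_TAU  # plateau reached in window
        and g * tau[0] <= 3.0  # rise not entirely below first lag
        and (not np.isfinite(perr[0]) or perr[0] == 0 or A > 2 * perr[0])
        and A > 0
    )
    return SingleExpFit(A, B, g, perr[0], perr[1], perr[2], converged)


def fit_double_exponential(
    d_values: np.ndarray,
    lags: np.ndarray,
    sigma: np.ndarray | None = None,
) -> DoubleExpFit:
    """Least-squares fit of the two-branch model
    D(tau) = A (1 - [alpha e^(-G1 tau) + (1-alpha) e^(-G2 tau)]) + B
    with 0 <= alpha <= 1 and rates > 0; ordering Gamma1 >= Gamma2 enforced.

    Multi-start initialisation brackets the single-exponential rate to avoid
    the local-minimum degeneracy.  ``resolved`` requires a converged fit,
    rate ratio >= 2, non-overlapping 1-sigma intervals and an interior
    amplitude fraction; unresolved fits must be excluded from rate-vs-q
    regressions.
    """
    d, tau, sigma = _clean(d_values, lags, sigma)
    if d.size < 6:
        raise ValueError("need at least 6 lag points spanning the decay")
    single = fit_single_exponential(d, tau, sigma)
    gs = single.gamma if np.isfinite(single.gamma) and single.gamma > 0 else 1.0 / tau[-1]
    gs = max(gs, 0.05 / tau[-1])  # keep multi-start rates inside the bounds
    a0 = single.A if np.isfinite(single.A) and single.A > 0 else max(float(d.max() - d.min()), 1e-12)
    b0 = single.B if np.isfinite(single.B) and single.B >= 0 else float(d.min())
    b0 = max(b0, 0.0)
    starts = [
        (0.5, 4 * gs, gs / 4),
        (0.3, 10 * gs, gs),
        (0.7, 2 * gs, gs / 2),
    ]
    best, best_ssr, best_cov = None, np.inf, None
    for alpha0, g10, g20 in starts:
        try:
            popt, pcov = curve_fit(
                _double_model,
                tau,
                d,
                p0=[a0, b0, alpha0, g10, g20],
                sigma=sigma,
                bounds=([0, 0, 0, 1e-12, 1e-12], [np.inf, np.inf, 1, np.inf, np.inf]),
                maxfev=20_000,
            )
        except RuntimeError:
            continue
        ssr = float(np.sum((_double_model(tau, *popt) - d) ** 2))
        if ssr < best_ssr:
            best, best_ssr, best_cov = popt, ssr, pcov
    if best is None:
        return DoubleExpFit(a0, b0, 1.0, gs, gs, converged=False, resolved=False)
    A, B, alpha, g1, g2 = best
    perr = np.sqrt(np.diag(best_cov))
    A_e, B_e, al_e, g1_e, g2_e = perr
    if g1 < g2:  # enforce fast-branch ordering
        g1, g2, g1_e, g2_e = g2, g1, g2_e, g1_e
        alpha = 1.0 - alpha
    converged = bool(
        np.all(np.isfinite([A, B, alpha, g1, g2]))
        and g2 * tau[-1] >= _PLATEAU_GAMMA_TAU
        and g1 * tau[0] <= 10.0
        and A > 0
        and (not np.isfinite(A_e) or A_e == 0 or A > 2 * A_e)
    )
    separable = g2 > 0 and g1 / g2 >= _SEPARABILITY_RATIO
    intervals_apart = (
        np.isfinite(g1_e)
        and np.isfinite(g2_e)
        and (g1 - g1_e) > (g2 + g2_e)
    )
    interior = 0.05 <= alpha <= 0.95
    resolved = bool(converged and separable and intervals_apart and interior)
    return DoubleExpFit(A, B, alpha, g1, g2, A_e, B_e, al_e, g1_e, g2_e, converged, resolved)


def _wls_through_origin(x, y, w):
    sxx = np.sum(w * x * x)
    slope = np.sum(w * x * y) / sxx
    n = x.size
    resid = y - slope * x
    s2 = np.sum(w * resid**2) / max(n - 1, 1)
    return slope, np.sqrt(s2 / sxx), resid


def _wls_affine(x, y, w):
    X = np.stack([np.ones_like(x), x], axis=1)
    W = np.diag(w)
    xtwx = X.T @ W @ X
    beta = np.linalg.solve(xtwx, X.T @ (w * y))
    resid = y - X @ beta
    s2 = np.sum(w * resid**2) / max(x.size - 2, 1)
    cov = s2 * np.linalg.inv(xtwx)
    return beta, cov, resid


def _weights(err, n):
    if err is None:
        return np.ones(n)
    err = np.asarray(err, dtype=float)
    if np.all(np.isfinite(err)) and np.all(err > 0):
        return 1.0 / err**2
    return np.ones(n)


def extract_DT(
    q: np.ndarray,
    gamma: np.ndarray,
    gamma_err: np.ndarray | None = None,
    q_max: float | None = None,
    source: str = "DDM",
) -> DiffusionEstimate:
    """D_T from the quadratic law Gamma(q) = D_T q^2 (WLS through origin).

    A significant intercept when refitting with an offset marks the input as
    non-quadratic (``non_quadratic`` flag): a constant offset in Gamma, e.g.
    an unmodelled rotational contribution, would bias D_T.
    """
    q = np.asarray(q, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    keep = np.isfinite(q) & np.isfinite(gamma)
    if q_max is not None:
        keep &= q <= q_max
    if keep.sum() < 4:
        raise ValueError(f"need >= 4 resolved q points, got {int(keep.sum())}")
    x = q[keep] ** 2
    y = gamma[keep]
    w = _weights(None if gamma_err is None else np.asarray(gamma_err)[keep], x.size)
    slope, se, _ = _wls_through_origin(x, y, w)
    beta, cov, _ = _wls_affine(x, y, w)
    non_quadratic = bool(abs(beta[0]) > 3.0 * np.sqrt(max(cov[0, 0], 0.0)))
    return DiffusionEstimate(
        D_T=float(slope),
        D_T_se=float(se),
        q_max_used=float(q[keep].max()),
        n_points=int(keep.sum()),
        source=source,
        non_quadratic=non_quadratic,
    )


def extract_DR(
    q: np.ndarray,
    gamma1: np.ndarray,
    gamma1_err: np.ndarray | None = None,
    q_max: float | None = None,
    source: str = "SG-DDM",
    method: str = "theil-sen",
) -> DiffusionEstimate:
    """D_R (and cross-check D_T) from Gamma_1(q) = 6 D_R + D_T q^2.

    Affine-in-q^2 regression of the fast rate; D_R is intercept/6, the slope
    is a translational cross-check.  The default estimator is the Theil–Sen
    robust line (median of pairwise slopes): the per-bin rate uncertainties
    from unweighted fits on correlated residuals are unreliable, and the
    occasional degenerate double-exponential solution produces a confidently
    wrong rate that would dominate a weighted least-squares intercept.  The
    intercept uncertainty comes from a bin-resampling bootstrap.
    ``method="wls"`` gives the plain weighted-least-squares line.  A negative
    fitted intercept is flagged non-physical.
    """
    q = np.asarray(q, dtype=float)
    gamma1 = np.asarray(gamma1, dtype=float)
    keep = np.isfinite(q) & np.isfinite(gamma1)
    if q_max is not None:
        keep &= q <= q_max
    if keep.sum() < 4:
        raise ValueError(f"need >= 4 resolved q points, got {int(keep.sum())}")
    x = q[keep] ** 2
    y = gamma1[keep]
    if method == "wls":
        w = _weights(None if gamma1_err is None else np.asarray(gamma1_err)[keep], x.size)
        beta, cov, _ = _wls_affine(x, y, w)
        intercept, slope = beta
        int_se = float(np.sqrt(max(cov[0, 0], 0.0)))
        slope_se = float(np.sqrt(max(cov[1, 1], 0.0)))
    elif method == "theil-sen":
        from scipy.stats import theilslopes

        slope, intercept, *_ = theilslopes(y, x)
        rng = np.random.default_rng(0)
        boots = []
        for _ in range(199):
            idx = rng.integers(0, x.size, size=x.size)
            if np.unique(x[idx]).size < 2:
                continue
            s_b, i_b, *_ = theilslopes(y[idx], x[idx])
            boots.append((i_b, s_b))
        boots = np.asarray(boots)
        int_se = float(boots[:, 0].std(ddof=1))
        slope_se = float(boots[:, 1].std(ddof=1))
        cov = np.cov(boots.T)
    else:
        raise ValueError("method must be 'theil-sen' or 'wls'")
    return DiffusionEstimate(
        D_T=float(slope),
        D_T_se=slope_se,
        D_R=float(intercept / 6.0),
        D_R_se=int_se / 6.0,
        q_max_used=float(q[keep].max()),
        n_points=int(keep.sum()),
        source=source,
        non_physical=bool(intercept < 0),
        covariance=cov,
    )


def isf_from_structure_function(
    d_values: np.ndarray, A: float, B: float
) -> tuple[np.ndarray, np.ndarray]:
    """Invert D = A (1 - f) + B to f = 1 - (D - B)/A.

    Returns (f clipped to the report range [-0.2, 1.2], out-of-range mask).
    """
    if A <= 0:
        raise ValueError("amplitude A must be positive")
    f = 1.0 - (np.asarray(d_values, dtype=float) - B) / A
    out = (f < -0.2) | (f > 1.2)
    return np.clip(f, -0.2, 1.2), out


def rates_consistent(
    g_a: np.ndarray,
    e_a: np.ndarray,
    g_b: np.ndarray,
    e_b: np.ndarray,
    n_sigma: float = 2.0,
) -> np.ndarray:
    """Per-q agreement of two rate curves within joint confidence intervals:
    |Gamma_a - Gamma_b| <= n_sigma * sqrt(err_a^2 + err_b^2)."""
    g_a, e_a, g_b, e_b = map(np.asarray, (g_a, e_a, g_b, e_b))
    return np.abs(g_a - g_b) <= n_sigma * np.sqrt(e_a**2 + e_b**2)


class StructureFunctionFit:
    """ISF model over a structure-function table.

    Parameters
    ----------
    table : StructureFunctionTable
        D(q, tau) with counts, from `sgddm.ddm` or `sgddm.sgmap`.
    model : {"single", "double"}
        Single exponential (standard DDM of monodisperse diffusers) or the
        two-branch roto-translational model (SG-DDM of anisotropic
        particles).
    q_min, q_max : float, optional
        Restrict the q rows that are fitted.
    weighting : {"uniform", "counts"}
        Per-lag weights for the least squares; "counts" uses the relative
        error implied by the number of averaged Fourier modes.
    """

    def __init__(
        self,
        table: StructureFunctionTable,
        model: str = "double",
        q_min: float | None = None,
        q_max: float | None = None,
        weighting: str = "uniform",
    ):
        if model not in ("single", "double"):
            raise ValueError("model must be 'single' or 'double'")
        if weighting not in ("uniform", "counts"):
            raise ValueError("weighting must be 'uniform' or 'counts'")
        self.table = table
        self.model = model
        self.q_min = q_min
        self.q_max = q_max
        self.weighting = weighting

    def fit(self) -> "StructureFunctionFitResults":
        tab = self.table
        rows = []
        for i, q in enumerate(tab.q_values):
            if self.q_min is not None and q < self.q_min:
                continue
            if self.q_max is not None and q > self.q_max:
                continue
            d = tab.values[i]
            finite = np.isfinite(d)
            if finite.sum() < 6:
                continue
            sigma = None
            if self.weighting == "counts":
                with np.errstate(divide="ignore", invalid="ignore"):
                    sigma = np.where(
                        tab.counts[i] > 0, d / np.sqrt(np.maximum(tab.counts[i], 1)), np.inf
                    )
                sigma = np.where(np.isfinite(sigma) & (sigma > 0), sigma, np.nanmax(d))
            row = {"q": q}
            if self.model == "single":
                r = fit_single_exponential(d, tab.lags, sigma)
                row.update(
                    A=r.A, B=r.B, alpha=1.0, gamma1=r.gamma, gamma2=r.gamma,
                    A_err=r.A_err, B_err=r.B_err, alpha_err=np.nan,
                    gamma1_err=r.gamma_err, gamma2_err=r.gamma_err,
                    converged=r.converged, resolved=r.converged,
                )
            else:
                r = fit_double_exponential(d, tab.lags, sigma)
                row.update(
                    A=r.A, B=r.B, alpha=r.alpha, gamma1=r.gamma1, gamma2=r.gamma2,
                    A_err=r.A_err, B_err=r.B_err, alpha_err=r.alpha_err,
                    gamma1_err=r.gamma1_err, gamma2_err=r.gamma2_err,
                    converged=r.converged, resolved=r.resolved,
                )
            rows.append(row)
        params = pd.DataFrame(rows).set_index("q") if rows else pd.DataFrame()
        return StructureFunctionFitResults(self, params)


class StructureFunctionFitResults:
    """Per-q ISF fit parameters and the derived diffusion coefficients."""

    def __init__(self, model: StructureFunctionFit, params: pd.DataFrame):
        self.model = model
        self.table = model.table
        self.params = params

    # -- selections ------------------------------------------------------
    def _resolved(self) -> pd.DataFrame:
        if self.params.empty:
            return self.params
        return self.params[self.params["resolved"]]

    @property
    def q_max_resolved(self) -> float:
        """Edge of the contiguous low-q resolved regime.

        Scanning q upward, the usable range ends at the last resolved bin
        before the first run of three consecutive unresolved bins: beyond
        the branch-crossover resolution is lost for good, and isolated
        spuriously "resolved" bins at higher q must not re-open the range.
        """
        if self.params.empty:
            return np.nan
        run = 0
        last_q = np.nan
        for q, r in zip(self.params.index, self.params["resolved"].to_numpy()):
            if r:
                run = 0
                last_q = float(q)
            elif np.isfinite(last_q):
                run += 1
                if run >= 3:
                    break
        return last_q

    # -- diffusion estimates --------------------------------------------
    def translational_diffusion(self, q_max: float | None = None) -> DiffusionEstimate:
        """D_T from the slow (translational) branch: Gamma_2 = D_T q^2."""
        res = self._resolved()
        if q_max is None:
            q_max = self.q_max_resolved
        label = self.table.label
        return extract_DT(
            res.index.to_numpy(),
            res["gamma2"].to_numpy(),
            res["gamma2_err"].to_numpy(),
            q_max=q_max,
            source=label,
        )

    def rotational_diffusion(
        self, q_max: float | None = None, method: str = "joint"
    ) -> DiffusionEstimate:
        """D_R of the fast (roto-translational) branch.

        ``method="joint"`` (default) refits the structure functions of all
        q bins in the resolved low-q range jointly, sharing D_T and D_R
        across bins with per-bin amplitudes (A, B, alpha) profiled out by
        linear least squares; the rate law Gamma_1 = 6 D_R + D_T q^2,
        Gamma_2 = D_T q^2 is imposed in the fit rather than regressed
        afterwards.  Per-bin double-exponential fits are ill-conditioned at
        small roto-translational amplitude — two free rates, a free baseline
        and a free amplitude fraction trade off against each other — and the
        two-stage rate regression inherits that noise; the joint fit removes
        the degeneracy by construction.

        ``method="two-stage"`` gives the classic estimator instead: the
        affine-in-q^2 regression (`extract_DR`) of the per-bin fast rates.
        """
        if self.model.model != "double":
            raise ValueError("rotational rate requires the double-exponential model")
        if q_max is None:
            q_max = self.q_max_resolved
        if method == "two-stage":
            res = self._resolved()
            return extract_DR(
                res.index.to_numpy(),
                res["gamma1"].to_numpy(),
                res["gamma1_err"].to_numpy(),
                q_max=q_max,
                source=self.table.label,
            )
        if method != "joint":
            raise ValueError("method must be 'joint' or 'two-stage'")
        return self._joint_diffusion(q_max)

    def _joint_bins(self, q_max: float):
        tab = self.table
        rows = []
        for q in self.params.index:
            if not np.isfinite(q_max) or q > q_max:
                continue
            i = int(np.argmin(np.abs(tab.q_values - q)))
            d = tab.values[i]
            if np.isfinite(d).sum() >= 6:
                rows.append((float(q), d))
        return rows

    def _joint_diffusion(self, q_max: float) -> DiffusionEstimate:
        from scipy.optimize import minimize

        rows = self._joint_bins(q_max)
        if len(rows) < 4:
            raise ValueError(f"need >= 4 usable q bins below q_max={q_max}")
        tau = self.table.lags

        def ssr(theta):
            d_t, d_r = theta
            if d_t <= 0 or d_r <= 0:
                return 1e12
            total = 0.0
            for q, d in rows:
                g2 = d_t * q * q
                g1 = 6.0 * d_r + g2
                X = np.stack(
                    [np.ones_like(tau), -np.exp(-g1 * tau), -np.exp(-g2 * tau)], axis=1
                )
                fin = np.isfinite(d)
                coef, *_ = np.linalg.lstsq(X[fin], d[fin], rcond=None)
                scale = d[fin].max() - d[fin].min() + 1e-300
                r = (X[fin] @ coef - d[fin]) / scale
                total += float(r @ r)
            return total

        best = None
        for dr0 in (0.15, 0.3, 0.6):
            sol = minimize(
                ssr,
                [0.25, dr0],
                method="Nelder-Mead",
                options=dict(xatol=1e-4, fatol=1e-10),
            )
            if best is None or sol.fun < best.fun:
                best = sol
        d_t, d_r = best.x

        # curvature-based uncertainties from the profiled SSR surface
        n_resid = sum(np.isfinite(d).sum() for _, d in rows)
        s2 = best.fun / max(n_resid - (2 + 3 * len(rows)), 1)
        h = np.empty((2, 2))
        steps = (max(1e-3 * d_t, 1e-5), max(1e-3 * d_r, 1e-5))
        for a in range(2):
            for b in range(a, 2):
                th = np.array([d_t, d_r])
                ea = np.eye(2)[a] * steps[a]
                eb = np.eye(2)[b] * steps[b]
                h[a, b] = h[b, a] = (
                    ssr(th + ea + eb) - ssr(th + ea - eb) - ssr(th - ea + eb) + ssr(th - ea - eb)
                ) / (4 * steps[a] * steps[b])
        try:
            cov = 2.0 * s2 * np.linalg.inv(h)
            d_t_se = float(np.sqrt(max(cov[0, 0], 0.0)))
            d_r_se = float(np.sqrt(max(cov[1, 1], 0.0)))
        except np.linalg.LinAlgError:
            cov, d_t_se, d_r_se = None, np.nan, np.nan
        return DiffusionEstimate(
            D_T=float(d_t),
            D_T_se=d_t_se,
            D_R=float(d_r),
            D_R_se=d_r_se,
            q_max_used=float(max(q for q, _ in rows)),
            n_points=len(rows),
            source=self.table.label,
            covariance=cov,
        )

    # -- ISF reconstruction ---------------------------------------------
    def isf(self, q: float) -> pd.DataFrame:
        """Reconstructed ISF f(tau) at the q row closest to ``q``."""
        i = int(np.argmin(np.abs(self.table.q_values - q)))
        row = self.params.loc[self.params.index[np.argmin(np.abs(self.params.index - q))]]
        f, out = isf_from_structure_function(self.table.values[i], row["A"], row["B"])
        return pd.DataFrame(
            {"tau": self.table.lags, "f": f, "out_of_range": out}
        )

    # -- reporting -------------------------------------------------------
    def summary(self) -> str:
        lines = [
            f"ISF fit summary ({self.table.label}, model={self.model.model})",
            f"  q rows fitted: {len(self.params)}; resolved: {int(self.params['resolved'].sum()) if len(self.params) else 0}",
        ]
        if len(self._resolved()) >= 4:
            try:
                dt = self.translational_diffusion()
                lines.append(f"  {dt}")
            except ValueError:
                pass
            if self.model.model == "double":
                try:
                    dr = self.rotational_diffusion()
                    lines.append(f"  {dr}")
                except ValueError:
                    pass
        return "\n".join(lines)

    def plot_rates(self, ax=None):
        """Relaxation rates versus q on log-log axes (Gamma_1, Gamma_2)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        res = self._resolved()
        if self.model.model == "double":
            ax.loglog(res.index, res["gamma1"], "o", label=r"$\Gamma_1$ (fast)")
            ax.loglog(res.index, res["gamma2"], "s", label=r"$\Gamma_2$ (slow)")
        else:
            ax.loglog(res.index, res["gamma1"], "^", label=r"$\Gamma$")
        ax.set_xlabel(r"$q$ ($\mu m^{-1}$)")
        ax.set_ylabel(r"rate (s$^{-1}$)")
        ax.legend()
        return ax

    def plot_isf(self, q_values=None, ax=None):
        """Reconstructed ISFs versus lag time for a few q values."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if q_values is None:
            qs = self.params.index.to_numpy()
            q_values = qs[:: max(1, len(qs) // 6)]
        for q in q_values:
            curve = self.isf(q)
            ax.semilogx(curve["tau"], curve["f"], "o-", ms=3, label=f"q={q:.2f}")
        ax.set_xlabel(r"$\tau$ (s)")
        ax.set_ylabel(r"$f(q,\tau)$")
        ax.legend(fontsize="small")
        return ax
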