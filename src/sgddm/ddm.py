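"""Differential dynamic microscopy: image structure functions.

DDM characterises the dynamics of a time-lapse image sequence I(x, t) through
the image structure function

    D(q, tau) = < | FFT2[ I(x, t + tau) - I(x, t) ] |^2 >_t ,

averaged over reference times t and, exploiting the isotropy of Brownian
motion, azimuthally over wavevector directions, leaving a function of the
radial wavevector q = |q| and the lag time tau.  The wavevector convention is
angular: q = 2*pi times the spatial frequency, in µm^-1.

The production path precomputes the real FFT of every frame once and forms
difference spectra in Fourier space; ``difference_spectrum`` is the explicit
per-lag reference implementation used by the tests and for map inspection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.fft

__all__ = [
    "ImageSequence",
    "StructureFunctionTable",
    "default_lags",
    "difference_spectrum",
    "radial_average",
    "structure_function",
]


@dataclass
class ImageSequence:
    """A calibrated stack of 2D grayscale frames.

    Parameters
    ----------
    frames : ndarray, shape (T, H, W)
        Intensity frames in acquisition order (float).
    dt : float
        Frame interval in seconds.
    pixel_size : float
        Pixel size in µm per pixel.
    """

    frames: np.ndarray
    dt: float
    pixel_size: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) array")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if np.issubdtype(self.frames.dtype, np.integer):
            self.frames = self.frames.astype(np.float32)

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]


@dataclass
class StructureFunctionTable:
    """D(q, tau) on a radial q grid x lag grid, with per-cell counts.

    ``values[i, j]`` is the structure function at ``q_values[i]``,
    ``lags[j]``; ``counts`` holds the number of (reference time, Fourier
    mode) pairs averaged into each cell.  Empty q bins are NaN, never zero.
    """

    q_values: np.ndarray  # µm^-1, strictly increasing
    lags: np.ndarray  # seconds, strictly increasing
    values: np.ndarray  # (n_q, n_lags)
    counts: np.ndarray  # (n_q, n_lags)
    pixel_size: float = 0.0
    label: str = "DDM"

    def __post_init__(self) -> None:
        self.q_values = np.asarray(self.q_values, dtype=float)
        self.lags = np.asarray(self.lags, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.counts = np.asarray(self.counts)
        if np.any(np.diff(self.q_values) <= 0):
            raise ValueError("q grid must be strictly increasing")
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lag grid must be strictly increasing")
        if self.values.shape != (self.q_values.size, self.lags.size):
            raise ValueError("values must have shape (n_q, n_lags)")
        with np.errstate(invalid="ignore"):
            if np.any(self.values < -1e-9):
                raise ValueError("structure function values must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with columns q, tau, D, count."""
        qq, tt = np.meshgrid(self.q_values, self.lags, indexing="ij")
        return pd.DataFrame(
            {
                "q": qq.ravel(),
                "tau": tt.ravel(),
                "D": self.values.ravel(),
                "count": self.counts.ravel(),
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, **kwargs) -> "StructureFunctionTable":
        q = np.unique(df["q"].to_numpy())
        lags = np.unique(df["tau"].to_numpy())
        piv = df.pivot_table(index="q", columns="tau", values="D", dropna=False)
        cnt = df.pivot_table(index="q", columns="tau", values="count", dropna=False)
        return cls(
            q_values=q,
            lags=lags,
            values=piv.reindex(index=q, columns=lags).to_numpy(),
            counts=np.nan_to_num(cnt.reindex(index=q, columns=lags).to_numpy()),
            **kwargs,
        )


def default_lags(n_frames: int, per_decade: int = 25, max_fraction: float = 0.25) -> np.ndarray:
    """Log-spaced integer frame lags, ~`per_decade` per decade, capped at
    ``max_fraction * n_frames`` so every lag retains many reference times."""
    max_lag = max(1, int(n_frames * max_fraction))
    n_decades = np.log10(max_lag) if max_lag > 1 else 1.0
    n_pts = max(2, int(np.ceil(per_decade * n_decades)))
    lags = np.unique(np.round(np.logspace(0, np.log10(max_lag), n_pts)).astype(int))
    return lags[lags >= 1]


def _reference_times(n_frames: int, lag: int, max_pairs: int) -> np.ndarray:
    """Evenly strided subset of reference times t for a given frame lag."""
    n_avail = n_frames - lag
    if n_avail < 1:
        raise ValueError(f"lag {lag} >= sequence length {n_frames}")
    n_use = min(max_pairs, n_avail)
    return np.unique(np.linspace(0, n_avail - 1, n_use).astype(int))


def _window2d(shape: tuple[int, int], window: str | None) -> np.ndarray | None:
    if window in (None, "none"):
        return None
    if window in ("bh", "blackmanharris"):
        from scipy.signal.windows import blackmanharris

        return np.outer(blackmanharris(shape[0]), blackmanharris(shape[1]))
    raise ValueError(f"unknown window {window!r}")


def difference_spectrum(
    frames: np.ndarray,
    lag_frames: int,
    max_pairs: int = 300,
    rng=None,
    window: str | None = None,
) -> np.ndarray:
    """Time-averaged 2D power spectrum of frame differences at one lag.

    Returns the full-plane map < |FFT2(I(t+lag) - I(t))|^2 >_t in numpy FFT
    layout (DC at [0, 0]; it is retained in the map and excluded later by the
    radial average).  ``rng`` is accepted for signature compatibility; the
    reference times are an evenly strided, deterministic subset.
    """
    frames = np.asarray(frames)
    if frames.ndim != 3:
        raise ValueError("frames must be (T, H, W)")
    refs = _reference_times(frames.shape[0], int(lag_frames), max_pairs)
    win = _window2d(frames.shape[1:], window)
    acc = np.zeros(frames.shape[1:], dtype=np.float64)
    for t in refs:
        diff = frames[t + lag_frames].astype(np.float64) - frames[t].astype(np.float64)
        if win is not None:
            diff = diff * win
        fh = np.fft.fft2(diff)
        acc += fh.real**2 + fh.imag**2
    return acc / refs.size


def radial_average(
    map2d: np.ndarray,
    pixel_size: float,
    n_bins: int | None = None,
    weights: np.ndarray | None = None,
    qx: np.ndarray | None = None,
    qy: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Azimuthal average of a 2D Fourier map onto a radial q grid.

    Each mode (k_x, k_y) is assigned q = 2*pi*sqrt((k_x/(W*px))^2 +
    (k_y/(H*px))^2) and binned into annuli of width one fundamental mode
    dq = 2*pi/(min(H, W)*px) centred at integer multiples of dq.  The DC mode
    is excluded; empty bins are NaN with zero count.

    ``weights``/``qx``/``qy`` support half-plane (rfft) maps where interior
    columns stand for two conjugate modes; by default a full-plane map in
    numpy FFT layout is assumed.

    Returns (q_values, profile, counts); counts are full-plane mode
    multiplicities per bin.
    """
    map2d = np.asarray(map2d, dtype=float)
    if qx is None:
        qx = 2 * np.pi * np.fft.fftfreq(map2d.shape[1], d=pixel_size)
        qy = 2 * np.pi * np.fft.fftfreq(map2d.shape[0], d=pixel_size)
    qr = np.sqrt(qy[:, None] ** 2 + qx[None, :] ** 2)
    dq_x = np.min(np.abs(qx[qx != 0])) if np.any(qx != 0) else np.inf
    dq_y = np.min(np.abs(qy[qy != 0])) if np.any(qy != 0) else np.inf
    dq = max(dq_x, dq_y)  # larger fundamental mode sets the bin width

    idx = np.rint(qr / dq).astype(int)
    if weights is None:
        weights = np.ones_like(map2d)
    mask = qr > 0  # exclude DC
    n_max = idx[mask].max()
    if n_bins is not None:
        n_max = min(n_max, n_bins)
        mask = mask & (idx <= n_max)
    flat_idx = idx[mask]
    wsum = np.bincount(flat_idx, weights=weights[mask], minlength=n_max + 1)
    vsum = np.bincount(flat_idx, weights=(weights * map2d)[mask], minlength=n_max + 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        profile = np.where(wsum > 0, vsum / np.maximum(wsum, 1e-300), np.nan)
    q_values = dq * np.arange(n_max + 1)
    return q_values[1:], profile[1:], wsum[1:]


def _rfft_grids(shape: tuple[int, int], pixel_size: float):
    """q grids and full-plane multiplicity weights for an rfft2 half-plane."""
    H, W = shape
    qx = 2 * np.pi * np.fft.rfftfreq(W, d=pixel_size)
    qy = 2 * np.pi * np.fft.fftfreq(H, d=pixel_size)
    w = np.full(qx.size, 2.0)
    w[0] = 1.0
    if W % 2 == 0:
        w[-1] = 1.0  # Nyquist column is self-conjugate
    weights = np.broadcast_to(w[None, :], (H, qx.size)).copy()
    return qx, qy, weights


def _mean_power_halfplane(fft_stack: np.ndarray, lag: int, max_pairs: int) -> np.ndarray:
    refs = _reference_times(fft_stack.shape[0], lag, max_pairs)
    d = fft_stack[refs + lag] - fft_stack[refs]
    return np.mean(np.abs(d) ** 2, axis=0, dtype=np.float64)


def _structure_function_from_stack(
    frames: np.ndarray,
    transforms,
    dt: float,
    pixel_size: float,
    lags: np.ndarray,
    max_pairs: int,
    window: str | None,
    label: str,
    q_max: float | None = None,
) -> StructureFunctionTable:
    """Shared engine: sum of per-transform difference power spectra,
    radially averaged.

    ``transforms`` maps a (t, H, W) frame block to the per-frame maps whose
    spectra are analysed — one identity transform for DDM, the two
    squared-gradient transforms for SG-DDM; the sum over transforms is taken
    mode-by-mode before the azimuthal average.  Frames are processed in
    blocks and spectra truncated to the ``q_max`` band immediately, so no
    movie-sized temporary is ever resident beside the source stack.
    """
    shape = frames.shape[1:]
    n_frames = frames.shape[0]
    win = _window2d(shape, window)
    if win is not None:
        win = win.astype(np.float32)
    qx, qy, wts = _rfft_grids(shape, pixel_size)
    row_sel = col_sel = None
    if q_max is not None:
        # keep only modes inside the analysis band: bins above q_max are
        # noise-baseline-dominated and cost most of the memory
        col_sel = qx <= q_max
        row_sel = np.abs(qy) <= q_max
        qx, qy, wts = qx[col_sel], qy[row_sel], wts[np.ix_(row_sel, col_sel)]
    n_rows = int(row_sel.sum()) if row_sel is not None else shape[0]
    n_cols = int(col_sel.sum()) if col_sel is not None else shape[1] // 2 + 1

    ffts = []
    chunk = 512
    for transform in transforms:
        f = np.empty((n_frames, n_rows, n_cols), dtype=np.complex64)
        for t0 in range(0, n_frames, chunk):
            block = transform(frames[t0 : t0 + chunk].astype(np.float32, copy=False))
            if win is not None:
                block = block * win
            fc = scipy.fft.rfft2(block, axes=(-2, -1))
            if col_sel is not None:
                fc = fc[:, row_sel][:, :, col_sel]
            f[t0 : t0 + chunk] = fc
        ffts.append(f)
    lags = np.asarray(lags, dtype=int)
    if lags.max() >= n_frames:
        raise ValueError("largest lag must be below the number of frames")

    n_bins = None
    if q_max is not None:
        dq = max(np.min(qx[qx > 0]), np.min(np.abs(qy[qy != 0])))
        n_bins = int(q_max / dq)  # only complete annuli inside the band
    n_q = None
    values, counts = [], []
    for lag in lags:
        pm = sum(_mean_power_halfplane(f, int(lag), max_pairs) for f in ffts)
        q, prof, cnt = radial_average(
            pm, pixel_size, n_bins=n_bins, weights=wts, qx=qx, qy=qy
        )
        n_pairs = _reference_times(n_frames, int(lag), max_pairs).size
        values.append(prof)
        counts.append(cnt * n_pairs)
        n_q = q
    values = np.stack(values, axis=1)
    counts = np.stack(counts, axis=1)
    # tiny negative round-off from float32 accumulation
    values = np.where(values < 0, 0.0, values)
    return StructureFunctionTable(
        q_values=n_q,
        lags=lags * dt,
        values=values,
        counts=counts,
        pixel_size=pixel_size,
        label=label,
    )


def structure_function(
    sequence: ImageSequence,
    lags: np.ndarray | None = None,
    max_pairs: int = 300,
    window: str | None = None,
    q_max: float | None = None,
) -> StructureFunctionTable:
    """Image structure function D(q, tau) of an image sequence.

    Composes the per-lag difference power spectrum with the azimuthal
    average on the default log-spaced lag grid (or explicit integer frame
    ``lags``).  ``q_max`` (µm^-1) optionally truncates the analysis band,
    saving the memory and time spent on noise-dominated high-q modes.
    Deterministic given the sequence and parameters.
    """
    if lags is None:
        lags = default_lags(len(sequence))
    return _structure_function_from_stack(
        sequence.frames,
        [lambda block: block],
        sequence.dt,
        sequence.pixel_size,
        np.asarray(lags),
        max_pairs,
        window,
        label="DDM",
        q_max=q_max,
    )
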