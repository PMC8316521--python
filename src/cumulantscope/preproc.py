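"""Raw-stack preparation: frame exclusion, bleaching-lifetime fit, drift correction.

Drift is estimated between 2nd-order cumulant images of movie sub-sequences
(blocks): each block image is cross-correlated against block 0, the
correlation peak is refined with a per-axis 3-point quadratic fit, and
per-frame shifts are linearly interpolated between block centers (constant
extrapolation at the ends).
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

from .synth import BlinkMovie

__all__ = [
    "DriftTrack",
    "BleachFit",
    "exclude_frames",
    "fit_bleaching",
    "estimate_drift",
    "apply_drift",
]


@dataclass
class DriftTrack:
    """Per-block (dy, dx) shifts in pixels, plus interpolated per-frame shifts."""

    block_shifts: np.ndarray  # B x 2 (dy, dx), block 0 is (0, 0)
    block_len: int
    frame_shifts: np.ndarray  # T x 2
    meta: dict = field(default_factory=dict)

    @property
    def n_blocks(self) -> int:
        return self.block_shifts.shape[0]

    def to_frame(self) -> pd.DataFrame:
        centers = [b * self.block_len + (self.block_len - 1) / 2 for b in range(self.n_blocks)]
        return pd.DataFrame(
            {
                "block_index": np.arange(self.n_blocks),
                "frame_center": centers,
                "dx": self.block_shifts[:, 1],
                "dy": self.block_shifts[:, 0],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, n_frames: int | None = None) -> "DriftTrack":
        df = pd.read_csv(path)
        block_len = int(round((df["frame_center"].iloc[0] + 0.5) * 2)) if len(df) else 0
        shifts = np.column_stack([df["dy"].to_numpy(), df["dx"].to_numpy()])
        if n_frames is None:
            n_frames = int(df["frame_center"].iloc[-1] + block_len / 2)
        frames = _interp_frames(shifts, block_len, n_frames)
        return cls(block_shifts=shifts, block_len=block_len, frame_shifts=frames)


@dataclass
class BleachFit:
    """Single-exponential bleaching fit I(t) = A exp(-t/lifetime) + offset."""

    lifetime: float  # seconds; +inf flags a non-decaying trace
    amplitude: float
    offset: float
    residual_rms: float

    @property
    def is_finite(self) -> bool:
        return np.isfinite(self.lifetime)


def exclude_frames(movie: BlinkMovie, n_skip: int) -> BlinkMovie:
    """Drop the first ``n_skip`` frames; the exclusion is recorded in metadata."""
    if n_skip < 0:
        raise ValueError("n_skip must be >= 0")
    if n_skip >= movie.n_frames:
        raise ValueError(
            f"cannot skip {n_skip} of {movie.n_frames} frames (empty result)"
        )
    if n_skip == 0:
        return movie
    meta = dict(movie.meta)
    meta["frames_excluded"] = meta.get("frames_excluded", 0) + n_skip
    return BlinkMovie(
        data=movie.data[n_skip:],
        exposure=movie.exposure,
        optics=movie.optics,
        seed=movie.seed,
        meta=meta,
    )


def fit_bleaching(movie: BlinkMovie) -> BleachFit:
    """Least-squares single-exponential fit to the total frame intensity.

    The lifetime is returned in seconds using the movie's exposure metadata.
    A non-decreasing intensity trace is flagged with an infinite lifetime
    rather than raising.
    """
    T = movie.n_frames
    if T < 10:
        raise ValueError("need at least 10 frames to fit bleaching")
    trace = movie.data.reshape(T, -1).sum(axis=1).astype(float)
    t = np.arange(T) * movie.exposure

    slope = np.polyfit(t, trace, 1)[0]
    span = trace.max() - trace.min()
    if slope >= 0 or span == 0:
        return BleachFit(np.inf, 0.0, float(trace.mean()), float(trace.std()))

    def model(t, A, lam, c):
        return A * np.exp(-t / lam) + c

    A0 = trace[0] - trace[-1]
    lam0 = max(t[-1] / 2, movie.exposure)
    c0 = trace[-1]
    try:
        popt, _ = optimize.curve_fit(
            model, t, trace, p0=[A0, lam0, c0],
            bounds=([0, movie.exposure * 1e-3, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError:
        return BleachFit(np.inf, 0.0, float(trace.mean()), float(trace.std()))
    resid = trace - model(t, *popt)
    return BleachFit(float(popt[1]), float(popt[0]), float(popt[2]),
                     float(np.sqrt(np.mean(resid**2))))


def _quadratic_peak(c: np.ndarray, iy: int, ix: int) -> tuple[float, float]:
    """Sub-pixel refine an argmax of a 2D array by per-axis 3-point quadratic fit."""
    def refine(m1, m0, p1):
        denom = m1 - 2 * m0 + p1
        if denom >= 0:  # not a concave peak
            return 0.0
        return float(np.clip(0.5 * (m1 - p1) / denom, -0.5, 0.5))

    ny, nx = c.shape
    dy = refine(c[(iy - 1) % ny, ix], c[iy, ix], c[(iy + 1) % ny, ix])
    dx = refine(c[iy, (ix - 1) % nx], c[iy, ix], c[iy, (ix + 1) % nx])
    return dy, dx


def _block_image(movie: BlinkMovie, start: int, stop: int) -> np.ndarray:
    from .sofi import sofi2d  # deferred: avoid import cycle at module load

    sub = BlinkMovie(
        data=movie.data[start:stop], exposure=movie.exposure,
        optics=movie.optics, seed=movie.seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        img = sofi2d(sub, order=2)
    return img.filled(0.0)


def _xcorr_shift(ref: np.ndarray, img: np.ndarray, peak_threshold: float = 0.2):
    """Shift (dy, dx) in pixels such that img ~ ref translated by (dy, dx)."""
    a = ref - ref.mean()
    b = img - img.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return None
    c = np.real(np.fft.ifft2(np.conj(np.fft.fft2(a)) * np.fft.fft2(b))) / (na * nb)
    iy, ix = np.unravel_index(np.argmax(c), c.shape)
    if c[iy, ix] < peak_threshold:
        return None
    sy, sx = _quadratic_peak(c, iy, ix)
    dy = iy + sy
    dx = ix + sx
    if dy > c.shape[0] / 2:
        dy -= c.shape[0]
    if dx > c.shape[1] / 2:
        dx -= c.shape[1]
    return dy, dx


def _interp_frames(block_shifts: np.ndarray, block_len: int, n_frames: int) -> np.ndarray:
    centers = np.array(
        [b * block_len + (block_len - 1) / 2 for b in range(len(block_shifts))]
    )
    frames = np.arange(n_frames, dtype=float)
    out = np.empty((n_frames, 2))
    for ax in range(2):
        out[:, ax] = np.interp(frames, centers, block_shifts[:, ax])
        # linear extrapolation beyond the first/last block center: steady
        # drift continues ramping there, and constant extrapolation leaves an
        # asymmetric residual smear in the end blocks that breaks closure
        if len(centers) >= 2:
            s0 = (block_shifts[1, ax] - block_shifts[0, ax]) / (centers[1] - centers[0])
            s1 = (block_shifts[-1, ax] - block_shifts[-2, ax]) / (centers[-1] - centers[-2])
            lo = frames < centers[0]
            hi = frames > centers[-1]
            out[lo, ax] = block_shifts[0, ax] + s0 * (frames[lo] - centers[0])
            out[hi, ax] = block_shifts[-1, ax] + s1 * (frames[hi] - centers[-1])
    return out


def estimate_drift(movie: BlinkMovie, block_len: int = 500) -> DriftTrack:
    """Estimate lateral drift between 2nd-order cumulant images of frame blocks.

    The last partial block is dropped. Featureless blocks (correlation peak
    below threshold) get a warning and a zero shift.
    """
    if movie.data.ndim != 3:
        raise ValueError("drift estimation expects a single-plane movie")
    T = movie.n_frames
    if T < 2 * block_len:
        raise ValueError(f"need at least 2 blocks of {block_len} frames, have T={T}")
    n_blocks = T // block_len
    ref = _block_image(movie, 0, block_len)
    shifts = np.zeros((n_blocks, 2))
    for b in range(1, n_blocks):
        img = _block_image(movie, b * block_len, (b + 1) * block_len)
        res = _xcorr_shift(ref, img)
        if res is None:
            warnings.warn(f"block {b}: featureless (weak correlation peak); zero shift",
                          stacklevel=2)
            continue
        # block images live on the 2x-refined cumulant grid -> input pixels
        shifts[b] = np.asarray(res) / 2.0
    return DriftTrack(
        block_shifts=shifts,
        block_len=block_len,
        frame_shifts=_interp_frames(shifts, block_len, T),
        meta={"n_blocks": n_blocks},
    )


def apply_drift(movie: BlinkMovie, track: DriftTrack) -> BlinkMovie:
    """Translate each frame by -shift(t) (bilinear); out-of-field pixels zero-filled."""
    if track.frame_shifts.shape[0] < movie.n_frames:
        raise ValueError("drift track does not cover all frames")
    if np.all(track.frame_shifts[: movie.n_frames] == 0):
        return movie
    out = np.empty_like(movie.data, dtype=np.float32)
    for t in range(movie.n_frames):
        dy, dx = track.frame_shifts[t]
        out[t] = ndimage.shift(
            movie.data[t].astype(float), (-dy, -dx), order=1, mode="constant", cval=0.0
        )
    meta = dict(movie.meta)
    meta["drift_corrected"] = True
    return BlinkMovie(
        data=np.clip(out, 0, None), exposure=movie.exposure,
        optics=movie.optics, seed=movie.seed, meta=meta,
    )
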