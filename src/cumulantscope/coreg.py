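"""Control-point affine registration and cross-section correlation statistics.

Feature pairs are user-supplied (hand-selected); the affine map is the least
squares fit, images are resampled bilinearly onto the target grid, and
topography-fluorescence correspondence is quantified by the Pearson
coefficient of min-max normalized line profiles, with groups compared by a
Welch two-sided t-test on Fisher-z transformed r values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

__all__ = [
    "AffineMap",
    "CrossSection",
    "fit_affine",
    "warp_image",
    "extract_profiles",
    "pearson",
    "compare_groups",
    "read_control_points",
]


@dataclass
class AffineMap:
    """2D affine transform target = A @ source + t (units follow the inputs)."""

    A: np.ndarray  # 2 x 2
    t: np.ndarray  # 2
    residual_rms: float = 0.0
    n_points: int = 0

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float).reshape(2, 2)
        self.t = np.asarray(self.t, dtype=float).reshape(2)
        if abs(np.linalg.det(self.A)) < 1e-12:
            raise ValueError("affine linear part is singular")

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.A.T + self.t

    def inverse(self) -> "AffineMap":
        Ainv = np.linalg.inv(self.A)
        return AffineMap(A=Ainv, t=-Ainv @ self.t,
                         residual_rms=self.residual_rms, n_points=self.n_points)

    @classmethod
    def identity(cls) -> "AffineMap":
        return cls(A=np.eye(2), t=np.zeros(2))


@dataclass
class CrossSection:
    """Paired height/intensity profiles sampled along one polyline."""

    endpoints: np.ndarray  # 2 x 2, [(x0, y0), (x1, y1)]
    height: np.ndarray
    intensity: np.ndarray
    normalized: bool = False
    meta: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return len(self.height)


def fit_affine(pairs) -> AffineMap:
    """Least-squares affine from >= 3 non-collinear (source, target) point pairs.

    ``pairs`` is an iterable of ((x_src, y_src), (x_dst, y_dst)) or an
    (N, 4) array. With exactly 3 non-collinear pairs the fit interpolates.
    """
    arr = np.asarray([np.concatenate([np.ravel(s), np.ravel(d)]) for s, d in pairs]
                     if not isinstance(pairs, np.ndarray) else pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 4 or arr.shape[0] < 3:
        raise ValueError("need at least 3 (source, target) point pairs")
    src, dst = arr[:, :2], arr[:, 2:]
    centered = src - src.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, np.abs(src).max())) < 2:
        raise ValueError("control points are collinear: affine geometry is degenerate")
    design = np.column_stack([src, np.ones(len(src))])
    coef, *_ = np.linalg.lstsq(design, dst, rcond=None)  # 3 x 2
    A = coef[:2].T
    t = coef[2]
    resid = design @ coef - dst
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return AffineMap(A=A, t=t, residual_rms=rms, n_points=len(src))


def warp_image(
    image: np.ndarray, amap: AffineMap, target_shape: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Resample ``image`` onto the target grid under source->target ``amap``.

    Bilinear interpolation; returns (warped, valid_mask) with out-of-source
    pixels masked. Coordinates are (x, y) pixel indices.
    """
    inv = amap.inverse()
    ny, nx = target_shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    pts = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
    src = inv.apply(pts)  # (N, 2) x, y in source pixels
    sx = src[:, 0].reshape(ny, nx)
    sy = src[:, 1].reshape(ny, nx)
    warped = ndimage.map_coordinates(
        np.asarray(image, dtype=float), [sy, sx], order=1, mode="constant", cval=np.nan
    )
    h, w = image.shape
    valid = (sx >= 0) & (sx <= w - 1) & (sy >= 0) & (sy <= h - 1) & np.isfinite(warped)
    return warped, valid


def _minmax(profile: np.ndarray) -> tuple[np.ndarray, bool]:
    lo, hi = np.min(profile), np.max(profile)
    if hi == lo:
        return np.zeros_like(profile), True
    return (profile - lo) / (hi - lo), False


def extract_profiles(
    height: np.ndarray,
    intensity: np.ndarray,
    section: np.ndarray,
    width: int = 1,
    n_samples: int | None = None,
    normalize: bool = True,
) -> CrossSection:
    """Sample both channels along a line, averaged across ``width`` pixels.

    ``section`` is [(x0, y0), (x1, y1)] in pixel coordinates of the shared
    (post-registration) grid. Profiles are min-max normalized by default;
    a constant profile sets the ``zero_range`` flag instead of dividing by 0.
    Raises if any sample falls outside either image or on an invalid (NaN)
    pixel, listing the offending sample indices.
    """
    sec = np.asarray(section, dtype=float).reshape(2, 2)
    (x0, y0), (x1, y1) = sec
    length = float(np.hypot(x1 - x0, y1 - y0))
    if n_samples is None:
        n_samples = max(int(np.ceil(length)) + 1, 2)
    ts = np.linspace(0.0, 1.0, n_samples)
    xs = x0 + ts * (x1 - x0)
    ys = y0 + ts * (y1 - y0)
    # unit normal for width averaging
    if length == 0:
        raise ValueError("section endpoints coincide")
    nxv, nyv = -(y1 - y0) / length, (x1 - x0) / length
    offsets = np.arange(width) - (width - 1) / 2

    def sample(img):
        img = np.asarray(img, dtype=float)
        acc = np.zeros(n_samples)
        for o in offsets:
            vals = ndimage.map_coordinates(
                img, [ys + o * nyv, xs + o * nxv], order=1, mode="constant", cval=np.nan
            )
            acc += vals
        return acc / len(offsets)

    hprof = sample(height)
    iprof = sample(intensity)
    bad = np.flatnonzero(~np.isfinite(hprof) | ~np.isfinite(iprof))
    if bad.size:
        raise ValueError(
            f"section leaves the valid image region at samples {bad.tolist()[:10]}"
        )
    meta: dict = {"width": width}
    if normalize:
        hprof, hflat = _minmax(hprof)
        iprof, iflat = _minmax(iprof)
        meta["zero_range"] = {"height": hflat, "intensity": iflat}
    return CrossSection(endpoints=sec, height=hprof, intensity=iprof,
                        normalized=normalize, meta=meta)


def pearson(section: CrossSection) -> float:
    """Pearson product-moment r of the section's two profiles; nan if degenerate."""
    if section.n_samples < 3:
        raise ValueError("need at least 3 samples")
    h, i = section.height, section.intensity
    if np.ptp(h) == 0 or np.ptp(i) == 0:
        return np.nan
    return float(stats.pearsonr(h, i).statistic)


def compare_groups(
    r_values_a, r_values_b, use_fisher_z: bool = True
) -> tuple[float, float, float]:
    """Welch two-sided t-test between two groups of correlation coefficients.

    By default the r values are Fisher-z transformed first (r is bounded);
    pass ``use_fisher_z=False`` for the raw-r comparison. Returns
    (t, dof, p); degenerate zero-variance-in-both-groups input yields
    (0, dof, 1) when the means agree, (inf-like t, dof, 0) otherwise.
    """
    a = np.asarray(r_values_a, dtype=float)
    b = np.asarray(r_values_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs at least 3 values")
    if use_fisher_z:
        a = np.arctanh(np.clip(a, -1 + 1e-12, 1 - 1e-12))
        b = np.arctanh(np.clip(b, -1 + 1e-12, 1 - 1e-12))
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        dof = float(len(a) + len(b) - 2)
        if a.mean() == b.mean():
            return 0.0, dof, 1.0
        return float(np.sign(a.mean() - b.mean()) * np.inf), dof, 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def read_control_points(path) -> np.ndarray:
    """Read a control-point CSV (x_src, y_src, x_dst, y_dst[, label]) to an (N, 4) array."""
    df = pd.read_csv(path)
    cols = ["x_src", "y_src", "x_dst", "y_dst"]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"control-point CSV missing columns: {missing}")
    return df[cols].to_numpy(dtype=float)
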