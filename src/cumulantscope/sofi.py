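"""2nd-4th order auto-/cross-cumulant imaging on n-fold refined virtual grids.

The order-n image places each cumulant value at the centroid of its
contributing real pixels, refining the sampling grid n-fold laterally (and
axially for multiplane input). The canonical pixel combination for each
virtual-grid phase is the most compact multiset of real pixels whose centroid
lands on that phase (sum of squared distances to the centroid minimized, ties
broken by lexicographic order of the sorted offset tuple); this makes outputs
reproducible bit-for-bit.

Cross-cumulants of a Gaussian PSF are attenuated relative to the
auto-cumulant at the same centroid by the distance factor
``D = prod_{i<j} exp(-|r_i - r_j|^2 / (2 n sigma^2))``; dividing it out
("flattening") removes the resulting grid-phase checkerboard.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .synth import BlinkMovie

__all__ = [
    "CumulantImage",
    "cumulant_timeseries",
    "sofi2d",
    "sofi3d",
    "flatten",
    "lateral_combinations",
    "distance_factor",
    "n_output_planes",
]

_ORDERS = (2, 3, 4)


@dataclass
class CumulantImage:
    """An order-n cumulant image/volume on the n-fold refined grid.

    ``values`` is (nY, nX) for 2D input or (n(P-1)+1, nY, nX) for multiplane
    input; virtual pixels whose pixel combinations fall outside the detector
    are masked invalid (``mask`` False) and hold NaN.
    """

    order: int
    values: np.ndarray
    mask: np.ndarray
    grid_spacing: float  # nm, = input pixel size / order
    plane_spacing_out: float | None = None  # nm, = input plane spacing / order
    n_frames_used: int = 0
    flattened: bool = False
    meta: dict = field(default_factory=dict)

    @property
    def is_volume(self) -> bool:
        return self.values.ndim == 3

    def filled(self, fill: float = 0.0) -> np.ndarray:
        out = self.values.copy()
        out[~self.mask] = fill
        return out

    def sidecar(self) -> dict:
        return {
            "kind": "CumulantImage",
            "order": self.order,
            "grid_spacing": self.grid_spacing,
            "plane_spacing_out": self.plane_spacing_out,
            "n_frames_used": self.n_frames_used,
            "flattened": self.flattened,
            "meta": self.meta,
        }


def cumulant_timeseries(traces: np.ndarray, order: int) -> float:
    """Joint cumulant (order 2-4, zero time lag) of ``order`` pixel time series.

    ``traces`` is T x k with k == order. Fluctuations are taken about the
    per-series time mean and all expectations are time averages:
    kappa2 = <d1 d2>, kappa3 = <d1 d2 d3>,
    kappa4 = <d1 d2 d3 d4> - <d1 d2><d3 d4> - <d1 d3><d2 d4> - <d1 d4><d2 d3>.
    """
    traces = np.asarray(traces, dtype=float)
    if traces.ndim != 2:
        raise ValueError("traces must be a T x k matrix")
    T, k = traces.shape
    if k != order:
        raise ValueError(f"need k == order series, got k={k}, order={order}")
    if T < 10:
        raise ValueError("need at least 10 time points")
    d = traces - traces.mean(axis=0)
    return float(_joint_cumulant([d[:, i] for i in range(order)], order))


def _joint_cumulant(deltas: list[np.ndarray], order: int):
    """Order-n joint cumulant of zero-mean series (arrays broadcast over trailing dims)."""
    if order == 2:
        return (deltas[0] * deltas[1]).mean(axis=0)
    if order == 3:
        return (deltas[0] * deltas[1] * deltas[2]).mean(axis=0)
    if order == 4:
        d1, d2, d3, d4 = deltas
        m = lambda a, b: (a * b).mean(axis=0)
        return (
            (d1 * d2 * d3 * d4).mean(axis=0)
            - m(d1, d2) * m(d3, d4)
            - m(d1, d3) * m(d2, d4)
            - m(d1, d4) * m(d2, d3)
        )
    raise ValueError(f"order must be one of {_ORDERS}, got {order}")


@lru_cache(maxsize=None)
def lateral_combinations(order: int) -> dict[tuple[int, int], tuple[tuple[int, int], ...]]:
    """Canonical pixel combination (as (dy, dx) offsets) per lateral grid phase.

    For each phase (a, b) in {0..n-1}^2 the returned offsets are a multiset of
    n real-pixel offsets with mean exactly (a/n, b/n), chosen to minimize the
    sum of squared distances to the centroid; ties broken lexicographically on
    the sorted tuple. Phase (0, 0) is always the auto-cumulant (same pixel n
    times).
    """
    if order not in _ORDERS:
        raise ValueError(f"order must be one of {_ORDERS}, got {order}")
    n = order
    neighborhood = list(itertools.product(range(-1, 3), repeat=2))
    combos: dict[tuple[int, int], tuple[tuple[int, int], ...]] = {}
    for a, b in itertools.product(range(n), repeat=2):
        best = None
        for multiset in itertools.combinations_with_replacement(neighborhood, n):
            sy = sum(p[0] for p in multiset)
            sx = sum(p[1] for p in multiset)
            if sy != a or sx != b:
                continue
            cy, cx = a / n, b / n
            score = sum((p[0] - cy) ** 2 + (p[1] - cx) ** 2 for p in multiset)
            key = (round(score, 12), tuple(sorted(multiset)))
            if best is None or key < best:
                best = key
        assert best is not None
        combos[(a, b)] = best[1]
    return combos


def distance_factor(
    offsets, pixel_size: float, order: int, sigma: float
) -> float:
    """D = prod_{i<j} exp(-|r_i - r_j|^2 / (2 n sigma^2)), lateral distances in nm."""
    d2 = 0.0
    for (y1, x1), (y2, x2) in itertools.combinations(offsets, 2):
        d2 += ((y1 - y2) ** 2 + (x1 - x2) ** 2) * pixel_size**2
    return float(np.exp(-d2 / (2 * order * sigma**2)))


def _check_order(order: int) -> None:
    if order not in _ORDERS:
        raise ValueError(f"order must be one of {_ORDERS}, got {order}")


def sofi2d(
    movie: BlinkMovie, order: int, flatten: bool = False, sigma: float | None = None
) -> CumulantImage:
    """Order-n cumulant image of a single-plane movie on the n-fold refined grid."""
    _check_order(order)
    if movie.data.ndim != 3:
        raise ValueError("sofi2d expects a single-plane (T x Y x X) movie")
    if movie.n_frames < 100:
        warnings.warn(
            f"only {movie.n_frames} frames; cumulant estimates will be noisy",
            stacklevel=2,
        )
    if flatten and sigma is None:
        if movie.optics is not None:
            sigma = movie.optics.sigma0
        else:
            raise ValueError("flattening requires sigma (PSF width in nm)")

    n = order
    T, Y, X = movie.data.shape
    delta = movie.data.astype(np.float64)
    delta -= delta.mean(axis=0)
    out = np.full((n * Y, n * X), np.nan)
    mask = np.zeros((n * Y, n * X), dtype=bool)
    px = movie.optics.pixel_size if movie.optics is not None else 1.0

    for (a, b), offsets in lateral_combinations(n).items():
        dys = [o[0] for o in offsets]
        dxs = [o[1] for o in offsets]
        lo_y, hi_y = max(0, -min(dys)), Y - max(0, max(dys))
        lo_x, hi_x = max(0, -min(dxs)), X - max(0, max(dxs))
        if hi_y <= lo_y or hi_x <= lo_x:
            continue
        members = [
            delta[:, lo_y + dy : hi_y + dy, lo_x + dx : hi_x + dx]
            for dy, dx in offsets
        ]
        kappa = _joint_cumulant(members, n)
        if flatten:
            kappa = kappa / distance_factor(offsets, px, n, sigma)
        out[n * lo_y + a : n * hi_y + a : n, n * lo_x + b : n * hi_x + b : n] = kappa
        mask[n * lo_y + a : n * hi_y + a : n, n * lo_x + b : n * hi_x + b : n] = True

    grid = px / n
    return CumulantImage(
        order=n,
        values=out,
        mask=mask,
        grid_spacing=grid,
        n_frames_used=T,
        flattened=flatten,
        meta={"pixel_size_in": px, "sigma_flatten": sigma if flatten else None},
    )


def n_output_planes(order: int, n_physical: int) -> int:
    """Virtual plane count n(P-1)+1 produced by order-n axial cross-cumulants."""
    return order * (n_physical - 1) + 1


def sofi3d(
    movie: BlinkMovie, order: int, flatten: bool = False, sigma: float | None = None
) -> CumulantImage:
    """Order-n cumulant volume of a multiplane movie.

    Output plane j in {0..n(P-1)} sits at axial position j * plane_spacing/n;
    its combinations draw from at most the two adjacent physical planes
    (n-k copies of plane p and k of plane p+1 for j = n*p + k). Lateral
    treatment is identical to :func:`sofi2d`; the flattening distance factor
    uses lateral separations only.
    """
    _check_order(order)
    if movie.data.ndim != 4:
        raise ValueError("sofi3d expects a multiplane (T x P x Y x X) movie")
    P = movie.data.shape[1]
    if P < 2:
        raise ValueError("multiplane cumulants need P >= 2 planes; use sofi2d")
    if flatten and sigma is None:
        if movie.optics is not None:
            sigma = movie.optics.sigma0
        else:
            raise ValueError("flattening requires sigma (PSF width in nm)")

    n = order
    T, _, Y, X = movie.data.shape
    delta = movie.data.astype(np.float64)
    delta -= delta.mean(axis=0)
    n_out = n_output_planes(n, P)
    out = np.full((n_out, n * Y, n * X), np.nan)
    mask = np.zeros((n_out, n * Y, n * X), dtype=bool)
    px = movie.optics.pixel_size if movie.optics is not None else 1.0
    dz = movie.optics.plane_spacing if movie.optics is not None else 350.0

    lat = lateral_combinations(n)
    for j in range(n_out):
        p, k = divmod(j, n)
        if k == 0:
            planes = [p] * n
        else:
            planes = [p] * (n - k) + [p + 1] * k
        for (a, b), offsets in lat.items():
            dys = [o[0] for o in offsets]
            dxs = [o[1] for o in offsets]
            lo_y, hi_y = max(0, -min(dys)), Y - max(0, max(dys))
            lo_x, hi_x = max(0, -min(dxs)), X - max(0, max(dxs))
            if hi_y <= lo_y or hi_x <= lo_x:
                continue
            members = [
                delta[:, pl, lo_y + dy : hi_y + dy, lo_x + dx : hi_x + dx]
                for pl, (dy, dx) in zip(planes, offsets)
            ]
            kappa = _joint_cumulant(members, n)
            if flatten:
                kappa = kappa / distance_factor(offsets, px, n, sigma)
            out[j, n * lo_y + a : n * hi_y + a : n, n * lo_x + b : n * hi_x + b : n] = kappa
            mask[j, n * lo_y + a : n * hi_y + a : n, n * lo_x + b : n * hi_x + b : n] = True

    return CumulantImage(
        order=n,
        values=out,
        mask=mask,
        grid_spacing=px / n,
        plane_spacing_out=dz / n,
        n_frames_used=T,
        flattened=flatten,
        meta={"n_physical_planes": P, "sigma_flatten": sigma if flatten else None},
    )


def flatten(image: CumulantImage, sigma: float) -> CumulantImage:
    """Divide each virtual pixel by its combination's distance factor.

    Auto-cumulant phases (zero pairwise distance) are unchanged (D = 1).
    Raises if the image is already flattened.
    """
    if image.flattened:
        raise ValueError("image is already flattened")
    n = image.order
    px = image.grid_spacing * n
    values = image.values.copy()
    for (a, b), offsets in lateral_combinations(n).items():
        D = distance_factor(offsets, px, n, sigma)
        if image.is_volume:
            values[:, a::n, b::n] /= D
        else:
            values[a::n, b::n] /= D
    return CumulantImage(
        order=n,
        values=values,
        mask=image.mask.copy(),
        grid_spacing=image.grid_spacing,
        plane_spacing_out=image.plane_spacing_out,
        n_frames_used=image.n_frames_used,
        flattened=True,
        meta={**image.meta, "sigma_flatten": sigma},
    )
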