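"""Synthetic blinking-emitter movies and cell-like topographies with ground truth.

Coordinate convention (used throughout the package): all positions are in
nanometres; pixel (0, 0) has its *center* at (pixel_size/2, pixel_size/2), so
pixel index j spans [j*pixel_size, (j+1)*pixel_size) along each axis. For
multiplane stacks, physical plane p sits at z = p * plane_spacing.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Emitter",
    "EmitterSet",
    "OpticsModel",
    "NoiseModel",
    "BlinkMovie",
    "TopoFeature",
    "Topography",
    "simulate_blink_traces",
    "render_movie",
    "simulate_topography",
]


@dataclass(frozen=True)
class Emitter:
    """A point emitter with two-state (telegraph) blinking statistics.

    Parameters
    ----------
    x, y, z : float
        Position in nm.
    epsilon : float
        Mean on-state brightness in photons/frame.
    tau_on, tau_off : float
        Mean dwell times of the on and off states, in frames (>= 1).
    """

    x: float
    y: float
    z: float = 0.0
    epsilon: float = 100.0
    tau_on: float = 3.0
    tau_off: float = 12.0

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError(f"epsilon must be > 0, got {self.epsilon}")
        if self.tau_on < 1 or self.tau_off < 1:
            raise ValueError(
                f"dwell times must be >= 1 frame, got tau_on={self.tau_on}, "
                f"tau_off={self.tau_off}"
            )

    @property
    def p_on(self) -> float:
        """Stationary on-probability (duty cycle) of the telegraph process."""
        return self.tau_on / (self.tau_on + self.tau_off)


class EmitterSet(list):
    """An ordered collection of :class:`Emitter` with CSV round-trip."""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(e) for e in self])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "EmitterSet":
        df = pd.read_csv(path)
        return cls(Emitter(**row) for row in df.to_dict(orient="records"))


@dataclass(frozen=True)
class OpticsModel:
    """Imaging model: Gaussian PSF, pixel grid, and (optional) multiplane geometry.

    ``defocus_slope`` is the linear growth rate of the PSF standard deviation
    with axial distance from a detection plane (nm of sigma per nm of defocus).
    """

    sigma0: float
    pixel_size: float
    n_planes: int = 1
    plane_spacing: float = 350.0
    defocus_slope: float = 0.35

    def __post_init__(self) -> None:
        if self.sigma0 <= 0:
            raise ValueError("sigma0 must be > 0")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.n_planes < 1:
            raise ValueError("n_planes must be >= 1")
        if self.n_planes > 1 and self.plane_spacing <= 0:
            raise ValueError("plane_spacing must be > 0 for multiplane optics")

    def z_plane(self, p: int) -> float:
        """Axial position (nm) of physical plane ``p``."""
        return p * self.plane_spacing

    @property
    def axial_span(self) -> float:
        """Distance (nm) from the first to the last physical plane."""
        return (self.n_planes - 1) * self.plane_spacing

    def sigma_at(self, z_emitter: float, p: int = 0) -> float:
        """Effective PSF sigma (nm) of an emitter at ``z_emitter`` seen by plane ``p``."""
        return self.sigma0 + self.defocus_slope * abs(z_emitter - self.z_plane(p))


@dataclass(frozen=True)
class NoiseModel:
    poisson: bool = True
    read_sigma: float = 1.6  # photons rms, additive Gaussian, clipped at 0


@dataclass
class BlinkMovie:
    """A T x Y x X (or T x P x Y x X) photon-count stack plus acquisition metadata."""

    data: np.ndarray
    exposure: float = 0.05
    optics: OpticsModel | None = None
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim not in (3, 4):
            raise ValueError("movie data must be T x Y x X or T x P x Y x X")
        if self.data.shape[0] < 2:
            raise ValueError("movie must have T >= 2 frames")
        if np.nanmin(self.data) < 0:
            raise ValueError("photon counts must be nonnegative")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_planes(self) -> int:
        return self.data.shape[1] if self.data.ndim == 4 else 1

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[-2], self.data.shape[-1]

    def sidecar(self) -> dict:
        side = {
            "kind": "BlinkMovie",
            "exposure": self.exposure,
            "seed": self.seed,
            "shape": list(self.data.shape),
            "meta": self.meta,
        }
        if self.optics is not None:
            side["optics"] = dataclasses.asdict(self.optics)
        return side


def simulate_blink_traces(
    emitters: Sequence[Emitter], n_frames: int, seed: int
) -> np.ndarray:
    """Simulate independent stationary two-state Markov on/off traces.

    Each emitter switches on->off with probability 1/tau_on per frame and
    off->on with probability 1/tau_off; the initial state is drawn from the
    stationary distribution, so the chain is stationary from frame 0.

    Returns
    -------
    ndarray of uint8, shape (n_frames, n_emitters)
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    for e in emitters:
        if e.tau_on < 1 or e.tau_off < 1:
            raise ValueError("dwell times must be >= 1 frame")
    rng = np.random.default_rng(seed)
    n = len(emitters)
    p_on = np.array([e.p_on for e in emitters])
    p_off_to_on = np.array([1.0 / e.tau_off for e in emitters])
    p_on_to_off = np.array([1.0 / e.tau_on for e in emitters])

    u = rng.random((n_frames, n))
    traces = np.empty((n_frames, n), dtype=np.uint8)
    state = (u[0] < p_on).astype(np.uint8)
    traces[0] = state
    for t in range(1, n_frames):
        switch_p = np.where(state == 1, p_on_to_off, p_off_to_on)
        state = np.where(u[t] < switch_p, 1 - state, state).astype(np.uint8)
        traces[t] = state
    return traces


def _psf_image(
    e: Emitter, optics: OpticsModel, shape: tuple[int, int], p: int
) -> np.ndarray:
    """Pixel-integrated (center-sampled x area) Gaussian PSF image, total mass ~ 1."""
    ny, nx = shape
    px = optics.pixel_size
    sigma = optics.sigma_at(e.z, p)
    xc = (np.arange(nx) + 0.5) * px
    yc = (np.arange(ny) + 0.5) * px
    gx = px / (np.sqrt(2 * np.pi) * sigma) * np.exp(-((xc - e.x) ** 2) / (2 * sigma**2))
    gy = px / (np.sqrt(2 * np.pi) * sigma) * np.exp(-((yc - e.y) ** 2) / (2 * sigma**2))
    return np.outer(gy, gx)


def render_movie(
    emitters: Sequence[Emitter],
    traces: np.ndarray,
    optics: OpticsModel,
    shape: tuple[int, int],
    noise: NoiseModel | None = None,
    seed: int = 0,
    exposure: float = 0.05,
) -> BlinkMovie:
    """Render a blinking-emitter movie through the Gaussian-PSF camera model.

    Frame t (plane p) is sum_e epsilon_e * on_e(t) * G(x, y; sigma(p, z_e)),
    integrated over pixels, plus Poisson shot noise and additive read noise
    (Gaussian, clipped at 0) when enabled.

    Raises
    ------
    ValueError
        If any emitter's PSF support (+-4 sigma at the worst-focus plane)
        does not fit inside the field of view.
    """
    traces = np.asarray(traces)
    if traces.ndim != 2 or traces.shape[1] != len(emitters):
        raise ValueError("traces must be (n_frames, n_emitters)")
    ny, nx = shape
    px = optics.pixel_size
    P = optics.n_planes
    for e in emitters:
        # support check at the best-focus plane; defocused planes may spill
        # over the field edge (physical vignetting, not an error)
        sig_min = min(optics.sigma_at(e.z, p) for p in range(P))
        if not (
            4 * sig_min <= e.x <= nx * px - 4 * sig_min
            and 4 * sig_min <= e.y <= ny * px - 4 * sig_min
        ):
            raise ValueError(
                f"field too small to contain PSF support of emitter at "
                f"({e.x:.0f}, {e.y:.0f}) nm (needs +-{4 * sig_min:.0f} nm margin)"
            )

    T = traces.shape[0]
    # stack per-emitter PSFs: (N, P*ny*nx), then one matmul against the traces
    psfs = np.empty((len(emitters), P, ny, nx))
    for i, e in enumerate(emitters):
        for p in range(P):
            psfs[i, p] = e.epsilon * _psf_image(e, optics, shape, p)
    clean = traces.astype(float) @ psfs.reshape(len(emitters), -1)
    clean = clean.reshape(T, P, ny, nx)

    rng = np.random.default_rng(seed)
    data = clean
    if noise is not None:
        if noise.poisson:
            data = rng.poisson(clean).astype(float)
        if noise.read_sigma > 0:
            data = data + rng.normal(0.0, noise.read_sigma, size=data.shape)
            data = np.clip(data, 0.0, None)
    if P == 1:
        data = data[:, 0]
    return BlinkMovie(
        data=np.ascontiguousarray(data.astype(np.float32)),
        exposure=exposure,
        optics=optics,
        seed=seed,
        meta={"n_emitters": len(emitters), "noise": None if noise is None else dataclasses.asdict(noise)},
    )


@dataclass(frozen=True)
class TopoFeature:
    kind: str  # "dome" | "microvillus" | "filopodium"
    x: float  # nm
    y: float
    width: float  # characteristic sigma (nm)
    amplitude: float  # nm
    length: float = 0.0  # ridge length (filopodia only), nm
    angle: float = 0.0  # ridge orientation, radians


@dataclass
class Topography:
    """A Y x X surface height map (nm) with the feature list that generated it."""

    height: np.ndarray
    pixel_size: float
    features: list[TopoFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.height = np.asarray(self.height, dtype=float)
        if not np.all(np.isfinite(self.height)):
            raise ValueError("topography heights must be finite")

    def features_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(f) for f in self.features])


def simulate_topography(
    shape: tuple[int, int],
    pixel_size: float,
    n_microvilli: int = 0,
    n_filopodia: int = 0,
    dome_amplitude: float = 500.0,
    dome_sigma: float | None = None,
    microvillus_amplitude: tuple[float, float] = (100.0, 300.0),
    microvillus_sigma: tuple[float, float] = (100.0, 250.0),
    filopodium_amplitude: tuple[float, float] = (80.0, 200.0),
    filopodium_sigma: tuple[float, float] = (80.0, 160.0),
    filopodium_length: tuple[float, float] = (1500.0, 4000.0),
    seed: int = 0,
    margin: float = 0.15,
) -> Topography:
    """Generate a cell-like surface: smooth dome + microvilli bumps + filopodia ridges.

    All ground-truth features are recorded in ``Topography.features``; passing
    zero feature counts and ``dome_amplitude`` yields the dome alone.
    """
    ny, nx = shape
    if ny < 64 or nx < 64:
        raise ValueError("topography shape must be at least 64 x 64")
    rng = np.random.default_rng(seed)
    Lx, Ly = nx * pixel_size, ny * pixel_size
    if dome_sigma is None:
        dome_sigma = 0.35 * min(Lx, Ly)

    xc = (np.arange(nx) + 0.5) * pixel_size
    yc = (np.arange(ny) + 0.5) * pixel_size
    X, Y = np.meshgrid(xc, yc)

    features: list[TopoFeature] = []
    height = np.zeros(shape)
    if dome_amplitude != 0.0:
        cx, cy = Lx / 2, Ly / 2
        height += dome_amplitude * np.exp(
            -((X - cx) ** 2 + (Y - cy) ** 2) / (2 * dome_sigma**2)
        )
        features.append(TopoFeature("dome", cx, cy, dome_sigma, dome_amplitude))

    def _snap(v: float) -> float:
        # feature apex on a pixel center so recorded amplitudes are exact
        return (np.floor(v / pixel_size) + 0.5) * pixel_size

    def _rand_pos():
        return (
            _snap(rng.uniform(margin * Lx, (1 - margin) * Lx)),
            _snap(rng.uniform(margin * Ly, (1 - margin) * Ly)),
        )

    for _ in range(n_microvilli):
        x0, y0 = _rand_pos()
        amp = rng.uniform(*microvillus_amplitude)
        sig = rng.uniform(*microvillus_sigma)
        if amp <= 0:
            raise ValueError("microvillus amplitude must be > 0")
        height += amp * np.exp(-((X - x0) ** 2 + (Y - y0) ** 2) / (2 * sig**2))
        features.append(TopoFeature("microvillus", x0, y0, sig, amp))

    for _ in range(n_filopodia):
        x0, y0 = _rand_pos()
        amp = rng.uniform(*filopodium_amplitude)
        sig = rng.uniform(*filopodium_sigma)
        length = rng.uniform(*filopodium_length)
        ang = rng.uniform(0, np.pi)
        # ridge: Gaussian profile across, smooth box along the axis
        u = (X - x0) * np.cos(ang) + (Y - y0) * np.sin(ang)
        v = -(X - x0) * np.sin(ang) + (Y - y0) * np.cos(ang)
        along = 0.5 * (np.tanh((u + length / 2) / sig) - np.tanh((u - length / 2) / sig))
        height += amp * along * np.exp(-(v**2) / (2 * sig**2))
        features.append(TopoFeature("filopodium", x0, y0, sig, amp, length, ang))

    return Topography(height=height, pixel_size=pixel_size, features=features)


def topography_sidecar(topo: Topography) -> str:
    return json.dumps(
        {
            "kind": "Topography",
            "pixel_size": topo.pixel_size,
            "features": [dataclasses.asdict(f) for f in topo.features],
        }
    )
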