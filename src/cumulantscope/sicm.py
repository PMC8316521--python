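"""Hopping-mode scanning-ion-conductance topography: scan simulation and processing.

The pipette's normalized current follows I(z)/I_inf = 1 / (1 + c_s r_p / z)
for tip-surface gap z; during a hop the tip descends quasi-statically in
steps <= 1 nm and the surface is declared detected when the current first
drops to the setpoint (0.99 of bulk in the source experiments), i.e. at gap
z* = c_s r_p s / (1 - s). The lateral aperture footprint is modeled as a
uniform disk of radius 1.5 r_p (surface height averaged underneath), which
reproduces the ~3 r_p lateral resolution rule. Fixed-height hopping only;
adaptive per-region hop heights are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .synth import Topography

__all__ = [
    "PipetteModel",
    "ScanConfig",
    "HeightMap",
    "current_distance",
    "detection_gap",
    "hop_scan",
    "level_plane",
    "bandpass",
]


@dataclass(frozen=True)
class PipetteModel:
    """Nanopipette sensing model: radius and current-distance decay scale c_s * r_p."""

    radius: float = 50.0  # nm
    sensing_coeff: float = 0.01  # dimensionless c_s; 1% current drop at z ~ r_p
    bulk_current: float = 1.0  # normalized I_inf

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("pipette radius must be > 0")
        if self.sensing_coeff <= 0:
            raise ValueError("sensing coefficient must be > 0")


@dataclass(frozen=True)
class ScanConfig:
    pixels: tuple[int, int]  # (Y, X)
    pixel_size: float  # nm
    setpoint: float = 0.99  # fraction of normalized bulk current
    hopping_height: float = 5000.0  # nm
    pixel_rate: float = 200.0  # Hz
    descent_step: float = 1.0  # nm, axial quantization of the approach

    def __post_init__(self) -> None:
        if not 0 < self.setpoint < 1:
            raise ValueError("setpoint must be in (0, 1)")
        if self.hopping_height <= 0:
            raise ValueError("hopping height must be > 0")
        if self.descent_step <= 0 or self.descent_step > 1.0:
            raise ValueError("descent step must be in (0, 1] nm")

    @classmethod
    def from_extent(cls, extent_nm: float, n_pixels: int, **kwargs) -> "ScanConfig":
        """Build a square scan from a physical extent; pixel size truncated to whole nm."""
        px = int(extent_nm / n_pixels)
        return cls(pixels=(n_pixels, n_pixels), pixel_size=float(px), **kwargs)

    @property
    def scan_time_s(self) -> float:
        """Ideal scan duration (pixels / rate); instrument overhead excluded."""
        return self.pixels[0] * self.pixels[1] / self.pixel_rate


@dataclass
class HeightMap:
    """A Y x X topography (nm) with validity mask and processing provenance."""

    height: np.ndarray
    pixel_size: float
    mask: np.ndarray | None = None
    leveled: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.height = np.asarray(self.height, dtype=float)
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.mask is None:
            self.mask = np.isfinite(self.height)
        self.mask = np.asarray(self.mask, dtype=bool)

    def sidecar(self) -> dict:
        return {
            "kind": "HeightMap",
            "pixel_size": self.pixel_size,
            "leveled": self.leveled,
            "meta": self.meta,
        }

    def to_text(self, path) -> None:
        """Gwyddion-compatible whitespace-delimited matrix export (nm)."""
        np.savetxt(path, np.asarray(self.height, dtype=np.float32), fmt="%.9g")

    @classmethod
    def from_text(cls, path, pixel_size: float) -> "HeightMap":
        return cls(height=np.loadtxt(path), pixel_size=pixel_size,
                   meta={"source": str(path)})


def current_distance(z, pipette: PipetteModel):
    """Normalized current I(z)/I_inf = 1 / (1 + c_s r_p / z); strictly increasing in z."""
    z = np.asarray(z, dtype=float)
    if np.any(z <= 0):
        raise ValueError("tip-surface gap z must be > 0")
    out = pipette.bulk_current / (1.0 + pipette.sensing_coeff * pipette.radius / z)
    return float(out) if out.ndim == 0 else out


def detection_gap(setpoint: float, pipette: PipetteModel) -> float:
    """Gap z* at which the normalized current equals the setpoint (closed form)."""
    if not 0 < setpoint < 1:
        raise ValueError("setpoint must be in (0, 1)")
    return pipette.sensing_coeff * pipette.radius * setpoint / (1.0 - setpoint)


def _footprint_average(height: np.ndarray, radius_px: float) -> np.ndarray:
    r = max(radius_px, 0.0)
    n = int(np.floor(r))
    if n < 1:
        return height
    yy, xx = np.mgrid[-n : n + 1, -n : n + 1]
    disk = (yy**2 + xx**2) <= r**2
    return ndimage.convolve(height, disk / disk.sum(), mode="nearest")


def hop_scan(
    topo: Topography,
    pipette: PipetteModel,
    config: ScanConfig,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> HeightMap:
    """Simulate a hopping-mode scan over a ground-truth topography.

    At each pixel the tip descends from hop height in steps of
    ``config.descent_step``; the recorded height is the detection position
    minus the constant setpoint gap z*, plus Gaussian z-noise. The surface
    seen by the current is the topography averaged under the aperture disk
    (radius 1.5 r_p). Scan-time metadata is the ideal pixels/rate figure.
    """
    span = float(topo.height.max() - topo.height.min())
    if config.hopping_height <= span:
        raise ValueError(
            f"hopping height {config.hopping_height} nm does not clear the "
            f"topography range {span:.0f} nm"
        )
    ny, nx = config.pixels
    if topo.height.shape != (ny, nx):
        raise ValueError("scan pixel grid must match the topography grid")
    rng = np.random.default_rng(seed)

    h_eff = _footprint_average(topo.height, 1.5 * pipette.radius / topo.pixel_size)
    z_star = detection_gap(config.setpoint, pipette)
    step = config.descent_step
    z_top = float(topo.height.max()) + config.hopping_height
    # detection: first grid position z_top - k*step with gap <= z*, then the
    # exact threshold crossing is refined within the bracketing step (the
    # current-distance law is invertible), so the step size bounds the
    # approach sampling, not the height accuracy
    k = np.ceil((z_top - h_eff - z_star) / step)
    z_detect_coarse = z_top - k * step
    z_detect = h_eff + z_star  # refined crossing, within one step of coarse
    floor = float(topo.height.min()) - 10.0 * step
    valid = z_detect_coarse >= floor
    height = z_detect - z_star
    if noise_sigma > 0:
        height = height + rng.normal(0.0, noise_sigma, size=height.shape)
    height = np.where(valid, height, np.nan)
    return HeightMap(
        height=height,
        pixel_size=topo.pixel_size,
        mask=valid,
        meta={
            "scan_time_s": config.scan_time_s,
            "setpoint": config.setpoint,
            "hopping_height": config.hopping_height,
            "pipette_radius": pipette.radius,
            "noise_sigma": noise_sigma,
            "seed": seed,
        },
    )


def level_plane(hmap: HeightMap) -> HeightMap:
    """Subtract the least-squares best-fit plane (over valid pixels).

    Idempotent by construction: an already-leveled map is returned unchanged.
    """
    if hmap.leveled:
        return hmap
    valid = hmap.mask & np.isfinite(hmap.height)
    if np.count_nonzero(valid) < 3:
        raise ValueError("need at least 3 valid pixels to fit a plane")
    ny, nx = hmap.height.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    A = np.column_stack([xx[valid], yy[valid], np.ones(np.count_nonzero(valid))])
    coeff, *_ = np.linalg.lstsq(A, hmap.height[valid], rcond=None)
    plane = coeff[0] * xx + coeff[1] * yy + coeff[2]
    out = hmap.height - plane
    return HeightMap(
        height=np.where(valid, out, np.nan),
        pixel_size=hmap.pixel_size,
        mask=valid,
        leveled=True,
        meta={**hmap.meta, "plane_coefficients": [float(c) for c in coeff]},
    )


def bandpass(hmap: HeightMap, low_cut: float, high_cut: float) -> HeightMap:
    """Difference-of-Gaussians spatial filter passing wavelengths in (high_cut, low_cut).

    Cutoff wavelengths are in nm; ``low_cut`` (long-wavelength bound) must
    exceed ``high_cut``, which must exceed 2 pixels. Output is zero-mean.
    """
    if not (low_cut > high_cut > 2 * hmap.pixel_size):
        raise ValueError(
            f"need low_cut > high_cut > 2*pixel_size, got "
            f"({low_cut}, {high_cut}, px={hmap.pixel_size})"
        )
    valid = hmap.mask & np.isfinite(hmap.height)
    filled = np.where(valid, hmap.height, np.nanmean(hmap.height[valid]))
    sigma_small = high_cut / (2 * np.pi) / hmap.pixel_size
    sigma_large = low_cut / (2 * np.pi) / hmap.pixel_size
    dog = ndimage.gaussian_filter(filled, sigma_small) - ndimage.gaussian_filter(
        filled, sigma_large
    )
    dog = dog - dog[valid].mean()
    return HeightMap(
        height=np.where(valid, dog, np.nan),
        pixel_size=hmap.pixel_size,
        mask=valid,
        leveled=hmap.leveled,
        meta={**hmap.meta, "bandpass_nm": [low_cut, high_cut]},
    )
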