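"""Shared fixtures and oracles for the test suite.

Expensive synthetic scenes are session-scoped; every stochastic object is
seeded so the suite is deterministic.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest
from scipy.optimize import curve_fit

from cumulantscope import synth


def fit_gaussian2d(img: np.ndarray, spacing: float = 1.0) -> tuple[float, float, float]:
    """Least-squares isotropic Gaussian fit; returns (sigma, x0, y0) in nm.

    Independent oracle used to measure PSF widths of simulator and cumulant
    images (fit, not moments, so background noise barely biases it).
    """
    img = np.abs(np.nan_to_num(np.asarray(img, dtype=float)))
    ny, nx = img.shape
    yy, xx = (np.mgrid[0:ny, 0:nx] + 0.5) * spacing

    def g(xy, A, x0, y0, s):
        x, y = xy
        return A * np.exp(-((x - x0) ** 2 + (y - y0) ** 2) / (2 * s**2))

    iy, ix = np.unravel_index(np.argmax(img), img.shape)
    p0 = [img.max(), xx[iy, ix], yy[iy, ix], 2.0 * spacing]
    popt, _ = curve_fit(
        g, (xx.ravel(), yy.ravel()), img.ravel(), p0=p0, maxfev=20000
    )
    return abs(popt[3]), popt[1], popt[2]


def quiet_sofi2d(movie, order, **kw):
    from cumulantscope import sofi

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sofi.sofi2d(movie, order, **kw)


@pytest.fixture(scope="session")
def single_emitter_movie():
    """One centered emitter, p_on = 0.5, T = 5000 frames, noise-free."""
    optics = synth.OpticsModel(sigma0=130.0, pixel_size=100.0)
    emitters = [synth.Emitter(820.0, 790.0, epsilon=500.0, tau_on=10, tau_off=10)]
    traces = synth.simulate_blink_traces(emitters, 5000, seed=11)
    movie = synth.render_movie(emitters, traces, optics, (16, 16), noise=None, seed=11)
    return movie, emitters, traces


@pytest.fixture(scope="session")
def dense_scene_movie():
    """~150 emitters on a 64 x 64 grid with Poisson + read noise, T = 1000."""
    rng = np.random.default_rng(3)
    px, s0 = 107.0, 106.0
    ny = nx = 64
    margin = 5 * s0
    optics = synth.OpticsModel(sigma0=s0, pixel_size=px)
    emitters = [
        synth.Emitter(
            float(rng.uniform(margin, nx * px - margin)),
            float(rng.uniform(margin, ny * px - margin)),
            epsilon=300.0, tau_on=3, tau_off=9,
        )
        for _ in range(150)
    ]
    traces = synth.simulate_blink_traces(emitters, 1000, seed=3)
    movie = synth.render_movie(
        emitters, traces, optics, (ny, nx), noise=synth.NoiseModel(), seed=3
    )
    return movie, emitters


@pytest.fixture(scope="session")
def multiplane_movie():
    """8-plane stack, one emitter centered on physical plane 2, noise-free."""
    optics = synth.OpticsModel(
        sigma0=130.0, pixel_size=100.0, n_planes=8, plane_spacing=350.0
    )
    emitters = [synth.Emitter(820.0, 790.0, z=700.0, epsilon=500.0, tau_on=5, tau_off=5)]
    traces = synth.simulate_blink_traces(emitters, 400, seed=2)
    movie = synth.render_movie(emitters, traces, optics, (16, 16), noise=None, seed=2)
    return movie, emitters
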