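"""Interleaved live-cell acquisition bookkeeping: alternating topography scans
and fluorescence sub-stacks, per-cycle timing, and time-lapse assembly.

The scheduler reports ideal durations (pixels/rate and frames x exposure);
real acquisitions include instrument overhead, exposed here as an explicit
``overhead_s`` parameter rather than folded into the physics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from . import preproc, sicm, sofi, synth

__all__ = ["TimelapseSchedule", "plan_timelapse", "run_synthetic_timelapse"]


@dataclass(frozen=True)
class TimelapseSchedule:
    n_cycles: int
    sicm_pixels: tuple[int, int] = (200, 100)
    pixel_rate: float = 200.0  # Hz
    sofi_frames: int = 300
    exposure: float = 0.05  # s
    skip_frames: int = 50
    overhead_s: float = 0.0  # per-cycle instrument overhead (ideal = 0)

    def __post_init__(self) -> None:
        if self.n_cycles < 1:
            raise ValueError("need at least one cycle")
        if self.skip_frames >= self.sofi_frames:
            raise ValueError("skip_frames must be < sofi_frames")

    @property
    def sicm_duration_s(self) -> float:
        return self.sicm_pixels[0] * self.sicm_pixels[1] / self.pixel_rate

    @property
    def sofi_duration_s(self) -> float:
        return self.sofi_frames * self.exposure

    @property
    def frames_used(self) -> int:
        return self.sofi_frames - self.skip_frames

    @property
    def sofi_temporal_resolution_s(self) -> float:
        """Duration of the frames actually contributing to one SOFI frame."""
        return self.frames_used * self.exposure


def plan_timelapse(schedule: TimelapseSchedule) -> pd.DataFrame:
    """Per-cycle event table: durations, frame bookkeeping, cumulative clock."""
    rows = []
    clock = 0.0
    for c in range(schedule.n_cycles):
        t0 = clock
        clock += schedule.sicm_duration_s
        clock += schedule.sofi_duration_s
        clock += schedule.overhead_s
        rows.append(
            {
                "cycle": c,
                "t_start_s": t0,
                "sicm_duration_s": schedule.sicm_duration_s,
                "sofi_duration_s": schedule.sofi_duration_s,
                "frames_used_for_sofi": schedule.frames_used,
                "sofi_temporal_resolution_s": schedule.sofi_temporal_resolution_s,
                "t_end_s": clock,
            }
        )
    return pd.DataFrame(rows)


def run_synthetic_timelapse(
    scene: Callable[[int], tuple[synth.Topography, list[synth.Emitter]]],
    schedule: TimelapseSchedule,
    optics: synth.OpticsModel,
    shape: tuple[int, int],
    pipette: sicm.PipetteModel | None = None,
    scan: sicm.ScanConfig | None = None,
    noise: synth.NoiseModel | None = None,
    seed: int = 0,
) -> list[dict]:
    """Run the interleaved acquisition on a synthetic, possibly time-varying scene.

    ``scene(cycle)`` returns the (Topography, emitters) pair current at that
    cycle. Each cycle scans the topography, records a fresh ``sofi_frames``
    sub-stack, drops the first ``skip_frames``, and computes a 2nd-order
    cumulant image from the remaining frames of *that cycle only*. Returns a
    list of per-cycle dicts with keys ``height_map``, ``sofi`` and ``clock_s``.
    """
    plan = plan_timelapse(schedule)
    results = []
    rng = np.random.default_rng(seed)
    for c in range(schedule.n_cycles):
        topo, emitters = scene(c)
        cfg = scan or sicm.ScanConfig(
            pixels=topo.height.shape, pixel_size=topo.pixel_size,
            hopping_height=max(1000.0, np.ptp(topo.height) * 2 + 100.0),
            pixel_rate=schedule.pixel_rate,
        )
        hm = sicm.hop_scan(topo, pipette or sicm.PipetteModel(), cfg,
                           seed=int(rng.integers(2**31)))
        traces = synth.simulate_blink_traces(
            emitters, schedule.sofi_frames, seed=int(rng.integers(2**31))
        )
        movie = synth.render_movie(
            emitters, traces, optics, shape, noise=noise,
            seed=int(rng.integers(2**31)), exposure=schedule.exposure,
        )
        movie = preproc.exclude_frames(movie, schedule.skip_frames)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            image = sofi.sofi2d(movie, order=2, flatten=True)
        results.append(
            {
                "cycle": c,
                "height_map": hm,
                "sofi": image,
                "clock_s": float(plan.loc[c, "t_end_s"]),
                "frames_used": schedule.frames_used,
            }
        )
    return results
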