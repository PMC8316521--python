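"""Run configuration and the end-to-end synthetic correlative pipeline.

A run is described by a single YAML file (schema-versioned; unknown keys are
rejected before any compute). ``run_pipeline`` executes
simulate -> preprocess -> cumulants -> postprocess -> resolution -> scan ->
register -> correlate on a fully synthetic scene whose fluorescence emitters
are planted on the topography's microvillus features, so the correlation
stage has real shared ground truth. Every stage logs its parameters,
duration, and output hashes into a JSON report; reruns with the same seed
are bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from pathlib import Path

import numpy as np
import yaml

from . import coreg, decorr, io, postproc, preproc, sicm, sofi, synth

__all__ = ["PipelineConfig", "load_config", "run_pipeline", "DEFAULT_CONFIG"]

SCHEMA_VERSION = 1

DEFAULT_CONFIG: dict = {
    "schema_version": SCHEMA_VERSION,
    "seed": 1,
    "out_dir": "pipeline_out",
    "simulate": {
        "shape": [64, 64],
        "pixel_size": 107.0,
        "sigma0": 130.0,
        "frames": 600,
        "exposure": 0.05,
        "epsilon": 300.0,
        "tau_on": 3.0,
        "tau_off": 9.0,
        "n_background_emitters": 25,
        "emitters_per_feature": 3,
        "noise": {"poisson": True, "read_sigma": 1.6},
        "topography": {"n_microvilli": 6, "n_filopodia": 1, "dome_amplitude": 400.0},
    },
    "preprocess": {"skip_frames": 50, "drift_block_len": 0},
    "cumulants": {"order": 2, "flatten": True},
    "postprocess": {"deconv_iters": 10, "no_deconv": False},
    "resolution": {"n_filters": 10},
    "scan": {
        "pipette_radius": 50.0,
        "setpoint": 0.99,
        "hopping_height": 3000.0,
        "pixel_rate": 200.0,
        "noise_sigma": 2.0,
    },
    "register": {"jitter_px": 0.0},
    "correlate": {"section_half_length_px": 6, "displace_factor": 2.0},
}


class PipelineConfig(dict):
    """A validated pipeline configuration (plain mapping with schema checking)."""

    @classmethod
    def from_mapping(cls, mapping: dict) -> "PipelineConfig":
        merged = _merge_validate(DEFAULT_CONFIG, mapping or {}, path="")
        cfg = cls(merged)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self["schema_version"] != SCHEMA_VERSION:
            raise ValueError(
                f"unsupported schema_version {self['schema_version']}"
            )
        order = self["cumulants"]["order"]
        if order not in (2, 3, 4):
            raise ValueError(f"cumulants.order must be 2, 3 or 4, got {order}")
        if not 0 < self["scan"]["setpoint"] < 1:
            raise ValueError("scan.setpoint must be in (0, 1)")
        if self["preprocess"]["skip_frames"] >= self["simulate"]["frames"]:
            raise ValueError("preprocess.skip_frames must be < simulate.frames")
        if self["seed"] is None:
            raise ValueError("a seed is mandatory (no silent nondeterminism)")


def _merge_validate(defaults: dict, override: dict, path: str) -> dict:
    out = dict(defaults)
    for key, val in override.items():
        if key not in defaults:
            raise ValueError(f"unknown config key {path + key!r}")
        if isinstance(defaults[key], dict) and isinstance(val, dict):
            out[key] = _merge_validate(defaults[key], val, path + key + ".")
        else:
            out[key] = val
    return out


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig.from_mapping(raw)


def _hash(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Execute the full synthetic correlative pipeline described by ``config``."""
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_mapping(config)
    out = Path(out_dir or config["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": json.loads(json.dumps(config)), "stages": {}}
    rng = np.random.default_rng(config["seed"])

    def stage(name):
        t0 = time.perf_counter()

        def done(**kw):
            report["stages"][name] = {
                "params": config.get(name, {}),
                "duration_s": round(time.perf_counter() - t0, 4),
                **kw,
            }

        return done

    # --- simulate -----------------------------------------------------------
    done = stage("simulate")
    sim = config["simulate"]
    ny, nx = sim["shape"]
    px = sim["pixel_size"]
    optics = synth.OpticsModel(sigma0=sim["sigma0"], pixel_size=px)
    topo = synth.simulate_topography(
        (ny, nx), px, seed=config["seed"], **sim["topography"]
    )
    margin = 5 * sim["sigma0"]
    emitters = synth.EmitterSet()
    for f in topo.features:
        if f.kind != "microvillus":
            continue
        for _ in range(sim["emitters_per_feature"]):
            ex = float(np.clip(f.x + rng.normal(0, f.width / 2), margin, nx * px - margin))
            ey = float(np.clip(f.y + rng.normal(0, f.width / 2), margin, ny * px - margin))
            emitters.append(synth.Emitter(ex, ey, epsilon=sim["epsilon"],
                                          tau_on=sim["tau_on"], tau_off=sim["tau_off"]))
    for _ in range(sim["n_background_emitters"]):
        emitters.append(
            synth.Emitter(
                float(rng.uniform(margin, nx * px - margin)),
                float(rng.uniform(margin, ny * px - margin)),
                epsilon=sim["epsilon"], tau_on=sim["tau_on"], tau_off=sim["tau_off"],
            )
        )
    traces = synth.simulate_blink_traces(emitters, sim["frames"], seed=config["seed"])
    movie = synth.render_movie(
        emitters, traces, optics, (ny, nx),
        noise=synth.NoiseModel(**sim["noise"]), seed=config["seed"],
        exposure=sim["exposure"],
    )
    io.write_stack(movie, out / "movie.tif")
    emitters.to_csv(out / "emitters.csv")
    topo.features_frame().to_csv(out / "topo_features.csv", index=False)
    done(n_emitters=len(emitters), movie_hash=_hash(movie.data))

    # --- preprocess ---------------------------------------------------------
    done = stage("preprocess")
    pre = config["preprocess"]
    movie = preproc.exclude_frames(movie, pre["skip_frames"])
    bleach = preproc.fit_bleaching(movie)
    drift_info = None
    if pre["drift_block_len"]:
        track = preproc.estimate_drift(movie, block_len=pre["drift_block_len"])
        movie = preproc.apply_drift(movie, track)
        track.to_csv(out / "drift.csv")
        drift_info = track.block_shifts.tolist()
    done(
        frames_used=movie.n_frames,
        bleach_lifetime_s=bleach.lifetime if np.isfinite(bleach.lifetime) else "inf",
        drift_blocks=drift_info,
    )

    # --- cumulants ----------------------------------------------------------
    done = stage("cumulants")
    order = config["cumulants"]["order"]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cum = sofi.sofi2d(movie, order=order, flatten=config["cumulants"]["flatten"])
    io.write_stack(cum, out / "cumulant.tif")
    done(order=order, image_hash=_hash(np.nan_to_num(cum.values)))

    # --- postprocess --------------------------------------------------------
    done = stage("postprocess")
    lin = postproc.linearize(cum)
    lin = np.nan_to_num(lin)
    if not config["postprocess"]["no_deconv"]:
        psf = postproc.PsfModel.for_cumulant(sim["sigma0"], order, cum.grid_spacing)
        final = postproc.lucy_richardson(lin, psf,
                                         iters=config["postprocess"]["deconv_iters"])
    else:
        final = lin
    done(deconvolved=not config["postprocess"]["no_deconv"], image_hash=_hash(final))

    # --- resolution ---------------------------------------------------------
    done = stage("resolution")
    res = decorr.estimate_resolution(
        final, grid_spacing=cum.grid_spacing,
        n_filters=config["resolution"]["n_filters"],
    )
    done(kc=None if not res.defined else res.kc,
         resolution_nm=None if not res.defined else res.resolution_nm)

    # --- scan ---------------------------------------------------------------
    done = stage("scan")
    sc = config["scan"]
    pipette = sicm.PipetteModel(radius=sc["pipette_radius"])
    scan_cfg = sicm.ScanConfig(
        pixels=(ny, nx), pixel_size=px, setpoint=sc["setpoint"],
        hopping_height=sc["hopping_height"], pixel_rate=sc["pixel_rate"],
    )
    hmap = sicm.hop_scan(topo, pipette, scan_cfg, noise_sigma=sc["noise_sigma"],
                         seed=config["seed"])
    hmap = sicm.level_plane(hmap)
    io.write_stack(hmap, out / "height.tif")
    hmap.to_text(out / "height.txt")
    done(scan_time_s=scan_cfg.scan_time_s, height_hash=_hash(np.nan_to_num(hmap.height)))

    # --- register -----------------------------------------------------------
    done = stage("register")
    feats = [f for f in topo.features if f.kind == "microvillus"]
    if len(feats) >= 3:
        jitter = config["register"]["jitter_px"]
        pairs = []
        for f in feats:
            # fluorescence coords on the cumulant grid; SICM coords on the scan grid
            src = (f.x / cum.grid_spacing, f.y / cum.grid_spacing)
            dst = (f.x / px + rng.normal(0, jitter), f.y / px + rng.normal(0, jitter))
            pairs.append((src, dst))
        amap = coreg.fit_affine(pairs)
        warped, valid = coreg.warp_image(np.nan_to_num(final), amap, (ny, nx))
        done(residual_rms_px=amap.residual_rms, n_points=amap.n_points)
    else:
        amap = coreg.AffineMap.identity()
        warped = np.nan_to_num(final)[::order, ::order]
        valid = np.ones_like(warped, dtype=bool)
        done(skipped="fewer than 3 registration features")

    # --- correlate ----------------------------------------------------------
    done = stage("correlate")
    half = config["correlate"]["section_half_length_px"]
    disp = config["correlate"]["displace_factor"]
    # correlate against the band-passed topography: the dome's smooth ramp
    # would otherwise dominate every profile and mask the feature-level match
    bp = sicm.bandpass(hmap, low_cut=20 * px, high_cut=2.2 * px)
    height_img = np.nan_to_num(bp.height)
    r_matched, r_displaced = [], []
    for f in feats:
        cxp, cyp = f.x / px, f.y / px
        w_px = f.width / px
        for dx, dy, bucket in [
            (0.0, 0.0, r_matched),
            # displace far enough that the section clears the feature entirely
            (disp * 2 * w_px + 2 * half, 0.0, r_displaced),
        ]:
            x0, x1 = cxp + dx - half, cxp + dx + half
            if not (0 <= x0 and x1 < nx and 0 <= cyp + dy < ny):
                continue
            try:
                sec = coreg.extract_profiles(
                    height_img, np.where(valid, warped, 0.0),
                    [(x0, cyp + dy), (x1, cyp + dy)], width=1,
                )
                r = coreg.pearson(sec)
            except ValueError:
                continue
            if np.isfinite(r):
                bucket.append(r)
    stats_out: dict = {
        "n_matched": len(r_matched),
        "n_displaced": len(r_displaced),
        "median_r_matched": float(np.median(r_matched)) if r_matched else None,
        "median_r_displaced": float(np.median(r_displaced)) if r_displaced else None,
    }
    if len(r_matched) >= 3 and len(r_displaced) >= 3:
        t, dof, p = coreg.compare_groups(r_matched, r_displaced)
        stats_out.update({"welch_t": t, "welch_dof": dof, "welch_p": p})
    done(**stats_out)

    report["seed"] = config["seed"]
    (out / "report.json").write_text(json.dumps(report, indent=1, default=io._json_default))
    return report
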