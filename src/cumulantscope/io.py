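"""Stack and height-map I/O: multi-page TIFF with JSON sidecar metadata.

Round trips are lossless for 32-bit float data; the sidecar carries all
acquisition metadata (exposure, optics geometry, seeds, processing flags) as
plain JSON next to the TIFF (`<name>.json`).
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import tifffile

from .sicm import HeightMap
from .sofi import CumulantImage
from .synth import BlinkMovie, OpticsModel

__all__ = ["write_stack", "read_stack", "sidecar_path"]


def sidecar_path(path) -> Path:
    p = Path(path)
    return p.with_suffix(p.suffix + ".json")


def write_stack(obj, path) -> Path:
    """Write a BlinkMovie, HeightMap, or CumulantImage as TIFF + JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(obj, BlinkMovie):
        data = obj.data
        pages = data.reshape(-1, *data.shape[-2:])
        side = obj.sidecar()
    elif isinstance(obj, HeightMap):
        pages = np.asarray(obj.height, dtype=np.float32)
        side = obj.sidecar()
    elif isinstance(obj, CumulantImage):
        vals = np.asarray(obj.values, dtype=np.float32)
        pages = vals.reshape(-1, *vals.shape[-2:]) if vals.ndim == 3 else vals
        side = obj.sidecar()
        side["shape"] = list(obj.values.shape)
    else:
        raise TypeError(f"cannot write object of type {type(obj).__name__}")
    tifffile.imwrite(path, pages)
    sidecar_path(path).write_text(json.dumps(side, indent=1, default=_json_default))
    return path


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON-serializable: {type(o)}")


def read_stack(path):
    """Read a TIFF + sidecar back into its domain object.

    A missing sidecar yields a BlinkMovie with default metadata and a
    warning (pixel size unknown); a malformed sidecar raises a schema error.
    """
    path = Path(path)
    data = tifffile.imread(path)
    sp = sidecar_path(path)
    if not sp.exists():
        warnings.warn(
            f"no sidecar for {path.name}: loading with defaults, pixel size unknown",
            stacklevel=2,
        )
        if data.ndim == 2:
            return HeightMap(height=data.astype(float), pixel_size=1.0,
                             meta={"pixel_size_known": False})
        return BlinkMovie(data=data, meta={"pixel_size_known": False})
    try:
        side = json.loads(sp.read_text())
        kind = side["kind"]
    except (json.JSONDecodeError, KeyError) as exc:
        raise ValueError(f"malformed sidecar {sp}: {exc}") from exc

    if kind == "BlinkMovie":
        shape = tuple(side["shape"])
        optics = OpticsModel(**side["optics"]) if "optics" in side else None
        return BlinkMovie(
            data=data.reshape(shape),
            exposure=side.get("exposure", 0.05),
            optics=optics,
            seed=side.get("seed"),
            meta=side.get("meta", {}),
        )
    if kind == "HeightMap":
        return HeightMap(height=data.astype(float), pixel_size=side["pixel_size"],
                         leveled=side.get("leveled", False), meta=side.get("meta", {}))
    if kind == "CumulantImage":
        shape = tuple(side.get("shape", data.shape))
        values = data.reshape(shape).astype(float)
        return CumulantImage(
            order=side["order"],
            values=values,
            mask=np.isfinite(values),
            grid_spacing=side["grid_spacing"],
            plane_spacing_out=side.get("plane_spacing_out"),
            n_frames_used=side.get("n_frames_used", 0),
            flattened=side.get("flattened", False),
            meta=side.get("meta", {}),
        )
    raise ValueError(f"unknown sidecar kind {kind!r} in {sp}")
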