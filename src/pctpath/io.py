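"""Thin file-format helpers: 32-bit float TIFF stacks and JSON configs."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .geometry import ImagingGeometry


def write_tiff_stack(path, array: np.ndarray) -> None:
    """Write a 2D image or 3D stack as multi-page 32-bit float TIFF."""
    tifffile.imwrite(str(path), np.asarray(array, dtype=np.float32))


def read_tiff_stack(path) -> np.ndarray:
    return tifffile.imread(str(path)).astype(np.float64)


def load_geometry(path) -> ImagingGeometry:
    """Read an ImagingGeometry from a JSON config.

    Recognized keys: energy_keV, distance_m, pixel_m, epsilon, delta, beta.
    """
    cfg = json.loads(Path(path).read_text())
    allowed = {"energy_keV", "distance_m", "pixel_m", "epsilon", "delta", "beta"}
    unknown = set(cfg) - allowed
    if unknown:
        raise ValueError(f"unknown geometry keys: {sorted(unknown)}")
    return ImagingGeometry(**cfg)


def save_json(path, obj) -> None:
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=_default) + "\n")
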