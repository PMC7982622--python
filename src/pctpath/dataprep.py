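"""Deterministic dataset-construction arithmetic for classifier training.

A cubic reconstructed volume is sectioned along the three orthogonal
orientations; every slice is center-cropped, divided into four quadrant
subgraphs, resized to the classifier input size, and optionally rotated
through 0/90/180/270 degrees (fourfold augmentation).  The resulting tile
counts are exact and countable from the volume shape alone — a 1024^3
volume yields 3 x 1024 x 4 = 12,288 original tiles and 49,152 with the
fourfold rotations — so manifests can be built without materializing any
image.  Classifier training itself is out of scope; this module certifies
the data pipeline feeding it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skimage.transform import resize

__all__ = [
    "ORIENTATIONS",
    "tile_manifest",
    "tile_volume",
    "split_dataset",
    "dataset_size",
]

ORIENTATIONS = ("transverse", "sagittal", "coronal")
MANIFEST_COLUMNS = ["specimen", "orientation", "slice_index", "quadrant", "rotation_deg"]


def tile_manifest(
    shape: tuple[int, int, int],
    crop: int = 1024,
    subgraph: int = 512,
    rotations: tuple[int, ...] = (0, 90, 180, 270),
    specimen: str = "spec0",
) -> pd.DataFrame:
    """Exact tile bookkeeping for one volume, without materializing images.

    Each orientation contributes its full axis extent of slices; each
    slice is center-cropped to ``crop`` squared and quartered into
    ``subgraph`` squared quadrants (crop must equal 2*subgraph), and each
    quadrant emits one record per rotation.  Total records =
    3 * n_slices * 4 * n_rotations.
    """
    if len(shape) != 3:
        raise ValueError("volume shape must be 3D")
    if crop != 2 * subgraph:
        raise ValueError("crop must be twice the subgraph size (four quadrants)")
    if not rotations or any(r not in (0, 90, 180, 270) for r in rotations):
        raise ValueError("rotations must be a non-empty subset of {0, 90, 180, 270}")
    axes = {"transverse": 0, "sagittal": 2, "coronal": 1}
    records = []
    for orientation in ORIENTATIONS:
        axis = axes[orientation]
        plane = tuple(s for i, s in enumerate(shape) if i != axis)
        if min(plane) < crop:
            raise ValueError(
                f"{orientation} plane {plane} smaller than crop {crop}"
            )
        for slice_index in range(shape[axis]):
            for quadrant in range(4):
                for rot in rotations:
                    records.append((specimen, orientation, slice_index, quadrant, rot))
    return pd.DataFrame(records, columns=MANIFEST_COLUMNS)


def _center_crop(img: np.ndarray, size: int) -> np.ndarray:
    r0 = (img.shape[0] - size) // 2
    c0 = (img.shape[1] - size) // 2
    return img[r0:r0 + size, c0:c0 + size]


def tile_volume(
    volume: np.ndarray,
    crop: int | None = None,
    subgraph: int | None = None,
    out_size: int = 227,
    rotations: tuple[int, ...] = (0, 90, 180, 270),
    specimen: str = "spec0",
) -> tuple[pd.DataFrame, list[np.ndarray]]:
    """Materialize the tiles of a (small) cubic volume plus their manifest.

    Defaults derive crop from the volume (largest even size fitting every
    sliced plane) with subgraph = crop // 2; tiles are resized to
    ``out_size`` squared with bilinear interpolation and rotated by exact
    90-degree array rotations.  Tiles are returned in manifest order.
    """
    vol = np.asarray(volume, dtype=float)
    if vol.ndim != 3:
        raise ValueError("volume must be 3D")
    if crop is None:
        crop = min(vol.shape) - (min(vol.shape) % 2)
    if subgraph is None:
        subgraph = crop // 2
    manifest = tile_manifest(vol.shape, crop, subgraph, rotations, specimen)
    axes = {"transverse": 0, "sagittal": 2, "coronal": 1}
    tiles: list[np.ndarray] = []
    resize_cache: dict[tuple[str, int, int], np.ndarray] = {}
    for rec in manifest.itertuples(index=False):
        key = (rec.orientation, rec.slice_index, rec.quadrant)
        if key not in resize_cache:
            sl = np.take(vol, rec.slice_index, axis=axes[rec.orientation])
            sl = _center_crop(sl, crop)
            r, c = divmod(rec.quadrant, 2)
            quad = sl[r * subgraph:(r + 1) * subgraph, c * subgraph:(c + 1) * subgraph]
            resize_cache[key] = resize(quad, (out_size, out_size), order=1,
                                       anti_aliasing=False)
        tiles.append(np.rot90(resize_cache[key], k=rec.rotation_deg // 90))
    return manifest, tiles


def split_dataset(
    manifest: pd.DataFrame,
    ratios: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
) -> pd.DataFrame:
    """Assign train/val/test splits at the specimen level.

    All tiles of a specimen share one split (no leakage across splits);
    specimen counts match the requested proportions to within integer
    rounding (largest-remainder apportionment) and the assignment is
    reproducible under ``seed``.
    """
    ratios = tuple(float(r) for r in ratios)
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"split ratios must sum to 1, got {sum(ratios)}")
    if any(r < 0 for r in ratios):
        raise ValueError("split ratios must be non-negative")
    specimens = manifest["specimen"].unique()
    rng = np.random.default_rng(seed)
    shuffled = rng.permutation(specimens)
    n = len(shuffled)
    exact = np.array(ratios) * n
    counts = np.floor(exact).astype(int)
    for i in np.argsort(-(exact - counts))[: n - counts.sum()]:
        counts[i] += 1
    names = ("train", "val", "test")
    assignment: dict = {}
    start = 0
    for name, cnt in zip(names, counts):
        for s in shuffled[start:start + cnt]:
            assignment[s] = name
        start += cnt
    out = manifest.copy()
    out["split"] = out["specimen"].map(assignment)
    return out


def dataset_size(n_specimens: int, tiles_per_specimen: int) -> int:
    """Total image count: specimens x tiles-per-specimen."""
    if n_specimens < 0 or tiles_per_specimen < 0:
        raise ValueError("counts must be non-negative")
    return int(n_specimens) * int(tiles_per_specimen)
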