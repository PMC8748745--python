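"""Volumetric image I/O and tiled-inference plumbing.

Volumes are 3D arrays in (Z, Y, X) axis order, 0-based. Two on-disk dialects
are supported: single-channel multi-page TIFF and HDF5 (one 3D dataset per
key). Tiling splits a large volume into overlapping cuboids whose *core*
regions exactly partition the volume, so that per-tile network predictions
can be stitched back seam-free by discarding the overlap margins.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional, Sequence

import h5py
import numpy as np
import tifffile

__all__ = [
    "IntensityVolume",
    "LabelVolume",
    "TileLayout",
    "read_intensity_volume",
    "read_label_volume",
    "write_intensity_volume",
    "write_label_volume",
    "plan_tiles",
    "stitch_probability_tiles",
]


class VolumeFormatError(ValueError):
    """Raised for unreadable files or data that is not a 3D volume."""


@dataclasses.dataclass
class IntensityVolume:
    """A 3D scalar image, axis order (Z, Y, X).

    Parameters
    ----------
    data
        Finite real intensities. Integer input is converted to float32
        without rescaling.
    voxel_size
        Optional physical spacing per axis in micrometers.
    """

    data: np.ndarray
    voxel_size: Optional[tuple[float, float, float]] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise VolumeFormatError(
                f"non-3D data: expected a (Z, Y, X) volume, got shape {self.data.shape}"
            )
        if self.data.dtype.kind in "iub":
            self.data = self.data.astype(np.float32)
        if not np.all(np.isfinite(self.data)):
            raise ValueError("intensity volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclasses.dataclass
class LabelVolume:
    """A 3D non-negative integer instance map; 0 is background/unassigned."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise VolumeFormatError(
                f"non-3D data: expected a (Z, Y, X) label volume, got shape {self.labels.shape}"
            )
        if self.labels.dtype.kind not in "iu":
            raise ValueError("label volume must be integer-typed")
        if self.labels.size and self.labels.min() < 0:
            raise ValueError("label volume contains negative labels")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def label_ids(self) -> np.ndarray:
        """Sorted nonzero labels present in the volume."""
        ids = np.unique(self.labels)
        return ids[ids != 0]


@dataclasses.dataclass
class TileLayout:
    """Overlapping tiles whose core regions exactly partition a volume.

    ``tiles`` is a list of ``(origin, core)`` pairs, where ``origin`` is the
    tile's low corner and both tile and core are half-open index boxes
    ``(start, stop)`` per axis in full-volume coordinates.
    """

    extent: tuple[int, int, int]
    tile_extent: tuple[int, int, int]
    overlap: tuple[int, int, int]
    tiles: list[tuple[tuple[int, int, int], tuple[tuple[int, int], ...]]]


def _as_triple(v: Sequence[int], name: str) -> tuple[int, int, int]:
    t = tuple(int(x) for x in v)
    if len(t) != 3:
        raise ValueError(f"{name} must have 3 entries, got {len(t)}")
    return t  # type: ignore[return-value]


def read_intensity_volume(path, dataset_key: Optional[str] = None) -> IntensityVolume:
    """Read a 3D intensity volume from multi-page TIFF or HDF5.

    ``dataset_key`` is required for HDF5 files and ignored for TIFF.
    """
    arr = _read_array(path, dataset_key)
    return IntensityVolume(arr)


def read_label_volume(path, dataset_key: Optional[str] = None) -> LabelVolume:
    """Read a 3D integer label volume (same dialects as intensities)."""
    arr = _read_array(path, dataset_key)
    if arr.dtype.kind not in "iu":
        if not np.all(arr == np.round(arr)):
            raise VolumeFormatError(f"{path}: label volume holds non-integer values")
        arr = arr.astype(np.int64)
    return LabelVolume(arr)


def _read_array(path, dataset_key: Optional[str]) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    suffix = path.suffix.lower()
    if suffix in (".h5", ".hdf5", ".hdf"):
        if dataset_key is None:
            raise ValueError(f"{path}: dataset_key is required for HDF5 input")
        with h5py.File(path, "r") as f:
            if dataset_key not in f:
                raise KeyError(f"{path}: no dataset {dataset_key!r}")
            arr = f[dataset_key][()]
    elif suffix in (".tif", ".tiff"):
        try:
            arr = tifffile.imread(path)
        except Exception as exc:  # pragma: no cover - tifffile error text varies
            raise VolumeFormatError(f"{path}: unreadable TIFF ({exc})") from exc
    else:
        raise VolumeFormatError(f"{path}: unsupported format {suffix!r} (use TIFF or HDF5)")
    arr = np.asarray(arr)
    if arr.ndim != 3:
        raise VolumeFormatError(
            f"{path}: non-3D data (shape {arr.shape}); expected a (Z, Y, X) stack"
        )
    return arr


def _label_dtype(max_label: int) -> np.dtype:
    for dt in (np.uint8, np.uint16, np.uint32, np.uint64):
        if max_label <= np.iinfo(dt).max:
            return np.dtype(dt)
    raise ValueError("label exceeds uint64 range")


def write_label_volume(labels: LabelVolume, path, dataset_key: str = "labels") -> None:
    """Write labels as TIFF/HDF5 with the narrowest unsigned dtype that fits."""
    arr = labels.labels
    out = arr.astype(_label_dtype(int(arr.max()) if arr.size else 0))
    _write_array(out, path, dataset_key)


def write_intensity_volume(volume: IntensityVolume, path, dataset_key: str = "intensity") -> None:
    _write_array(volume.data.astype(np.float32), path, dataset_key)


def _write_array(arr: np.ndarray, path, dataset_key: str) -> None:
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".h5", ".hdf5", ".hdf"):
        with h5py.File(path, "w") as f:
            f.create_dataset(dataset_key, data=arr)
    elif suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, arr, photometric="minisblack")
    else:
        raise VolumeFormatError(f"{path}: unsupported format {suffix!r} (use TIFF or HDF5)")


def plan_tiles(
    extent: Sequence[int], tile_extent: Sequence[int], overlap: Sequence[int]
) -> TileLayout:
    """Plan overlapping tiles over a volume of the given extent.

    Tiles larger than the volume along an axis are clamped to the volume.
    Along each axis tile origins advance by ``tile - overlap``; the last tile
    is shifted inward so it fits. Core boundaries are placed at the midpoints
    of consecutive tile overlaps, so cores abut exactly and partition the
    volume while every core lies strictly inside its tile.
    """
    extent = _as_triple(extent, "extent")
    tile_extent = _as_triple(tile_extent, "tile_extent")
    overlap = _as_triple(overlap, "overlap")
    if any(e < 1 for e in extent):
        raise ValueError(f"extent must be >= 1 per axis, got {extent}")
    tile_extent = tuple(min(t, e) for t, e in zip(tile_extent, extent))
    if any(o < 0 or (o >= t and e > t) for o, t, e in zip(overlap, tile_extent, extent)):
        raise ValueError(f"overlap {overlap} must be >= 0 and < tile extent {tile_extent}")

    per_axis: list[list[tuple[int, int, int]]] = []  # (origin, core_start, core_stop)
    for e, t, o in zip(extent, tile_extent, overlap):
        step = max(t - o, 1)
        origins = list(range(0, max(e - t, 0) + 1, step))
        if origins[-1] + t < e:
            origins.append(e - t)
        segs = []
        for i, org in enumerate(origins):
            lo = 0 if i == 0 else (origins[i - 1] + t + org) // 2
            hi = e if i == len(origins) - 1 else (org + t + origins[i + 1]) // 2
            segs.append((org, lo, hi))
        per_axis.append(segs)

    tiles = []
    for sz in per_axis[0]:
        for sy in per_axis[1]:
            for sx in per_axis[2]:
                origin = (sz[0], sy[0], sx[0])
                core = ((sz[1], sz[2]), (sy[1], sy[2]), (sx[1], sx[2]))
                tiles.append((origin, core))
    return TileLayout(extent=extent, tile_extent=tile_extent, overlap=overlap, tiles=tiles)


def stitch_probability_tiles(layout: TileLayout, tiles: list[np.ndarray]) -> np.ndarray:
    """Assemble per-tile class-probability cuboids into one full volume.

    Each tile array has shape (C,) + tile_extent (clipped at the volume
    boundary). Only the core region of each tile contributes; overlap
    margins are discarded, which removes seam effects at tile interfaces.
    """
    if len(tiles) != len(layout.tiles):
        raise ValueError(f"expected {len(layout.tiles)} tiles, got {len(tiles)}")
    n_classes = tiles[0].shape[0]
    out = np.empty((n_classes,) + layout.extent, dtype=tiles[0].dtype)
    filled = np.zeros(layout.extent, dtype=bool)
    for (origin, core), tile in zip(layout.tiles, tiles):
        tz = tuple(min(layout.tile_extent[a], layout.extent[a] - origin[a]) for a in range(3))
        if tile.shape[1:] != tz:
            raise ValueError(f"tile shape {tile.shape[1:]} does not match layout extent {tz}")
        src = tuple(slice(core[a][0] - origin[a], core[a][1] - origin[a]) for a in range(3))
        dst = tuple(slice(core[a][0], core[a][1]) for a in range(3))
        out[(slice(None),) + dst] = tile[(slice(None),) + src]
        filled[dst] = True
    if not filled.all():  # partition invariant; should be unreachable
        raise AssertionError("tile cores do not cover the volume")
    return out
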