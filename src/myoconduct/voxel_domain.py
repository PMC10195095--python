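"""Voxel-grid data types, volume I/O, and substack extraction.

All volumes in this package live on a common isotropic voxel grid and are
indexed ``array[x, y, z]``. The axes carry a fixed anatomical meaning that
every downstream stage relies on:

* x — *normal* direction, i.e. normal to the interlaminar cleft planes,
* y — *longitudinal* direction, the myocyte long axis,
* z — *transverse* direction, across myocytes within the laminar sheet.

Voxel centers sit at ``(index + 0.5) * spacing`` so that geometric
quantities (projection distances, moments of inertia) are unambiguous.

On disk, volumes are stored either as multi-page TIFF (one page per
z-slice, spacing in a small JSON sidecar) or as HDF5 (one 3D dataset per
channel, spacing in meters as a dataset attribute).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import tifffile

from .errors import (
    AnisotropicSpacingError,
    DatasetNotFoundError,
    MissingSpacingError,
    NonVolumeDataError,
    SubstackExtentError,
)

#: Fixed mapping from anatomical role to array axis.
AXIS_ROLES: dict[str, int] = {"normal": 0, "longitudinal": 1, "transverse": 2}

#: Names of the tissue-class masks carried by :class:`TissueLabels`.
LABEL_CLASSES = ("vessel", "fibroblast", "myofibroblast", "cleft")

_SPACING_ATTR = "spacing_m"


@dataclass(frozen=True)
class GridSpec:
    """Geometry of an isotropic voxel grid.

    Parameters
    ----------
    shape
        Number of voxels ``(nx, ny, nz)`` along the normal, longitudinal
        and transverse axes.
    spacing
        Edge length of a voxel in meters (isotropic).
    """

    shape: tuple[int, int, int]
    spacing: float

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        object.__setattr__(self, "shape", shape)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ValueError(f"grid shape must be three entries >= 1, got {shape}")
        if not (self.spacing > 0):
            raise ValueError(f"voxel spacing must be positive, got {self.spacing}")

    @property
    def axis_roles(self) -> dict[str, int]:
        return dict(AXIS_ROLES)

    @property
    def n_voxels(self) -> int:
        nx, ny, nz = self.shape
        return nx * ny * nz

    def extent(self, axis: int) -> float:
        """Physical length of the grid along ``axis`` in meters."""
        return self.shape[axis] * self.spacing


def _check_shape(grid: GridSpec, arr: np.ndarray, name: str) -> None:
    if arr.shape != grid.shape:
        raise ValueError(f"{name} shape {arr.shape} does not match grid {grid.shape}")


@dataclass
class SegmentVolume:
    """Myocyte instance segmentation: 0 = background, k > 0 = myocyte k."""

    grid: GridSpec
    ids: np.ndarray

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        if not np.issubdtype(self.ids.dtype, np.integer):
            raise ValueError("segment ids must be integer-typed")
        _check_shape(self.grid, self.ids, "ids")
        if self.ids.size and self.ids.min() < 0:
            raise ValueError("segment ids must be non-negative")

    def myocyte_ids(self) -> np.ndarray:
        """Sorted array of positive myocyte IDs present in the volume."""
        ids = np.unique(self.ids)
        return ids[ids > 0]


@dataclass
class TissueLabels:
    """Co-registered boolean masks for the non-myocyte tissue classes.

    The vessel/fibroblast/myofibroblast masks are cell classes and must be
    pairwise disjoint; the cleft mask marks extracellular interlaminar
    clefts and must not intersect any cell class.
    """

    grid: GridSpec
    vessel: np.ndarray
    fibroblast: np.ndarray
    myofibroblast: np.ndarray
    cleft: np.ndarray

    def __post_init__(self) -> None:
        for name in LABEL_CLASSES:
            arr = np.asarray(getattr(self, name), dtype=bool)
            _check_shape(self.grid, arr, name)
            setattr(self, name, arr)

    @classmethod
    def empty(cls, grid: GridSpec) -> "TissueLabels":
        z = np.zeros(grid.shape, dtype=bool)
        return cls(grid, z.copy(), z.copy(), z.copy(), z.copy())


@dataclass
class IntensityVolume:
    """A scalar fluorescence volume (e.g. the Cx43 channel)."""

    grid: GridSpec
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        _check_shape(self.grid, self.values, "values")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("intensity values must be finite")
        if self.values.size and self.values.min() < 0:
            raise ValueError("intensity values must be non-negative")


Volume = SegmentVolume | TissueLabels | IntensityVolume


def _resolve_spacing(spacing) -> float:
    if spacing is None:
        raise MissingSpacingError(
            "voxel spacing not found; provide it via the sidecar file, HDF5 "
            "attribute, or the `spacing` argument (meters)"
        )
    arr = np.atleast_1d(np.asarray(spacing, dtype=float))
    if arr.size not in (1, 3):
        raise MissingSpacingError(f"cannot interpret spacing {spacing!r}")
    if arr.size == 3 and not (arr[0] == arr[1] == arr[2]):
        raise AnisotropicSpacingError(f"anisotropic spacing {arr.tolist()} is not supported")
    return float(arr[0])


def _wrap(arr: np.ndarray, spacing: float) -> Volume:
    if arr.ndim != 3:
        raise NonVolumeDataError(f"expected a 3D dataset, got ndim={arr.ndim}")
    grid = GridSpec(arr.shape, spacing)
    if np.issubdtype(arr.dtype, np.bool_):
        arr = arr.astype(np.uint8)
    if np.issubdtype(arr.dtype, np.integer):
        return SegmentVolume(grid, arr)
    return IntensityVolume(grid, arr.astype(np.float64))


def read_volume(path, dataset: str | None = None, spacing: float | None = None) -> Volume:
    """Read a 3D volume from a multi-page TIFF or an HDF5 file.

    Integer data yield a :class:`SegmentVolume`, float data an
    :class:`IntensityVolume`. An HDF5 file that contains the four class
    datasets ``vessel``, ``fibroblast``, ``myofibroblast`` and ``cleft``
    (and ``dataset`` is not given) is returned as :class:`TissueLabels`.

    Parameters
    ----------
    path
        Input file; suffix selects the format (.h5/.hdf5 vs .tif/.tiff).
    dataset
        HDF5 dataset name. If omitted, the label group is detected, else a
        single 3D dataset is expected.
    spacing
        Voxel edge length in meters; overrides on-disk metadata.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume file: {path}")
    if path.suffix.lower() in (".h5", ".hdf5"):
        return _read_hdf5(path, dataset, spacing)
    return _read_tiff(path, spacing)


def _read_hdf5(path: Path, dataset: str | None, spacing) -> Volume:
    with h5py.File(path, "r") as f:
        names = [k for k in f.keys() if isinstance(f[k], h5py.Dataset)]
        if dataset is None and all(c in names for c in LABEL_CLASSES):
            masks = {}
            sp = spacing
            for c in LABEL_CLASSES:
                ds = f[c]
                if sp is None:
                    sp = ds.attrs.get(_SPACING_ATTR)
                masks[c] = np.asarray(ds[()]).astype(bool)
            sp = _resolve_spacing(sp)
            if masks["vessel"].ndim != 3:
                raise NonVolumeDataError("label datasets must be 3D")
            grid = GridSpec(masks["vessel"].shape, sp)
            return TissueLabels(grid, **masks)
        if dataset is None:
            if len(names) != 1:
                raise DatasetNotFoundError(
                    f"{path} holds datasets {names}; specify which one to read"
                )
            dataset = names[0]
        if dataset not in f:
            raise DatasetNotFoundError(f"dataset not found: {dataset!r} in {path}")
        ds = f[dataset]
        if spacing is None:
            spacing = ds.attrs.get(_SPACING_ATTR)
        return _wrap(np.asarray(ds[()]), _resolve_spacing(spacing))


def _read_tiff(path: Path, spacing) -> Volume:
    pages = tifffile.imread(path)
    if pages.ndim == 2:  # single page
        pages = pages[None]
    if pages.ndim != 3:
        raise NonVolumeDataError(f"expected a 3D TIFF stack, got ndim={pages.ndim}")
    if spacing is None:
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            spacing = json.loads(sidecar.read_text()).get(_SPACING_ATTR)
    # pages are (z, y, x) -> (x, y, z)
    return _wrap(np.ascontiguousarray(pages.transpose(2, 1, 0)), _resolve_spacing(spacing))


def write_volume(path, volume: Volume, dataset: str = "volume") -> None:
    """Write a volume to TIFF (+ JSON spacing sidecar) or HDF5."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            if isinstance(volume, TissueLabels):
                for c in LABEL_CLASSES:
                    ds = f.create_dataset(c, data=getattr(volume, c))
                    ds.attrs[_SPACING_ATTR] = volume.grid.spacing
            else:
                arr = volume.ids if isinstance(volume, SegmentVolume) else volume.values
                ds = f.create_dataset(dataset, data=arr)
                ds.attrs[_SPACING_ATTR] = volume.grid.spacing
        return
    if isinstance(volume, TissueLabels):
        raise NonVolumeDataError("TissueLabels require HDF5 (one dataset per class)")
    arr = volume.ids if isinstance(volume, SegmentVolume) else volume.values
    tifffile.imwrite(
        path, np.ascontiguousarray(arr.transpose(2, 1, 0)), photometric="minisblack"
    )
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({_SPACING_ATTR: volume.grid.spacing}))


def _slice_volume(volume: Volume, sl: tuple[slice, slice, slice]) -> Volume:
    spacing = volume.grid.spacing
    if isinstance(volume, SegmentVolume):
        sub = volume.ids[sl]
        return SegmentVolume(GridSpec(sub.shape, spacing), sub.copy())
    if isinstance(volume, IntensityVolume):
        sub = volume.values[sl]
        return IntensityVolume(GridSpec(sub.shape, spacing), sub.copy())
    masks = {c: getattr(volume, c)[sl].copy() for c in LABEL_CLASSES}
    grid = GridSpec(masks["vessel"].shape, spacing)
    return TissueLabels(grid, **masks)


def extract_substacks(volume: Volume, extent_xy: float) -> list[Volume]:
    """Tile a volume into non-overlapping substacks of ``extent_xy`` in x and y.

    Each substack spans the full z depth. Tiling is anchored at index 0;
    trailing voxels that do not fill a whole tile are discarded. Myocyte
    IDs are preserved (no relabeling), so substacks remain comparable to
    the parent volume.

    Parameters
    ----------
    volume
        Any grid-typed volume.
    extent_xy
        Substack edge length in meters along x and y.
    """
    grid = volume.grid
    tol = 1.0 + 1e-9  # guard against float rounding of n * spacing
    if extent_xy > grid.extent(0) * tol or extent_xy > grid.extent(1) * tol:
        raise SubstackExtentError(
            f"substack extent {extent_xy} m exceeds volume extents "
            f"({grid.extent(0)}, {grid.extent(1)}) m"
        )
    k = int(round(extent_xy / grid.spacing))
    n_x = int(grid.extent(0) / extent_xy + 1e-9)
    n_y = int(grid.extent(1) / extent_xy + 1e-9)
    out = []
    for iy in range(n_y):
        for ix in range(n_x):
            sl = (
                slice(ix * k, (ix + 1) * k),
                slice(iy * k, (iy + 1) * k),
                slice(None),
            )
            out.append(_slice_volume(volume, sl))
    return out
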