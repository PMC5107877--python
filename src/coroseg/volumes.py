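"""Domain types, grid geometry, and volume I/O.

Conventions used throughout the package
---------------------------------------
* Voxel indices are 0-based and in ``(k, j, i)`` = ``(z, y, x)`` array order.
* ``spacing`` is ``(sz, sy, sx)`` in millimetres per voxel.
* World coordinates are ``(x, y, z)`` in millimetres; ``origin`` is the world
  position of voxel ``(0, 0, 0)``.
* ``voxel_to_world((k, j, i)) = origin + (i*sx, j*sy, k*sz)`` — axis-aligned
  grids only (no direction cosines).

Supported on-disk formats: NIfTI-1 (``.nii``/``.nii.gz``, via nibabel) and
MetaImage (``.mha``/``.mhd``, via SimpleITK).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence, Tuple

import numpy as np


# ---------------------------------------------------------------------------
# Exceptions
# ---------------------------------------------------------------------------

class CorosegError(Exception):
    """Base class for all package errors."""


class FormatError(CorosegError):
    """Unreadable file or unsupported volume format."""


class GeometryError(CorosegError):
    """Mismatched grids or out-of-bounds indices."""


class ParameterError(CorosegError):
    """Invalid parameter value."""


class OptimizationError(CorosegError):
    """Registration optimizer failure (non-finite cost, empty sample set)."""


class PipelineError(CorosegError):
    """A pipeline stage could not produce its contracted output."""


class NoSeedsError(PipelineError):
    """Seed detection produced an empty seed set."""


# ---------------------------------------------------------------------------
# Grid geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Grid:
    """Geometry of a regular 3D voxel lattice.

    Parameters
    ----------
    shape : (nz, ny, nx) voxel counts.
    spacing : (sz, sy, sx) mm per voxel; all components > 0.
    origin : world (x, y, z) mm position of voxel (0, 0, 0).
    """

    shape: Tuple[int, int, int]
    spacing: Tuple[float, float, float]
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        shape = tuple(int(s) for s in self.shape)
        spacing = tuple(float(s) for s in self.spacing)
        origin = tuple(float(o) for o in self.origin)
        if len(shape) != 3 or len(spacing) != 3 or len(origin) != 3:
            raise GeometryError("Grid requires 3D shape/spacing/origin")
        if any(s < 1 for s in shape):
            raise GeometryError(f"shape components must be >= 1, got {shape}")
        if any(s <= 0 for s in spacing):
            raise GeometryError(f"spacing components must be > 0, got {spacing}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    # -- coordinate transforms ------------------------------------------------

    def contains_index(self, index: Sequence[int]) -> bool:
        k, j, i = index
        nz, ny, nx = self.shape
        return 0 <= k < nz and 0 <= j < ny and 0 <= i < nx

    def world_extent(self) -> Tuple[np.ndarray, np.ndarray]:
        """(min_corner, max_corner) of the voxel-centre bounding box, (x,y,z) mm."""
        nz, ny, nx = self.shape
        sz, sy, sx = self.spacing
        lo = np.asarray(self.origin, float)
        hi = lo + np.array([(nx - 1) * sx, (ny - 1) * sy, (nz - 1) * sz])
        return lo, hi

    def index_grid_world(self) -> np.ndarray:
        """World coordinates of every voxel, shape ``(*grid.shape, 3)`` (x,y,z)."""
        nz, ny, nx = self.shape
        sz, sy, sx = self.spacing
        ox, oy, oz = self.origin
        zs = oz + np.arange(nz) * sz
        ys = oy + np.arange(ny) * sy
        xs = ox + np.arange(nx) * sx
        Z, Y, X = np.meshgrid(zs, ys, xs, indexing="ij")
        return np.stack([X, Y, Z], axis=-1)


class GridPoint(NamedTuple):
    """A voxel index ``(k, j, i)`` with an optional cached world position."""

    index: Tuple[int, int, int]
    world: Optional[Tuple[float, float, float]] = None


def voxel_to_world(grid: Grid, index: Sequence[int]) -> Tuple[float, float, float]:
    """World (x, y, z) mm position of voxel ``(k, j, i)``.

    Raises
    ------
    GeometryError
        If the index lies outside the grid.
    """
    if not grid.contains_index(index):
        raise GeometryError(f"index {tuple(index)} out of bounds for shape {grid.shape}")
    k, j, i = index
    sz, sy, sx = grid.spacing
    ox, oy, oz = grid.origin
    return (ox + i * sx, oy + j * sy, oz + k * sz)


def world_to_voxel(grid: Grid, world: Sequence[float]) -> Tuple[float, float, float]:
    """Continuous voxel coordinates ``(k, j, i)`` of a world (x, y, z) point."""
    x, y, z = world
    sz, sy, sx = grid.spacing
    ox, oy, oz = grid.origin
    return ((z - oz) / sz, (y - oy) / sy, (x - ox) / sx)


def indices_to_world(grid: Grid, indices: np.ndarray) -> np.ndarray:
    """Vectorized voxel→world: ``indices`` (N, 3) in (k,j,i) → (N, 3) (x,y,z) mm."""
    idx = np.asarray(indices, float)
    sz, sy, sx = grid.spacing
    ox, oy, oz = grid.origin
    out = np.empty_like(idx)
    out[:, 0] = ox + idx[:, 2] * sx
    out[:, 1] = oy + idx[:, 1] * sy
    out[:, 2] = oz + idx[:, 0] * sz
    return out


def world_to_indices(grid: Grid, world: np.ndarray) -> np.ndarray:
    """Vectorized world→voxel: ``world`` (N, 3) (x,y,z) mm → (N, 3) continuous (k,j,i)."""
    w = np.asarray(world, float)
    sz, sy, sx = grid.spacing
    ox, oy, oz = grid.origin
    out = np.empty_like(w)
    out[:, 0] = (w[:, 2] - oz) / sz
    out[:, 1] = (w[:, 1] - oy) / sy
    out[:, 2] = (w[:, 0] - ox) / sx
    return out


# ---------------------------------------------------------------------------
# Volume and mask containers
# ---------------------------------------------------------------------------

@dataclass
class Volume3D:
    """A scalar 3D image on a :class:`Grid`.

    ``data`` holds Hounsfield units for CTA inputs and arbitrary response
    units after filtering.  HU calibration is assumed already applied by the
    source file; intensities are stored signed and unmodified.
    """

    data: np.ndarray
    grid: Grid

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise GeometryError(f"Volume3D data must be 3D, got ndim={self.data.ndim}")
        if tuple(self.data.shape) != tuple(self.grid.shape):
            raise GeometryError(
                f"data shape {self.data.shape} != grid shape {self.grid.shape}")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.grid.shape

    @property
    def spacing(self) -> Tuple[float, float, float]:
        return self.grid.spacing

    @property
    def origin(self) -> Tuple[float, float, float]:
        return self.grid.origin

    def with_data(self, data: np.ndarray) -> "Volume3D":
        """New volume with the same grid (derived volumes keep the input grid)."""
        return Volume3D(np.asarray(data), self.grid)


@dataclass
class BinaryMask3D:
    """A boolean label map sharing the geometry of a companion :class:`Volume3D`."""

    data: np.ndarray
    grid: Grid

    def __post_init__(self):
        arr = np.asarray(self.data)
        if arr.dtype != np.bool_:
            uniq = np.unique(arr)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ParameterError(
                    f"mask values must be exactly {{0, 1}}, got {uniq[:10]}")
            arr = arr.astype(bool)
        if tuple(arr.shape) != tuple(self.grid.shape):
            raise GeometryError(
                f"mask shape {arr.shape} != grid shape {self.grid.shape}")
        self.data = arr

    @property
    def shape(self):
        return self.grid.shape

    @property
    def spacing(self):
        return self.grid.spacing

    def count(self) -> int:
        return int(self.data.sum())


def require_same_grid(*objs) -> Grid:
    """Assert that all volumes/masks share one grid; return it."""
    grids = [o.grid for o in objs]
    for g in grids[1:]:
        if g != grids[0]:
            raise GeometryError(f"grid mismatch: {grids[0]} vs {g}")
    return grids[0]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_NIFTI_EXT = (".nii", ".nii.gz")
_META_EXT = (".mha", ".mhd")


def _ext_of(path: str) -> str:
    low = str(path).lower()
    if low.endswith(".nii.gz"):
        return ".nii.gz"
    return os.path.splitext(low)[1]


def load_volume(path) -> Volume3D:
    """Load a NIfTI-1 or MetaImage volume.

    Spacing and origin are taken from the file header; intensities are not
    modified.  Raises :class:`FormatError` for missing, truncated, or
    unsupported files.
    """
    path = str(path)
    if not os.path.exists(path):
        raise FormatError(f"no such file: {path}")
    ext = _ext_of(path)
    try:
        if ext in _NIFTI_EXT:
            return _load_nifti(path)
        if ext in _META_EXT:
            return _load_meta(path)
    except CorosegError:
        raise
    except Exception as exc:  # corrupt/truncated file from the backend reader
        raise FormatError(f"cannot read volume {path!r}: {exc}") from exc
    raise FormatError(f"unsupported volume format {ext!r} for {path!r} "
                      "(expected .nii, .nii.gz, .mha or .mhd)")


def save_volume(vol: Volume3D, path) -> None:
    """Write a volume readable by :func:`load_volume`; header records spacing/origin."""
    path = str(path)
    ext = _ext_of(path)
    parent = os.path.dirname(os.path.abspath(path))
    if not os.path.isdir(parent):
        raise IOError(f"parent directory does not exist: {parent}")
    if ext in _NIFTI_EXT:
        _save_nifti(vol, path)
    elif ext in _META_EXT:
        _save_meta(vol, path)
    else:
        raise FormatError(f"unsupported volume format {ext!r} for {path!r}")


def _load_nifti(path: str) -> Volume3D:
    import nibabel as nib

    img = nib.load(path)
    arr = np.asanyarray(img.dataobj)  # (x, y, z) storage order
    if arr.ndim != 3:
        raise FormatError(f"{path!r}: expected a 3D volume, got ndim={arr.ndim}")
    zooms = img.header.get_zooms()[:3]
    affine = img.affine
    origin = tuple(float(v) for v in affine[:3, 3])
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    data = np.ascontiguousarray(np.transpose(arr, (2, 1, 0)))
    return Volume3D(data, Grid(data.shape, spacing, origin))


def _save_nifti(vol: Volume3D, path: str) -> None:
    import nibabel as nib

    sz, sy, sx = vol.spacing
    affine = np.diag([sx, sy, sz, 1.0])
    affine[:3, 3] = vol.origin
    arr = np.ascontiguousarray(np.transpose(vol.data, (2, 1, 0)))
    img = nib.Nifti1Image(arr, affine)
    img.header.set_zooms((sx, sy, sz))
    nib.save(img, path)


def _load_meta(path: str) -> Volume3D:
    import SimpleITK as sitk

    img = sitk.ReadImage(path)
    data = sitk.GetArrayFromImage(img)  # (z, y, x)
    if data.ndim != 3:
        raise FormatError(f"{path!r}: expected a 3D volume, got ndim={data.ndim}")
    sp = img.GetSpacing()       # (sx, sy, sz)
    og = img.GetOrigin()        # (x, y, z)
    grid = Grid(data.shape, (float(sp[2]), float(sp[1]), float(sp[0])),
                (float(og[0]), float(og[1]), float(og[2])))
    return Volume3D(np.ascontiguousarray(data), grid)


def _save_meta(vol: Volume3D, path: str) -> None:
    import SimpleITK as sitk

    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.data))
    sz, sy, sx = vol.spacing
    img.SetSpacing((sx, sy, sz))
    img.SetOrigin(tuple(vol.origin))
    sitk.WriteImage(img, path)
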