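"""NIfTI volume I/O and grid-compatibility checks.

All pipeline stages operate on volumes that are already co-registered to a
single voxel grid; this module loads them, enforces that contract, and never
resamples. Coordinates are 0-based voxel indices; world coordinates are
``origin + index * spacing`` (one shared orientation, no axis flipping).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "VolumeGrid",
    "BinaryMask",
    "LabelMap",
    "GridMismatchError",
    "VolumeValidationError",
    "read_volume",
    "read_mask",
    "read_labelmap",
    "write_volume",
    "check_same_grid",
]


class VolumeValidationError(ValueError):
    """Raised when a volume violates its type contract (dimensionality, values)."""


class GridMismatchError(ValueError):
    """Raised when two volumes do not share a voxel grid; names the offending field."""


@dataclass
class VolumeGrid:
    """A 3D scalar image with voxel spacing and origin in millimetres.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Scalar intensities, arbitrary units. Must be finite.
    spacing : tuple of 3 floats
        Voxel edge lengths in mm; all strictly positive.
    origin : tuple of 3 floats
        World coordinate of voxel (0, 0, 0) in mm.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise VolumeValidationError(
                f"volume must be 3D, got {self.data.ndim}D with shape {self.data.shape}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or len(self.origin) != 3:
            raise VolumeValidationError("spacing and origin must be 3-vectors")
        if any(s <= 0 for s in self.spacing):
            raise VolumeValidationError(f"spacing must be positive, got {self.spacing}")
        if np.issubdtype(self.data.dtype, np.floating) and not np.all(
            np.isfinite(self.data)
        ):
            raise VolumeValidationError("volume contains non-finite voxels")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in millilitres (1 ml = 1000 mm^3)."""
        return float(np.prod(self.spacing)) / 1000.0

    def same_geometry(self, data: np.ndarray) -> "VolumeGrid":
        """A new VolumeGrid carrying ``data`` on this grid."""
        return VolumeGrid(data, self.spacing, self.origin)


@dataclass
class BinaryMask:
    """Voxelwise membership mask: values exactly 0 or 1 on a :class:`VolumeGrid`."""

    grid: VolumeGrid

    def __post_init__(self) -> None:
        vals = np.unique(self.grid.data)
        if not np.all(np.isin(vals, (0, 1))):
            raise VolumeValidationError(
                f"binary mask may only contain 0 and 1, found values {vals[:10]}"
            )
        if self.grid.data.dtype != np.uint8:
            self.grid = VolumeGrid(
                self.grid.data.astype(np.uint8), self.grid.spacing, self.grid.origin
            )

    @property
    def data(self) -> np.ndarray:
        return self.grid.data

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.grid.spacing

    @property
    def origin(self) -> tuple[float, float, float]:
        return self.grid.origin

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    def as_bool(self) -> np.ndarray:
        return self.grid.data.astype(bool)


@dataclass
class LabelMap:
    """Integer label image; label 0 is background."""

    grid: VolumeGrid

    def __post_init__(self) -> None:
        data = self.grid.data
        if not np.issubdtype(data.dtype, np.integer):
            if not np.allclose(data, np.round(data)):
                raise VolumeValidationError("label map contains non-integer values")
            data = np.round(data).astype(np.int32)
        if data.min() < 0:
            raise VolumeValidationError("label map contains negative labels")
        self.grid = VolumeGrid(data.astype(np.int32), self.grid.spacing, self.grid.origin)

    @property
    def data(self) -> np.ndarray:
        return self.grid.data

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.grid.spacing

    @property
    def origin(self) -> tuple[float, float, float]:
        return self.grid.origin

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    def labels(self) -> np.ndarray:
        """Sorted nonzero labels present in the map."""
        u = np.unique(self.grid.data)
        return u[u != 0]


def _affine_from_grid(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    aff[:3, 3] = origin
    return aff


def _grid_from_nifti(img: nib.Nifti1Image, path) -> VolumeGrid:
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise VolumeValidationError(
            f"{path}: expected a 3D volume, got {data.ndim}D with shape {data.shape}"
        )
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(t) for t in img.affine[:3, 3])
    return VolumeGrid(data, spacing, origin)


def read_volume(path) -> VolumeGrid:
    """Read a NIfTI file into a :class:`VolumeGrid` without any resampling.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    VolumeValidationError
        For 2D/4D inputs or non-finite voxel values.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume file: {path}")
    img = nib.load(str(path))
    return _grid_from_nifti(img, path)


def read_mask(path) -> BinaryMask:
    """Read a NIfTI file as a binary mask.

    Any strictly positive voxel maps to 1 and zero stays 0; when values other
    than {0, 1} are encountered the binarization is logged. Negative voxels
    are a contract violation.
    """
    v = read_volume(path)
    data = v.data
    if data.min() < 0:
        raise VolumeValidationError(f"{path}: mask contains negative voxel values")
    vals = np.unique(data)
    if not np.all(np.isin(vals, (0, 1))):
        logger.info("binarizing mask %s: values %s mapped by '> 0'", path, vals[:10])
    return BinaryMask(VolumeGrid((data > 0).astype(np.uint8), v.spacing, v.origin))


def read_labelmap(path) -> LabelMap:
    """Read a NIfTI file as an integer label map (label 0 = background)."""
    v = read_volume(path)
    return LabelMap(v)


def write_volume(v, path) -> None:
    """Write a :class:`VolumeGrid`, :class:`BinaryMask` or :class:`LabelMap` as NIfTI.

    The file round-trips exactly through :func:`read_volume` / :func:`read_mask`.
    """
    if isinstance(v, (BinaryMask, LabelMap)):
        grid = v.grid
    elif isinstance(v, VolumeGrid):
        grid = v
    else:
        raise TypeError(f"cannot write object of type {type(v).__name__}")
    path = Path(path)
    if path.is_dir():
        raise IsADirectoryError(f"cannot write volume to directory path: {path}")
    data = grid.data
    if data.dtype == np.uint8 or data.dtype == np.int32:
        out = data
    elif np.issubdtype(data.dtype, np.integer):
        out = data.astype(np.int32)
    else:
        out = data.astype(np.float64)
    img = nib.Nifti1Image(out, _affine_from_grid(grid.spacing, grid.origin))
    img.header.set_zooms(grid.spacing)
    nib.save(img, str(path))


def check_same_grid(a, b, tol: float = 1e-3) -> None:
    """Assert that two volumes share one voxel grid.

    Registration is performed upstream of this tool; every stage that combines
    two volumes calls this to enforce (not perform) co-registration.

    Parameters
    ----------
    a, b : VolumeGrid, BinaryMask or LabelMap
    tol : float
        Agreement tolerance for spacing and origin, in mm (default 1e-3).

    Raises
    ------
    GridMismatchError
        Naming the first offending field (shape, spacing or origin).
    """
    ga = a.grid if isinstance(a, (BinaryMask, LabelMap)) else a
    gb = b.grid if isinstance(b, (BinaryMask, LabelMap)) else b
    if ga.shape != gb.shape:
        raise GridMismatchError(f"shape mismatch: {ga.shape} vs {gb.shape}")
    if any(abs(x - y) > tol for x, y in zip(ga.spacing, gb.spacing)):
        raise GridMismatchError(f"spacing mismatch: {ga.spacing} vs {gb.spacing}")
    if any(abs(x - y) > tol for x, y in zip(ga.origin, gb.origin)):
        raise GridMismatchError(f"origin mismatch: {ga.origin} vs {gb.origin}")
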