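"""Volume data model, NIfTI-1 I/O, coordinate conversion and resampling.

Every geometric object in the package lives on a :class:`Grid`: a voxel
lattice with a 4x4 voxel-index-to-world affine in RAS+ millimetres.  Voxel
indices are 0-based and refer to voxel *centers*.  All other modules build
on the primitives here; nothing outside this module touches nibabel.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage


class DimensionError(ValueError):
    """Raised when a volume has the wrong number of dimensions."""


@dataclass(frozen=True)
class Grid:
    """A 3D voxel lattice: shape plus voxel-index -> world-mm affine (RAS+)."""

    shape: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s <= 0 for s in shape):
            raise ValueError(f"shape must be 3 positive integers, got {self.shape}")
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if not np.allclose(aff[3], [0, 0, 0, 1]):
            raise ValueError("last affine row must be (0, 0, 0, 1)")
        if abs(np.linalg.det(aff[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        if np.any(np.linalg.norm(aff[:3, :3], axis=0) <= 0):
            raise ValueError("voxel sizes must be strictly positive")
        aff = aff.copy()
        aff.flags.writeable = False
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "affine", aff)

    @property
    def spacing(self) -> np.ndarray:
        """Voxel edge lengths in mm (column norms of the 3x3 block)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def corners_world(self) -> np.ndarray:
        """World coordinates of the 8 outermost voxel centers."""
        hi = np.array(self.shape, dtype=float) - 1.0
        corners = np.array(
            [[i, j, k] for i in (0, hi[0]) for j in (0, hi[1]) for k in (0, hi[2])]
        )
        return self.voxel_to_world(corners)

    def voxel_centers_world(self) -> np.ndarray:
        """World coordinates of all voxel centers, shape ``self.shape + (3,)``."""
        idx = np.indices(self.shape, dtype=float)
        pts = idx.reshape(3, -1).T
        return self.voxel_to_world(pts).reshape(self.shape + (3,))

    def same_as(self, other: "Grid", tol: float = 1e-5) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=tol
        )


@dataclass
class Volume:
    """A 3D scalar image on a :class:`Grid`."""

    grid: Grid
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.shape != self.grid.shape:
            raise DimensionError(
                f"data shape {self.data.shape} != grid shape {self.grid.shape}"
            )


@dataclass
class Volume4D:
    """A 4D timeseries image: ``grid.shape + (T,)`` with repetition time ``tr``."""

    grid: Grid
    data: np.ndarray
    tr: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4 or self.data.shape[:3] != self.grid.shape:
            raise DimensionError(
                f"data shape {self.data.shape} incompatible with grid {self.grid.shape}"
            )
        if self.data.shape[3] < 2:
            raise ValueError("timeseries needs at least 2 timepoints")
        if not self.tr > 0:
            raise ValueError("tr must be positive")

    @property
    def n_timepoints(self) -> int:
        return int(self.data.shape[3])


# --------------------------------------------------------------------------- I/O


def _affine_from_header(img) -> np.ndarray:
    """Best available transform: sform preferred over qform; neither -> error."""
    sform, scode = img.get_sform(coded=True)
    if scode > 0:
        return np.asarray(sform, dtype=float)
    qform, qcode = img.get_qform(coded=True)
    if qcode > 0:
        return np.asarray(qform, dtype=float)
    raise ValueError(f"{img.get_filename()}: neither sform nor qform is set")


def _clean_nan(data: np.ndarray, nan_policy: str, path) -> np.ndarray:
    bad = ~np.isfinite(data)
    if bad.any():
        if nan_policy == "zero":
            data = np.where(bad, 0.0, data)
        else:
            raise ValueError(f"{path}: volume contains non-finite values")
    return data


def load_volume(path, nan_policy: str = "raise") -> Volume:
    """Load a 3D NIfTI-1 file (optionally gzipped), applying scl slope/intercept.

    Parameters
    ----------
    path : path-like
    nan_policy : {"raise", "zero"}
        Non-finite voxels either abort the load or are zero-filled.
    """
    img = nib.load(str(path))
    if img.ndim != 3:
        raise DimensionError(f"{path}: expected 3D volume, got {img.ndim}D")
    affine = _affine_from_header(img)
    data = np.asarray(img.get_fdata(dtype=np.float64))
    data = _clean_nan(data, nan_policy, path)
    return Volume(Grid(img.shape[:3], affine), data)


def load_volume4d(path, nan_policy: str = "raise") -> Volume4D:
    """Load a 4D NIfTI-1 timeseries; ``tr`` is read from pixdim[4]."""
    img = nib.load(str(path))
    if img.ndim != 4:
        raise DimensionError(f"{path}: expected 4D volume, got {img.ndim}D")
    affine = _affine_from_header(img)
    data = np.asarray(img.get_fdata(dtype=np.float64))
    data = _clean_nan(data, nan_policy, path)
    tr = float(img.header.get_zooms()[3])
    return Volume4D(Grid(img.shape[:3], affine), data, tr=tr)


def save_volume(v: Volume | Volume4D, path) -> None:
    """Write a NIfTI-1 file; sets both sform and qform; 4D writes tr to pixdim[4]."""
    path = Path(path)
    if not path.parent.is_dir():
        raise FileNotFoundError(f"directory does not exist: {path.parent}")
    data = v.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(data, np.asarray(v.grid.affine))
    img.header.set_data_dtype(data.dtype)
    img.set_sform(v.grid.affine, code=1)
    img.set_qform(v.grid.affine, code=1)
    if isinstance(v, Volume4D):
        zooms = img.header.get_zooms()
        img.header.set_zooms(zooms[:3] + (float(v.tr),))
    nib.save(img, str(path))


# ------------------------------------------------------------------- resampling

_ORDER = {"nearest": 0, "trilinear": 1}


def _voxel_map(source: Grid, target: Grid) -> tuple[np.ndarray, np.ndarray]:
    """Matrix/offset mapping target voxel indices into source voxel indices."""
    m = np.linalg.inv(source.affine) @ target.affine
    return m[:3, :3], m[:3, 3]


def resample_to_grid(
    v: Volume, target: Grid, method: str = "trilinear", fill: float = 0.0
) -> Volume:
    """Resample a volume onto ``target`` by pulling each target voxel center.

    Both grids must be expressed in the same world frame.  Target voxels whose
    centers map outside the source grid receive ``fill``.
    """
    if method not in _ORDER:
        raise ValueError(f"unknown method {method!r}; use 'nearest' or 'trilinear'")
    matrix, offset = _voxel_map(v.grid, target)
    out = ndimage.affine_transform(
        np.asarray(v.data, dtype=float),
        matrix,
        offset=offset,
        output_shape=target.shape,
        order=_ORDER[method],
        mode="constant",
        cval=fill,
        prefilter=False,
    )
    return Volume(target, out)


def world_to_voxel(g: Grid, points: np.ndarray) -> np.ndarray:
    """World mm -> continuous voxel coordinates (module-level convenience)."""
    return g.world_to_voxel(points)


def voxel_to_world(g: Grid, points: np.ndarray) -> np.ndarray:
    return g.voxel_to_world(points)
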