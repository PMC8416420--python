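"""Coronal slab decomposition and standard-size block placement.

Emulates the brain-cutting bench protocol in silico: the brain is divided
into contiguous coronal slabs of fixed thickness (4 mm by default) along the
anterior-posterior (AP) world axis, and rectangular tissue blocks of a
standard in-plane size (3.8 cm x 3.2 cm by default) are placed on chosen
slabs, anchored to a gross anatomical landmark such as the anterior
commissure.

Slabs are half-open intervals ``[origin + i*t, origin + (i+1)*t)`` in world
AP millimetres; a point exactly on a boundary belongs to the later (higher
index) slab.  The slab test is applied to voxel-center world coordinates, so
slabs remain true coronal slabs even when the voxel grid is oblique to the
world axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .volume import Grid, Volume, save_volume

#: index of the anterior-posterior axis in RAS+ world coordinates (y)
AP_AXIS = 1

#: slab thickness of the emulated brain-cutting protocol, mm
DEFAULT_SLAB_THICKNESS_MM = 4.0

#: in-plane block size (left-right width, inferior-superior height), mm
DEFAULT_BLOCK_SIZE_MM = (38.0, 32.0)

#: the four cortical regions sampled by the standard dementia protocol
STANDARD_ROIS = ("MFG", "MSTG", "IPL", "V1")


class EmptyBlockError(ValueError):
    """Raised when a block specification selects no voxels."""


@dataclass(frozen=True)
class SliceStack:
    """A coronal slab partition of a grid along the world AP axis."""

    grid: Grid
    origin_mm: float
    thickness_mm: float
    n_slabs: int
    axis: int = AP_AXIS

    def slab_interval(self, i: int) -> tuple[float, float]:
        """World-AP half-open interval ``[start, stop)`` of slab ``i``."""
        if not 0 <= i < self.n_slabs:
            raise IndexError(f"slab index {i} not in [0, {self.n_slabs})")
        start = self.origin_mm + i * self.thickness_mm
        return (start, start + self.thickness_mm)


@dataclass(frozen=True)
class BlockSpec:
    """A block to be cut: ROI label, in-plane size/center (mm), slab index."""

    roi_label: str
    slab_index: int
    in_plane_center_mm: tuple[float, float]  # (left-right x, inferior-superior z)
    in_plane_size_mm: tuple[float, float] = DEFAULT_BLOCK_SIZE_MM

    def __post_init__(self) -> None:
        w, h = self.in_plane_size_mm
        if not (w > 0 and h > 0):
            raise ValueError("in_plane_size_mm must be strictly positive")


@dataclass
class BlockMask:
    """A binary sampled-block volume with its sampling provenance."""

    grid: Grid
    data: np.ndarray
    roi_label: str = ""
    method: str = "target"  # subject_specific | target | reference | guided | optimal
    slab_index: int | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.shape != self.grid.shape:
            raise ValueError("mask shape does not match grid")
        vals = np.unique(self.data)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("mask values must be 0/1")
        self.data = self.data.astype(np.uint8)

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())

    @property
    def volume_mm3(self) -> float:
        return self.voxel_count * self.grid.voxel_volume_mm3

    def centroid_world(self) -> np.ndarray:
        idx = np.argwhere(self.data > 0)
        if idx.size == 0:
            raise EmptyBlockError("empty mask has no centroid")
        return self.grid.voxel_to_world(idx.mean(axis=0))[0]

    def to_volume(self) -> Volume:
        return Volume(self.grid, self.data)

    def save(self, path) -> None:
        save_volume(self.to_volume(), path)


# ------------------------------------------------------------------ slab stack


def _ap_extent(grid: Grid) -> tuple[float, float]:
    """Min/max world-AP coordinate over voxel centers (extrema at corners)."""
    ap = grid.corners_world()[:, AP_AXIS]
    return float(ap.min()), float(ap.max())


def make_slice_stack(
    grid: Grid,
    thickness_mm: float = DEFAULT_SLAB_THICKNESS_MM,
    origin: str | float = "edge",
) -> SliceStack:
    """Partition a grid into coronal slabs.

    Parameters
    ----------
    grid : Grid
    thickness_mm : float
        Slab thickness; 4 mm matches the standard brain-cutting protocol.
    origin : "edge" or float
        World-AP coordinate of the first slab's start.  ``"edge"`` anchors it
        at the minimum AP voxel-center coordinate so every voxel center falls
        in exactly one slab.
    """
    if not thickness_mm > 0:
        raise ValueError("thickness_mm must be positive")
    lo, hi = _ap_extent(grid)
    origin_mm = lo if origin == "edge" else float(origin)
    if origin_mm > lo:
        raise ValueError(f"origin {origin_mm} excludes voxels anterior of it (min AP {lo})")
    n_slabs = int(np.floor((hi - origin_mm) / thickness_mm)) + 1
    return SliceStack(grid, origin_mm, float(thickness_mm), n_slabs)


def slab_of_point(stack: SliceStack, p) -> int:
    """Slab index containing a world point (half-open boundary rule)."""
    p = np.asarray(p, dtype=float)
    ap = float(p[stack.axis]) if p.ndim == 1 else float(p)
    i = int(np.floor((ap - stack.origin_mm) / stack.thickness_mm))
    if not 0 <= i < stack.n_slabs:
        raise ValueError(
            f"point AP={ap} mm outside stack extent "
            f"[{stack.origin_mm}, {stack.origin_mm + stack.n_slabs * stack.thickness_mm})"
        )
    return i


def slab_index_map(stack: SliceStack) -> np.ndarray:
    """Per-voxel slab index (may fall outside [0, n_slabs) beyond the extent)."""
    ap = stack.grid.voxel_centers_world()[..., stack.axis]
    return np.floor((ap - stack.origin_mm) / stack.thickness_mm).astype(int)


# --------------------------------------------------------------- block cutting


def _box_mask(grid: Grid, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Voxels whose centers fall in the world-axis-aligned half-open box [lo, hi).

    Only the voxel bounding box of the world box is examined, so placement is
    cheap even on large grids.
    """
    corners = np.array(
        [[x, y, z] for x in (lo[0], hi[0]) for y in (lo[1], hi[1]) for z in (lo[2], hi[2])]
    )
    vox = grid.world_to_voxel(corners)
    lo_i = np.maximum(np.floor(vox.min(axis=0)).astype(int) - 1, 0)
    hi_i = np.minimum(np.ceil(vox.max(axis=0)).astype(int) + 1, np.array(grid.shape) - 1)
    mask = np.zeros(grid.shape, dtype=np.uint8)
    if np.any(hi_i < lo_i):
        return mask
    ii, jj, kk = np.meshgrid(
        *(np.arange(lo_i[a], hi_i[a] + 1) for a in range(3)), indexing="ij"
    )
    pts = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
    world = grid.voxel_to_world(pts)
    inside = np.all((world >= lo) & (world < hi), axis=1)
    mask[pts[inside, 0], pts[inside, 1], pts[inside, 2]] = 1
    return mask


def place_block(stack: SliceStack, spec: BlockSpec, method: str = "target") -> BlockMask:
    """Cut a block: in-plane rectangle x slab interval, voxel-center membership."""
    y0, y1 = stack.slab_interval(spec.slab_index)
    cx, cz = spec.in_plane_center_mm
    w, h = spec.in_plane_size_mm
    lo = np.array([cx - w / 2.0, y0, cz - h / 2.0])
    hi = np.array([cx + w / 2.0, y1, cz + h / 2.0])
    data = _box_mask(stack.grid, lo, hi)
    if data.sum() == 0:
        raise EmptyBlockError(
            f"empty block: {spec.roi_label} rectangle at {spec.in_plane_center_mm} "
            f"slab {spec.slab_index} lies outside the grid"
        )
    return BlockMask(
        stack.grid,
        data,
        roi_label=spec.roi_label,
        method=method,
        slab_index=spec.slab_index,
        provenance={
            "in_plane_center_mm": list(spec.in_plane_center_mm),
            "in_plane_size_mm": list(spec.in_plane_size_mm),
            "slab_interval_mm": [y0, y1],
        },
    )


def landmark_anchored_block(
    stack: SliceStack,
    landmark,
    roi_offset,
    size_mm: tuple[float, float] = DEFAULT_BLOCK_SIZE_MM,
    roi_label: str = "",
    method: str = "subject_specific",
) -> BlockMask:
    """Place a block on the slab containing ``landmark``, offset in-plane.

    This is the operational model of bench sampling: the prosector picks the
    slab that contains a gross landmark (e.g. the anterior commissure) and
    positions the block within that coronal face by eye.
    """
    landmark = np.asarray(landmark, dtype=float)
    slab = slab_of_point(stack, landmark)
    off = np.asarray(roi_offset, dtype=float)
    center = (float(landmark[0] + off[0]), float(landmark[2] + off[1]))
    spec = BlockSpec(roi_label, slab, center, tuple(size_mm))
    blk = place_block(stack, spec, method=method)
    blk.provenance["landmark_mm"] = [float(v) for v in landmark]
    blk.provenance["roi_offset_mm"] = [float(v) for v in off]
    return blk


# ------------------------------------------------------------------- TSV I/O


def write_block_specs(specs: list[BlockSpec], path) -> None:
    rows = [
        {
            "roi_label": s.roi_label,
            "slab_index": s.slab_index,
            "center_x_mm": s.in_plane_center_mm[0],
            "center_z_mm": s.in_plane_center_mm[1],
            "width_mm": s.in_plane_size_mm[0],
            "height_mm": s.in_plane_size_mm[1],
        }
        for s in specs
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_block_specs(path) -> list[BlockSpec]:
    df = pd.read_csv(path, sep="\t")
    return [
        BlockSpec(
            str(r.roi_label),
            int(r.slab_index),
            (float(r.center_x_mm), float(r.center_z_mm)),
            (float(r.width_mm), float(r.height_mm)),
        )
        for r in df.itertuples()
    ]
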