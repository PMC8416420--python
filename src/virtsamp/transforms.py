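"""Rigid/affine/dense transforms on block masks, and the two
neuroimaging-guided sampling improvements.

Two searches quantify how much better sampling could be if imaging guided
the bench protocol:

* :func:`ap_slab_search` ("guided" sample) translates a slab-cut block in
  whole-slab steps along the anterior-posterior axis to the slab that
  maximizes overlap with the reference block -- the improvement achievable
  simply by cutting the right slice.
* :func:`rigid_overlap_optimize` ("optimal" sample) finds the 6-DOF rigid
  motion (rotation + translation, no scaling/shear/warp) of the block that
  maximizes overlap -- the improvement achievable if the brain could also be
  repositioned and re-angled before slicing.

Masks are moved by pulling: the moved mask's value at each target voxel is
the trilinear interpolation of the source 0/1 field at the inverse-mapped
point, thresholded at 0.5.  Overlap is always reported on hard binary masks;
the rigid search internally optimizes a Gaussian-smoothed soft surrogate
because the hard overlap is piecewise constant in the parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize
from scipy.spatial.transform import Rotation

from .sampling import AP_AXIS, BlockMask, SliceStack
from .volume import Grid


@dataclass(frozen=True)
class RigidTransform:
    """6-parameter rigid motion: extrinsic x->y->z Euler rotation about
    ``center`` followed by translation (all world mm / radians)."""

    rotation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def rotation_matrix(self) -> np.ndarray:
        return Rotation.from_euler("xyz", self.rotation).as_matrix()

    def matrix(self) -> np.ndarray:
        """4x4 world-to-world map: p -> R (p - c) + c + t."""
        r = self.rotation_matrix()
        m = np.eye(4)
        m[:3, :3] = r
        c = np.asarray(self.center)
        m[:3, 3] = c + np.asarray(self.translation) - r @ c
        return m

    def inverse(self) -> "RigidTransform":
        r_inv = Rotation.from_euler("xyz", self.rotation).inv()
        ang = r_inv.as_euler("xyz")
        c = np.asarray(self.center)
        t = np.asarray(self.translation)
        # solve: inverse map q -> Rinv (q - c - t) + c  ==  Rinv (q - c') + c' + t'
        t_new = r_inv.as_matrix() @ (-t)
        return RigidTransform(tuple(ang), tuple(t_new), tuple(c))

    def apply(self, points: np.ndarray) -> np.ndarray:
        m = self.matrix()
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ m[:3, :3].T + m[:3, 3]

    @property
    def rotation_deg(self) -> np.ndarray:
        return np.degrees(self.rotation)

    def param_norm(self) -> float:
        """Comparable magnitude: degrees and millimetres weighted equally."""
        return float(
            np.linalg.norm(np.r_[np.degrees(self.rotation), self.translation])
        )


def rotation_angle_deg(a: RigidTransform, b: RigidTransform) -> float:
    """Geodesic angle between the two rotations, degrees."""
    r = a.rotation_matrix().T @ b.rotation_matrix()
    return float(np.degrees(np.abs(Rotation.from_matrix(r).magnitude())))


def save_transform(t: RigidTransform | np.ndarray, path) -> None:
    m = t.matrix() if isinstance(t, RigidTransform) else np.asarray(t, dtype=float)
    np.savetxt(path, m, fmt="%.12g", header="4x4 world-mm affine (RAS+)")


def load_transform(path) -> np.ndarray:
    m = np.loadtxt(path)
    if m.shape != (4, 4):
        raise ValueError(f"{path}: expected a 4x4 matrix, got {m.shape}")
    return m


@dataclass
class DisplacementField:
    """Dense world-mm displacement: maps p -> p + vectors(p) (pull direction)."""

    grid: Grid
    vectors: np.ndarray  # grid.shape + (3,)

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.shape != self.grid.shape + (3,):
            raise ValueError("vectors must have shape grid.shape + (3,)")
        if not np.isfinite(self.vectors).all():
            raise ValueError("displacement field contains non-finite values")

    def __call__(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        vox = self.grid.world_to_voxel(pts)
        disp = np.stack(
            [
                ndimage.map_coordinates(
                    self.vectors[..., a], vox.T, order=1, mode="nearest"
                )
                for a in range(3)
            ],
            axis=1,
        )
        return pts + disp


@dataclass
class OverlapResult:
    """Outcome of a sampling-improvement search."""

    percent_overlap: float
    transform: RigidTransform
    moved_mask: BlockMask
    info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_overlap <= 100.0:
            raise ValueError("percent_overlap must lie in [0, 100]")


# ----------------------------------------------------------- mask resampling


def _pull_mask_values(
    data: np.ndarray, src: Grid, pull, target: Grid, order: int = 1
) -> np.ndarray:
    """Interpolate ``data`` (on ``src``) at target voxel centers mapped by the
    pull map (target world -> source world)."""
    if isinstance(pull, RigidTransform):
        m = np.linalg.inv(src.affine) @ pull.matrix() @ target.affine
        return ndimage.affine_transform(
            np.asarray(data, dtype=float),
            m[:3, :3],
            offset=m[:3, 3],
            output_shape=target.shape,
            order=order,
            mode="constant",
            cval=0.0,
            prefilter=False,
        )
    if isinstance(pull, np.ndarray) and pull.shape == (4, 4):
        m = np.linalg.inv(src.affine) @ pull @ target.affine
        return ndimage.affine_transform(
            np.asarray(data, dtype=float),
            m[:3, :3],
            offset=m[:3, 3],
            output_shape=target.shape,
            order=order,
            mode="constant",
            cval=0.0,
            prefilter=False,
        )
    # dense field or arbitrary callable on world points
    pts = target.voxel_centers_world().reshape(-1, 3)
    src_world = pull(pts)
    vox = src.world_to_voxel(src_world)
    out = ndimage.map_coordinates(
        np.asarray(data, dtype=float), vox.T, order=order, mode="constant", cval=0.0
    )
    return out.reshape(target.shape)


def apply_transform_to_mask(
    m: BlockMask,
    transform,
    target: Grid | None = None,
    threshold: float = 0.5,
    allow_empty: bool = False,
) -> BlockMask:
    """Resample a binary mask through a transform onto ``target``.

    ``transform`` maps *target-space world points into source-space world
    points* (pull convention): a :class:`RigidTransform`, a 4x4 affine, a
    :class:`DisplacementField`, or any callable on (N, 3) world points.
    The 0/1 field is interpolated trilinearly and thresholded at 0.5.
    """
    target = target or m.grid
    soft = _pull_mask_values(m.data, m.grid, transform, target, order=1)
    data = (soft >= threshold).astype(np.uint8)
    if data.sum() == 0 and not allow_empty:
        raise ValueError("transformed mask is empty on the target grid")
    out = BlockMask(
        target, data, roi_label=m.roi_label, method=m.method, slab_index=None
    )
    out.provenance = dict(m.provenance)
    return out


def move_mask(
    m: BlockMask, t: RigidTransform, target: Grid | None = None, **kw
) -> BlockMask:
    """Physically move a mask by the *forward* rigid motion ``t``."""
    return apply_transform_to_mask(m, t.inverse(), target, **kw)


def resample_mask_to_grid(m: BlockMask, target: Grid, **kw) -> BlockMask:
    """Identity-world resampling of a mask onto another grid."""
    return apply_transform_to_mask(m, np.eye(4), target, **kw)


# -------------------------------------------------------------------- overlap


def percent_overlap(
    sample: BlockMask, reference: BlockMask, denominator: str = "reference"
) -> float:
    """Percent of the reference block covered by the sample block.

    ``denominator`` may be ``"reference"`` (default), ``"sample"``,
    ``"union"``, or ``"dice"`` (2|A∩B| / (|A|+|B|), as a percentage).
    """
    if not sample.grid.same_as(reference.grid):
        raise ValueError("masks must be on the same grid; resample first")
    a = sample.data > 0
    b = reference.data > 0
    nb = int(b.sum())
    if nb == 0:
        raise ValueError("empty reference mask")
    inter = int((a & b).sum())
    if denominator == "reference":
        return 100.0 * inter / nb
    if denominator == "sample":
        na = int(a.sum())
        if na == 0:
            raise ValueError("empty sample mask")
        return 100.0 * inter / na
    if denominator == "union":
        return 100.0 * inter / int((a | b).sum())
    if denominator == "dice":
        return 100.0 * 2.0 * inter / (int(a.sum()) + nb)
    raise ValueError(f"unknown denominator {denominator!r}")


# ------------------------------------------------------------ AP slab search


def _integer_shift_axis(grid: Grid, shift_mm: float) -> tuple[int, int] | None:
    """If a world-AP translation is an exact integer voxel shift along one grid
    axis, return (axis, n_voxels); else None."""
    cols = grid.affine[:3, :3]
    for ax in range(3):
        col = cols[:, ax]
        if abs(col[AP_AXIS]) > 1e-9 and np.allclose(
            np.delete(col, AP_AXIS), 0.0, atol=1e-9
        ):
            n = shift_mm / col[AP_AXIS]
            if abs(n - round(n)) < 1e-9:
                # the other columns must not move AP
                others = np.delete(np.arange(3), ax)
                if np.allclose(cols[AP_AXIS, others], 0.0, atol=1e-9):
                    return ax, int(round(n))
    return None


def _shift_mask_ap(m: BlockMask, shift_mm: float) -> np.ndarray:
    """Binary array of the mask translated by ``shift_mm`` along world AP."""
    fast = _integer_shift_axis(m.grid, shift_mm)
    if fast is not None:
        ax, n = fast
        out = np.zeros_like(m.data)
        if n == 0:
            return m.data.copy()
        src = [slice(None)] * 3
        dst = [slice(None)] * 3
        if n > 0:
            src[ax], dst[ax] = slice(0, m.data.shape[ax] - n), slice(n, None)
        else:
            src[ax], dst[ax] = slice(-n, None), slice(0, m.data.shape[ax] + n)
        out[tuple(dst)] = m.data[tuple(src)]
        return out
    t = np.zeros(3)
    t[AP_AXIS] = shift_mm
    pull = RigidTransform(translation=tuple(-t))  # inverse of forward shift
    soft = _pull_mask_values(m.data, m.grid, pull, m.grid, order=1)
    return (soft >= 0.5).astype(np.uint8)


def ap_slab_search(
    sample: BlockMask,
    reference: BlockMask,
    stack: SliceStack,
    denominator: str = "reference",
) -> OverlapResult:
    """Exhaustive whole-slab AP translation maximizing overlap (guided sample).

    Every integer slab offset keeping the block within the stack is tried;
    ties prefer the smallest |offset|, then the smaller offset, so a no-gain
    search returns the original placement.
    """
    if sample.slab_index is not None:
        k_lo = -sample.slab_index
        k_hi = stack.n_slabs - 1 - sample.slab_index
    else:
        k_lo, k_hi = -(stack.n_slabs - 1), stack.n_slabs - 1
    ks = sorted(range(k_lo, k_hi + 1), key=lambda k: (abs(k), k))
    best = None
    for k in ks:
        shifted = _shift_mask_ap(sample, k * stack.thickness_mm)
        if shifted.sum() == 0:
            continue
        cand = BlockMask(sample.grid, shifted, roi_label=sample.roi_label)
        ov = percent_overlap(cand, reference, denominator)
        if best is None or ov > best[0] + 1e-12:
            best = (ov, k, cand)
    if best is None:
        raise ValueError("sample mask empty at every admissible slab offset")
    ov, k, moved = best
    moved.method = "guided"
    moved.slab_index = None if sample.slab_index is None else sample.slab_index + k
    moved.provenance = dict(sample.provenance, slab_offset=k)
    shift = np.zeros(3)
    shift[AP_AXIS] = k * stack.thickness_mm
    return OverlapResult(
        ov,
        RigidTransform(translation=tuple(shift)),
        moved,
        info={"slab_offset": k, "n_offsets_tried": len(ks)},
    )


# ------------------------------------------------------- rigid 6-DOF search


def _crop_to_bbox(data: np.ndarray, grid: Grid, pad_vox: int) -> tuple[np.ndarray, Grid]:
    """Cut an array down to its padded nonzero bounding box (big speed win)."""
    idx = np.argwhere(data > 0)
    lo = np.maximum(idx.min(axis=0) - pad_vox, 0)
    hi = np.minimum(idx.max(axis=0) + pad_vox + 1, np.array(grid.shape))
    sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    aff = grid.affine.copy()
    aff[:3, 3] = grid.voxel_to_world(lo)[0]
    sub = Grid(tuple(int(b - a) for a, b in zip(lo, hi)), aff)
    return data[sl].astype(float), sub


def _params_to_rigid(p: np.ndarray, center) -> RigidTransform:
    return RigidTransform(
        rotation=tuple(np.radians(p[:3])),
        translation=tuple(p[3:6]),
        center=tuple(center),
    )


def _refine_grid(grid: Grid, factor: int) -> Grid:
    """Subdivide each voxel ``factor``-fold, keeping voxel centers nested."""
    aff = grid.affine.copy()
    aff[:3, :3] = grid.affine[:3, :3] / factor
    aff[:3, 3] = grid.affine[:3, 3] - grid.affine[:3, :3] @ np.full(
        3, (factor - 1) / (2.0 * factor)
    )
    return Grid(tuple(int(s * factor) for s in grid.shape), aff)


def rigid_overlap_optimize(
    sample: BlockMask,
    reference: BlockMask,
    bounds_mm: float = 20.0,
    bounds_deg: float = 20.0,
    n_starts: int = 8,
    seed: int = 0,
    guided: OverlapResult | None = None,
    sigma_vox: float = 1.0,
    denominator: str = "reference",
    maxfev: int = 150,
    refine_factor: int = 2,
    polish_maxfev: int = 300,
) -> OverlapResult:
    """Multi-start derivative-free 6-DOF rigid maximization of block overlap.

    The search objective is the inner product of Gaussian-smoothed (sigma =
    ``sigma_vox`` voxels) soft masks, which is smooth in the parameters;
    Powell restarts explore the basin structure, after which the best
    solution is polished by a local Nelder-Mead on the same objective
    evaluated on a ``refine_factor``-times supersampled grid (better
    quadrature of the overlap integral, which reduces voxelization bias in
    the recovered parameters).  The reported overlap is always recomputed on
    hard binary masks.  Rotation is about the reference-mask centroid.  The
    identity, the centroid-alignment translation, and (if given) the guided
    slab offset are always among the candidate solutions, so the result can
    never fall below any of them.  Ties within 1e-9 overlap prefer the
    smallest-magnitude transform.
    """
    if not sample.grid.same_as(reference.grid):
        raise ValueError("masks must be on the same grid; resample first")
    center = reference.centroid_world()
    # the overlap numerator lives entirely inside the reference support, so
    # the objective only needs to be evaluated on a small crop around it
    pad = int(np.ceil(3 * sigma_vox)) + 2
    samp, sgrid = _crop_to_bbox(sample.data, sample.grid, pad)
    ref, rgrid = _crop_to_bbox(reference.data, reference.grid, pad)
    samp_soft = ndimage.gaussian_filter(samp, sigma_vox)
    ref_soft = ndimage.gaussian_filter(ref, sigma_vox)
    ref_norm = float(ref_soft.sum())
    ref_count = int((ref > 0).sum())
    ref_hard = ref > 0
    samp_centroid = sample.centroid_world()

    n_evals = [0]

    def soft_score(p: np.ndarray) -> float:
        n_evals[0] += 1
        pull = _params_to_rigid(p, center).inverse()
        moved = _pull_mask_values(samp_soft, sgrid, pull, rgrid, order=1)
        return -float((moved * ref_soft).sum() / ref_norm)

    def hard_overlap(p: np.ndarray) -> float:
        pull = _params_to_rigid(p, center).inverse()
        moved = _pull_mask_values(samp, sgrid, pull, rgrid, order=1) >= 0.5
        inter = int((moved & ref_hard).sum())
        # the moved-mask voxel count is approximated by the (rigid-motion
        # invariant) sample count; exact values are recomputed at the end
        if denominator == "reference":
            return 100.0 * inter / ref_count
        if denominator == "sample":
            return 100.0 * inter / max(sample.voxel_count, 1)
        if denominator == "union":
            return 100.0 * inter / (sample.voxel_count + ref_count - inter)
        if denominator == "dice":
            return 100.0 * 2 * inter / (sample.voxel_count + ref_count)
        raise ValueError(f"unknown denominator {denominator!r}")

    # -- starting points -----------------------------------------------------
    starts = [np.zeros(6)]
    d_centroid = center - samp_centroid
    starts.append(np.r_[0.0, 0.0, 0.0, np.clip(d_centroid, -bounds_mm, bounds_mm)])
    if guided is not None:
        starts.append(
            np.r_[0.0, 0.0, 0.0, np.clip(guided.transform.translation, -bounds_mm, bounds_mm)]
        )
    rng = np.random.default_rng(seed)
    base = starts[1]
    while len(starts) < n_starts:
        pert = np.r_[rng.uniform(-8, 8, 3), rng.uniform(-5, 5, 3)]
        starts.append(np.clip(base + pert, [-bounds_deg] * 3 + [-bounds_mm] * 3,
                              [bounds_deg] * 3 + [bounds_mm] * 3))

    bounds = [(-bounds_deg, bounds_deg)] * 3 + [(-bounds_mm, bounds_mm)] * 3
    candidates = [np.asarray(s, dtype=float) for s in starts]
    powell = []
    for s in starts:
        res = optimize.minimize(
            soft_score,
            s,
            method="Powell",
            bounds=bounds,
            options={"maxfev": maxfev, "xtol": 1e-2, "ftol": 1e-6},
        )
        powell.append(np.asarray(res.x, dtype=float))
    candidates.extend(powell)

    if refine_factor > 1 and polish_maxfev > 0:
        fine_s = _refine_grid(sgrid, refine_factor)
        fine_r = _refine_grid(rgrid, refine_factor)
        samp_fine = ndimage.gaussian_filter(
            _pull_mask_values(samp, sgrid, np.eye(4), fine_s, order=1),
            refine_factor * sigma_vox,
        )
        ref_fine = ndimage.gaussian_filter(
            _pull_mask_values(ref, rgrid, np.eye(4), fine_r, order=1),
            refine_factor * sigma_vox,
        )
        ref_fine_norm = float(ref_fine.sum())

        def fine_score(p: np.ndarray) -> float:
            n_evals[0] += 1
            pull = _params_to_rigid(p, center).inverse()
            moved = _pull_mask_values(samp_fine, fine_s, pull, fine_r, order=1)
            return -float((moved * ref_fine).sum() / ref_fine_norm)

        p0 = min(powell, key=soft_score)
        simplex = np.vstack([p0, p0 + np.eye(6) * 0.6])
        res = optimize.minimize(
            fine_score,
            p0,
            method="Nelder-Mead",
            options={
                "initial_simplex": simplex,
                "maxfev": polish_maxfev,
                "xatol": 1e-4,
                "fatol": 1e-13,
            },
        )
        candidates.append(np.asarray(res.x, dtype=float))

    scored = [(hard_overlap(p), float(np.linalg.norm(p)), i, p)
              for i, p in enumerate(candidates)]
    best_ov = max(s[0] for s in scored)
    # tie-break: among near-ties, the smallest parameter norm
    ov, _, _, best_p = min(
        (s for s in scored if s[0] >= best_ov - 1e-9), key=lambda s: (s[1], s[2])
    )
    best_t = _params_to_rigid(best_p, center)
    moved_full = move_mask(sample, best_t, allow_empty=True)
    moved_full.method = "optimal"
    moved_full.provenance = dict(sample.provenance, rigid_params=list(best_p))
    full_ov = percent_overlap(moved_full, reference, denominator)
    return OverlapResult(
        full_ov,
        best_t,
        moved_full,
        info={"n_starts": len(starts), "n_soft_evals": n_evals[0], "crop_overlap": ov},
    )
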