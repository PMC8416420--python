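"""Seed-based functional connectivity of sampled blocks and the
subject-specific vs reference discrepancy analysis.

A sampled block's functional profile is the Pearson correlation of its mean
BOLD timeseries with the mean timeseries of each region in a whole-brain
region set (spheres around published coordinates, or explicit masks).  For
each region, the paired difference between the profile of the
subject-specific block and that of the reference block is tested across
subjects with a sign-flip permutation null and empirical top/bottom-5%
thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sampling import BlockMask
from .stats import SignFlipResult, sign_flip_null
from .volume import Grid, Volume4D

DEFAULT_REGION_RADIUS_MM = 5.0


@dataclass
class RegionSet:
    """Whole-brain region set: ids, centers (world mm) and voxel membership."""

    ids: np.ndarray
    centers: np.ndarray  # N x 3 world mm
    radius_mm: float
    grid: Grid | None = None
    masks: list[np.ndarray] | None = None  # flat voxel indices per region
    empty: np.ndarray | None = None

    @property
    def n_regions(self) -> int:
        return int(len(self.ids))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "x_mm": self.centers[:, 0],
                "y_mm": self.centers[:, 1],
                "z_mm": self.centers[:, 2],
                "radius_mm": self.radius_mm,
            }
        )

    def save_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def read_region_centers(path) -> tuple[np.ndarray, np.ndarray, float | None]:
    """Read a region TSV (id, x_mm, y_mm, z_mm[, radius_mm])."""
    df = pd.read_csv(path, sep="\t")
    centers = df[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)
    radius = float(df["radius_mm"].iloc[0]) if "radius_mm" in df else None
    return df["id"].to_numpy(), centers, radius


def make_sphere_regions(
    centers,
    radius_mm: float = DEFAULT_REGION_RADIUS_MM,
    grid: Grid | None = None,
    ids=None,
) -> RegionSet:
    """Build spherical region masks: voxels whose centers lie within radius.

    Overlapping spheres are permitted (membership is not exclusive).  Regions
    that catch no voxel on the grid are flagged empty; if every region is
    empty the grid cannot support the set and an error is raised.
    """
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    if not radius_mm > 0:
        raise ValueError("radius_mm must be positive")
    ids = np.arange(len(centers)) if ids is None else np.asarray(ids)
    if grid is None:
        return RegionSet(ids, centers, radius_mm)
    masks: list[np.ndarray] = []
    empty = np.zeros(len(centers), dtype=bool)
    shape = np.array(grid.shape)
    inv_reach = radius_mm / grid.spacing + 1.0
    for i, c in enumerate(centers):
        vox_c = grid.world_to_voxel(c)[0]
        lo = np.maximum(np.floor(vox_c - inv_reach).astype(int), 0)
        hi = np.minimum(np.ceil(vox_c + inv_reach).astype(int), shape - 1)
        if np.any(hi < lo):
            masks.append(np.empty(0, dtype=np.int64))
            empty[i] = True
            continue
        ii, jj, kk = np.meshgrid(
            *(np.arange(lo[a], hi[a] + 1) for a in range(3)), indexing="ij"
        )
        pts = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
        world = grid.voxel_to_world(pts)
        keep = np.linalg.norm(world - c, axis=1) <= radius_mm
        flat = np.ravel_multi_index(pts[keep].T, grid.shape)
        masks.append(flat)
        empty[i] = flat.size == 0
    if empty.all():
        raise ValueError("all regions are empty on the given grid")
    return RegionSet(ids, centers, radius_mm, grid=grid, masks=masks, empty=empty)


# --------------------------------------------------------------- timeseries


def mean_timeseries(ts: Volume4D, mask: BlockMask) -> np.ndarray:
    """Mean BOLD series over the mask.

    A mask on a different (usually finer, structural) grid is transferred to
    the functional grid by trilinear partial-volume weights, so thin blocks
    contribute proportionally even when the functional voxels are coarser
    than the block thickness.
    """
    if mask.grid.same_as(ts.grid):
        weights = (mask.data > 0).astype(float)
    else:
        from .volume import Volume, resample_to_grid

        weights = resample_to_grid(
            Volume(mask.grid, mask.data.astype(float)), ts.grid, "trilinear"
        ).data
    total = weights.sum()
    if total <= 1e-9:
        raise ValueError("mask is empty on the functional grid")
    sel = weights > 0
    return (ts.data[sel] * weights[sel, None]).sum(axis=0) / total


def region_mean_series(ts: Volume4D, regions: RegionSet) -> np.ndarray:
    """Regions x T matrix of mean series; empty regions yield NaN rows."""
    if regions.masks is None:
        raise ValueError("region set has no voxel masks; build with a grid")
    if regions.grid is not None and not regions.grid.same_as(ts.grid):
        raise ValueError("region set was built on a different grid")
    flat = ts.data.reshape(-1, ts.data.shape[3])
    out = np.full((regions.n_regions, ts.data.shape[3]), np.nan)
    for i, idx in enumerate(regions.masks):
        if idx.size:
            out[i] = flat[idx].mean(axis=0)
    return out


# ---------------------------------------------------------------- FC profile


@dataclass
class FCProfile:
    """Pearson correlations from one sampled block to every region."""

    r: np.ndarray
    undefined: np.ndarray  # zero-variance or empty regions, flagged not zeroed
    sample_method: str = ""
    roi_label: str = ""
    subject_id: str = ""


def fc_profile(
    seed_series,
    region_series,
    sample_method: str = "",
    roi_label: str = "",
    subject_id: str = "",
) -> FCProfile:
    """Pearson r of the seed series against each region's series.

    Zero-variance (or missing) region series are flagged ``undefined`` and
    carry NaN in ``r`` rather than a silent zero.
    """
    seed = np.asarray(seed_series, dtype=float)
    reg = np.atleast_2d(np.asarray(region_series, dtype=float))
    t = seed.size
    if t < 3:
        raise ValueError("need at least 3 timepoints")
    if reg.shape[1] != t:
        raise ValueError("region series length does not match seed")
    seed_c = seed - seed.mean()
    seed_ss = float(seed_c @ seed_c)
    if seed_ss == 0.0:
        raise ValueError("seed series is constant")
    undefined = ~np.isfinite(reg).all(axis=1)
    reg = np.where(np.isfinite(reg), reg, 0.0)
    reg_c = reg - reg.mean(axis=1, keepdims=True)
    reg_ss = np.einsum("ij,ij->i", reg_c, reg_c)
    # constant series leave rounding residue after demeaning; flag relative
    # to the series magnitude rather than testing for exact zero
    scale = np.abs(reg).max(axis=1)
    undefined |= np.sqrt(reg_ss / t) <= 1e-10 * (1.0 + scale)
    denom = np.sqrt(seed_ss * np.where(reg_ss > 0, reg_ss, 1.0))
    r = (reg_c @ seed_c) / denom
    r = np.clip(r, -1.0, 1.0)
    r[undefined] = np.nan
    return FCProfile(r, undefined, sample_method, roi_label, subject_id)


# -------------------------------------------------------- discrepancy analysis


@dataclass
class FCDiscrepancy:
    """Cohort-level subject-specific vs reference connectivity comparison."""

    table: pd.DataFrame
    increased: np.ndarray  # region ids with significantly higher FC to the
    decreased: np.ndarray  # subject-specific block, resp. significantly lower
    n_increased: int
    n_decreased: int
    signflip: SignFlipResult
    deltas: np.ndarray = field(repr=False, default=None)


def fc_discrepancy_analysis(
    profiles_subject_specific,
    profiles_reference,
    region_ids=None,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int | np.random.Generator | None = None,
    statistic: str = "signed_count",
) -> FCDiscrepancy:
    """Test, per region, whether block FC differs between sampling methods.

    Inputs are matched subjects x regions matrices of Pearson r (or lists of
    :class:`FCProfile`).  The per-subject delta is r(subject-specific block)
    minus r(reference block); significance uses the sign-flip permutation
    null with empirical top/bottom-``alpha`` thresholds.  Regions undefined
    for any subject are excluded from significance calls.
    """

    def _stack(profiles):
        if isinstance(profiles, np.ndarray):
            return profiles, np.zeros(profiles.shape[1], dtype=bool)
        rs = np.stack([p.r for p in profiles])
        und = np.any(np.stack([p.undefined for p in profiles]), axis=0)
        return rs, und

    rs_ss, und_ss = _stack(profiles_subject_specific)
    rs_ref, und_ref = _stack(profiles_reference)
    if rs_ss.shape != rs_ref.shape:
        raise ValueError("profile matrices must have matching shapes")
    n_subj, n_reg = rs_ss.shape
    if n_subj < 3:
        raise ValueError("need at least 3 subjects")
    excluded = und_ss | und_ref
    deltas = rs_ss - rs_ref
    deltas = np.where(excluded[None, :], 0.0, deltas)

    res = sign_flip_null(deltas, n_perm=n_perm, alpha=alpha, seed=seed,
                         statistic=statistic)
    ids = np.arange(n_reg) if region_ids is None else np.asarray(region_ids)
    sig_up = res.significant_up & ~excluded
    sig_down = res.significant_down & ~excluded
    table = pd.DataFrame(
        {
            "region": ids,
            "mean_delta": deltas.mean(axis=0),
            "observed": res.observed,
            "lower": res.lower,
            "upper": res.upper,
            "significant_up": sig_up,
            "significant_down": sig_down,
            "excluded": excluded | res.degenerate,
        }
    )
    return FCDiscrepancy(
        table,
        ids[sig_up],
        ids[sig_down],
        int(sig_up.sum()),
        int(sig_down.sum()),
        res,
        deltas,
    )
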