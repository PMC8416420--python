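"""Cohort-level sampling precision surfaces and accuracy tables.

Precision: after mapping every subject's block into the common template
space, count at each voxel how many subjects' blocks cover it.  Accuracy:
per subject and region, the percent of the reference block covered by the
sample placed by each method.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .sampling import BlockMask
from .volume import Grid, Volume, save_volume

METHODS = ("subject_specific", "guided", "optimal")


@dataclass
class OverlapMap:
    """Per-voxel count of subjects whose blocks cover the voxel (template space)."""

    grid: Grid
    counts: np.ndarray
    n_subjects: int
    roi_label: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != self.grid.shape:
            raise ValueError("counts shape does not match grid")
        if self.counts.min() < 0 or self.counts.max() > self.n_subjects:
            raise ValueError("counts must lie in [0, n_subjects]")

    def save(self, path) -> None:
        save_volume(Volume(self.grid, self.counts.astype(np.int16)), path)


def overlap_count_map(
    masks: Iterable[BlockMask], n_subjects: int | None = None, roi_label: str = ""
) -> OverlapMap:
    """Sum the subjects' binary masks voxelwise (all must share one grid)."""
    masks = list(masks)
    if not masks:
        raise ValueError("no masks given")
    grid = masks[0].grid
    counts = np.zeros(grid.shape, dtype=np.int32)
    for m in masks:
        if not m.grid.same_as(grid):
            raise ValueError("all masks must be on the same grid")
        counts += m.data > 0
    return OverlapMap(grid, counts, n_subjects or len(masks), roi_label=roi_label)


def overlap_histogram(omap: OverlapMap, domain: str = "union_of_masks") -> pd.DataFrame:
    """Voxel counts and percentages for each degree of overlap k = 1..n.

    ``domain`` chooses the denominator of the percentage column: the union of
    all subjects' masks (counts >= 1, default) or every voxel of the map.
    """
    if domain not in ("union_of_masks", "whole_map"):
        raise ValueError(f"unknown domain {domain!r}")
    ks = np.arange(1, omap.n_subjects + 1)
    nvox = np.array([(omap.counts == k).sum() for k in ks], dtype=int)
    if domain == "union_of_masks":
        denom = int((omap.counts >= 1).sum())
    else:
        denom = int(np.prod(omap.grid.shape))
    pct = 100.0 * nvox / denom if denom else np.zeros_like(nvox, dtype=float)
    df = pd.DataFrame({"k": ks, "n_voxels": nvox, "pct_of_domain": pct})
    return df[df["n_voxels"] > 0].reset_index(drop=True) if denom == 0 else df


class MaxOverlapSummary(NamedTuple):
    max_k: int
    pct_at_max: float  # % of union voxels at the maximal degree of overlap
    pct_k_ge_2: float  # % of union voxels covered by at least two subjects


def max_overlap_summary(omap: OverlapMap) -> MaxOverlapSummary:
    union = int((omap.counts >= 1).sum())
    if union == 0:
        return MaxOverlapSummary(0, 0.0, 0.0)
    max_k = int(omap.counts.max())
    at_max = int((omap.counts == max_k).sum())
    ge2 = int((omap.counts >= 2).sum())
    return MaxOverlapSummary(max_k, 100.0 * at_max / union, 100.0 * ge2 / union)


# ------------------------------------------------------------ accuracy table


@dataclass(frozen=True)
class AccuracyRecord:
    subject_id: str
    roi_label: str
    method: str
    percent_overlap: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_overlap <= 100.0:
            raise ValueError("percent_overlap must lie in [0, 100]")


def accuracy_table(
    records: Iterable[AccuracyRecord] | pd.DataFrame,
    methods: tuple[str, ...] = METHODS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format accuracy records plus per-(ROI, method) summary statistics.

    Every subject must have a row for each of ``methods`` in each ROI;
    duplicates and missing cells are hard errors, never silently dropped.
    Returns ``(records_df, summary_df)`` where the summary carries mean,
    unbiased SD, median, quartiles and IQR.
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame(
            [
                {
                    "subject_id": r.subject_id,
                    "roi_label": r.roi_label,
                    "method": r.method,
                    "percent_overlap": r.percent_overlap,
                }
                for r in records
            ]
        )
    if df.empty:
        raise ValueError("no accuracy records")
    key = ["subject_id", "roi_label", "method"]
    dup = df.duplicated(subset=key)
    if dup.any():
        raise ValueError(f"duplicate accuracy records: {df.loc[dup, key].values.tolist()}")
    missing = []
    for (subj, roi), grp in df.groupby(["subject_id", "roi_label"]):
        for m in methods:
            if m not in set(grp["method"]):
                missing.append((subj, roi, m))
    if missing:
        raise ValueError(f"missing accuracy cells: {missing}")

    def _q(s, q):
        return float(np.quantile(s, q))

    rows = []
    for (roi, method), grp in df.groupby(["roi_label", "method"]):
        v = grp["percent_overlap"].to_numpy(dtype=float)
        q1, q3 = _q(v, 0.25), _q(v, 0.75)
        rows.append(
            {
                "roi_label": roi,
                "method": method,
                "n": len(v),
                "mean": float(v.mean()),
                "sd": float(v.std(ddof=1)) if len(v) > 1 else 0.0,
                "median": float(np.median(v)),
                "q1": q1,
                "q3": q3,
                "iqr": q3 - q1,
            }
        )
    summary = pd.DataFrame(rows).sort_values(["roi_label", "method"]).reset_index(drop=True)
    return df.reset_index(drop=True), summary
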