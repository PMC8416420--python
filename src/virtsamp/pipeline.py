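"""Orchestration of the full sampling analysis over a phantom cohort.

Three stages mirror the scientific questions:

* ``run_precision`` -- how consistently do subject-specific blocks hit the
  same template voxels across subjects? (overlap count maps + histograms)
* ``run_accuracy`` -- how much of each subject's reference block does each
  sampling method capture, and are the improvements significant?
  (percent-overlap table, Wilcoxon matched pairs, Poisson regression with
  cluster-robust SEs)
* ``run_connectivity`` -- do the subject-specific and reference blocks carry
  different functional connectivity profiles? (seed FC to the region set,
  sign-flip permutation thresholds)

Each stage is restartable: it takes an in-memory :class:`~.phantom.Cohort`
(or a cohort directory) and optionally writes its tables/volumes under an
output directory.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .connectivity import (
    fc_discrepancy_analysis,
    fc_profile,
    mean_timeseries,
    region_mean_series,
)
from .overlap import (
    AccuracyRecord,
    accuracy_table,
    max_overlap_summary,
    overlap_count_map,
    overlap_histogram,
)
from .phantom import Cohort, load_cohort, simulate_bold
from .sampling import BlockMask
from .stats import poisson_robust, wilcoxon_signed_rank
from .transforms import ap_slab_search, percent_overlap, rigid_overlap_optimize

log = logging.getLogger("virtsamp")


@dataclass
class RunConfig:
    """All analysis knobs; defaults follow the emulated bench protocol."""

    cohort: str | None = None  # cohort directory (None = in-memory cohort)
    output: str | None = None
    slab_thickness_mm: float = 4.0
    block_size_mm: tuple[float, float] = (38.0, 32.0)
    rois: tuple[str, ...] = ()  # empty = all ROIs in the cohort
    overlap_denominator: str = "reference"
    optimizer_bounds_mm: float = 20.0
    optimizer_bounds_deg: float = 20.0
    optimizer_starts: int = 8
    n_perm: int = 1000
    alpha: float = 0.05
    seed: int = 0
    histogram_domain: str = "union_of_masks"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("block_size_mm", "rois"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["block_size_mm"] = list(self.block_size_mm)
        d["rois"] = list(self.rois)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def _resolve_cohort(cohort: Cohort | str | Path) -> Cohort:
    if isinstance(cohort, Cohort):
        return cohort
    return load_cohort(cohort)


def _roi_labels(cohort: Cohort, config: RunConfig) -> list[str]:
    labels = [r.label for r in cohort.template.spec.rois]
    if config.rois:
        missing = set(config.rois) - set(labels)
        if missing:
            raise ValueError(f"unknown ROIs requested: {sorted(missing)}")
        labels = [l for l in labels if l in config.rois]
    return labels


# ------------------------------------------------------------------ precision


@dataclass
class PrecisionResult:
    overlap_maps: dict
    histograms: dict
    summaries: dict

    def summary_frame(self) -> pd.DataFrame:
        rows = [
            {"roi_label": roi, "max_k": s.max_k, "pct_at_max": s.pct_at_max,
             "pct_k_ge_2": s.pct_k_ge_2}
            for roi, s in self.summaries.items()
        ]
        return pd.DataFrame(rows)


def run_precision(cohort: Cohort | str, config: RunConfig | None = None) -> PrecisionResult:
    """Map every subject-specific block to template space and count overlap."""
    config = config or RunConfig()
    cohort = _resolve_cohort(cohort)
    tgrid = cohort.template.volume.grid
    maps, hists, summaries = {}, {}, {}
    for roi in _roi_labels(cohort, config):
        t0 = time.perf_counter()
        mni_masks = []
        for s in cohort.subjects:
            blk = s.subject_specific_blocks[roi]
            # pull convention: template voxel -> subject world via the true map
            moved = _apply_pull(blk, s.deformation.template_to_subject, tgrid)
            mni_masks.append(moved)
        omap = overlap_count_map(mni_masks, cohort.n_subjects, roi_label=roi)
        maps[roi] = omap
        hists[roi] = overlap_histogram(omap, domain=config.histogram_domain)
        summaries[roi] = max_overlap_summary(omap)
        log.info("precision %s: %.1fs", roi, time.perf_counter() - t0)
    result = PrecisionResult(maps, hists, summaries)
    if config.output:
        out = Path(config.output)
        out.mkdir(parents=True, exist_ok=True)
        for roi, omap in maps.items():
            omap.save(out / f"precision_{roi}_overlap_map.nii.gz")
            hists[roi].to_csv(out / f"precision_{roi}_histogram.tsv", sep="\t", index=False)
        summary = {
            roi: dict(s._asdict()) for roi, s in summaries.items()
        }
        (out / "precision_summary.json").write_text(json.dumps(summary, indent=2))
    return result


def _apply_pull(blk: BlockMask, pull, target_grid) -> BlockMask:
    from .transforms import apply_transform_to_mask

    return apply_transform_to_mask(blk, pull, target_grid, allow_empty=True)


# ------------------------------------------------------------------- accuracy


@dataclass
class AccuracyResult:
    records: pd.DataFrame
    summary: pd.DataFrame
    wilcoxon: pd.DataFrame
    poisson: pd.DataFrame
    guided_results: dict = field(default_factory=dict)
    optimal_results: dict = field(default_factory=dict)


def run_accuracy(cohort: Cohort | str, config: RunConfig | None = None) -> AccuracyResult:
    """Percent overlap with the reference per subject/ROI for all three
    sampling methods, plus the paired and regression tests."""
    config = config or RunConfig()
    cohort = _resolve_cohort(cohort)
    records = []
    count_rows = []
    guided_store, optimal_store = {}, {}
    denom = config.overlap_denominator
    for s in cohort.subjects:
        t0 = time.perf_counter()
        for roi in _roi_labels(cohort, config):
            ss = s.subject_specific_blocks[roi]
            ref = s.reference_blocks[roi]
            ov_ss = percent_overlap(ss, ref, denom)
            guided = ap_slab_search(ss, ref, s.stack, denominator=denom)
            # widen the rigid bounds if the guided offset sits outside them,
            # so the guided solution stays in the rigid feasible set
            guided_shift = float(np.abs(guided.transform.translation).max())
            bounds_mm = max(config.optimizer_bounds_mm,
                            guided_shift + cohort.template.spec.slab_thickness_mm)
            optimal = rigid_overlap_optimize(
                ss,
                ref,
                bounds_mm=bounds_mm,
                bounds_deg=config.optimizer_bounds_deg,
                n_starts=config.optimizer_starts,
                seed=config.seed,
                guided=guided,
                denominator=denom,
            )
            guided_store[(s.subject_id, roi)] = guided
            optimal_store[(s.subject_id, roi)] = optimal
            for method, ov, mask in (
                ("subject_specific", ov_ss, ss),
                ("guided", guided.percent_overlap, guided.moved_mask),
                ("optimal", optimal.percent_overlap, optimal.moved_mask),
            ):
                records.append(AccuracyRecord(s.subject_id, roi, method, ov))
                count_rows.append(
                    {
                        "subject_id": s.subject_id,
                        "roi_label": roi,
                        "method": method,
                        "overlap_voxels": int(
                            ((mask.data > 0) & (ref.data > 0)).sum()
                        ),
                        "reference_voxels": int((ref.data > 0).sum()),
                    }
                )
        log.info("accuracy %s: %.1fs", s.subject_id, time.perf_counter() - t0)
    rec_df, summary = accuracy_table(records)

    wil_rows = []
    for roi in _roi_labels(cohort, config):
        sub = rec_df[rec_df.roi_label == roi].pivot(
            index="subject_id", columns="method", values="percent_overlap"
        )
        for a, b in (("guided", "subject_specific"), ("optimal", "guided")):
            diffs = sub[a] - sub[b]
            if np.all(diffs == 0):
                wil_rows.append(
                    {"roi_label": roi, "comparison": f"{a}_vs_{b}", "W": np.nan,
                     "p": 1.0, "n_nonzero": 0, "note": "all differences zero"}
                )
                continue
            res = wilcoxon_signed_rank(sub[a].to_numpy(), sub[b].to_numpy())
            wil_rows.append(
                {"roi_label": roi, "comparison": f"{a}_vs_{b}", "W": res.statistic,
                 "p": res.pvalue, "n_nonzero": res.n_used, "note": res.mode_used}
            )
    wilcoxon = pd.DataFrame(wil_rows)

    cnt = pd.DataFrame(count_rows)
    design = pd.DataFrame(
        {
            "guided": (cnt.method == "guided").astype(float),
            "optimal": (cnt.method == "optimal").astype(float),
        }
    )
    try:
        glm = poisson_robust(
            cnt.overlap_voxels.to_numpy(),
            cnt.reference_voxels.to_numpy(),
            design,
            cluster=cnt.subject_id.to_numpy(),
        )
        poisson = glm.to_frame()
    except (ValueError, RuntimeError) as err:
        log.warning("Poisson regression degenerate: %s", err)
        poisson = pd.DataFrame(
            {"term": ["intercept", "guided", "optimal"], "estimate": np.nan,
             "robust_se": np.nan, "z": np.nan, "p": np.nan, "note": str(err)}
        )

    result = AccuracyResult(rec_df, summary, wilcoxon, poisson,
                            guided_store, optimal_store)
    if config.output:
        out = Path(config.output)
        out.mkdir(parents=True, exist_ok=True)
        rec_df.to_csv(out / "accuracy_records.tsv", sep="\t", index=False)
        summary.to_csv(out / "accuracy_summary.tsv", sep="\t", index=False)
        wilcoxon.to_csv(out / "accuracy_wilcoxon.tsv", sep="\t", index=False)
        poisson.to_csv(out / "accuracy_poisson.tsv", sep="\t", index=False)
    return result


# --------------------------------------------------------------- connectivity


@dataclass
class ConnectivityResult:
    discrepancies: dict  # roi -> FCDiscrepancy
    counts: pd.DataFrame


def run_connectivity(
    cohort: Cohort | str, config: RunConfig | None = None
) -> ConnectivityResult:
    """Seed FC of subject-specific vs reference blocks against the region set."""
    config = config or RunConfig()
    cohort = _resolve_cohort(cohort)
    rois = _roi_labels(cohort, config)
    profiles = {roi: {"subject_specific": [], "reference": []} for roi in rois}
    for s in cohort.subjects:
        t0 = time.perf_counter()
        bold, truth = simulate_bold(s, cohort.template, cohort.bold_spec)
        reg_series = region_mean_series(bold, truth.regions)
        for roi in rois:
            for method, blk in (
                ("subject_specific", s.subject_specific_blocks[roi]),
                ("reference", s.reference_blocks[roi]),
            ):
                seed_series = mean_timeseries(bold, blk)
                profiles[roi][method].append(
                    fc_profile(seed_series, reg_series, method, roi, s.subject_id)
                )
        del bold
        log.info("connectivity %s: %.1fs", s.subject_id, time.perf_counter() - t0)

    discrepancies = {}
    count_rows = []
    for i, roi in enumerate(rois):
        disc = fc_discrepancy_analysis(
            profiles[roi]["subject_specific"],
            profiles[roi]["reference"],
            region_ids=cohort.template.regions.ids,
            n_perm=config.n_perm,
            alpha=config.alpha,
            seed=np.random.default_rng(
                np.random.SeedSequence([config.seed, 0xFC, i])
            ),
        )
        discrepancies[roi] = disc
        count_rows.append(
            {"roi_label": roi, "n_increased": disc.n_increased,
             "n_decreased": disc.n_decreased}
        )
    counts = pd.DataFrame(count_rows)
    result = ConnectivityResult(discrepancies, counts)
    if config.output:
        out = Path(config.output)
        out.mkdir(parents=True, exist_ok=True)
        for roi, disc in discrepancies.items():
            disc.table.to_csv(out / f"connectivity_{roi}_regions.tsv", sep="\t", index=False)
        counts.to_csv(out / "connectivity_counts.tsv", sep="\t", index=False)
    return result


# ---------------------------------------------------------------------- whole


@dataclass
class RunReport:
    precision: PrecisionResult
    accuracy: AccuracyResult
    connectivity: ConnectivityResult
    config: RunConfig
    wall_clock_s: dict
    version: str = __version__


def run_all(cohort: Cohort | str, config: RunConfig | None = None) -> RunReport:
    config = config or RunConfig()
    cohort = _resolve_cohort(cohort)
    timings = {}
    t0 = time.perf_counter()
    precision = run_precision(cohort, config)
    timings["precision"] = time.perf_counter() - t0
    t0 = time.perf_counter()
    accuracy = run_accuracy(cohort, config)
    timings["accuracy"] = time.perf_counter() - t0
    t0 = time.perf_counter()
    connectivity = run_connectivity(cohort, config)
    timings["connectivity"] = time.perf_counter() - t0
    report = RunReport(precision, accuracy, connectivity, config, timings)
    if config.output:
        out = Path(config.output)
        out.mkdir(parents=True, exist_ok=True)
        (out / "run_report.json").write_text(
            json.dumps(
                {
                    "version": report.version,
                    "config": {**asdict(config),
                               "block_size_mm": list(config.block_size_mm),
                               "rois": list(config.rois)},
                    "wall_clock_s": timings,
                },
                indent=2,
            )
        )
    return report
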