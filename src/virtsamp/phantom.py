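"""Self-contained phantom cohort with known ground truth.

The generator builds everything the sampling analyses need without any
external data: an MNI-like template brain (smooth ellipsoid with a
sinusoidally modulated cortical shell), per-subject anatomy derived from the
template by a known rigid motion plus a smooth analytic nonlinear warp, a
jittered anterior-commissure-like landmark that drives bench-style block
placement, ground-truth reference blocks (the target blocks mapped through
the true deformation), a whole-brain region set with a planted community
structure, and BOLD-like timeseries whose region covariance is known.

Because the true template<->subject deformation is available in closed form,
registration estimation is never needed: the "registration output" consumed
by the pipeline *is* the true transform, which isolates the sampling
computations from registration error.  Every random choice flows from one
master seed through named substreams, so cohorts are bit-reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.cluster.vq import kmeans2
from scipy.spatial import cKDTree

from .connectivity import RegionSet, make_sphere_regions
from .sampling import (
    DEFAULT_BLOCK_SIZE_MM,
    DEFAULT_SLAB_THICKNESS_MM,
    AP_AXIS,
    BlockMask,
    BlockSpec,
    SliceStack,
    landmark_anchored_block,
    make_slice_stack,
    place_block,
    slab_of_point,
)
from .transforms import RigidTransform
from .volume import Grid, Volume, Volume4D, save_volume


# ------------------------------------------------------------- specifications


@dataclass(frozen=True)
class RoiDef:
    """One standard sampling target on the template."""

    label: str
    ap_mm: float  # anterior-posterior coordinate of the intended slab
    in_plane_center_mm: tuple[float, float]  # (left-right x, inferior-superior z)


DEFAULT_ROIS = (
    RoiDef("MFG", 4.0, (-34.0, 28.0)),  # dorsolateral frontal, on the AC slab
    RoiDef("MSTG", 4.0, (-50.0, -14.0)),  # lateral temporal, on the AC slab
    RoiDef("IPL", -38.0, (-42.0, 44.0)),  # lateral parietal
    RoiDef("V1", -62.0, (-10.0, 2.0)),  # medial occipital
)


@dataclass(frozen=True)
class PhantomSpec:
    """Template geometry, landmark, target ROIs, and region-set layout."""

    shape: tuple[int, int, int] = (96, 120, 96)
    voxel_mm: float = 2.0
    brain_semiaxes_mm: tuple[float, float, float] = (72.0, 90.0, 68.0)
    ribbon_amplitude: float = 0.35
    ribbon_wavelength_mm: float = 24.0
    landmark_mm: tuple[float, float, float] = (0.0, 4.0, -2.0)
    rois: tuple[RoiDef, ...] = DEFAULT_ROIS
    block_size_mm: tuple[float, float] = DEFAULT_BLOCK_SIZE_MM
    slab_thickness_mm: float = DEFAULT_SLAB_THICKNESS_MM
    n_regions: int = 264
    region_radius_mm: float = 5.0
    region_min_dist_mm: float = 11.0
    n_communities: int = 8
    seed: int = 0


@dataclass(frozen=True)
class SubjectVariability:
    """Distributional parameters of the per-subject truth draws."""

    sigma_ap_mm: float = 6.0  # landmark jitter along anterior-posterior
    sigma_inplane_mm: float = 3.0  # landmark jitter within the coronal plane
    sigma_place_mm: float = 3.0  # in-plane block placement jitter
    rigid_rot_sd_deg: float = 3.0
    rigid_trans_sd_mm: float = 5.0
    warp_amplitude_mm: float = 3.0  # max total nonlinear displacement
    warp_wavelength_mm: tuple[float, float] = (60.0, 120.0)
    n_warp_components: int = 4


@dataclass(frozen=True)
class BoldSpec:
    """BOLD-like simulation: acquisition shape plus region covariance."""

    shape: tuple[int, int, int] = (56, 68, 56)
    voxel_mm: float = 3.5
    n_volumes: int = 240
    tr_s: float = 2.5
    rho_in: float = 0.6  # within-community region correlation
    rho_out: float = 0.05  # between-community region correlation
    noise_sd: float = 1.0  # voxelwise white noise (latent signals have SD 1)
    temporal_sigma_tr: float = 0.0  # optional Gaussian smoothing along time


# ------------------------------------------------------------ true deformation


@dataclass(frozen=True)
class WarpParams:
    """Smooth analytic displacement: sum of low-frequency sinusoids (mm)."""

    amplitudes: tuple  # K x 3 displacement vectors
    directions: tuple  # K x 3 unit wave vectors
    wavelengths: tuple  # K
    phases: tuple  # K

    def lipschitz_bound(self) -> float:
        amps = np.asarray(self.amplitudes, dtype=float)
        lams = np.asarray(self.wavelengths, dtype=float)
        return float(np.sum(np.linalg.norm(amps, axis=1) * 2 * np.pi / lams))


class TrueDeformation:
    """Known template->subject map: phi(p) = R p + t + w(p), w analytic.

    The inverse (subject->template) is obtained by fixed-point iteration,
    which converges because the warp's Lipschitz constant is kept below 0.5.
    """

    def __init__(self, rigid: RigidTransform, warp: WarpParams):
        if warp.lipschitz_bound() >= 0.5:
            raise ValueError(
                "warp too large: Lipschitz bound "
                f"{warp.lipschitz_bound():.2f} >= 0.5 risks folding"
            )
        self.rigid = rigid
        self.warp = warp
        self._amps = np.asarray(warp.amplitudes, dtype=float)
        self._dirs = np.asarray(warp.directions, dtype=float)
        self._freq = 2 * np.pi / np.asarray(warp.wavelengths, dtype=float)
        self._phases = np.asarray(warp.phases, dtype=float)

    def displacement(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        phase = pts @ (self._dirs.T * self._freq) + self._phases  # N x K
        return np.sin(phase) @ self._amps

    def template_to_subject(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return self.rigid.apply(pts) + self.displacement(pts)

    def subject_to_template(
        self, points: np.ndarray, n_iter: int = 12, tol: float = 1e-8
    ) -> np.ndarray:
        q = np.atleast_2d(np.asarray(points, dtype=float))
        inv = self.rigid.inverse()
        p = inv.apply(q)
        for _ in range(n_iter):
            p_new = inv.apply(q - self.displacement(p))
            if np.max(np.abs(p_new - p)) < tol:
                p = p_new
                break
            p = p_new
        return p

    def to_dict(self) -> dict:
        return {
            "rigid": {
                "rotation": list(self.rigid.rotation),
                "translation": list(self.rigid.translation),
                "center": list(self.rigid.center),
            },
            "warp": {
                "amplitudes": np.asarray(self.warp.amplitudes).tolist(),
                "directions": np.asarray(self.warp.directions).tolist(),
                "wavelengths": list(self.warp.wavelengths),
                "phases": list(self.warp.phases),
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrueDeformation":
        r = d["rigid"]
        w = d["warp"]
        return cls(
            RigidTransform(
                tuple(r["rotation"]), tuple(r["translation"]), tuple(r["center"])
            ),
            WarpParams(
                tuple(map(tuple, w["amplitudes"])),
                tuple(map(tuple, w["directions"])),
                tuple(w["wavelengths"]),
                tuple(w["phases"]),
            ),
        )


# ------------------------------------------------------------------- template


@dataclass
class TemplateBundle:
    spec: PhantomSpec
    volume: Volume
    brain_mask: np.ndarray
    stack: SliceStack
    target_blocks: dict
    landmark: np.ndarray
    regions: RegionSet  # centers in template space (no grid masks)
    communities: np.ndarray


def _centered_grid(shape, voxel_mm: float) -> Grid:
    shape = tuple(int(s) for s in shape)
    aff = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    aff[:3, 3] = -(np.array(shape) - 1) / 2.0 * voxel_mm
    return Grid(shape, aff)


def _ellipsoid_radius(points: np.ndarray, semiaxes) -> np.ndarray:
    return np.linalg.norm(points / np.asarray(semiaxes, dtype=float), axis=-1)


def _sample_region_centers(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Blue-noise-ish centers inside the brain: rejection + min-distance greedy."""
    semi = np.asarray(spec.brain_semiaxes_mm) * 0.88
    accepted: list[np.ndarray] = []
    tree_pts: list[np.ndarray] = []
    attempts = 0
    while len(accepted) < spec.n_regions and attempts < 300000:
        cand = rng.uniform(-1, 1, size=(512, 3)) * semi
        inside = _ellipsoid_radius(cand, semi) <= 1.0
        for c in cand[inside]:
            attempts += 1
            if tree_pts:
                d = np.linalg.norm(np.asarray(tree_pts) - c, axis=1).min()
                if d < spec.region_min_dist_mm:
                    continue
            accepted.append(c)
            tree_pts.append(c)
            if len(accepted) >= spec.n_regions:
                break
    if len(accepted) < spec.n_regions:
        raise RuntimeError(
            f"could not place {spec.n_regions} regions at min distance "
            f"{spec.region_min_dist_mm} mm"
        )
    return np.asarray(accepted)


def make_template(spec: PhantomSpec | None = None) -> TemplateBundle:
    """Deterministically build the template brain and its ground truth."""
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x7E4]))
    grid = _centered_grid(spec.shape, spec.voxel_mm)
    world = grid.voxel_centers_world()
    rho = _ellipsoid_radius(world, spec.brain_semiaxes_mm)
    brain = rho <= 1.0

    # intensity: bright deep core, sinusoidally gyrified cortical shell
    k = 2 * np.pi / spec.ribbon_wavelength_mm
    gyri = (
        np.sin(k * world[..., 0])
        * np.sin(k * world[..., 1] + 1.3)
        * np.sin(k * world[..., 2] + 2.1)
    )
    shell = (rho > 0.75) & brain
    data = np.zeros(spec.shape, dtype=float)
    data[brain] = 550.0
    data[shell] += 200.0 * (1.0 + spec.ribbon_amplitude * gyri[shell])
    volume = Volume(grid, data)

    stack = make_slice_stack(grid, spec.slab_thickness_mm)
    landmark = np.asarray(spec.landmark_mm, dtype=float)
    if _ellipsoid_radius(landmark, spec.brain_semiaxes_mm) > 1.0:
        raise ValueError("landmark lies outside the brain")
    target_blocks = {}
    for roi in spec.rois:
        anchor = np.array([roi.in_plane_center_mm[0], roi.ap_mm, roi.in_plane_center_mm[1]])
        if _ellipsoid_radius(anchor, spec.brain_semiaxes_mm) > 1.0:
            raise ValueError(f"ROI {roi.label} center lies outside the brain")
        bspec = BlockSpec(
            roi.label,
            slab_of_point(stack, anchor),
            roi.in_plane_center_mm,
            spec.block_size_mm,
        )
        target_blocks[roi.label] = place_block(stack, bspec, method="target")

    centers = _sample_region_centers(spec, rng)
    _, communities = kmeans2(
        centers, spec.n_communities, minit="++", seed=rng.integers(2**31)
    )
    regions = RegionSet(
        ids=np.arange(spec.n_regions), centers=centers, radius_mm=spec.region_radius_mm
    )
    return TemplateBundle(
        spec, volume, brain, stack, target_blocks, landmark, regions,
        communities.astype(int),
    )


# ------------------------------------------------------------------- subjects


@dataclass
class SubjectTruth:
    """Everything random about one subject, serializable for regeneration."""

    subject_id: str
    deformation_params: dict
    landmark_jitter_mm: tuple[float, float, float]
    placement_jitter_mm: dict  # roi label -> (dx, dz)
    bold_seed: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "subject_id": self.subject_id,
                "deformation": self.deformation_params,
                "landmark_jitter_mm": list(self.landmark_jitter_mm),
                "placement_jitter_mm": {
                    k: list(v) for k, v in self.placement_jitter_mm.items()
                },
                "bold_seed": int(self.bold_seed),
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "SubjectTruth":
        d = json.loads(text)
        return cls(
            d["subject_id"],
            d["deformation"],
            tuple(d["landmark_jitter_mm"]),
            {k: tuple(v) for k, v in d["placement_jitter_mm"].items()},
            int(d["bold_seed"]),
        )


@dataclass
class SubjectBundle:
    subject_id: str
    volume: Volume
    stack: SliceStack
    deformation: TrueDeformation
    reference_blocks: dict
    subject_specific_blocks: dict
    landmark_true: np.ndarray  # true warped landmark, subject space
    landmark: np.ndarray  # jittered landmark the prosector "found"
    truth: SubjectTruth


def draw_subject_truth(
    subject_id: str,
    template: TemplateBundle,
    variability: SubjectVariability,
    rng: np.random.Generator,
) -> SubjectTruth:
    """Sample one subject's deformation, landmark jitter and placement jitter."""
    v = variability
    rot = np.radians(rng.normal(0.0, v.rigid_rot_sd_deg, 3))
    trans = rng.normal(0.0, v.rigid_trans_sd_mm, 3)
    rigid = RigidTransform(tuple(rot), tuple(trans), center=(0.0, 0.0, 0.0))
    k = v.n_warp_components
    dirs = rng.normal(size=(k, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    lams = rng.uniform(*v.warp_wavelength_mm, size=k)
    raw = rng.normal(size=(k, 3))
    raw /= np.linalg.norm(raw, axis=1, keepdims=True)
    mags = rng.dirichlet(np.ones(k)) * rng.uniform(0.5, 1.0) * v.warp_amplitude_mm
    amps = raw * mags[:, None]
    phases = rng.uniform(0, 2 * np.pi, size=k)
    warp = WarpParams(
        tuple(map(tuple, amps)), tuple(map(tuple, dirs)), tuple(lams), tuple(phases)
    )
    deform = TrueDeformation(rigid, warp)  # validates the fold bound
    jitter = (
        rng.normal(0.0, v.sigma_inplane_mm),
        rng.normal(0.0, v.sigma_ap_mm),
        rng.normal(0.0, v.sigma_inplane_mm),
    )
    placement = {
        roi.label: tuple(rng.normal(0.0, v.sigma_place_mm, 2)) for roi in template.spec.rois
    }
    bold_seed = int(rng.integers(2**31))
    return SubjectTruth(subject_id, deform.to_dict(), jitter, placement, bold_seed)


def _pull_through_map(
    data: np.ndarray, src_grid: Grid, target_grid: Grid, pull, order: int = 1
) -> np.ndarray:
    pts = target_grid.voxel_centers_world().reshape(-1, 3)
    src = pull(pts)
    vox = src_grid.world_to_voxel(src)
    out = ndimage.map_coordinates(
        np.asarray(data, dtype=float), vox.T, order=order, mode="constant", cval=0.0
    )
    return out.reshape(target_grid.shape)


def _pull_mask_cropped(
    mask: BlockMask, target_grid: Grid, deform: TrueDeformation, pad_mm: float = 16.0
) -> BlockMask:
    """Map a template-space mask into subject space, restricted to a padded
    bounding box around its expected location (the full grid is never needed)."""
    idx = np.argwhere(mask.data > 0)
    corners_vox = np.array(
        [[i, j, k]
         for i in (idx[:, 0].min(), idx[:, 0].max())
         for j in (idx[:, 1].min(), idx[:, 1].max())
         for k in (idx[:, 2].min(), idx[:, 2].max())],
        dtype=float,
    )
    moved = deform.template_to_subject(mask.grid.voxel_to_world(corners_vox))
    vox = target_grid.world_to_voxel(moved)
    pad = np.ceil(pad_mm / target_grid.spacing).astype(int)
    lo = np.maximum(np.floor(vox.min(axis=0)).astype(int) - pad, 0)
    hi = np.minimum(np.ceil(vox.max(axis=0)).astype(int) + pad, np.array(target_grid.shape) - 1)
    sub_shape = tuple(int(b - a + 1) for a, b in zip(lo, hi))
    aff = target_grid.affine.copy()
    aff[:3, 3] = target_grid.voxel_to_world(lo)[0]
    sub_grid = Grid(sub_shape, aff)
    soft = _pull_through_map(mask.data, mask.grid, sub_grid, deform.subject_to_template)
    data = np.zeros(target_grid.shape, dtype=np.uint8)
    sl = tuple(slice(int(a), int(b) + 1) for a, b in zip(lo, hi))
    data[sl] = soft >= 0.5
    if data.sum() == 0:
        raise ValueError(f"reference block {mask.roi_label} empty after warping")
    out = BlockMask(
        target_grid, data, roi_label=mask.roi_label, method="reference", slab_index=None
    )
    return out


def make_subject(
    template: TemplateBundle, truth: SubjectTruth, make_image: bool = True
) -> SubjectBundle:
    """Realize one subject: warped anatomy, reference blocks, bench placement.

    The subject image is the template pulled through the true deformation;
    the reference blocks are the target blocks mapped by the same (exact)
    transform.  Subject-specific blocks emulate the prosector: the slab is
    chosen from the jittered landmark (offset by each ROI's nominal
    slab-count distance from the landmark), and the in-plane position is the
    true warped ROI position perturbed by placement jitter.
    """
    deform = TrueDeformation.from_dict(truth.deformation_params)
    grid = template.volume.grid
    if make_image:
        img = _pull_through_map(
            template.volume.data, grid, grid, deform.subject_to_template
        )
        volume = Volume(grid, img)
    else:
        volume = Volume(grid, np.zeros(grid.shape, dtype=np.float32))
    stack = make_slice_stack(grid, template.spec.slab_thickness_mm)

    reference_blocks = {
        label: _pull_mask_cropped(blk, grid, deform)
        for label, blk in template.target_blocks.items()
    }
    landmark_true = deform.template_to_subject(template.landmark)[0]
    landmark = landmark_true + np.asarray(truth.landmark_jitter_mm, dtype=float)

    ss_blocks = {}
    for roi in template.spec.rois:
        anchor_t = np.array(
            [roi.in_plane_center_mm[0], roi.ap_mm, roi.in_plane_center_mm[1]]
        )
        roi_ap_offset = roi.ap_mm - template.landmark[AP_AXIS]
        slab_anchor = landmark + np.array([0.0, roi_ap_offset, 0.0])
        true_inplane = deform.template_to_subject(anchor_t)[0][[0, 2]]
        jit = np.asarray(truth.placement_jitter_mm[roi.label], dtype=float)
        offset = true_inplane + jit - slab_anchor[[0, 2]]
        ss_blocks[roi.label] = landmark_anchored_block(
            stack,
            slab_anchor,
            offset,
            size_mm=template.spec.block_size_mm,
            roi_label=roi.label,
            method="subject_specific",
        )
    return SubjectBundle(
        truth.subject_id,
        volume,
        stack,
        deform,
        reference_blocks,
        ss_blocks,
        landmark_true,
        landmark,
        truth,
    )


# ----------------------------------------------------------------------- BOLD


@dataclass
class BoldTruth:
    """Ground truth behind one simulated BOLD run."""

    region_cov: np.ndarray
    communities: np.ndarray
    centers_subject: np.ndarray
    regions: RegionSet  # sphere masks on the functional grid, subject space
    membership: np.ndarray  # per-brain-voxel nearest-region index (flat)
    brain_flat: np.ndarray  # flat indices of in-brain functional voxels


def community_covariance(
    communities: np.ndarray, rho_in: float, rho_out: float
) -> np.ndarray:
    """Region covariance with unit variances and block community structure."""
    same = communities[:, None] == communities[None, :]
    cov = np.where(same, rho_in, rho_out)
    np.fill_diagonal(cov, 1.0)
    try:
        np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as err:
        raise ValueError("implied region covariance is not positive definite") from err
    return cov


def simulate_bold(
    subject: SubjectBundle,
    template: TemplateBundle,
    spec: BoldSpec | None = None,
    seed: int | None = None,
) -> tuple[Volume4D, BoldTruth]:
    """BOLD-like 4D series on a functional grid in subject space.

    Region latent signals are drawn from the community covariance; every
    in-brain voxel carries the latent signal of its nearest region plus
    white noise.  Deterministic given the seed (default: the subject's
    recorded ``bold_seed``).
    """
    spec = spec or BoldSpec()
    seed = subject.truth.bold_seed if seed is None else seed
    rng = np.random.default_rng(seed)
    fgrid = _centered_grid(spec.shape, spec.voxel_mm)

    cov = community_covariance(template.communities, spec.rho_in, spec.rho_out)
    chol = np.linalg.cholesky(cov)
    latent = chol @ rng.standard_normal((template.regions.n_regions, spec.n_volumes))
    if spec.temporal_sigma_tr > 0:
        latent = ndimage.gaussian_filter1d(latent, spec.temporal_sigma_tr, axis=1)
        latent /= latent.std(axis=1, keepdims=True)

    centers_subj = subject.deformation.template_to_subject(template.regions.centers)
    regions = make_sphere_regions(
        centers_subj, template.spec.region_radius_mm, grid=fgrid,
        ids=template.regions.ids,
    )

    # in-brain functional voxels: the template brain mask pulled into subject space
    brain = (
        _pull_through_map(
            template.brain_mask.astype(float),
            template.volume.grid,
            fgrid,
            subject.deformation.subject_to_template,
        )
        >= 0.5
    )
    brain_flat = np.flatnonzero(brain.reshape(-1))
    vox_world = fgrid.voxel_centers_world().reshape(-1, 3)[brain_flat]
    _, membership = cKDTree(centers_subj).query(vox_world)

    data = rng.standard_normal(
        (int(np.prod(spec.shape)), spec.n_volumes), dtype=np.float32
    )
    data *= spec.noise_sd
    data[brain_flat] += latent[membership].astype(np.float32)
    vol4d = Volume4D(fgrid, data.reshape(spec.shape + (spec.n_volumes,)), tr=spec.tr_s)
    return vol4d, BoldTruth(cov, template.communities, centers_subj, regions,
                            membership, brain_flat)


# --------------------------------------------------------------------- cohort


@dataclass
class Cohort:
    template: TemplateBundle
    subjects: list
    variability: SubjectVariability
    bold_spec: BoldSpec
    master_seed: int

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)


def make_cohort(
    n: int = 35,
    master_seed: int = 0,
    phantom_spec: PhantomSpec | None = None,
    variability: SubjectVariability | None = None,
    bold_spec: BoldSpec | None = None,
    make_images: bool | None = None,
    outdir=None,
    write_bold: bool = False,
) -> Cohort:
    """Generate a phantom cohort; optionally serialize it to ``outdir``.

    ``make_images=False`` skips rendering the (analysis-irrelevant) subject
    anatomy volumes; block masks and deformations are always produced.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if make_images is None:
        make_images = outdir is not None
    phantom_spec = phantom_spec or PhantomSpec()
    variability = variability or SubjectVariability()
    bold_spec = bold_spec or BoldSpec()
    template = make_template(phantom_spec)
    root = np.random.SeedSequence([int(master_seed), 0xC0C0])
    subjects = []
    for i, child in enumerate(root.spawn(n)):
        rng = np.random.default_rng(child)
        truth = draw_subject_truth(f"sub-{i + 1:02d}", template, variability, rng)
        subjects.append(make_subject(template, truth, make_image=make_images))
    cohort = Cohort(template, subjects, variability, bold_spec, int(master_seed))
    if outdir is not None:
        save_cohort(cohort, outdir, write_bold=write_bold)
    return cohort


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def save_cohort(cohort: Cohort, outdir, write_bold: bool = False) -> Path:
    """Write the cohort tree: template + subject volumes, masks, truth JSON,
    and a checksum manifest from which everything is regenerable."""
    out = Path(outdir)
    (out / "subjects").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(exist_ok=True)
    (out / "truth").mkdir(exist_ok=True)
    save_volume(cohort.template.volume, out / "template.nii.gz")
    meta = {
        "n_subjects": cohort.n_subjects,
        "master_seed": cohort.master_seed,
        "phantom_spec": asdict(cohort.template.spec),
        "variability": asdict(cohort.variability),
        "bold_spec": asdict(cohort.bold_spec),
    }
    (out / "cohort.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    cohort.template.regions.save_tsv(out / "regions.tsv")
    for label, blk in cohort.template.target_blocks.items():
        blk.save(out / "masks" / f"template_{label}_target.nii.gz")
    for s in cohort.subjects:
        save_volume(s.volume, out / "subjects" / f"{s.subject_id}_T1.nii.gz")
        (out / "truth" / f"{s.subject_id}.json").write_text(s.truth.to_json())
        for label, blk in s.reference_blocks.items():
            blk.save(out / "masks" / f"{s.subject_id}_{label}_reference.nii.gz")
        for label, blk in s.subject_specific_blocks.items():
            blk.save(out / "masks" / f"{s.subject_id}_{label}_subject_specific.nii.gz")
        if write_bold:
            vol4d, _ = simulate_bold(s, cohort.template, cohort.bold_spec)
            save_volume(vol4d, out / "subjects" / f"{s.subject_id}_bold.nii.gz")
    rows = []
    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name != "manifest.tsv":
            rows.append(f"{p.relative_to(out)}\t{_sha256(p)}")
    (out / "manifest.tsv").write_text("path\tsha256\n" + "\n".join(rows) + "\n")
    return out


def verify_manifest(cohort_dir) -> bool:
    root = Path(cohort_dir)
    lines = (root / "manifest.tsv").read_text().strip().splitlines()[1:]
    for line in lines:
        rel, digest = line.split("\t")
        if _sha256(root / rel) != digest:
            return False
    return True


def load_cohort(cohort_dir, make_images: bool = False) -> Cohort:
    """Regenerate a cohort in memory from its serialized truth records."""
    root = Path(cohort_dir)
    meta = json.loads((root / "cohort.json").read_text())
    ps = meta["phantom_spec"]
    phantom_spec = PhantomSpec(
        shape=tuple(ps["shape"]),
        voxel_mm=ps["voxel_mm"],
        brain_semiaxes_mm=tuple(ps["brain_semiaxes_mm"]),
        ribbon_amplitude=ps["ribbon_amplitude"],
        ribbon_wavelength_mm=ps["ribbon_wavelength_mm"],
        landmark_mm=tuple(ps["landmark_mm"]),
        rois=tuple(
            RoiDef(r["label"], r["ap_mm"], tuple(r["in_plane_center_mm"]))
            for r in ps["rois"]
        ),
        block_size_mm=tuple(ps["block_size_mm"]),
        slab_thickness_mm=ps["slab_thickness_mm"],
        n_regions=ps["n_regions"],
        region_radius_mm=ps["region_radius_mm"],
        region_min_dist_mm=ps["region_min_dist_mm"],
        n_communities=ps["n_communities"],
        seed=ps["seed"],
    )
    vb = meta["variability"]
    variability = SubjectVariability(
        sigma_ap_mm=vb["sigma_ap_mm"],
        sigma_inplane_mm=vb["sigma_inplane_mm"],
        sigma_place_mm=vb["sigma_place_mm"],
        rigid_rot_sd_deg=vb["rigid_rot_sd_deg"],
        rigid_trans_sd_mm=vb["rigid_trans_sd_mm"],
        warp_amplitude_mm=vb["warp_amplitude_mm"],
        warp_wavelength_mm=tuple(vb["warp_wavelength_mm"]),
        n_warp_components=vb["n_warp_components"],
    )
    bs = meta["bold_spec"]
    bold_spec = BoldSpec(
        shape=tuple(bs["shape"]),
        voxel_mm=bs["voxel_mm"],
        n_volumes=bs["n_volumes"],
        tr_s=bs["tr_s"],
        rho_in=bs["rho_in"],
        rho_out=bs["rho_out"],
        noise_sd=bs["noise_sd"],
        temporal_sigma_tr=bs["temporal_sigma_tr"],
    )
    template = make_template(phantom_spec)
    subjects = []
    for p in sorted((root / "truth").glob("*.json")):
        truth = SubjectTruth.from_json(p.read_text())
        subjects.append(make_subject(template, truth, make_image=make_images))
    return Cohort(template, subjects, variability, bold_spec, meta["master_seed"])
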