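"""Synthetic phantom cohort: template, subjects, BOLD, serialization."""

import numpy as np
import pytest

from virtsamp.phantom import (
    BoldSpec,
    PhantomSpec,
    SubjectTruth,
    SubjectVariability,
    TrueDeformation,
    WarpParams,
    community_covariance,
    draw_subject_truth,
    load_cohort,
    make_cohort,
    make_subject,
    make_template,
    simulate_bold,
    verify_manifest,
)
from virtsamp.sampling import slab_of_point
from virtsamp.transforms import RigidTransform, apply_transform_to_mask, percent_overlap


@pytest.fixture(scope="module")
def template():
    return make_template(PhantomSpec())


def identity_truth(template, **over):
    base = dict(
        subject_id="sub-id",
        deformation_params=TrueDeformation(
            RigidTransform(),
            WarpParams(((0.0, 0.0, 0.0),), ((1.0, 0.0, 0.0),), (80.0,), (0.0,)),
        ).to_dict(),
        landmark_jitter_mm=(0.0, 0.0, 0.0),
        placement_jitter_mm={r.label: (0.0, 0.0) for r in template.spec.rois},
        bold_seed=7,
    )
    base.update(over)
    return SubjectTruth(**base)


class TestTemplate:
    def test_deterministic(self):
        a = make_template(PhantomSpec())
        b = make_template(PhantomSpec())
        assert np.array_equal(a.volume.data, b.volume.data)
        assert np.array_equal(a.regions.centers, b.regions.centers)
        assert np.array_equal(a.communities, b.communities)

    def test_four_target_blocks_nominal_volume(self, template):
        assert set(template.target_blocks) == {"MFG", "MSTG", "IPL", "V1"}
        nominal = 38.0 * 32.0 * 4.0
        for blk in template.target_blocks.values():
            assert abs(blk.volume_mm3 - nominal) / nominal < 0.12

    def test_brain_volume_close_to_analytic(self, template):
        a, b, c = template.spec.brain_semiaxes_mm
        analytic = 4.0 / 3.0 * np.pi * a * b * c
        measured = template.brain_mask.sum() * template.volume.grid.voxel_volume_mm3
        assert abs(measured - analytic) / analytic < 0.10

    def test_regions_inside_brain_and_spaced(self, template):
        spec = template.spec
        r = np.linalg.norm(
            template.regions.centers / np.array(spec.brain_semiaxes_mm), axis=1
        )
        assert (r <= 1.0).all()
        d = np.linalg.norm(
            template.regions.centers[:, None] - template.regions.centers[None], axis=-1
        )
        np.fill_diagonal(d, np.inf)
        assert d.min() >= spec.region_min_dist_mm - 1e-9


class TestSubjects:
    def test_identity_subject_reproduces_template(self, template):
        sb = make_subject(template, identity_truth(template), make_image=True)
        inner = template.brain_mask
        assert np.allclose(sb.volume.data[inner], template.volume.data[inner], atol=1e-6)
        for label, tgt in template.target_blocks.items():
            assert percent_overlap(sb.reference_blocks[label], tgt) == 100.0
            assert percent_overlap(sb.subject_specific_blocks[label], tgt) == 100.0

    def test_pure_translation_shifts_reference_two_slabs(self, template):
        truth = identity_truth(template)
        truth.deformation_params["rigid"]["translation"] = [0.0, 8.0, 0.0]
        sb = make_subject(template, truth, make_image=False)
        for label, tgt in template.target_blocks.items():
            ref_slab = slab_of_point(sb.stack, sb.reference_blocks[label].centroid_world())
            assert ref_slab == tgt.slab_index + 2

    def test_landmark_slab_error_rate_at_default_jitter(self, template):
        # with 6 mm AP landmark jitter and 4 mm slabs, a sizeable fraction of
        # subjects must sample a different slab than the reference occupies
        rng = np.random.default_rng(11)
        mismatches = 0
        n = 20
        for i in range(n):
            truth = draw_subject_truth(f"s{i}", template, SubjectVariability(), rng)
            sb = make_subject(template, truth, make_image=False)
            ref = sb.reference_blocks["MFG"]
            ss = sb.subject_specific_blocks["MFG"]
            ref_slab = slab_of_point(sb.stack, ref.centroid_world())
            if ref_slab != ss.slab_index:
                mismatches += 1
        assert mismatches / n >= 0.30

    def test_reference_equals_independently_rewarped_target(self, template):
        rng = np.random.default_rng(3)
        truth = draw_subject_truth("s0", template, SubjectVariability(), rng)
        sb = make_subject(template, truth, make_image=False)
        for label, tgt in template.target_blocks.items():
            redone = apply_transform_to_mask(
                tgt, sb.deformation.subject_to_template, sb.volume.grid
            )
            assert percent_overlap(sb.reference_blocks[label], redone) >= 99.0

    def test_fold_risk_rejected(self):
        big = WarpParams(((20.0, 0.0, 0.0),), ((1.0, 0.0, 0.0),), (40.0,), (0.0,))
        with pytest.raises(ValueError, match="warp too large"):
            TrueDeformation(RigidTransform(), big)

    def test_deformation_inverse_consistency(self, template, rng):
        truth = draw_subject_truth("s0", template, SubjectVariability(), rng)
        deform = TrueDeformation.from_dict(truth.deformation_params)
        pts = rng.uniform(-60, 60, size=(50, 3))
        back = deform.subject_to_template(deform.template_to_subject(pts))
        assert np.max(np.abs(back - pts)) < 1e-6


class TestBold:
    def test_covariance_structure_valid(self, template):
        cov = community_covariance(template.communities, 0.6, 0.05)
        assert np.allclose(np.diag(cov), 1.0)
        assert np.linalg.eigvalsh(cov).min() > 0

    def test_zero_noise_region_voxels_identical(self, template):
        sb = make_subject(template, identity_truth(template), make_image=False)
        spec = BoldSpec(shape=(28, 34, 28), voxel_mm=7.0, n_volumes=20, noise_sd=0.0)
        vol4d, truth = simulate_bold(sb, template, spec, seed=5)
        flat = vol4d.data.reshape(-1, 20)
        one_region = truth.brain_flat[truth.membership == truth.membership[0]]
        assert np.allclose(flat[one_region], flat[one_region][0], atol=1e-5)

    def test_empirical_region_correlations_match_truth(self, template):
        from virtsamp.connectivity import region_mean_series

        sb = make_subject(template, identity_truth(template), make_image=False)
        spec = BoldSpec(shape=(40, 48, 40), voxel_mm=5.0, n_volumes=4000, noise_sd=0.3)
        vol4d, truth = simulate_bold(sb, template, spec, seed=5)
        series = region_mean_series(vol4d, truth.regions)
        ok = np.isfinite(series).all(axis=1)
        emp = np.corrcoef(series[ok])
        expected = truth.region_cov[np.ix_(ok, ok)]
        # mean-over-sphere noise attenuates diagonal-free entries only mildly
        off = ~np.eye(ok.sum(), dtype=bool)
        assert np.abs(emp[off] - expected[off]).mean() < 0.05

    def test_deterministic_given_seed(self, template):
        sb = make_subject(template, identity_truth(template), make_image=False)
        spec = BoldSpec(shape=(28, 34, 28), voxel_mm=7.0, n_volumes=10)
        a, _ = simulate_bold(sb, template, spec, seed=9)
        b, _ = simulate_bold(sb, template, spec, seed=9)
        assert np.array_equal(a.data, b.data)


class TestCohort:
    def test_same_master_seed_identical_truth(self):
        a = make_cohort(n=2, master_seed=5, make_images=False)
        b = make_cohort(n=2, master_seed=5, make_images=False)
        for sa, sb in zip(a.subjects, b.subjects):
            assert sa.truth.to_json() == sb.truth.to_json()

    def test_roundtrip_through_disk(self, tmp_path):
        out = tmp_path / "cohort"
        a = make_cohort(n=2, master_seed=5, outdir=out)
        assert verify_manifest(out)
        b = load_cohort(out)
        assert b.n_subjects == 2 and b.master_seed == 5
        for sa, sb in zip(a.subjects, b.subjects):
            assert sa.truth.to_json() == sb.truth.to_json()
            for roi in ("MFG", "V1"):
                assert np.array_equal(
                    sa.subject_specific_blocks[roi].data,
                    sb.subject_specific_blocks[roi].data,
                )

    def test_expected_files_written(self, tmp_path):
        out = tmp_path / "cohort"
        make_cohort(n=2, master_seed=1, outdir=out)
        assert (out / "template.nii.gz").exists()
        assert len(list((out / "subjects").glob("*_T1.nii.gz"))) == 2
        # per subject: 4 reference + 4 subject-specific masks
        assert len(list((out / "masks").glob("sub-*_*.nii.gz"))) == 16
        assert (out / "manifest.tsv").exists()

    def test_invalid_n_rejected(self):
        with pytest.raises(ValueError):
            make_cohort(n=0)
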