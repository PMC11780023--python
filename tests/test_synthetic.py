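import numpy as np
import pytest

from dlradiomics.io_preproc import Mask
from dlradiomics.synthetic import (
    PhantomSpec,
    generate_case,
    generate_cohort,
    perturb_mask,
    write_cohort,
)


def dice(a, b):
    a = a.astype(bool)
    b = b.astype(bool)
    return 2 * (a & b).sum() / (a.sum() + b.sum())


class TestPhantomSpec:
    def test_class_probs_validated(self):
        with pytest.raises(ValueError, match="class_probs"):
            PhantomSpec(class_probs=(0.5, 0.5, 0.5))

    def test_grid_too_small(self):
        with pytest.raises(ValueError, match="grid too small"):
            PhantomSpec(grid_shape=(16, 16, 16), lesion_radius_mm=(6.0, 10.0))

    def test_null_spec_has_no_class_signal(self):
        assert PhantomSpec.null(30).is_null
        assert not PhantomSpec.strong_effect(30).is_null


class TestGenerateCohort:
    def test_balanced_apportionment(self):
        recs = generate_cohort(PhantomSpec(n_cases=12, seed=0))
        counts = np.bincount([r.label for r in recs], minlength=3)
        assert counts.tolist() == [4, 4, 4]

    def test_deterministic(self):
        spec = PhantomSpec(n_cases=3, seed=42)
        a = generate_cohort(spec)
        b = generate_cohort(spec)
        for ra, rb in zip(a, b):
            assert ra.label == rb.label
            assert np.array_equal(ra.ap_volume.data, rb.ap_volume.data)
            assert np.array_equal(ra.pp_volume.data, rb.pp_volume.data)
            assert np.array_equal(ra.mask.data, rb.mask.data)

    def test_shared_mask_and_tags(self):
        recs = generate_cohort(PhantomSpec(n_cases=6, seed=1, external_frac=0.5))
        tags = [r.cohort_tag for r in recs]
        assert tags.count("external") == 3
        for r in recs:
            assert r.ap_volume.shape == r.mask.shape == r.pp_volume.shape
            assert r.mask.n_voxels > 0


class TestGenerateCase:
    def test_zero_perturbation_gives_symmetric_sphere(self):
        spec = PhantomSpec(
            n_cases=1,
            grid_shape=(40, 40, 40),
            margin_irregularity=(0.0, 0.0, 0.0),
            capsule_prob=(0.0, 0.0, 0.0),
            center_jitter_mm=0.0,
            seed=0,
        )
        rec = generate_case(0, spec, np.random.default_rng(0))
        m = rec.mask.data
        assert np.array_equal(m, m.transpose(1, 0, 2))
        assert np.array_equal(m, m.transpose(2, 1, 0))

    def test_enhancement_contrast_recovered(self):
        spec = PhantomSpec(
            n_cases=1,
            grid_shape=(44, 44, 36),
            lesion_radius_mm=(10.0, 10.0),
            margin_irregularity=(0.0, 0.0, 0.0),
            capsule_prob=(0.0, 0.0, 0.0),
            enhancement_ap=(40.0, 40.0, 40.0),
            texture_sd=(2.0, 2.0, 2.0),
            noise_sd=5.0,
            seed=0,
        )
        rec = generate_case(0, spec, np.random.default_rng(5))
        inside = rec.ap_volume.data[rec.mask.data.astype(bool)].mean()
        outside = rec.ap_volume.data[~rec.mask.data.astype(bool)].mean()
        assert 37.0 <= inside - outside <= 43.0

    def test_zero_jitter_reader_masks_identical(self):
        spec = PhantomSpec(n_cases=1, reader_jitter_mm=0.0, seed=0)
        rec = generate_case(1, spec, np.random.default_rng(1))
        assert np.array_equal(rec.reader2_mask.data, rec.mask.data)
        assert np.array_equal(rec.reader1_repeat_mask.data, rec.mask.data)

    def test_bad_label(self):
        spec = PhantomSpec(n_cases=1, seed=0)
        with pytest.raises(ValueError, match="label"):
            generate_case(3, spec, np.random.default_rng(0))


class TestPerturbMask:
    def test_zero_jitter_is_identity(self, sphere_mask):
        out = perturb_mask(sphere_mask, 0.0, np.random.default_rng(0))
        assert np.array_equal(out.data, sphere_mask.data)

    def test_small_jitter_high_dice(self, sphere_mask):
        out = perturb_mask(sphere_mask, 1.0, np.random.default_rng(3))
        assert 0.8 <= dice(out.data, sphere_mask.data) <= 1.0

    def test_bounded_jitter_dice_floor(self, sphere_mask):
        # radius 10 mm >= 8 mm, jitter <= 2 mm: overlap stays above 0.5
        for seed in range(5):
            out = perturb_mask(sphere_mask, 2.0, np.random.default_rng(seed))
            assert dice(out.data, sphere_mask.data) >= 0.5

    def test_different_seeds_differ(self, sphere_mask):
        a = perturb_mask(sphere_mask, 1.5, np.random.default_rng(1))
        b = perturb_mask(sphere_mask, 1.5, np.random.default_rng(2))
        assert dice(a.data, b.data) < 1.0

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            perturb_mask(Mask(np.zeros((4, 4, 4))), 1.0, np.random.default_rng(0))


class TestNullFaithfulness:
    def test_feature_means_match_across_classes_under_null(self):
        # under the null spec the per-class mean enhancement contrast
        # must agree within sampling noise
        recs = generate_cohort(PhantomSpec.null(n_cases=45, seed=3))
        contrasts = {0: [], 1: [], 2: []}
        for r in recs:
            m = r.mask.data.astype(bool)
            contrasts[r.label].append(r.ap_volume.data[m].mean() - r.ap_volume.data[~m].mean())
        means = [np.mean(v) for v in contrasts.values()]
        ses = [np.std(v, ddof=1) / np.sqrt(len(v)) for v in contrasts.values()]
        for i in range(3):
            for j in range(i + 1, 3):
                t = abs(means[i] - means[j]) / np.hypot(ses[i], ses[j])
                assert t < 4.0


def test_write_cohort_manifest(tmp_path):
    recs = generate_cohort(PhantomSpec(n_cases=3, seed=9))
    manifest = write_cohort(recs, tmp_path)
    import pandas as pd

    df = pd.read_csv(manifest)
    assert len(df) == 3
    assert {"case_id", "cohort_tag", "label", "ap_path", "pp_path", "mask_path"} <= set(df.columns)
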