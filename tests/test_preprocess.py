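import numpy as np
import pytest

from lesionfuse.io_core import ClinicalRecord, DatasetManifest
from lesionfuse.preprocess import (PreprocessStats, assemble_arrays,
                                   augment_image, balance_classes,
                                   impute_and_encode, preprocess_image,
                                   split_dataset)
from lesionfuse.synthetic_data import SynthConfig, generate_metadata


def make_manifest(counts: dict[str, int]) -> DatasetManifest:
    records = []
    i = 0
    for dx, n in counts.items():
        for _ in range(n):
            records.append(ClinicalRecord(
                image_id=f"I{i:04d}", lesion_id=f"L{i:04d}", dx=dx,
                dx_type="histo", age=40.0 + (i % 5) * 10, sex="male",
                localization="back"))
            i += 1
    return DatasetManifest(records)


class TestSplit:
    def test_exact_stratified_arithmetic(self):
        m = make_manifest({dx: 10 for dx in
                           ("MEL", "NV", "BCC", "AKIEC", "BKL", "DF",
                            "VASC")})
        train, test = split_dataset(m, 0.7, seed=0)
        assert all(v == 7 for v in train.class_counts().values())
        assert all(v == 3 for v in test.class_counts().values())

    def test_partition_contract(self, tiny_cohort):
        _, manifest, _ = tiny_cohort
        train, test = split_dataset(manifest, 0.7, seed=1)
        tr, te = set(train.image_ids), set(test.image_ids)
        assert tr & te == set()
        assert tr | te == set(manifest.image_ids)

    def test_deterministic_given_seed(self, tiny_cohort):
        _, manifest, _ = tiny_cohort
        a1, b1 = split_dataset(manifest, 0.7, seed=5)
        a2, b2 = split_dataset(manifest, 0.7, seed=5)
        assert a1.image_ids == a2.image_ids
        assert b1.image_ids == b2.image_ids

    def test_singleton_class_rejected(self):
        m = make_manifest({"MEL": 1, "NV": 5})
        with pytest.raises(ValueError, match="MEL"):
            split_dataset(m, 0.7, seed=0)

    def test_bad_fraction_rejected(self, tiny_cohort):
        _, manifest, _ = tiny_cohort
        with pytest.raises(ValueError):
            split_dataset(manifest, 1.0, seed=0)


class TestBalance:
    def test_balancing_arithmetic(self):
        m = make_manifest({"MEL": 2, "NV": 5, "BCC": 9})
        out = balance_classes(m, 5, seed=0)
        counts = out.class_counts()
        assert counts["MEL"] == counts["NV"] == counts["BCC"] == 5
        assert len(out) == 15

    def test_undersampled_class_is_subset_of_originals(self):
        m = make_manifest({"MEL": 2, "NV": 9})
        out = balance_classes(m, 5, seed=0)
        nv = [r for r in out.records if r.dx == "NV"]
        originals = {r.image_id for r in m.records}
        assert all(r.image_id in originals for r in nv)
        assert all(r.augment is None for r in nv)

    def test_oversampled_class_keeps_provenance(self):
        m = make_manifest({"MEL": 2, "NV": 9})
        out = balance_classes(m, 5, seed=0)
        synth = [r for r in out.records if r.augment is not None]
        assert len(synth) == 3
        originals = {r.image_id for r in m.records}
        assert all(r.source_image_id in originals for r in synth)

    def test_idempotent_on_balanced_input(self):
        m = make_manifest({"MEL": 5, "NV": 5})
        out = balance_classes(m, 5, seed=3)
        assert sorted(out.image_ids) == sorted(m.image_ids)

    def test_empty_target_rejected(self):
        m = make_manifest({"MEL": 3})
        with pytest.raises(ValueError):
            balance_classes(m, 0)


class TestAugment:
    def test_hflip_is_involution(self, rng):
        img = rng.integers(0, 256, (8, 10, 3)).astype(np.uint8)
        out = augment_image(augment_image(img, "hflip"), "hflip")
        np.testing.assert_array_equal(out, img)

    def test_vflip_is_involution(self, rng):
        img = rng.integers(0, 256, (8, 10, 3)).astype(np.uint8)
        out = augment_image(augment_image(img, "vflip"), "vflip")
        np.testing.assert_array_equal(out, img)

    def test_rotate_90_four_times_identity(self, rng):
        img = rng.integers(0, 256, (8, 8, 3)).astype(np.uint8)
        out = img
        for _ in range(4):
            out = augment_image(out, "rotate", {"angle": 90.0})
        np.testing.assert_array_equal(out, img)

    def test_zero_amplitude_jitter_is_identity(self, rng):
        img = rng.integers(0, 256, (6, 6, 3)).astype(np.uint8)
        out = augment_image(img, "jitter", {"amplitude": 0.0}, rng)
        np.testing.assert_array_equal(out, img)

    def test_jitter_bounded_and_shape_preserved(self, rng):
        img = rng.integers(0, 256, (6, 6, 3)).astype(np.uint8)
        out = augment_image(img, "jitter", {"amplitude": 0.02}, rng)
        assert out.shape == img.shape
        assert out.min() >= 0 and out.max() <= 255

    @pytest.mark.parametrize("factor", [0.9, 1.1])
    def test_scale_preserves_canvas(self, rng, factor):
        img = rng.integers(0, 256, (12, 12, 3)).astype(np.uint8)
        out = augment_image(img, "scale", {"factor": factor}, rng)
        assert out.shape == img.shape

    def test_arbitrary_rotation_preserves_canvas(self, rng):
        img = rng.integers(0, 256, (12, 12, 3)).astype(np.uint8)
        out = augment_image(img, "rotate", {"angle": 17.0}, rng)
        assert out.shape == img.shape

    def test_unknown_op_rejected(self, rng):
        img = np.zeros((4, 4, 3), np.uint8)
        with pytest.raises(ValueError, match="warp"):
            augment_image(img, "warp")


class TestImagePreprocess:
    def test_constant_white_maps_to_ones(self):
        img = np.full((8, 8, 3), 255, np.uint8)
        out = preprocess_image(img, 16)
        assert out.shape == (16, 16, 3)
        np.testing.assert_allclose(out, 1.0, atol=1e-6)

    def test_division_by_255(self):
        img = np.full((8, 8, 3), 51, np.uint8)
        out = preprocess_image(img, 8)
        np.testing.assert_allclose(out, 0.2, atol=1e-7)

    def test_range_contract(self, rng):
        img = rng.integers(0, 256, (20, 30, 3)).astype(np.uint8)
        out = preprocess_image(img, 12)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_non_three_channel_rejected(self):
        with pytest.raises(ValueError):
            preprocess_image(np.zeros((8, 8), np.uint8), 8)


class TestImputeEncode:
    def _manifest_with_ages(self, ages, sexes=None):
        records = []
        sexes = sexes or ["male"] * len(ages)
        for i, (a, s) in enumerate(zip(ages, sexes)):
            records.append(ClinicalRecord(
                image_id=f"I{i}", lesion_id=f"L{i}", dx="NV",
                dx_type="histo", age=a, sex=s, localization="back"))
        return DatasetManifest(records)

    def test_median_imputation(self):
        m = self._manifest_with_ages([10.0, 20.0, None, 40.0])
        enc, _, stats = impute_and_encode(m, "fit")
        assert stats.age_median == 20.0
        # the standardized value of the imputed row equals that of age 20
        assert enc.matrix[2, 0] == enc.matrix[1, 0]

    def test_mode_imputation(self):
        m = self._manifest_with_ages([30.0, 30.0, 30.0],
                                     ["male", "male", None])
        enc, _, stats = impute_and_encode(m, "fit")
        assert stats.modes["sex"] == "male"
        names = enc.feature_names
        male_col = names.index("sex=male")
        assert (enc.matrix[:, male_col] == 1).all()

    def test_onehot_groups_sum_to_one(self, tiny_cohort):
        _, manifest, _ = tiny_cohort
        enc, _, _ = impute_and_encode(manifest, "fit")
        names = enc.feature_names
        for group in ("dx_type", "sex", "localization"):
            cols = [i for i, n in enumerate(names)
                    if n.startswith(group + "=")]
            np.testing.assert_allclose(enc.matrix[:, cols].sum(axis=1), 1.0)

    def test_standardized_age_mean_zero_unit_variance(self, tiny_cohort):
        _, manifest, _ = tiny_cohort
        enc, _, _ = impute_and_encode(manifest, "fit")
        age = enc.matrix[:, 0].astype(np.float64)
        assert abs(age.mean()) < 1e-6
        assert abs(age.std() - 1.0) < 1e-5

    def test_diagnosis_never_a_feature(self, tiny_cohort):
        _, manifest, _ = tiny_cohort
        enc, labels, _ = impute_and_encode(manifest, "fit")
        assert not any(n.startswith("dx=") for n in enc.feature_names)
        assert labels.shape == (len(manifest),)

    def test_transform_before_fit_rejected(self, tiny_cohort):
        _, manifest, _ = tiny_cohort
        with pytest.raises(RuntimeError):
            impute_and_encode(manifest, PreprocessStats(fitted=False))

    def test_no_leakage_into_fitted_stats(self, tiny_cohort):
        _, manifest, _ = tiny_cohort
        train, test = split_dataset(manifest, 0.7, seed=0)
        _, _, stats = impute_and_encode(train, "fit")
        snapshot = dict(stats.__dict__)
        impute_and_encode(test, stats)
        assert stats.__dict__ == snapshot

    def test_dx_type_exclusion_switch(self, tiny_cohort):
        _, manifest, _ = tiny_cohort
        enc, _, _ = impute_and_encode(manifest, "fit", include_dx_type=False)
        assert not any(n.startswith("dx_type=") for n in enc.feature_names)


class TestAlignment:
    def test_rows_labels_images_share_image_id(self, tiny_cohort):
        _, manifest, images = tiny_cohort
        train, _ = split_dataset(manifest, 0.7, seed=0)
        balanced = balance_classes(train, 9, seed=0)
        x_img, enc, labels, _ = assemble_arrays(balanced, images, "fit", 32)
        assert x_img.shape[0] == enc.matrix.shape[0] == len(labels)
        assert enc.image_ids == balanced.image_ids
        lut = {r.image_id: r for r in balanced.records}
        for i, image_id in enumerate(enc.image_ids):
            assert labels[i] == list(
                "MEL NV BCC AKIEC BKL DF VASC".split()).index(
                    lut[image_id].dx)

    def test_augmented_record_image_rebuilt_from_source(self, tiny_cohort):
        _, manifest, images = tiny_cohort
        train, _ = split_dataset(manifest, 0.7, seed=0)
        balanced = balance_classes(train, 9, seed=1)
        synth = [r for r in balanced.records if r.augment is not None]
        assert synth, "balancing should create augmented records here"
        x_img, enc, _, _ = assemble_arrays(balanced, images, "fit", 32)
        idx = balanced.image_ids.index(synth[0].image_id)
        assert np.isfinite(x_img[idx]).all()
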