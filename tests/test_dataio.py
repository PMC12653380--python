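"""Dataset layout round trips, patient-level splitting, and augmentation."""

import dataclasses
import os

import numpy as np
import pytest

from uwunet.dataio import (AugmentConfig, CohortLoadError, SampleMeta,
                           SplitPlan, augment, grouped_split, load_cohort,
                           manifest, read_mask, write_image, write_mask)
from uwunet.phantom import PhantomConfig, generate_cohort


@pytest.fixture(scope="module")
def cohort_dir(tmp_path_factory):
    root = tmp_path_factory.mktemp("phantom_cohort")
    cfg = dataclasses.replace(PhantomConfig().for_size(64), n_patients=4, seed=3)
    generate_cohort(cfg, str(root), total_images=20, overwrite=True)
    return str(root)


def _metas(patients):
    return [SampleMeta(p, "A", "MAG", "", "") for p in patients]


def test_cohort_round_trip(cohort_dir):
    cohort = load_cohort(cohort_dir)
    assert len(cohort) == 20
    assert len({m.patient_id for _, m in cohort}) == 4
    for sample, meta in cohort:
        assert sample.image.dtype == np.float32
        assert 0.0 <= sample.image.min() and sample.image.max() <= 1.0
        assert set(np.unique(sample.mask)) <= {0, 1}
        assert sample.image.shape == sample.mask.shape
        assert meta.stage in ("A", "B") and meta.modality in ("MAG", "PS")
    df = manifest(cohort)
    assert list(df.columns) == ["patient_id", "stage", "modality", "image", "mask"]
    assert len(df) == 20


def test_manifest_csv_emitted_on_load(cohort_dir, tmp_path):
    out = tmp_path / "manifest.csv"
    load_cohort(cohort_dir, manifest_path=str(out))
    assert out.exists()


def test_mask_write_read_is_bit_exact(tmp_path):
    rng = np.random.default_rng(0)
    mask = (rng.random((32, 32)) > 0.9).astype(np.uint8)
    path = str(tmp_path / "m_mask.png")
    write_mask(path, mask)
    assert np.array_equal(read_mask(path), mask)


def test_empty_directory_yields_empty_cohort(tmp_path):
    assert load_cohort(str(tmp_path)) == []
    assert load_cohort(str(tmp_path / "missing")) == []


def test_missing_mask_is_an_itemized_error(tmp_path):
    d = tmp_path / "p01" / "A" / "MAG"
    os.makedirs(d)
    write_image(str(d / "img0.png"), np.zeros((16, 16)))
    with pytest.raises(CohortLoadError, match="img0.png"):
        load_cohort(str(tmp_path))


def test_odd_sized_image_is_rejected(tmp_path):
    d = tmp_path / "p01" / "A" / "MAG"
    os.makedirs(d)
    write_image(str(d / "img0.png"), np.zeros((15, 15)))
    write_mask(str(d / "img0_mask.png"), np.zeros((15, 15), dtype=np.uint8))
    with pytest.raises(CohortLoadError, match="15x15"):
        load_cohort(str(tmp_path))


def test_grouped_split_patient_counts_and_rounding():
    metas = _metas([f"p{i:02d}" for i in range(22)])
    plan = grouped_split(metas, test_fraction=0.1, rng_seed=0)
    assert len(plan.test_patients) == 2
    assert len(plan.train_patients) == 20
    assert not plan.train_patients & plan.test_patients
    assert plan.train_patients | plan.test_patients == {m.patient_id for m in metas}


def test_grouped_split_is_deterministic_and_order_invariant():
    patients = [f"p{i}" for i in range(10)]
    a = grouped_split(_metas(patients), 0.2, rng_seed=5)
    b = grouped_split(_metas(list(reversed(patients))), 0.2, rng_seed=5)
    assert a == b
    c = grouped_split(_metas(patients), 0.2, rng_seed=6)
    assert isinstance(c, SplitPlan)


def test_grouped_split_requires_two_patients():
    with pytest.raises(ValueError):
        grouped_split(_metas(["solo"]), 0.1, rng_seed=0)


def _phantom_sample():
    from uwunet.phantom import PhantomConfig, draw_patient_profile, generate_sample
    cfg = PhantomConfig().for_size(64)
    rng = np.random.default_rng(11)
    profile = draw_patient_profile(cfg, "p", rng)
    sample, _ = generate_sample(cfg, profile, "A", "MAG", rng)
    return sample


def test_augment_identity_when_disabled():
    sample = _phantom_sample()
    cfg = AugmentConfig(flip_probability=0.0, max_rotation_degrees=0.0)
    out = augment(sample, cfg, np.random.default_rng(0))
    assert np.array_equal(out.image, sample.image)
    assert np.array_equal(out.mask, sample.mask)


def test_flip_is_an_involution():
    sample = _phantom_sample()
    cfg = AugmentConfig(flip_probability=1.0, max_rotation_degrees=0.0)
    once = augment(sample, cfg, np.random.default_rng(0))
    twice = augment(once, cfg, np.random.default_rng(0))
    assert np.array_equal(twice.image, sample.image)
    assert np.array_equal(twice.mask, sample.mask)


def test_augment_preserves_binarity_range_and_shape():
    sample = _phantom_sample()
    cfg = AugmentConfig()
    rng = np.random.default_rng(9)
    for _ in range(5):
        out = augment(sample, cfg, rng)
        assert out.image.shape == sample.image.shape
        assert 0.0 <= out.image.min() and out.image.max() <= 1.0
        assert set(np.unique(out.mask)) <= {0, 1}


def test_augment_draws_are_seed_reproducible():
    sample = _phantom_sample()
    cfg = AugmentConfig()
    a = augment(sample, cfg, np.random.default_rng(123))
    b = augment(sample, cfg, np.random.default_rng(123))
    assert np.array_equal(a.image, b.image)
    assert np.array_equal(a.mask, b.mask)


def test_augment_config_validation():
    with pytest.raises(ValueError):
        AugmentConfig(flip_probability=1.5)
    with pytest.raises(ValueError):
        AugmentConfig(max_rotation_degrees=-1.0)
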