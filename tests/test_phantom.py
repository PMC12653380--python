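"""Phantom generator: geometry against analytic areas, modality jitter
bounds, cohort structure, and determinism."""

import dataclasses
import json
import os

import numpy as np
import pytest
from scipy import ndimage

from uwunet.dataio import Sample
from uwunet.phantom import (PatientProfile, PhantomConfig,
                            draw_patient_profile, generate_cohort,
                            generate_cohort_samples, generate_frame_pair,
                            generate_sample, _render)


def _clean_config(size=96, **kw):
    return dataclasses.replace(
        PhantomConfig().for_size(size), noise_sigma=0.0, center_jitter=0.0,
        modality_mask_jitter=0.0, papillary_probability=0.0, **kw)


def test_circular_annulus_area_matches_analytic_formula():
    cfg = _clean_config(size=128)
    r_in, thick = 18.0, 8.0
    frame = {"center": (64.0, 64.0), "r_in": r_in, "r_out": r_in + thick,
             "ratio": 1.0, "theta": 0.0, "blobs": [], "illum": (0.0, 0.0)}
    sample = _render(cfg, frame, "MAG", np.random.default_rng(0))
    analytic = np.pi * ((r_in + thick) ** 2 - r_in ** 2)
    assert abs(sample.mask.sum() - analytic) / analytic < 0.05


def test_minimal_ring_is_nonempty_and_connected():
    cfg = _clean_config(size=96)
    frame = {"center": (48.0, 48.0), "r_in": 12.0, "r_out": 13.0,
             "ratio": 1.0, "theta": 0.0, "blobs": [], "illum": (0.0, 0.0)}
    mask = _render(cfg, frame, "MAG", np.random.default_rng(0)).mask
    assert mask.sum() > 0
    _, n_components = ndimage.label(mask, structure=np.ones((3, 3)))
    assert n_components == 1


def test_generation_is_bit_deterministic():
    cfg = PhantomConfig().for_size(64)
    out = []
    for _ in range(2):
        rng = np.random.default_rng(42)
        profile = draw_patient_profile(cfg, "p", rng)
        sample, _ = generate_sample(cfg, profile, "A", "MAG", rng)
        out.append(sample)
    assert np.array_equal(out[0].image, out[1].image)
    assert np.array_equal(out[0].mask, out[1].mask)
    cohort_cfg = dataclasses.replace(cfg, n_patients=4)
    a = generate_cohort_samples(cohort_cfg, total_images=8)
    b = generate_cohort_samples(cohort_cfg, total_images=8)
    assert all(np.array_equal(x.image, y.image) for (x, _), (y, _) in zip(a, b))


def test_foreground_fraction_stays_in_small_roi_band():
    cfg = dataclasses.replace(PhantomConfig().for_size(96), n_patients=8, seed=5)
    cohort = generate_cohort_samples(cfg, total_images=40)
    for sample, _ in cohort:
        frac = sample.mask.mean()
        assert 0.005 <= frac <= 0.08


def _hausdorff(a, b):
    da = ndimage.distance_transform_edt(1 - a)
    db = ndimage.distance_transform_edt(1 - b)
    return max(db[a.astype(bool)].max(), da[b.astype(bool)].max())


def test_modality_masks_differ_only_within_jitter_band():
    cfg = PhantomConfig().for_size(96)
    rng = np.random.default_rng(2)
    profile = draw_patient_profile(cfg, "p", rng)
    for _ in range(5):
        (mag, _), (ps, _) = generate_frame_pair(cfg, profile, "A", rng)
        assert _hausdorff(mag.mask, ps.mask) <= 2 * cfg.modality_mask_jitter + 1


def test_between_patient_geometry_variance_exceeds_within():
    cfg = dataclasses.replace(PhantomConfig().for_size(96), n_patients=8, seed=1)
    cohort = generate_cohort_samples(cfg, total_images=64)
    areas = {}
    for sample, meta in cohort:
        areas.setdefault(meta.patient_id, []).append(float(sample.mask.sum()))
    patient_means = [np.mean(v) for v in areas.values()]
    within = np.mean([np.var(v) for v in areas.values()])
    assert np.var(patient_means) > within


def test_cohort_counts_match_request():
    cfg = dataclasses.replace(PhantomConfig().for_size(64), n_patients=22, seed=0)
    cohort = generate_cohort_samples(cfg, total_images=269)
    assert len(cohort) == 269
    metas = [m for _, m in cohort]
    assert len({m.patient_id for m in metas}) == 22
    assert {m.stage for m in metas} == {"A", "B"}
    assert {m.modality for m in metas} == {"MAG", "PS"}

    tiny = dataclasses.replace(cfg, n_patients=2)
    assert len(generate_cohort_samples(tiny, total_images=2)) == 2


def test_generate_cohort_writes_layout_and_provenance(tmp_path):
    cfg = dataclasses.replace(PhantomConfig().for_size(64), n_patients=3, seed=9)
    out = str(tmp_path / "cohort")
    generate_cohort(cfg, out, total_images=12)
    assert os.path.exists(os.path.join(out, "manifest.csv"))
    with open(os.path.join(out, "config.json")) as fh:
        assert json.load(fh)["total_images"] == 12
    # refuses to clobber without the overwrite flag
    with pytest.raises(FileExistsError):
        generate_cohort(cfg, out, total_images=12)
    generate_cohort(cfg, out, total_images=12, overwrite=True)


def test_papillary_blobs_excluded_from_mask_by_default():
    cfg = _clean_config(size=96)
    frame = {"center": (48.0, 48.0), "r_in": 12.0, "r_out": 18.0,
             "ratio": 1.0, "theta": 0.0, "blobs": [(48.0, 50.0, 3.0)],
             "illum": (0.0, 0.0)}
    excl = _render(cfg, frame, "MAG", np.random.default_rng(0))
    incl = _render(dataclasses.replace(cfg, include_papillary_in_mask=True),
                   frame, "MAG", np.random.default_rng(0))
    assert incl.mask.sum() > excl.mask.sum()
    # the blob is visible in the image either way (ring-like intensity)
    assert isinstance(excl, Sample)


def test_invalid_geometry_is_rejected():
    with pytest.raises(ValueError):
        dataclasses.replace(PhantomConfig(), cavity_radius_range=(90.0, 120.0))
    with pytest.raises(ValueError):
        dataclasses.replace(PhantomConfig(), papillary_probability=1.5)


def test_ps_modality_inverts_contrast():
    cfg = _clean_config(size=96)
    frame = {"center": (48.0, 48.0), "r_in": 14.0, "r_out": 20.0,
             "ratio": 1.0, "theta": 0.0, "blobs": [], "illum": (0.0, 0.0)}
    mag = _render(cfg, frame, "MAG", np.random.default_rng(0))
    ps = _render(cfg, frame, "PS", np.random.default_rng(0))
    ring = mag.mask.astype(bool)
    cavity = ndimage.binary_fill_holes(ring) & ~ring
    assert mag.image[cavity].mean() > mag.image[ring].mean()
    assert ps.image[cavity].mean() < ps.image[ring].mean()
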