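"""Dataset layout, patient-level splitting, and training-time augmentation.

The on-disk convention mirrors the cardiac MRI cohort this package targets:

    <root>/<patient_id>/<A|B>/<MAG|PS>/<image_id>.png
    <root>/<patient_id>/<A|B>/<MAG|PS>/<image_id>_mask.png

``A``/``B`` are therapy stages (before/after intervention); ``MAG`` and
``PS`` are magnitude (anatomical) and phase-contrast image types, each with
its own manually drawn mask.  Images are 8-bit grayscale PNG; on load they
are scaled to [0, 1] and masks are binarized at 128/255.

Train/test splitting is by *patient*, never by image: all scans of one
patient land on one side of the split, preventing leakage of patient
anatomy between folds.

Augmentation follows the training protocol: a horizontal flip with
probability 0.5 and a rotation drawn uniformly from ±30° about the image
center, applied identically to image and mask (bilinear vs nearest
interpolation), on the fly each epoch.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "Sample",
    "SampleMeta",
    "SplitPlan",
    "AugmentConfig",
    "CohortLoadError",
    "STAGES",
    "MODALITIES",
    "load_cohort",
    "manifest",
    "grouped_split",
    "augment",
    "write_image",
    "write_mask",
    "read_mask",
]

STAGES = ("A", "B")
MODALITIES = ("MAG", "PS")

MASK_SUFFIX = "_mask"
MASK_BINARIZE_THRESHOLD = 128  # of 255


@dataclass
class Sample:
    """One grayscale image in [0, 1] with its binary mask of identical shape."""
    image: np.ndarray  # float32, H x W, values in [0, 1]
    mask: np.ndarray   # uint8, H x W, values in {0, 1}


@dataclass(frozen=True)
class SampleMeta:
    patient_id: str
    stage: str      # "A" (before therapy) or "B" (after)
    modality: str   # "MAG" or "PS"
    image_path: str
    mask_path: str


@dataclass(frozen=True)
class SplitPlan:
    """Patient-disjoint train/test partition."""
    train_patients: frozenset[str]
    test_patients: frozenset[str]
    fraction: float

    def __post_init__(self):
        if self.train_patients & self.test_patients:
            raise ValueError("train and test patients overlap")


@dataclass(frozen=True)
class AugmentConfig:
    flip_probability: float = 0.5
    max_rotation_degrees: float = 30.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.flip_probability <= 1.0:
            raise ValueError("flip_probability must lie in [0, 1]")
        if self.max_rotation_degrees < 0:
            raise ValueError("max_rotation_degrees must be >= 0")


class CohortLoadError(Exception):
    """Raised with an itemized list of per-file problems found on load."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("cohort load failed:\n" + "\n".join(problems))


def _read_gray(path: str) -> np.ndarray:
    arr = iio.imread(path)
    if arr.ndim == 3:  # grayscale saved with redundant channels
        arr = arr[..., 0]
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a 2-D grayscale image, got shape {arr.shape}")
    return arr


def load_cohort(root: str, manifest_path: str | None = None
                ) -> list[tuple[Sample, SampleMeta]]:
    """Load every image/mask pair under ``root``.

    Returns samples sorted by (patient, stage, modality, filename).  Images
    are scaled from 8-bit to [0, 1]; masks are binarized at 128/255.  An
    empty or missing directory yields an empty list.  Structural problems
    (missing mask, non-square or odd-sized image, unreadable file) are
    collected and raised together as :class:`CohortLoadError`.

    If ``manifest_path`` is given, a CSV with columns
    (patient_id, stage, modality, image, mask) is written there.
    """
    cohort: list[tuple[Sample, SampleMeta]] = []
    problems: list[str] = []
    if not os.path.isdir(root):
        return cohort
    for patient in sorted(os.listdir(root)):
        pdir = os.path.join(root, patient)
        if not os.path.isdir(pdir):
            continue
        for stage in STAGES:
            for modality in MODALITIES:
                mdir = os.path.join(pdir, stage, modality)
                if not os.path.isdir(mdir):
                    continue
                for fname in sorted(os.listdir(mdir)):
                    stem, ext = os.path.splitext(fname)
                    if ext.lower() != ".png" or stem.endswith(MASK_SUFFIX):
                        continue
                    ipath = os.path.join(mdir, fname)
                    mpath = os.path.join(mdir, stem + MASK_SUFFIX + ".png")
                    if not os.path.exists(mpath):
                        problems.append(f"missing mask for {ipath}")
                        continue
                    try:
                        img = _read_gray(ipath)
                        msk = _read_gray(mpath)
                    except Exception as exc:  # unreadable PNG
                        problems.append(f"unreadable image pair {ipath}: {exc}")
                        continue
                    h, w = img.shape
                    if h != w or h % 2:
                        problems.append(f"{ipath}: expected square even-sized image, "
                                        f"got {h}x{w}")
                        continue
                    if msk.shape != img.shape:
                        problems.append(f"{mpath}: mask shape {msk.shape} != "
                                        f"image shape {img.shape}")
                        continue
                    sample = Sample(
                        image=(img.astype(np.float32) / 255.0),
                        mask=(msk >= MASK_BINARIZE_THRESHOLD).astype(np.uint8),
                    )
                    meta = SampleMeta(patient, stage, modality, ipath, mpath)
                    cohort.append((sample, meta))
    if problems:
        raise CohortLoadError(problems)
    if manifest_path is not None:
        manifest(cohort).to_csv(manifest_path, index=False)
    return cohort


def manifest(cohort: list[tuple[Sample, SampleMeta]]) -> pd.DataFrame:
    """Tabulate cohort metadata (one row per image)."""
    return pd.DataFrame(
        [(m.patient_id, m.stage, m.modality, m.image_path, m.mask_path)
         for _, m in cohort],
        columns=["patient_id", "stage", "modality", "image", "mask"],
    )


def grouped_split(metas: list[SampleMeta], test_fraction: float = 0.1,
                  rng_seed: int = 0) -> SplitPlan:
    """Partition *patients* (not images) into train and test sets.

    The test set holds ``max(1, round(test_fraction * n_patients))``
    patients, drawn by a seeded permutation of the canonically sorted
    patient list — so the plan is deterministic under a fixed seed and
    invariant to the input ordering of ``metas``.
    """
    patients = sorted({m.patient_id for m in metas})
    if len(patients) < 2:
        raise ValueError("grouped_split requires at least 2 patients")
    n_test = max(1, int(np.floor(test_fraction * len(patients) + 0.5)))
    if n_test >= len(patients):
        raise ValueError("test fraction leaves no training patients")
    rng = np.random.default_rng(rng_seed)
    order = rng.permutation(len(patients))
    test = frozenset(patients[i] for i in order[:n_test])
    train = frozenset(patients) - test
    return SplitPlan(train_patients=train, test_patients=test,
                     fraction=test_fraction)


def augment(sample: Sample, config: AugmentConfig,
            rng: np.random.Generator) -> Sample:
    """Randomly flip and rotate an image/mask pair (shapes preserved).

    With probability ``flip_probability`` both grids are mirrored
    left-right; then both are rotated by one angle drawn uniformly from
    ±``max_rotation_degrees`` about the image center — the image with
    bilinear interpolation and zero fill, the mask with nearest-neighbor,
    re-binarized so the output mask stays strictly {0, 1}.
    """
    img, msk = sample.image, sample.mask
    if img.shape != msk.shape:
        raise ValueError("image and mask shapes differ")
    if rng.random() < config.flip_probability:
        img = img[:, ::-1]
        msk = msk[:, ::-1]
    if config.max_rotation_degrees > 0:
        angle = rng.uniform(-config.max_rotation_degrees, config.max_rotation_degrees)
        img = ndimage.rotate(img, angle, reshape=False, order=1,
                             mode="constant", cval=0.0)
        msk = ndimage.rotate(msk, angle, reshape=False, order=0,
                             mode="constant", cval=0)
    return Sample(image=np.clip(img, 0.0, 1.0).astype(np.float32),
                  mask=(np.asarray(msk) >= 1).astype(np.uint8))


def write_image(path: str, image: np.ndarray) -> None:
    """Write a [0, 1] float image as 8-bit grayscale PNG."""
    arr = np.clip(np.asarray(image), 0.0, 1.0)
    iio.imwrite(path, (arr * 255.0 + 0.5).astype(np.uint8))


def write_mask(path: str, mask: np.ndarray) -> None:
    """Write a {0, 1} mask as a {0, 255} 8-bit PNG (round-trips bit-exactly)."""
    arr = np.asarray(mask)
    iio.imwrite(path, (arr.astype(np.uint8) * 255))


def read_mask(path: str) -> np.ndarray:
    """Read a mask PNG back to a {0, 1} uint8 grid."""
    return (_read_gray(path) >= MASK_BINARIZE_THRESHOLD).astype(np.uint8)
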