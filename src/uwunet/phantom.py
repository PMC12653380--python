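"""Synthetic cardiac-phantom cohort generator.

Emulates the structure of short-axis cardiac MRI with myocardium
annotations so the whole pipeline — loading, patient-level splitting,
augmentation, training, evaluation — is exercisable without any real data.

Each phantom frame is an elliptical annulus (the myocardial ring) around a
bright ventricular cavity on a dark background.  The ring is the
segmentation foreground and occupies a few percent of the image, matching
the small-ROI regime that motivates Dice-based evaluation.  Per *patient*,
ring geometry (center, radii, eccentricity, orientation) is drawn once and
held across that patient's images, so patient-level splitting genuinely
matters; per image the center jitters and radii wobble slightly.  Optional
papillary-muscle blobs sit inside the cavity at ring intensity and are
excluded from the mask by default, mirroring the annotation-protocol
ambiguity around those structures.

Magnitude (MAG) images use bright cavity / mid-gray ring; phase-contrast
(PS) images invert that contrast and carry doubled noise.  The two
modalities of one frame get independently jittered mask radii, emulating
separately drawn manual masks.  These intensity conventions are package
choices (no pixel statistics of the real data are published) and are all
exposed on :class:`PhantomConfig`.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .dataio import (MODALITIES, STAGES, Sample, SampleMeta, manifest,
                     write_image, write_mask)

__all__ = [
    "PhantomConfig",
    "PatientProfile",
    "draw_patient_profile",
    "generate_sample",
    "generate_frame_pair",
    "generate_cohort_samples",
    "generate_cohort",
]

# nominal intensity levels (MAG); PS swaps cavity and ring
BACKGROUND_LEVEL = 0.15
CAVITY_LEVEL = 0.75
RING_LEVEL = 0.45
EDGE_BLUR_SIGMA = 0.7       # px, softens rasterized boundaries in the image
ILLUMINATION_AMPLITUDE = 0.1
ELLIPSE_RATIO_RANGE = (0.85, 1.0)
RADIUS_WOBBLE = 0.02        # per-image relative wobble of ring radii

_REFERENCE_SIZE = 224


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, intensity, and cohort-size parameters of the generator.

    Pixel-valued defaults are calibrated for 224x224 images;
    :meth:`for_size` rescales them proportionally for other resolutions
    (e.g. 96 for scaled-down training tests), preserving the foreground
    area fraction.
    """

    image_size: int = 224
    cavity_radius_range: tuple[float, float] = (18.0, 31.0)
    ring_thickness_range: tuple[float, float] = (6.5, 13.0)
    center_jitter: float = 9.0
    noise_sigma: float = 0.08
    papillary_probability: float = 0.5
    papillary_count_range: tuple[int, int] = (1, 3)
    papillary_radius_range: tuple[float, float] = (3.0, 6.0)
    modality_mask_jitter: float = 1.5
    n_patients: int = 22
    images_per_patient_range: tuple[int, int] = (10, 15)
    include_papillary_in_mask: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.ring_thickness_range[0] <= 0:
            raise ValueError("ring thickness must be > 0")
        if not 0.0 <= self.papillary_probability <= 1.0:
            raise ValueError("papillary_probability must lie in [0, 1]")
        reach = (self.cavity_radius_range[1] + self.ring_thickness_range[1]
                 + self.center_jitter)
        if reach >= self.image_size / 2:
            raise ValueError(
                f"geometry reach {reach:.1f}px exceeds half the {self.image_size}px image"
            )
        if self.n_patients < 1 or self.images_per_patient_range[0] < 1:
            raise ValueError("need at least one patient and one image per patient")

    def for_size(self, image_size: int) -> "PhantomConfig":
        """Rescale all pixel-valued fields to a new image size."""
        f = image_size / _REFERENCE_SIZE
        return dataclasses.replace(
            self,
            image_size=image_size,
            cavity_radius_range=(self.cavity_radius_range[0] * f,
                                 self.cavity_radius_range[1] * f),
            ring_thickness_range=(self.ring_thickness_range[0] * f,
                                  self.ring_thickness_range[1] * f),
            center_jitter=self.center_jitter * f,
            papillary_radius_range=(self.papillary_radius_range[0] * f,
                                    self.papillary_radius_range[1] * f),
            modality_mask_jitter=self.modality_mask_jitter * f,
        )


@dataclass(frozen=True)
class PatientProfile:
    """Per-patient anatomy, persistent across all of that patient's images."""
    patient_id: str
    center: tuple[float, float]     # (row, col)
    cavity_radius: float
    ring_thickness: float
    ellipse_ratio: float            # minor/major axis, in [0.85, 1.0]
    orientation: float              # radians


def draw_patient_profile(config: PhantomConfig, patient_id: str,
                         rng: np.random.Generator) -> PatientProfile:
    half = config.image_size / 2.0
    offset = 0.05 * config.image_size
    return PatientProfile(
        patient_id=patient_id,
        center=(half + rng.uniform(-offset, offset),
                half + rng.uniform(-offset, offset)),
        cavity_radius=rng.uniform(*config.cavity_radius_range),
        ring_thickness=rng.uniform(*config.ring_thickness_range),
        ellipse_ratio=rng.uniform(*ELLIPSE_RATIO_RANGE),
        orientation=rng.uniform(0.0, np.pi),
    )


def _elliptic_radius(size: int, center: tuple[float, float], ratio: float,
                     theta: float) -> np.ndarray:
    """Map each pixel to its generalized radius w.r.t. the ellipse family."""
    rows, cols = np.mgrid[0:size, 0:size]
    dy = rows - center[0]
    dx = cols - center[1]
    xr = np.cos(theta) * dx + np.sin(theta) * dy
    yr = -np.sin(theta) * dx + np.cos(theta) * dy
    return np.sqrt(xr ** 2 + (yr / ratio) ** 2)


def _draw_frame(config: PhantomConfig, profile: PatientProfile,
                rng: np.random.Generator) -> dict:
    """Draw the per-frame (shared-across-modality) scene parameters."""
    jit = config.center_jitter
    center = (profile.center[0] + rng.uniform(-jit, jit),
              profile.center[1] + rng.uniform(-jit, jit))
    r_in = profile.cavity_radius * (1.0 + rng.uniform(-RADIUS_WOBBLE, RADIUS_WOBBLE))
    r_out = r_in + profile.ring_thickness * (
        1.0 + rng.uniform(-RADIUS_WOBBLE, RADIUS_WOBBLE))
    blobs: list[tuple[float, float, float]] = []
    if rng.random() < config.papillary_probability:
        count = rng.integers(config.papillary_count_range[0],
                             config.papillary_count_range[1] + 1)
        for _ in range(count):
            ang = rng.uniform(0.0, 2 * np.pi)
            dist = rng.uniform(0.2, 0.6) * r_in
            blobs.append((center[0] + dist * np.sin(ang),
                          center[1] + dist * np.cos(ang),
                          rng.uniform(*config.papillary_radius_range)))
    illum = (rng.uniform(-ILLUMINATION_AMPLITUDE, ILLUMINATION_AMPLITUDE),
             rng.uniform(-ILLUMINATION_AMPLITUDE, ILLUMINATION_AMPLITUDE))
    return {"center": center, "r_in": r_in, "r_out": r_out,
            "ratio": profile.ellipse_ratio, "theta": profile.orientation,
            "blobs": blobs, "illum": illum}


def _render(config: PhantomConfig, frame: dict, modality: str,
            rng: np.random.Generator) -> Sample:
    """Render one modality of a frame: jittered mask plus noisy image."""
    size = config.image_size
    rho = _elliptic_radius(size, frame["center"], frame["ratio"], frame["theta"])
    j = config.modality_mask_jitter
    r_in = frame["r_in"] + rng.uniform(-j, j)
    r_out = frame["r_out"] + rng.uniform(-j, j)
    ring = (rho <= r_out) & (rho > r_in)
    cavity = rho <= r_in

    if modality == "MAG":
        cavity_level, ring_level, sigma = CAVITY_LEVEL, RING_LEVEL, config.noise_sigma
    else:  # PS: inverted cavity/ring contrast, doubled noise floor
        cavity_level, ring_level, sigma = RING_LEVEL, CAVITY_LEVEL, 2 * config.noise_sigma

    img = np.full((size, size), BACKGROUND_LEVEL, dtype=np.float64)
    img[cavity] = cavity_level
    img[ring] = ring_level

    blob_mask = np.zeros((size, size), dtype=bool)
    for by, bx, br in frame["blobs"]:
        rows, cols = np.mgrid[0:size, 0:size]
        blob = ((rows - by) ** 2 + (cols - bx) ** 2 <= br ** 2) & cavity
        blob_mask |= blob
    img[blob_mask] = ring_level

    img = ndimage.gaussian_filter(img, EDGE_BLUR_SIGMA)
    gy, gx = frame["illum"]
    rows, cols = np.mgrid[0:size, 0:size]
    img += gy * (rows / size - 0.5) + gx * (cols / size - 0.5)
    img += rng.normal(0.0, sigma, (size, size))
    img = np.clip(img, 0.0, 1.0).astype(np.float32)

    mask = ring | blob_mask if config.include_papillary_in_mask else ring
    return Sample(image=img, mask=mask.astype(np.uint8))


def generate_sample(config: PhantomConfig, profile: PatientProfile, stage: str,
                    modality: str, rng: np.random.Generator,
                    image_id: str = "img000") -> tuple[Sample, SampleMeta]:
    """Generate a single phantom image/mask pair with metadata.

    Deterministic given the generator state: the same seeded ``rng``
    produces a bit-identical sample.
    """
    if stage not in STAGES or modality not in MODALITIES:
        raise ValueError(f"stage must be in {STAGES}, modality in {MODALITIES}")
    frame = _draw_frame(config, profile, rng)
    sample = _render(config, frame, modality, rng)
    rel = f"{profile.patient_id}/{stage}/{modality}/{image_id}"
    meta = SampleMeta(profile.patient_id, stage, modality,
                      rel + ".png", rel + "_mask.png")
    return sample, meta


def generate_frame_pair(config: PhantomConfig, profile: PatientProfile, stage: str,
                        rng: np.random.Generator, image_id: str = "img000"
                        ) -> list[tuple[Sample, SampleMeta]]:
    """Generate the MAG and PS renderings of one anatomical frame.

    The two samples share scene geometry; their masks differ only within
    the configured per-modality jitter band.
    """
    frame = _draw_frame(config, profile, rng)
    out = []
    for modality in MODALITIES:
        sample = _render(config, frame, modality, rng)
        rel = f"{profile.patient_id}/{stage}/{modality}/{image_id}"
        out.append((sample, SampleMeta(profile.patient_id, stage, modality,
                                       rel + ".png", rel + "_mask.png")))
    return out


def _patient_image_counts(config: PhantomConfig, total_images: int | None,
                          rng: np.random.Generator) -> list[int]:
    n = config.n_patients
    if total_images is None:
        lo, hi = config.images_per_patient_range
        return [int(rng.integers(lo, hi + 1)) for _ in range(n)]
    if total_images < n:
        raise ValueError("need at least one image per patient")
    base, extra = divmod(total_images, n)
    counts = np.full(n, base, dtype=int)
    counts[rng.permutation(n)[:extra]] += 1
    return counts.tolist()


def generate_cohort_samples(config: PhantomConfig, total_images: int | None = None
                            ) -> list[tuple[Sample, SampleMeta]]:
    """Generate a full in-memory cohort.

    Per patient, images are produced as MAG/PS frame pairs alternating
    between therapy stages A and B (stages differ only by random stream —
    the emulated scans show no systematic stage effect).  If
    ``total_images`` is given, images are distributed as evenly as possible
    across patients and the total matches exactly (an odd per-patient count
    makes that patient's last frame MAG-only).
    """
    root_rng = np.random.default_rng(config.seed)
    counts = _patient_image_counts(config, total_images, root_rng)
    streams = root_rng.spawn(config.n_patients)
    cohort: list[tuple[Sample, SampleMeta]] = []
    for p, (count, rng) in enumerate(zip(counts, streams)):
        patient_id = f"patient{p + 1:02d}"
        profile = draw_patient_profile(config, patient_id, rng)
        produced = 0
        frame_idx = 0
        while produced < count:
            stage = STAGES[frame_idx % 2]
            pair = generate_frame_pair(config, profile, stage, rng,
                                       image_id=f"frame{frame_idx:03d}")
            for item in pair[: count - produced]:
                cohort.append(item)
                produced += 1
            frame_idx += 1
    return cohort


def generate_cohort(config: PhantomConfig, out_dir: str,
                    total_images: int | None = None,
                    overwrite: bool = False) -> str:
    """Generate a cohort and write it in the on-disk dataset convention.

    Writes 8-bit grayscale PNGs under
    ``<out_dir>/<patient>/<stage>/<modality>/``, a ``manifest.csv``, and a
    ``config.json`` provenance file.  Refuses to write into an existing
    non-empty directory unless ``overwrite`` is set.
    """
    if os.path.isdir(out_dir) and os.listdir(out_dir) and not overwrite:
        raise FileExistsError(f"{out_dir} exists and is not empty "
                              "(pass overwrite=True to replace)")
    cohort = generate_cohort_samples(config, total_images=total_images)
    os.makedirs(out_dir, exist_ok=True)
    rebased = []
    for sample, meta in cohort:
        ipath = os.path.join(out_dir, meta.image_path)
        mpath = os.path.join(out_dir, meta.mask_path)
        os.makedirs(os.path.dirname(ipath), exist_ok=True)
        write_image(ipath, sample.image)
        write_mask(mpath, sample.mask)
        rebased.append((sample, SampleMeta(meta.patient_id, meta.stage,
                                           meta.modality, ipath, mpath)))
    manifest(rebased).to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    with open(os.path.join(out_dir, "config.json"), "w") as fh:
        json.dump({"total_images": len(cohort),
                   **dataclasses.asdict(config)}, fh, indent=2)
    return out_dir
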