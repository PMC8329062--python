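"""Seeded synthetic cohort generator.

Emulates the study population the analysis assumes: ~24 adults with a single
unilateral posterolateral L5-S1 disc herniation, bilateral multifidus (MF)
and erector spinae (ES) segmentations on axial T2-weighted-like slices at the
L5-S1 and S1 levels, sex- and age-linked size/elongation and fat-fraction
effects, and a localized medial bulge of the affected-side multifidus at the
level below the herniation.

Muscle outlines are star-shaped Fourier radius functions
``r(theta) = r0 * (1 + sum_k a_k cos(k theta) + b_k sin(k theta))``,
rasterized on a pixel grid; intra-muscle texture is an equal-variance
two-Gaussian fat/lean mixture whose realized fat-pixel proportion matches the
target fraction exactly (to the nearest pixel).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure

from ._geometry import (
    Contour,
    GeometryError,
    canonicalize,
    rasterize_polygon,
    resample_closed,
)

LEVELS = ("L5S1", "S1")
MUSCLES = ("MF", "ES")
SIDES = ("left", "right")


class CohortGenerationError(RuntimeError):
    """A generated sample violated a structural invariant."""


class InvalidParameterError(ValueError):
    """Shape parameters outside their admissible domain."""


@dataclass
class SubjectRecord:
    """Covariate row for one patient."""

    subject_id: str
    sex: str  # {"F", "M"}
    age: float  # years
    affected_side: str  # {"left", "right"}

    def __post_init__(self):
        if self.sex not in ("F", "M"):
            raise ValueError(f"sex must be F or M, got {self.sex!r}")
        if self.affected_side not in SIDES:
            raise ValueError(f"affected_side must be left/right, got {self.affected_side!r}")
        if not self.age > 0:
            raise ValueError(f"age must be positive, got {self.age}")


@dataclass
class SliceSample:
    """One subject x spinal level: image raster plus four binary muscle masks."""

    subject_id: str
    level: str
    image: np.ndarray | None  # (H, W) float intensities, or None (shapes-only run)
    masks: dict  # (muscle, side) -> (H, W) bool
    pixel_spacing: float  # mm / pixel


@dataclass
class CohortConfig:
    """Parameters of the data-generating process.

    Effect amplitudes default to magnitudes that reproduce the study cohort's
    reported scale: MF CSA around 13 cm2, ES fat fraction around 0.40, female
    and older subjects fattier and (for age) slightly smaller, and a medial
    bulge of roughly 1 mm gaussian-sector amplitude on the affected-side
    multifidus at S1 that carries a few percent of total shape variance.
    """

    seed: int = 0
    n_subjects: int = 24
    n_female: int = 11
    n_affected_left: int = 15
    age_mean: float = 41.5
    age_sd: float = 7.9
    grid_size: tuple = (192, 256)  # (H, W) pixels
    pixel_spacing: float = 1.0  # mm / pixel
    levels: tuple = LEVELS
    muscles: tuple = MUSCLES
    landmark_count: int = 100  # K, even
    fourier_order: int = 4
    shape_noise_sd: float = 0.02  # sd of order-1 coefficients
    shape_noise_decay: float = 1.5  # order-k coefficient sd = shape_noise_sd / k**decay
    # mean radii (mm) chosen so pi*r^2 matches the reported CSAs
    base_radius: Mapping = field(
        default_factory=lambda: {
            ("MF", "L5S1"): 20.3,
            ("MF", "S1"): 20.3,
            ("ES", "L5S1"): 17.8,
            ("ES", "S1"): 14.2,
        }
    )
    base_elongation: Mapping = field(
        default_factory=lambda: {"MF": 0.08, "ES": 0.16}
    )
    center_offset_mm: Mapping = field(
        default_factory=lambda: {"MF": 28.0, "ES": 75.0}
    )
    beta_sex_elongation: float = 0.03  # added to a2 for females
    beta_age_elongation: float = 0.0012  # per year of (age - age_mean)
    beta_age_size: float = -0.004  # relative radius per year
    beta_pathology_bulge: float = 0.8  # mm, gaussian sector amplitude
    bulge_center_angle: float = float(np.pi)  # medial, right-side convention
    bulge_width: float = 0.12  # radians
    bulge_level: str = "S1"
    bulge_muscle: str = "MF"
    fat_base_logit: float = -1.3
    fat_muscle_logit: Mapping = field(default_factory=lambda: {"MF": 0.0, "ES": 0.75})
    fat_beta_sexF: float = 0.4
    fat_beta_age: float = 0.025  # per year of (age - age_mean)
    mu_lean: float = 60.0
    mu_fat: float = 140.0
    sigma_intensity: float = 10.0
    texture_smooth_sigma: float = 3.0  # pixels, spatial scale of the fat field
    intensity_scale_jitter: tuple = (0.8, 1.2)
    intensity_shift_jitter: tuple = (-10.0, 10.0)
    generate_images: bool = True

    def __post_init__(self):
        if self.n_subjects < 4:
            raise InvalidParameterError("n_subjects must be >= 4")
        if self.landmark_count < 16 or self.landmark_count % 2:
            raise InvalidParameterError("landmark_count must be even and >= 16")
        if not self.bulge_width > 0:
            raise InvalidParameterError("bulge_width must be positive")
        if not self.mu_fat > self.mu_lean:
            raise InvalidParameterError("mu_fat must exceed mu_lean")
        if not (0 <= self.n_female <= self.n_subjects):
            raise InvalidParameterError("n_female out of range")
        if not (0 <= self.n_affected_left <= self.n_subjects):
            raise InvalidParameterError("n_affected_left out of range")
        for name in (
            "beta_sex_elongation",
            "beta_age_elongation",
            "beta_age_size",
            "beta_pathology_bulge",
            "fat_base_logit",
            "fat_beta_sexF",
            "fat_beta_age",
        ):
            if not np.isfinite(getattr(self, name)):
                raise InvalidParameterError(f"{name} must be finite")

    def replace(self, **kw) -> "CohortConfig":
        return dataclasses.replace(self, **kw)


# ---------------------------------------------------------------------------
# contour synthesis
# ---------------------------------------------------------------------------

def synth_contour(
    r0: float,
    a: Sequence[float],
    b: Sequence[float],
    center: Sequence[float],
    K: int,
    n_fine: int = 1024,
) -> Contour:
    """Sample a Fourier radius-function outline as a K-point CCW contour.

    ``r(theta) = r0 * (1 + sum a_k cos(k theta) + b_k sin(k theta))`` is
    evaluated on a fine angular grid, rejected if non-positive anywhere, then
    resampled to K points equally spaced by arc length from the canonical
    (min-x) start.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    theta = np.linspace(0.0, 2.0 * np.pi, n_fine, endpoint=False)
    k = np.arange(1, len(a) + 1)
    r = r0 * (
        1.0
        + np.cos(np.outer(theta, k)) @ a
        + np.sin(np.outer(theta, k)) @ b
    )
    if np.min(r) <= 0:
        bad = theta[int(np.argmin(r))]
        raise InvalidParameterError(
            f"radius non-positive at theta={bad:.4f} rad (r={np.min(r):.4f})"
        )
    pts = np.column_stack(
        [center[0] + r * np.cos(theta), center[1] + r * np.sin(theta)]
    )
    pts = canonicalize(resample_closed(canonicalize(pts), K))
    return Contour(pts)


def apply_bulge(
    contour: Contour, amplitude: float, center_angle: float, width: float
) -> Contour:
    """Add a localized gaussian radial bulge to a contour.

    Each vertex at angle theta (about the contour centroid) moves radially
    outward by ``amplitude * exp(-(d/width)^2 / 2)`` where d is the wrapped
    angular distance to ``center_angle``; the result is re-resampled to the
    same K with the canonical start rule.  ``amplitude = 0`` returns the
    input unchanged.
    """
    if not width > 0:
        raise InvalidParameterError("bulge width must be positive")
    if amplitude == 0:
        return contour
    c = contour.centroid
    d = contour.points - c
    theta = np.arctan2(d[:, 1], d[:, 0])
    dtheta = np.angle(np.exp(1j * (theta - center_angle)))
    offset = amplitude * np.exp(-0.5 * (dtheta / width) ** 2)
    rho = np.hypot(d[:, 0], d[:, 1])
    pts = c + d * ((rho + offset) / rho)[:, None]
    pts = canonicalize(resample_closed(canonicalize(pts), contour.K))
    return Contour(pts)  # validation raises on self-intersection


# ---------------------------------------------------------------------------
# rasters and intensities
# ---------------------------------------------------------------------------

def rasterize_contour(
    contour: Contour, grid: tuple[int, int], pixel_spacing: float
) -> np.ndarray:
    """Pixel-centre even-odd rasterization (see `_geometry.rasterize_polygon`)."""
    return rasterize_polygon(contour, grid, pixel_spacing)


def synth_intensities(
    masks: Mapping,
    fat_fractions: Mapping,
    config: CohortConfig,
    rng: np.random.Generator,
    scale: float = 1.0,
    shift: float = 0.0,
) -> np.ndarray:
    """Bimodal fat/lean texture inside each mask, matched to target fractions.

    A smooth spatial noise field is thresholded within each mask so that
    exactly ``round(f * |mask|)`` pixels are fat; fat pixels draw from
    N(mu_fat, sigma), lean from N(mu_lean, sigma), background from
    N(mu_lean/2, sigma).  The whole image is then affinely jittered by
    (scale, shift).
    """
    keys = sorted(masks.keys())
    shape = masks[keys[0]].shape
    sigma = config.sigma_intensity
    image = config.mu_lean / 2.0 + sigma * rng.standard_normal(shape)
    fat_field = ndimage.gaussian_filter(
        rng.standard_normal(shape), config.texture_smooth_sigma
    )
    for key in keys:
        m = np.asarray(masks[key], dtype=bool)
        f = float(fat_fractions[key])
        if not 0.0 <= f <= 1.0:
            raise InvalidParameterError(f"fat fraction {f} outside [0, 1] for {key}")
        npx = int(m.sum())
        n_fat = int(round(f * npx))
        vals = fat_field[m]
        fat_local = np.zeros(npx, dtype=bool)
        if n_fat > 0:
            fat_local[np.argsort(vals)[::-1][:n_fat]] = True
        intens = config.mu_lean + sigma * rng.standard_normal(npx)
        intens[fat_local] = config.mu_fat + sigma * rng.standard_normal(int(n_fat))
        image[m] = intens
    return scale * image + shift


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


def _draw_subjects(config: CohortConfig, rng: np.random.Generator) -> list:
    sexes = np.array(
        ["F"] * config.n_female + ["M"] * (config.n_subjects - config.n_female)
    )
    rng.shuffle(sexes)
    sides = np.array(
        ["left"] * config.n_affected_left
        + ["right"] * (config.n_subjects - config.n_affected_left)
    )
    rng.shuffle(sides)
    subjects = []
    for i in range(config.n_subjects):
        age = 0.0
        while age < 18.0:  # truncate at adulthood
            age = config.age_mean + config.age_sd * rng.standard_normal()
        subjects.append(
            SubjectRecord(f"P{i + 1:03d}", str(sexes[i]), float(age), str(sides[i]))
        )
    return subjects


def generate_cohort_shapes(config: CohortConfig):
    """Generate covariates, ground truth, and all muscle contours (no rasters).

    Returns ``(subjects, contours, truth)`` where ``contours`` maps
    ``(subject_id, level, muscle, side)`` to a `Contour` and ``truth`` is a
    DataFrame recording every realized parameter (fat fraction, bulge
    amplitude, Fourier coefficients, centre).
    """
    ss = np.random.SeedSequence(config.seed)
    cov_seed, shape_seed, _ = ss.spawn(3)
    cov_rng = np.random.default_rng(cov_seed)
    shape_rng = np.random.default_rng(shape_seed)

    subjects = _draw_subjects(config, cov_rng)
    H, W = config.grid_size
    s = config.pixel_spacing
    cx = W * s / 2.0
    cy = H * s / 2.0
    order = config.fourier_order

    contours = {}
    rows = []
    for subj in subjects:
        age_c = subj.age - config.age_mean
        is_f = subj.sex == "F"
        for level in config.levels:
            for muscle in config.muscles:
                fat = _logistic(
                    config.fat_base_logit
                    + config.fat_muscle_logit.get(muscle, 0.0)
                    + config.fat_beta_sexF * is_f
                    + config.fat_beta_age * age_c
                )
                for side in SIDES:
                    r0 = config.base_radius[(muscle, level)] * (
                        1.0
                        + config.beta_age_size * age_c
                        + config.shape_noise_sd * shape_rng.standard_normal()
                    )
                    # smooth-contour noise: coefficient sd decays with harmonic order
                    k_decay = config.shape_noise_sd / np.arange(
                        1, order + 1
                    ) ** config.shape_noise_decay
                    a = k_decay * shape_rng.standard_normal(order)
                    b = k_decay * shape_rng.standard_normal(order)
                    a[1] += (
                        config.base_elongation[muscle]
                        + config.beta_sex_elongation * is_f
                        + config.beta_age_elongation * age_c
                    )
                    xoff = config.center_offset_mm[muscle]
                    center = (cx - xoff if side == "left" else cx + xoff, cy)
                    try:
                        contour = synth_contour(
                            r0, a, b, center, config.landmark_count
                        )
                        bulge = 0.0
                        if (
                            side == subj.affected_side
                            and level == config.bulge_level
                            and muscle == config.bulge_muscle
                            and config.beta_pathology_bulge != 0.0
                        ):
                            bulge = config.beta_pathology_bulge
                            angle = (
                                config.bulge_center_angle
                                if side == "right"
                                else np.pi - config.bulge_center_angle
                            )
                            contour = apply_bulge(
                                contour, bulge, angle, config.bulge_width
                            )
                    except GeometryError as exc:
                        raise CohortGenerationError(
                            f"subject {subj.subject_id} {level} {muscle} {side}: {exc}"
                        ) from exc
                    contours[(subj.subject_id, level, muscle, side)] = contour
                    row = {
                        "subject_id": subj.subject_id,
                        "level": level,
                        "muscle": muscle,
                        "side": side,
                        "true_fat_fraction": float(fat),
                        "true_bulge_amplitude": bulge,
                        "center_x": center[0],
                        "center_y": center[1],
                        "r0": r0,
                    }
                    for k in range(order):
                        row[f"a{k + 1}"] = a[k]
                        row[f"b{k + 1}"] = b[k]
                    rows.append(row)
    truth = pd.DataFrame(rows)
    return subjects, contours, truth


def _validate_masks(masks: Mapping, context: str) -> None:
    union = None
    for key, m in masks.items():
        lab, n = measure.label(m, connectivity=1, return_num=True)
        if n != 1:
            raise CohortGenerationError(
                f"{context} {key}: mask has {n} 4-connected components"
            )
        if ndimage.binary_fill_holes(m).sum() != m.sum():
            raise CohortGenerationError(f"{context} {key}: mask contains holes")
        if m.sum() < 50:
            raise CohortGenerationError(
                f"{context} {key}: mask has only {int(m.sum())} pixels (< 50)"
            )
        if union is None:
            union = m.copy()
        else:
            if np.any(union & m):
                raise CohortGenerationError(f"{context} {key}: masks overlap")
            union |= m
    return None


def generate_cohort(config: CohortConfig):
    """Full cohort: rasters + intensities + covariates + ground truth.

    Returns ``(samples, subjects, truth)``; every output is a pure function
    of the config (which carries the seed).
    """
    subjects, contours, truth = generate_cohort_shapes(config)
    ss = np.random.SeedSequence(config.seed)
    _, _, img_seed = ss.spawn(3)
    img_rng = np.random.default_rng(img_seed)
    lo_s, hi_s = config.intensity_scale_jitter
    lo_c, hi_c = config.intensity_shift_jitter
    jitter = {
        subj.subject_id: (img_rng.uniform(lo_s, hi_s), img_rng.uniform(lo_c, hi_c))
        for subj in subjects
    }
    streams = img_rng.spawn(len(subjects) * len(config.levels))

    fat_lookup = {
        (r.subject_id, r.level, r.muscle, r.side): r.true_fat_fraction
        for r in truth.itertuples()
    }
    samples = []
    idx = 0
    for subj in subjects:
        for level in config.levels:
            masks = {}
            for muscle in config.muscles:
                for side in SIDES:
                    c = contours[(subj.subject_id, level, muscle, side)]
                    try:
                        masks[(muscle, side)] = rasterize_contour(
                            c, config.grid_size, config.pixel_spacing
                        )
                    except GeometryError as exc:
                        raise CohortGenerationError(
                            f"subject {subj.subject_id} {level} {muscle} {side}: {exc}"
                        ) from exc
            _validate_masks(masks, f"subject {subj.subject_id} {level}")
            image = None
            if config.generate_images:
                fats = {
                    key: fat_lookup[(subj.subject_id, level) + key] for key in masks
                }
                sc, sh = jitter[subj.subject_id]
                image = synth_intensities(
                    masks, fats, config, streams[idx], scale=sc, shift=sh
                )
            idx += 1
            samples.append(
                SliceSample(subj.subject_id, level, image, masks, config.pixel_spacing)
            )
    return samples, subjects, truth


def subjects_frame(subjects: Sequence[SubjectRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "subject_id": s.subject_id,
                "sex": s.sex,
                "age": s.age,
                "affected_side": s.affected_side,
            }
            for s in subjects
        ]
    )
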