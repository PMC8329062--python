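"""Conventional muscle measures: CSA, k-means fat segmentation, fat%, Dice.

Cross-sectional area (CSA) is pixel count times pixel area, reported in cm2.
Fat is separated from lean muscle within each mask by two-class k-means on
intensity; on T2-weighted images fat is bright, so the higher-mean cluster is
labelled fat.  The one-dimensional two-class problem is solved exactly (the
optimal partition is a threshold on sorted intensities), which makes the
segmentation fully deterministic; a ``seed`` parameter is accepted for API
symmetry but is unused.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class DegenerateInputError(ValueError):
    """Input carries no usable signal (empty mask, constant intensities)."""


class InconsistencyError(ValueError):
    """Inputs violate a containment or pairing contract."""


def compute_csa(mask: np.ndarray, pixel_spacing: float) -> float:
    """Cross-sectional area in cm2: pixel count x spacing^2 / 100."""
    n = int(np.asarray(mask, dtype=bool).sum())
    if n == 0:
        raise DegenerateInputError("empty mask has no cross-sectional area")
    return n * pixel_spacing**2 / 100.0


def _kmeans_1d(values: np.ndarray):
    """Exact deterministic 2-means on 1-D data; returns (assignments, centroids).

    Optimal two-class k-means partitions of scalar data are threshold
    partitions, so the global minimum of the within-cluster sum of squares is
    found by scanning every split of the sorted values (prefix-sum SSW).
    Cluster 1 is the upper interval.
    """
    order = np.argsort(values, kind="stable")
    v = values[order]
    n = v.size
    cs = np.concatenate([[0.0], np.cumsum(v)])
    cs2 = np.concatenate([[0.0], np.cumsum(v * v)])
    m = np.arange(1, n)  # lower-cluster sizes
    low = cs2[1:-1] - cs[1:-1] ** 2 / m
    hi = (cs2[-1] - cs2[1:-1]) - (cs[-1] - cs[1:-1]) ** 2 / (n - m)
    split = int(np.argmin(low + hi)) + 1
    assign = np.zeros(n, dtype=int)
    assign[order[split:]] = 1
    c = np.array([v[:split].mean(), v[split:].mean()])
    return assign, c


def segment_fat_kmeans(
    image: np.ndarray, mask: np.ndarray, seed: int | None = None
) -> np.ndarray:
    """Binary fat raster: k=2 intensity clustering within the mask.

    The higher-mean cluster is fat (T2-weighted convention: fat is bright).
    Inverted-contrast inputs would silently flip the labels -- callers must
    supply T2-weighted-like intensities.
    """
    m = np.asarray(mask, dtype=bool)
    vals = np.asarray(image, dtype=float)[m]
    if vals.size == 0 or np.unique(vals).size < 2:
        raise DegenerateInputError(
            "fat segmentation needs >= 2 distinct intensities within the mask"
        )
    assign, c = _kmeans_1d(vals)
    fat_label = int(np.argmax(c))
    fat = np.zeros(m.shape, dtype=bool)
    fat[m] = assign == fat_label
    return fat


def fat_percent(fat: np.ndarray, mask: np.ndarray) -> float:
    """|fat| / |mask| as a proportion in [0, 1]."""
    f = np.asarray(fat, dtype=bool)
    m = np.asarray(mask, dtype=bool)
    if m.sum() == 0:
        raise DegenerateInputError("empty mask")
    if np.any(f & ~m):
        raise InconsistencyError("fat raster extends outside the muscle mask")
    return float(f.sum() / m.sum())


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap 2|A^B|/(|A|+|B|); both-empty is defined as 1.0 (logged)."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise InconsistencyError(f"grid mismatch: {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        logger.info("dice of two empty masks defined as 1.0")
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def reliability_harness(pairs) -> pd.DataFrame:
    """Dice agreement for re-segmented mask pairs, with per-stratum mean +/- sd.

    ``pairs`` is an iterable of dicts with keys ``level``, ``muscle``,
    ``rater_pair``, ``mask_a``, ``mask_b``.  Returns a tidy table with one
    row per pair plus ``mean``/``sd`` columns merged per
    (level, muscle, rater_pair) stratum.
    """
    pairs = list(pairs)
    if not pairs:
        raise InconsistencyError("no mask pairs supplied")
    rows = []
    for p in pairs:
        missing = {"level", "muscle", "rater_pair", "mask_a", "mask_b"} - set(p)
        if missing:
            raise InconsistencyError(f"pair missing keys: {sorted(missing)}")
        rows.append(
            {
                "level": p["level"],
                "muscle": p["muscle"],
                "rater_pair": p["rater_pair"],
                "dice": dice(p["mask_a"], p["mask_b"]),
            }
        )
    df = pd.DataFrame(rows)
    strata = (
        df.groupby(["level", "muscle", "rater_pair"])["dice"]
        .agg(mean="mean", sd=lambda s: s.std(ddof=0))
        .reset_index()
    )
    return df.merge(strata, on=["level", "muscle", "rater_pair"])


def morphometry_table(samples, subjects) -> pd.DataFrame:
    """Per-sample CSA and fat% rows for a cohort of slice samples.

    Requires images (for fat segmentation); columns match the documented CSV
    layout: subject_id, level, muscle, side, side_role, csa_cm2, fat_pct.
    """
    affected = {s.subject_id: s.affected_side for s in subjects}
    rows = []
    for sample in samples:
        if sample.image is None:
            raise DegenerateInputError(
                f"sample {sample.subject_id} {sample.level} has no image"
            )
        for (muscle, side), mask in sorted(sample.masks.items()):
            fat = segment_fat_kmeans(sample.image, mask)
            rows.append(
                {
                    "subject_id": sample.subject_id,
                    "level": sample.level,
                    "muscle": muscle,
                    "side": side,
                    "side_role": "affected"
                    if side == affected[sample.subject_id]
                    else "unaffected",
                    "csa_cm2": compute_csa(mask, sample.pixel_spacing),
                    "fat_pct": fat_percent(fat, mask),
                }
            )
    return pd.DataFrame(rows)
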