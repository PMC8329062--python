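"""Point-distribution shape modelling of muscle contours.

The pipeline: trace each binary mask to a closed contour with K arc-length
corresponded landmarks anchored at the medially most extreme boundary point;
mirror left-side shapes into the canonical right-side frame; build a
mirror-symmetric mean template by generalized Procrustes analysis (GPA) of
the shapes together with their reflected copies; similarity-align every
shape to the template (scale, rotation, translation -- never reflection,
which is always explicit); and fit a PCA statistical shape model retaining
the smallest number of modes whose cumulative variance fraction reaches the
threshold (0.90 by default).  Mode coefficients -- each sample's projection
onto the retained modes -- are the quantities correlated with clinical and
demographic factors downstream.

The model/results split follows the fit-object idiom: a
`PointDistributionModel` is constructed from aligned shapes and its
``fit()`` returns a `ShapeModelResults` carrying the mean shape, modes,
variances and diagnostics.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field as dataclass_field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure

from ._geometry import (
    Contour,
    GeometryError,
    TopologyError,
    canonical_start_index,
    perimeter,
    resample_closed,
    signed_area,
)


class ConvergenceError(RuntimeError):
    """Iterative alignment failed to converge."""


class AsymmetricInputWarning(UserWarning):
    """Template input set was not mirror-closed; the template may be asymmetric."""


# ---------------------------------------------------------------------------
# contour extraction and mirroring
# ---------------------------------------------------------------------------

def extract_contour(
    mask: np.ndarray, K: int, pixel_spacing: float = 1.0, smooth_mm: float = 0.0
) -> Contour:
    """Trace a mask boundary at the 0.5 iso-level into a K-landmark contour.

    The mask must be a single hole-free 4-connected component of >= 50
    pixels.  Landmarks are equally spaced by arc length starting from the
    boundary point of maximal medial extent (minimal x, ties by minimal y),
    in counterclockwise order.  ``smooth_mm > 0`` applies a periodic gaussian
    filter of that arc-length scale to the traced boundary before landmark
    placement, suppressing pixel-staircase quantization noise (the shape
    pipeline uses 1 mm by default; pass 0 for the raw trace).
    """
    m = np.asarray(mask, dtype=bool)
    _, n = measure.label(m, connectivity=1, return_num=True)
    if n != 1:
        raise TopologyError(f"mask has {n} connected components (need exactly 1)")
    if ndimage.binary_fill_holes(m).sum() != m.sum():
        raise TopologyError("mask contains interior holes")
    if m.sum() < 50:
        raise TopologyError(f"mask has only {int(m.sum())} pixels (< 50)")
    padded = np.pad(m.astype(float), 1)
    traces = measure.find_contours(padded, 0.5)
    # the single outer boundary of a filled component
    trace = max(traces, key=len)
    # (row, col) in padded index space -> physical mm (pixel centre convention)
    pts = np.column_stack(
        [(trace[:, 1] - 1 + 0.5) * pixel_spacing, (trace[:, 0] - 1 + 0.5) * pixel_spacing]
    )
    if np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    if signed_area(pts) < 0:
        pts = pts[::-1]
    if smooth_mm > 0:
        dense = resample_closed(pts, max(512, 4 * K))
        step = perimeter(dense) / len(dense)
        pts = ndimage.gaussian_filter1d(
            dense, sigma=smooth_mm / step, axis=0, mode="wrap"
        )
    pts = np.roll(pts, -canonical_start_index(pts), axis=0)
    return Contour(resample_closed(pts, K), validate=False)


def mirror_shape(contour: Contour, axis_x: float, restart: bool = True) -> Contour:
    """Reflect a contour about the vertical line x = axis_x.

    ``restart=True`` re-applies the canonical (min-x) start rule -- the form
    used to map left-side shapes into the canonical right-side frame, where
    it keeps landmark 0 at the medially most extreme point.  ``restart=False``
    preserves landmark labels through the reflection (used to build
    mirror-closed template sets with exactly consistent correspondence).
    """
    return contour.mirrored(axis_x, restart=restart)


def _reflect_labels(points: np.ndarray) -> np.ndarray:
    """Label-preserving reflection about the vertical axis through the centroid."""
    c = points.mean(axis=0)
    q = points.copy()
    q[:, 0] = 2.0 * c[0] - q[:, 0]
    return np.roll(q[::-1], 1, axis=0)


# ---------------------------------------------------------------------------
# similarity alignment (complex-number formulation; reflection impossible)
# ---------------------------------------------------------------------------

def _as_complex(points: np.ndarray) -> np.ndarray:
    return points[:, 0] + 1j * points[:, 1]


def _from_complex(z: np.ndarray) -> np.ndarray:
    return np.column_stack([z.real, z.imag])


@dataclass
class AlignedShape:
    """A contour expressed in the template frame plus its recovery transform.

    ``scale``, ``rotation`` (radians) and ``translation`` map the
    template-frame points back onto the original input:
    ``x_input = scale * R(rotation) @ x_template_frame + translation``.
    """

    points: np.ndarray  # (K, 2) template frame
    scale: float
    rotation: float
    translation: np.ndarray  # (2,)
    residual: float  # rms template-frame distance to the template
    tags: dict = dataclass_field(default_factory=dict)

    def to_input_frame(self) -> np.ndarray:
        ct, st = np.cos(self.rotation), np.sin(self.rotation)
        R = np.array([[ct, -st], [st, ct]])
        return self.scale * self.points @ R.T + self.translation


def align_to_template(
    contour: Contour, template: Contour, tags: dict | None = None
) -> AlignedShape:
    """Least-squares similarity registration onto the template.

    Minimizes the point-wise distance under the fixed arc-length
    correspondence over scale > 0, rotation and translation.  Reflections
    are not in the search space: mirroring is always an explicit step.
    """
    if contour.K != template.K:
        raise GeometryError(f"landmark count mismatch: {contour.K} vs {template.K}")
    z = _as_complex(contour.points)
    w = _as_complex(template.points)
    mz = z.mean()
    mw = w.mean()
    zc = z - mz
    wc = w - mw
    denom = float(np.sum(np.abs(zc) ** 2))
    if denom <= 1e-12 * contour.K:
        raise GeometryError("degenerate zero-size contour cannot be aligned")
    a = np.sum(np.conj(zc) * wc) / denom  # forward: w ~ a * zc + mw
    aligned = a * zc + mw
    residual = float(np.sqrt(np.mean(np.abs(aligned - w) ** 2)))
    inv = 1.0 / a
    t = mz - inv * mw
    return AlignedShape(
        points=_from_complex(aligned),
        scale=float(np.abs(inv)),
        rotation=float(np.angle(inv)),
        translation=np.array([t.real, t.imag]),
        residual=residual,
        tags=dict(tags or {}),
    )


# ---------------------------------------------------------------------------
# generalized Procrustes template
# ---------------------------------------------------------------------------

def _gpa_mean(z: np.ndarray, tol: float = 1e-6, max_iter: int = 100) -> np.ndarray:
    """GPA mean of complex landmark configurations (n, K), centroid size 1."""
    z = z - z.mean(axis=1, keepdims=True)
    ref = z[0] / np.sqrt(np.mean(np.abs(z[0]) ** 2))
    for _ in range(max_iter):
        a = np.sum(np.conj(z) * ref, axis=1) / np.sum(np.abs(z) ** 2, axis=1)
        mean = (a[:, None] * z).mean(axis=0)
        mean = mean - mean.mean()
        mean = mean / np.sqrt(np.mean(np.abs(mean) ** 2))
        if np.sqrt(np.mean(np.abs(mean - ref) ** 2)) < tol:
            return mean
        ref = mean
    raise ConvergenceError(f"generalized Procrustes did not converge in {max_iter} iterations")


def reflection_alignment(template: Contour) -> complex:
    """Complex similarity factor aligning the reflected template onto itself.

    The label-preserving reflection geometrically mirrors about the axis
    through landmark 0 and the centroid; for a mirror-symmetric template the
    returned unit-magnitude factor is the rotation relating the reflected
    frame back to the template frame.  Used to express the reflection
    operator in template coordinates (e.g. to classify modes as symmetric or
    antisymmetric).
    """
    z = _as_complex(template.points)
    z = z - z.mean()
    rz = _as_complex(_reflect_labels(template.points))
    rz = rz - rz.mean()
    return complex(np.sum(np.conj(rz) * z) / np.sum(np.abs(rz) ** 2))


def template_asymmetry(template: Contour) -> float:
    """RMS residual of the template against its best-aligned reflection.

    Zero (to numerical tolerance) for a mirror-symmetric template; the
    reflection preserves landmark labels, so no start-point search is needed.
    """
    reflected = Contour(_reflect_labels(template.points), validate=False)
    return align_to_template(reflected, template).residual


def build_symmetric_template(
    contours,
    add_mirrors: bool = False,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> Contour:
    """Mirror-symmetric mean shape by generalized Procrustes analysis.

    ``contours`` should be mirror-closed (contain a reflected copy of every
    member); alternatively pass ``add_mirrors=True`` and the label-preserving
    reflection of every input is appended automatically.  The GPA iterates
    {align all to the reference, average point-wise, re-centre and normalize
    centroid size to 1} until the mean moves by less than ``tol``.  A
    non-mirror-closed input produces a warning and a (documented) possibly
    asymmetric result.
    """
    shapes = [c.points for c in contours]
    if add_mirrors:
        shapes = shapes + [_reflect_labels(p) for p in shapes]
    if len(shapes) < 2:
        raise ValueError("template construction needs >= 2 contours")
    K = shapes[0].shape[0]
    if any(p.shape[0] != K for p in shapes):
        raise GeometryError("all contours must share the same landmark count")
    z = np.stack([_as_complex(p) for p in shapes])
    mean = _gpa_mean(z, tol=tol, max_iter=max_iter)
    template = Contour(_from_complex(mean), validate=False)
    asym = template_asymmetry(template)
    if asym > 1e-5:
        warnings.warn(
            f"template asymmetry {asym:.2e} exceeds 1e-5; the input set was "
            "probably not mirror-closed",
            AsymmetricInputWarning,
            stacklevel=2,
        )
    return template


# ---------------------------------------------------------------------------
# PCA statistical shape model
# ---------------------------------------------------------------------------

def _stack_shapes(shapes) -> np.ndarray:
    rows = []
    for s in shapes:
        pts = s.points if hasattr(s, "points") else np.asarray(s, dtype=float)
        rows.append(pts.reshape(-1))  # interleaved x0, y0, x1, y1, ...
    return np.stack(rows)


class PointDistributionModel:
    """PCA shape model over corresponded 2-D landmark configurations.

    Parameters
    ----------
    shapes : sequence of `AlignedShape` / `Contour` / (K, 2) arrays, all in
        the same (template) frame with consistent landmark correspondence.
    tags : optional DataFrame with one row of sample metadata per shape
        (subject_id, level, muscle, side, side_role, ...), carried through
        to the coefficient table.
    """

    def __init__(self, shapes, tags: pd.DataFrame | None = None):
        self.data = _stack_shapes(shapes)
        if self.data.shape[0] < 3:
            raise ValueError("shape model needs at least 3 samples")
        if tags is not None and len(tags) != self.data.shape[0]:
            raise ValueError("tags must have one row per shape")
        self.tags = tags.reset_index(drop=True) if tags is not None else None

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def K(self) -> int:
        return self.data.shape[1] // 2

    def fit(self, variance_threshold: float = 0.90) -> "ShapeModelResults":
        """Eigendecompose the sample covariance and retain modes to threshold.

        Uses the n x n Gram-matrix route when 2K > n (the covariance has rank
        <= n - 1); eigenvalues below 1e-12 of the largest are discarded as
        numerical nullspace.
        """
        X = self.data
        n, p = X.shape
        mean = X.mean(axis=0)
        Xc = X - mean
        total_var = float(np.sum(Xc**2) / (n - 1))
        if p > n:
            G = Xc @ Xc.T / (n - 1)
            w, U = np.linalg.eigh(G)
            w = w[::-1]
            U = U[:, ::-1]
            keep = w > 1e-12 * max(w[0], np.finfo(float).tiny)
            w = w[keep]
            U = U[:, keep]
            V = Xc.T @ U / np.sqrt(w * (n - 1))
        else:
            C = Xc.T @ Xc / (n - 1)
            w, V = np.linalg.eigh(C)
            w = w[::-1]
            V = V[:, ::-1]
            keep = w > 1e-12 * max(w[0], np.finfo(float).tiny)
            w = w[keep]
            V = V[:, keep]
        frac = w / total_var
        cum = np.cumsum(frac)
        if not 0 < variance_threshold <= 1:
            raise ValueError("variance_threshold must be in (0, 1]")
        M = int(np.searchsorted(cum, variance_threshold - 1e-12) + 1)
        M = min(M, len(w))
        return ShapeModelResults(
            model=self,
            mean_shape=mean,
            modes=V[:, :M],
            variances=w[:M],
            all_variances=w,
            total_variance=total_var,
            threshold=variance_threshold,
        )


class ShapeModelResults:
    """Fitted statistical shape model.

    Attributes
    ----------
    mean_shape : (2K,) mean landmark vector in the template frame.
    modes : (2K, M) orthonormal principal shape variations, variance-ranked.
    variances : (M,) per-mode variances (1/(n-1) normalization).
    variance_fraction : (M,) share of the total shape variance per mode.
    """

    def __init__(
        self, model, mean_shape, modes, variances, all_variances, total_variance, threshold
    ):
        self.model = model
        self.mean_shape = mean_shape
        self.modes = modes
        self.variances = variances
        self.all_variances = all_variances
        self.total_variance = total_variance
        self.threshold = threshold

    @property
    def n_modes(self) -> int:
        return self.modes.shape[1]

    @property
    def n_samples(self) -> int:
        return self.model.n_samples

    @property
    def K(self) -> int:
        return len(self.mean_shape) // 2

    @property
    def variance_fraction(self) -> np.ndarray:
        return self.variances / self.total_variance

    # -- projection / reconstruction --------------------------------------
    def _as_vector(self, shape) -> np.ndarray:
        if hasattr(shape, "points"):
            vec = np.asarray(shape.points, dtype=float).reshape(-1)
        else:
            vec = np.asarray(shape, dtype=float).reshape(-1)
        if vec.shape[0] != 2 * self.K:
            raise GeometryError(
                f"landmark count mismatch: got {vec.shape[0] // 2}, model has {self.K}"
            )
        return vec

    def project(self, shape) -> np.ndarray:
        """Mode coefficients b = modes^T (x - mean): the shape's loading on each mode."""
        return self.modes.T @ (self._as_vector(shape) - self.mean_shape)

    def reconstruct(self, coefficients) -> np.ndarray:
        """mean + modes @ b, returned as a (K, 2) landmark array."""
        b = np.asarray(coefficients, dtype=float)
        if b.shape != (self.n_modes,):
            raise ValueError(
                f"expected {self.n_modes} coefficients, got {b.shape}"
            )
        return (self.mean_shape + self.modes @ b).reshape(-1, 2)

    def mode_variant(self, mode: int, c: float) -> np.ndarray:
        """Shape at ``mean + c * sqrt(variance_m) * mode_m`` (mode is 1-based).

        ``c = +/-3`` gives the conventional three-standard-deviation variants
        used to visualize each mode's direction of variation.
        """
        if not 1 <= mode <= self.n_modes:
            raise IndexError(f"mode must be in 1..{self.n_modes}, got {mode}")
        m = mode - 1
        vec = self.mean_shape + c * np.sqrt(self.variances[m]) * self.modes[:, m]
        return vec.reshape(-1, 2)

    def coefficients_table(self) -> pd.DataFrame:
        """One row per training sample: tags plus columns b1..bM."""
        B = (self.model.data - self.mean_shape) @ self.modes
        cols = {f"b{m + 1}": B[:, m] for m in range(self.n_modes)}
        if self.model.tags is not None:
            return pd.concat([self.model.tags.copy(), pd.DataFrame(cols)], axis=1)
        return pd.DataFrame(cols)

    def summary(self) -> pd.DataFrame:
        frac = self.variance_fraction
        return pd.DataFrame(
            {
                "mode": np.arange(1, self.n_modes + 1),
                "variance": self.variances,
                "pct_variance": 100 * frac,
                "cum_pct_variance": 100 * np.cumsum(frac),
            }
        )

    def __str__(self) -> str:
        lines = [
            "Point distribution model",
            f"  samples: {self.n_samples}, landmarks: {self.K}",
            f"  modes retained: {self.n_modes} "
            f"(cumulative {100 * self.variance_fraction.sum():.1f}% "
            f">= {100 * self.threshold:.0f}% threshold)",
        ]
        for _, row in self.summary().iterrows():
            lines.append(
                f"  mode {int(row['mode'])}: {row['pct_variance']:.1f}% of variance"
            )
        return "\n".join(lines)

    # -- serialization -----------------------------------------------------
    def save(self, path) -> None:
        """Write the model to a single JSON archive (documented layout)."""
        payload = {
            "K": self.K,
            "n_samples": self.n_samples,
            "threshold": self.threshold,
            "total_variance": self.total_variance,
            "mean_shape": self.mean_shape.tolist(),
            "modes": self.modes.tolist(),
            "variances": self.variances.tolist(),
            "all_variances": self.all_variances.tolist(),
            "tags": self.model.tags.to_dict(orient="list")
            if self.model.tags is not None
            else None,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "ShapeModelResults":
        with open(path) as fh:
            payload = json.load(fh)
        model = object.__new__(PointDistributionModel)
        model.data = np.zeros((payload["n_samples"], 2 * payload["K"]))
        model.tags = (
            pd.DataFrame(payload["tags"]) if payload["tags"] is not None else None
        )
        return cls(
            model=model,
            mean_shape=np.asarray(payload["mean_shape"]),
            modes=np.asarray(payload["modes"]),
            variances=np.asarray(payload["variances"]),
            all_variances=np.asarray(payload["all_variances"]),
            total_variance=payload["total_variance"],
            threshold=payload["threshold"],
        )


def fit_ssm(shapes, variance_threshold: float = 0.90, tags=None) -> ShapeModelResults:
    """Functional shorthand for ``PointDistributionModel(shapes, tags).fit(...)``."""
    return PointDistributionModel(shapes, tags=tags).fit(variance_threshold)


# ---------------------------------------------------------------------------
# per-muscle/level shape analysis from masks
# ---------------------------------------------------------------------------

def canonical_shape(
    contour: Contour, side: str, axis_x: float
) -> Contour:
    """Map a muscle contour into the canonical right-side frame.

    Left-side shapes are mirrored about the image vertical midline with the
    start rule re-applied; right-side shapes pass through unchanged.
    """
    if side == "left":
        return mirror_shape(contour, axis_x, restart=True)
    return contour


def shape_analysis_for_group(
    samples,
    subjects,
    level: str,
    muscle: str,
    K: int = 100,
    variance_threshold: float = 0.90,
    smooth_mm: float = 1.0,
):
    """Contours -> symmetric template -> alignment -> SSM for one (level, muscle).

    The SSM sample set holds two shapes per subject (affected-side and
    unaffected-side, both in the canonical right frame); the template is
    additionally closed under reflection.  Returns
    ``(results, template, coeffs)`` where ``coeffs`` is the tagged
    coefficient table.
    """
    affected = {s.subject_id: s.affected_side for s in subjects}
    shapes, tag_rows = [], []
    for sample in samples:
        if sample.level != level:
            continue
        H, W = next(iter(sample.masks.values())).shape
        axis_x = W * sample.pixel_spacing / 2.0
        for side in ("left", "right"):
            mask = sample.masks[(muscle, side)]
            contour = extract_contour(mask, K, sample.pixel_spacing, smooth_mm=smooth_mm)
            shapes.append(canonical_shape(contour, side, axis_x))
            tag_rows.append(
                {
                    "subject_id": sample.subject_id,
                    "level": level,
                    "muscle": muscle,
                    "side": side,
                    "mirrored": side == "left",
                    "side_role": "affected"
                    if side == affected[sample.subject_id]
                    else "unaffected",
                }
            )
    if not shapes:
        raise ValueError(f"no samples found for level={level} muscle={muscle}")
    template = build_symmetric_template(shapes, add_mirrors=True)
    aligned = [align_to_template(c, template) for c in shapes]
    results = PointDistributionModel(aligned, tags=pd.DataFrame(tag_rows)).fit(
        variance_threshold
    )
    return results, template, results.coefficients_table()


def shape_analysis_from_contours(
    contour_items,
    subjects,
    axis_x: float,
    K: int | None = None,
    variance_threshold: float = 0.90,
):
    """Like `shape_analysis_for_group` but starting from already-traced contours.

    ``contour_items`` is an iterable of ``(tags_dict, Contour)`` where tags
    include subject_id and side; used by simulation studies that skip the
    raster round-trip.
    """
    affected = {s.subject_id: s.affected_side for s in subjects}
    shapes, tag_rows = [], []
    for tags, contour in contour_items:
        side = tags["side"]
        c = canonical_shape(contour if K is None else contour.resample(K), side, axis_x)
        shapes.append(c)
        row = dict(tags)
        row["mirrored"] = side == "left"
        row["side_role"] = (
            "affected" if side == affected[tags["subject_id"]] else "unaffected"
        )
        tag_rows.append(row)
    template = build_symmetric_template(shapes, add_mirrors=True)
    aligned = [align_to_template(c, template) for c in shapes]
    results = PointDistributionModel(aligned, tags=pd.DataFrame(tag_rows)).fit(
        variance_threshold
    )
    return results, template, results.coefficients_table()
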