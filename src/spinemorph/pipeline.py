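"""End-to-end orchestration: simulate -> standardize -> morphometry -> shape
-> stats -> report, with a manifest and reproducible seeding.

Artifacts are plain CSV/JSON (and PNG/SVG figures); rerunning with the same
config and seed produces byte-identical CSV outputs.  A single root seed is
carried by the cohort config; the generator derives independent substreams
internally so that toggling image generation never perturbs the shape draws.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pandas as pd

from . import __version__
from .cohort import (
    CohortConfig,
    SIDES,
    SliceSample,
    SubjectRecord,
    generate_cohort,
    subjects_frame,
)
from .morphometry import morphometry_table
from .preprocess import learn_standard_scale
from .shape import ShapeModelResults, shape_analysis_for_group
from .stats import (
    analyze_modes,
    analyze_morphometry,
    correlate_fat_with_modes,
    significant_modes_table,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "standardize", "morphometry", "shape", "stats", "report")
_CSV_FMT = "%.12g"


class PipelineError(RuntimeError):
    """A stage failed or was invoked out of dependency order."""


class LayoutError(ValueError):
    """A real-data directory does not follow the documented layout."""


@dataclass
class RunConfig:
    """Pipeline run parameters: cohort source, stages, thresholds, output."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    input_dir: str | None = None  # real-data layout; overrides simulation
    stages: tuple = STAGES
    output_dir: str = "spinemorph_run"
    landmark_count: int = 100
    variance_threshold: float = 0.90
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self):
        order = {s: i for i, s in enumerate(STAGES)}
        unknown = [s for s in self.stages if s not in order]
        if unknown:
            raise PipelineError(f"unknown stages: {unknown}")
        idx = [order[s] for s in self.stages]
        if idx != sorted(idx):
            raise PipelineError("stages must respect dependency order")
        if not 0 < self.alpha < 1:
            raise PipelineError("alpha must be in (0, 1)")
        self.cohort = dataclasses.replace(self.cohort, seed=self.seed)

    @classmethod
    def from_flat_dict(cls, d: dict) -> "RunConfig":
        """Build from a flat key-value mapping (JSON config file)."""
        d = dict(d)
        run_keys = {
            "stages",
            "output_dir",
            "landmark_count",
            "variance_threshold",
            "alpha",
            "seed",
            "input_dir",
        }
        run = {k: d.pop(k) for k in list(d) if k in run_keys}
        if "stages" in run:
            run["stages"] = tuple(run["stages"])
        cohort_fields = {f.name for f in dataclasses.fields(CohortConfig)}
        bad = set(d) - cohort_fields
        if bad:
            raise PipelineError(f"unknown config keys: {sorted(bad)}")
        for key in ("grid_size", "levels", "muscles"):
            if key in d:
                d[key] = tuple(d[key])
        cohort = CohortConfig(**d, seed=int(run.get("seed", 0)))
        return cls(cohort=cohort, **run)


# ---------------------------------------------------------------------------
# cohort directory IO
# ---------------------------------------------------------------------------

def save_cohort(samples, subjects, truth, out_dir) -> None:
    """Write a cohort in the documented file layout.

    Masks: ``{subject_id}_{level}_{muscle}_{side}.png`` (8-bit, 0/255).
    Images: ``{subject_id}_{level}_image.nii`` (float64 single slice, pixel
    spacing in the header).  Covariates and ground truth as CSV; pixel
    spacing also recorded in ``cohort_meta.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spacing = samples[0].pixel_spacing if samples else 1.0
    for s in samples:
        for (muscle, side), mask in s.masks.items():
            iio.imwrite(
                out / f"{s.subject_id}_{s.level}_{muscle}_{side}.png",
                (mask.astype(np.uint8) * 255),
            )
        if s.image is not None:
            img = nib.Nifti1Image(s.image[:, :, None].astype(np.float64), np.eye(4))
            img.header.set_zooms((spacing, spacing, 1.0))
            nib.save(img, out / f"{s.subject_id}_{s.level}_image.nii")
    subjects_frame(subjects).to_csv(out / "covariates.csv", index=False)
    truth.to_csv(out / "ground_truth.csv", index=False, float_format=_CSV_FMT)
    meta = {
        "pixel_spacing": spacing,
        "levels": sorted({s.level for s in samples}),
        "muscles": sorted({m for s in samples for (m, _) in s.masks}),
    }
    (out / "cohort_meta.json").write_text(json.dumps(meta, indent=2))


def load_real_layout(in_dir):
    """Load slice samples and subject records from a cohort directory.

    Mask invariants are enforced on load; subjects missing all four masks at
    a level are excluded at that level (logged); malformed files or covariate
    rows raise `LayoutError` with an itemized report.
    """
    from .cohort import _validate_masks  # enforce the same invariants

    root = Path(in_dir)
    cov_path = root / "covariates.csv"
    if not cov_path.exists():
        raise LayoutError(f"missing covariates.csv in {root}")
    cov = pd.read_csv(cov_path)
    problems = []
    subjects = []
    for row in cov.itertuples(index=False):
        try:
            subjects.append(
                SubjectRecord(
                    str(row.subject_id), str(row.sex), float(row.age),
                    str(row.affected_side),
                )
            )
        except (ValueError, AttributeError) as exc:
            problems.append(f"covariates row {row!r}: {exc}")
    if problems:
        raise LayoutError("invalid covariates:\n" + "\n".join(problems))

    meta_path = root / "cohort_meta.json"
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    spacing = float(meta.get("pixel_spacing", 1.0))
    levels = meta.get("levels") or sorted(
        {p.stem.split("_")[1] for p in root.glob("*_image.nii")}
    )
    muscles = meta.get("muscles", ["ES", "MF"])

    samples = []
    excluded = 0
    for subj in subjects:
        for level in levels:
            masks = {}
            missing = []
            for muscle in muscles:
                for side in SIDES:
                    p = root / f"{subj.subject_id}_{level}_{muscle}_{side}.png"
                    if not p.exists():
                        missing.append(p.name)
                        continue
                    masks[(muscle, side)] = iio.imread(p) > 127
            if missing:
                excluded += 1
                logger.warning(
                    "excluding subject %s at level %s (missing: %s)",
                    subj.subject_id, level, ", ".join(missing),
                )
                continue
            try:
                _validate_masks(masks, f"subject {subj.subject_id} {level}")
            except Exception as exc:
                raise LayoutError(str(exc)) from exc
            img_path = root / f"{subj.subject_id}_{level}_image.nii"
            image = None
            if img_path.exists():
                image = np.asarray(nib.load(img_path).dataobj)[:, :, 0]
            samples.append(SliceSample(subj.subject_id, level, image, masks, spacing))
    if excluded:
        logger.warning("%d subject-level slices excluded for missing files", excluded)
    return samples, subjects


# ---------------------------------------------------------------------------
# figures
# ---------------------------------------------------------------------------

def plot_mode_variants(results: ShapeModelResults, mode: int, direction: float = 1.0,
                       title: str | None = None, ax=None):
    """Mean contour with +/- 3 SD variants of one mode.

    ``direction`` flips which variant is drawn green: green is the direction
    of shape change toward the tested factor (affected side / female /
    older), red the opposite, following the usual visual convention.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    mean = results.mean_shape.reshape(-1, 2)
    plus = results.mode_variant(mode, 3.0 * np.sign(direction) or 3.0)
    minus = results.mode_variant(mode, -3.0 * np.sign(direction) or -3.0)
    for pts, color, label in (
        (plus, "green", "toward factor (+3 SD)"),
        (minus, "red", "opposite (-3 SD)"),
        (mean, "orange", "mean"),
    ):
        closed = np.vstack([pts, pts[:1]])
        ax.plot(closed[:, 0], closed[:, 1], color=color, label=label)
    pct = 100 * results.variance_fraction[mode - 1]
    ax.set_title(title or f"Mode {mode} [{pct:.1f}%]")
    ax.set_aspect("equal")
    ax.invert_yaxis()  # image convention: y increases downward
    ax.legend(fontsize=7)
    return ax


# ---------------------------------------------------------------------------
# pipeline driver
# ---------------------------------------------------------------------------

def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_CSV_FMT)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and return the run manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": {
            **{k: v for k, v in dataclasses.asdict(config).items() if k != "cohort"},
            "cohort": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in dataclasses.asdict(config.cohort).items()
                if not isinstance(v, dict)
            },
        },
        "stages_completed": [],
        "counts": {},
        "notes": [
            "p-values are reported without multiple-comparison correction",
        ],
    }
    samples = subjects = truth = None
    morph = None
    ssm_results: dict = {}
    coeff_all = None
    mode_assoc = None

    def done(stage, **counts):
        manifest["stages_completed"].append(stage)
        manifest["counts"].update(counts)
        logger.info("stage %s complete (%s)", stage, counts)

    try:
        if "simulate" in config.stages:
            samples, subjects, truth = generate_cohort(config.cohort)
            save_cohort(samples, subjects, truth, out / "cohort")
            done("simulate", subjects=len(subjects), slices=len(samples))
        elif config.input_dir is not None:
            samples, subjects = load_real_layout(config.input_dir)
            truth = None
            done("load", subjects=len(subjects), slices=len(samples))
        else:
            raise PipelineError(
                "no input: enable the simulate stage or provide input_dir"
            )

        if "standardize" in config.stages:
            # The learned common scale is an artifact for cross-subject
            # comparability and visualization.  Downstream fat segmentation
            # runs per-mask 1-D k-means, which is affine-equivariant, so it
            # consumes the native intensities: piecewise-linear landmark maps
            # can warp strongly bimodal within-muscle histograms and shift
            # the fat/lean split, whereas the per-subject contrast jitter the
            # standardization corrects for is already invisible to k-means.
            with_img = [s for s in samples if s.image is not None]
            if not with_img:
                raise PipelineError("standardize stage requires images")
            fgs = [np.logical_or.reduce(list(s.masks.values())) for s in with_img]
            scale = learn_standard_scale([s.image for s in with_img], fgs)
            scale.to_csv(out / "standard_scale.csv")
            done("standardize", standardized=len(with_img))

        if "morphometry" in config.stages:
            morph = morphometry_table(samples, subjects)
            _write_csv(morph, out / "morphometry.csv")
            done("morphometry", morphometry_rows=len(morph))

        if "shape" in config.stages:
            levels = sorted({s.level for s in samples})
            muscles = sorted({m for s in samples for (m, _) in s.masks})
            coeff_frames = []
            retained = {}
            for level in levels:
                for muscle in muscles:
                    res, template, coeffs = shape_analysis_for_group(
                        samples, subjects, level, muscle,
                        K=config.landmark_count,
                        variance_threshold=config.variance_threshold,
                    )
                    key = f"{level}_{muscle}"
                    ssm_results[(level, muscle)] = res
                    res.save(out / f"shape_model_{key}.json")
                    coeff_frames.append(coeffs)
                    retained[key] = res.n_modes
            coeff_all = pd.concat(coeff_frames, ignore_index=True)
            _write_csv(coeff_all, out / "mode_coefficients.csv")
            done("shape", modes_retained=retained)

        if "stats" in config.stages:
            if coeff_all is None or morph is None:
                raise PipelineError(
                    "stats stage requires prior shape and morphometry artifacts"
                )
            subj_df = subjects_frame(subjects)
            mode_assoc = analyze_modes(coeff_all, subj_df)
            _write_csv(mode_assoc, out / "mode_associations.csv")
            morph_assoc = analyze_morphometry(morph, subj_df)
            _write_csv(morph_assoc, out / "morphometry_associations.csv")
            _write_csv(
                significant_modes_table(mode_assoc), out / "significant_modes.csv"
            )
            fat_modes = correlate_fat_with_modes(
                mode_assoc, coeff_all, morph, subj_df
            )
            _write_csv(fat_modes, out / "fat_vs_modes.csv")
            done(
                "stats",
                mode_tests=len(mode_assoc),
                morphometry_tests=len(morph_assoc),
                fat_mode_tests=len(fat_modes),
            )

        if "report" in config.stages:
            import matplotlib

            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            if mode_assoc is None:
                raise PipelineError("report stage requires prior stats artifacts")
            fig_dir = out / "figures"
            fig_dir.mkdir(exist_ok=True)
            n_figs = 0
            sig = mode_assoc[mode_assoc["significant"]]
            for row in sig.itertuples():
                res = ssm_results[(row.level, row.muscle)]
                ax = plot_mode_variants(
                    res,
                    int(row.mode),
                    direction=np.sign(row.rho) or 1.0,
                    title=(
                        f"{row.level}-{row.muscle} mode {int(row.mode)} "
                        f"[{100 * res.variance_fraction[int(row.mode) - 1]:.1f}%] "
                        f"vs {row.factor} (p={row.p_value:.3g})"
                    ),
                )
                stem = f"{row.level}_{row.muscle}_mode{int(row.mode)}_{row.factor}"
                ax.figure.savefig(fig_dir / f"{stem}.png", dpi=150)
                ax.figure.savefig(fig_dir / f"{stem}.svg")
                plt.close(ax.figure)
                n_figs += 1
            done("report", figures=n_figs)
    except Exception:
        manifest["failed"] = True
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
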