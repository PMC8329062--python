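"""Spearman partial correlation analyses of morphometry and shape modes.

The partial Spearman coefficient is the Pearson correlation of rank
residuals: every column is rank-transformed (average ranks for ties), the x
and y ranks are each residualized by least squares on the covariate ranks
plus an intercept, and rho is the Pearson correlation of the residuals.  The
p-value comes from ``t = rho * sqrt((n - 2 - k) / (1 - rho^2))`` with
``n - 2 - k`` degrees of freedom (k covariates); with k = 0 this reduces to
the ordinary Spearman coefficient and its t approximation.

Conventions: sex is encoded F = 1, M = 0; side_role affected = 1; age is
centred (immaterial under rank transformation).  Affected- and
unaffected-side samples from one subject are treated as independent
observations, mirroring an analysis that correlates measures against a side
indicator rather than using a paired test.  No multiple-comparison
correction is applied by default; an optional Benjamini-Hochberg column can
be requested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

P_FLOOR = 1e-300
ALPHA = 0.05


class DegenerateInputError(ValueError):
    """Zero-variance residuals or other inputs without usable signal."""


@dataclass
class AssociationResult:
    """One Spearman partial correlation."""

    response: str
    factor: str
    covariates: tuple
    rho: float
    p_value: float
    n: int
    significant: bool = field(init=False)

    def __post_init__(self):
        self.significant = self.p_value < ALPHA


def _rank(x) -> np.ndarray:
    return sstats.rankdata(np.asarray(x, dtype=float))


def _residualize(r: np.ndarray, Z: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(Z, r, rcond=None)
    return r - Z @ beta


def spearman_partial(
    x,
    y,
    covariates=None,
    response: str = "y",
    factor: str = "x",
    covariate_names: tuple = (),
) -> AssociationResult:
    """Partial Spearman correlation of x and y given covariate columns.

    ``covariates`` is a sequence of equal-length columns (possibly empty).
    Binary factors must be encoded 0/1 by the caller.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    covariates = [np.asarray(c, dtype=float) for c in (covariates or [])]
    n = len(x)
    k = len(covariates)
    if len(y) != n or any(len(c) != n for c in covariates):
        raise ValueError("all columns must have equal length")
    if n <= k + 2:
        raise DegenerateInputError(f"need n > k + 2 observations (n={n}, k={k})")
    rx = _rank(x)
    ry = _rank(y)
    if k:
        Z = np.column_stack([np.ones(n)] + [_rank(c) for c in covariates])
        ex = _residualize(rx, Z)
        ey = _residualize(ry, Z)
    else:
        ex = rx - rx.mean()
        ey = ry - ry.mean()
    sx = float(np.sqrt(np.sum(ex**2)))
    sy = float(np.sqrt(np.sum(ey**2)))
    if sx == 0 or sy == 0:
        raise DegenerateInputError("zero-variance rank residuals")
    rho = float(np.clip(np.dot(ex, ey) / (sx * sy), -1.0, 1.0))
    df = n - 2 - k
    if abs(rho) >= 1.0:
        p = P_FLOOR  # perfect correlation: p at the numerical floor
    else:
        t = rho * np.sqrt(df / (1.0 - rho**2))
        p = max(2.0 * sstats.t.sf(abs(t), df), P_FLOOR)
    return AssociationResult(
        response=response,
        factor=factor,
        covariates=tuple(covariate_names),
        rho=rho,
        p_value=float(p),
        n=n,
    )


# ---------------------------------------------------------------------------
# cohort-level analyses
# ---------------------------------------------------------------------------

def _encode(df: pd.DataFrame, subjects: pd.DataFrame) -> pd.DataFrame:
    """Join covariates and encode sex (F=1), side_role (affected=1), centred age."""
    need = {"subject_id", "sex", "age"}
    missing = need - set(subjects.columns)
    if missing:
        raise KeyError(f"subject table missing columns: {sorted(missing)}")
    out = df.merge(subjects[["subject_id", "sex", "age"]], on="subject_id", how="left")
    if out["sex"].isna().any():
        raise KeyError("some samples have no matching subject record")
    bad = set(out["sex"].unique()) - {"F", "M"}
    if bad:
        raise ValueError(f"unknown sex codes: {sorted(bad)}")
    out["sex_f"] = (out["sex"] == "F").astype(float)
    out["age_c"] = out["age"] - out["age"].mean()
    out["affected"] = (out["side_role"] == "affected").astype(float)
    return out


_FACTOR_PLANS = (
    # (factor column, covariate columns, reported names)
    ("affected", ("sex_f", "age_c"), "side_role", ("sex", "age")),
    ("sex_f", ("age_c", "affected"), "sex", ("age", "side_role")),
    ("age_c", ("sex_f", "affected"), "age", ("sex", "side_role")),
)


def _result_row(res: AssociationResult, **extra) -> dict:
    row = {
        "response": res.response,
        "factor": res.factor,
        "covariates": "+".join(res.covariates),
        "rho": res.rho,
        "p_value": res.p_value,
        "n": res.n,
        "significant": res.significant,
    }
    row.update(extra)
    return row


def analyze_modes(
    coefficients: pd.DataFrame, subjects: pd.DataFrame, add_bh: bool = False
) -> pd.DataFrame:
    """Correlate every mode coefficient with side, sex and age.

    ``coefficients`` is the tagged table from the shape model (columns
    subject_id, level, muscle, side_role, b1..bM).  Each (level, muscle,
    mode) yields three partial correlations: side_role | {sex, age},
    sex | {age, side_role}, age | {sex, side_role}.  No multiple-comparison
    correction is applied (each mode is an uncorrelated shape variation);
    ``add_bh=True`` appends an optional Benjamini-Hochberg column.
    """
    df = _encode(coefficients, subjects)
    mode_cols = sorted(
        (c for c in df.columns if c.startswith("b") and c[1:].isdigit()),
        key=lambda c: int(c[1:]),
    )
    rows = []
    for (level, muscle), grp in df.groupby(["level", "muscle"], sort=True):
        for col in mode_cols:
            if grp[col].isna().any():
                continue
            mode = int(col[1:])
            for fac_col, cov_cols, fac_name, cov_names in _FACTOR_PLANS:
                res = spearman_partial(
                    grp[fac_col],
                    grp[col],
                    [grp[c] for c in cov_cols],
                    response=f"{level}-{muscle} mode {mode}",
                    factor=fac_name,
                    covariate_names=cov_names,
                )
                rows.append(
                    _result_row(res, level=level, muscle=muscle, mode=mode)
                )
    out = pd.DataFrame(rows)
    if add_bh and len(out):
        from statsmodels.stats.multitest import multipletests

        out["p_bh"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out


def _check_pairing(df: pd.DataFrame) -> None:
    counts = df.groupby(["subject_id", "level", "muscle"])["side_role"].agg(
        ["count", "nunique"]
    )
    bad = counts[(counts["count"] != 2) | (counts["nunique"] != 2)]
    if len(bad):
        raise ValueError(
            "morphometry rows must pair one affected and one unaffected sample "
            f"per subject x level x muscle; offending groups: {list(bad.index[:5])}"
        )


def analyze_morphometry(
    morphometry: pd.DataFrame, subjects: pd.DataFrame, add_bh: bool = False
) -> pd.DataFrame:
    """Correlate CSA and fat% with side, sex and age per (level, muscle).

    Output rows carry the partial correlation plus per-group mean +/- sd for
    binary factors (affected/unaffected; female/male), mirroring the usual
    tabular presentation.
    """
    _check_pairing(morphometry)
    df = _encode(morphometry, subjects)
    rows = []
    for (level, muscle), grp in df.groupby(["level", "muscle"], sort=True):
        for measure in ("csa_cm2", "fat_pct"):
            for fac_col, cov_cols, fac_name, cov_names in _FACTOR_PLANS:
                res = spearman_partial(
                    grp[fac_col],
                    grp[measure],
                    [grp[c] for c in cov_cols],
                    response=f"{level}-{muscle} {measure}",
                    factor=fac_name,
                    covariate_names=cov_names,
                )
                extra = {"level": level, "muscle": muscle, "measure": measure}
                if fac_name in ("side_role", "sex"):
                    g1 = grp.loc[grp[fac_col] == 1.0, measure]
                    g0 = grp.loc[grp[fac_col] == 0.0, measure]
                    lab1, lab0 = (
                        ("affected", "unaffected")
                        if fac_name == "side_role"
                        else ("female", "male")
                    )
                    extra.update(
                        {
                            "group1": lab1,
                            "group1_mean": g1.mean(),
                            "group1_sd": g1.std(ddof=1),
                            "group0": lab0,
                            "group0_mean": g0.mean(),
                            "group0_sd": g0.std(ddof=1),
                        }
                    )
                rows.append(_result_row(res, **extra))
    out = pd.DataFrame(rows)
    if add_bh and len(out):
        from statsmodels.stats.multitest import multipletests

        out["p_bh"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out


def correlate_fat_with_modes(
    mode_results: pd.DataFrame,
    coefficients: pd.DataFrame,
    morphometry: pd.DataFrame,
    subjects: pd.DataFrame,
) -> pd.DataFrame:
    """Partial Spearman of fat% against each identified (significant) mode.

    For every mode significant for any factor, fat% of the same muscle and
    level is correlated with the mode coefficient controlling sex, age and
    side_role.  An empty identified-mode set yields an empty table.
    """
    identified = (
        mode_results.loc[mode_results["significant"], ["level", "muscle", "mode"]]
        .drop_duplicates()
        .itertuples(index=False)
    )
    merged = coefficients.merge(
        morphometry[["subject_id", "level", "muscle", "side", "fat_pct"]],
        on=["subject_id", "level", "muscle", "side"],
        how="left",
    )
    if merged["fat_pct"].isna().any():
        raise KeyError("morphometry rows missing for some shape samples")
    df = _encode(merged, subjects)
    rows = []
    for level, muscle, mode in identified:
        grp = df[(df["level"] == level) & (df["muscle"] == muscle)]
        col = f"b{mode}"
        res = spearman_partial(
            grp[col],
            grp["fat_pct"],
            [grp["sex_f"], grp["age_c"], grp["affected"]],
            response=f"{level}-{muscle} fat_pct",
            factor=f"mode {mode}",
            covariate_names=("sex", "age", "side_role"),
        )
        rows.append(_result_row(res, level=level, muscle=muscle, mode=mode))
    cols = [
        "response",
        "factor",
        "covariates",
        "rho",
        "p_value",
        "n",
        "significant",
        "level",
        "muscle",
        "mode",
    ]
    return pd.DataFrame(rows, columns=cols)


def significant_modes_table(mode_results: pd.DataFrame) -> pd.DataFrame:
    """Pivot of significant modes: rows (level, muscle), one column per factor."""
    sig = mode_results[mode_results["significant"]]
    rows = []
    for (level, muscle), grp in mode_results.groupby(["level", "muscle"], sort=True):
        row = {"level": level, "muscle": muscle}
        for factor in ("side_role", "sex", "age"):
            hits = sig[
                (sig["level"] == level)
                & (sig["muscle"] == muscle)
                & (sig["factor"] == factor)
            ].sort_values("mode")
            row[factor] = (
                "; ".join(
                    f"Mode {int(r.mode)} (p={r.p_value:.3g})"
                    for r in hits.itertuples()
                )
                or "No significant modes"
            )
        rows.append(row)
    return pd.DataFrame(rows)
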