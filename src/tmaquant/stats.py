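"""Cohort-level statistics: concordance, summaries and associations.

The statistical surface mirrors standard TMA biomarker reporting: Pearson
correlation for inter-antibody concordance, per-entity/per-category
summary rows (n, percent, mean ± SD, median) and chi-square contingency
tests of a dichotomized analyte (density or CTLA-4/CD3 ratio) against
clinicopathological covariates, with missing data dropped per covariate.
All p values are two-sided; no multiplicity correction is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ZeroVarianceError",
    "PearsonResult",
    "AssociationResult",
    "pearson",
    "dichotomize_density",
    "chi_square",
    "entity_summary",
    "association_table",
    "density_stripplot",
]


class ZeroVarianceError(ValueError):
    """A correlation input vector is constant."""


@dataclass(frozen=True)
class PearsonResult:
    r: float
    p: float
    n: int


@dataclass(frozen=True)
class AssociationResult:
    """Chi-square association of one covariate with a dichotomized analyte."""

    covariate: str
    table: np.ndarray  # contingency counts, analyte level x covariate level
    statistic: float
    df: int
    p: float
    n: int


def pearson(x: Sequence[float], y: Sequence[float]) -> PearsonResult:
    """Product-moment correlation with a two-sided p from the t transform
    on n-2 degrees of freedom.

    Inputs must be equal-length (>= 3), finite, and non-constant; a
    constant vector raises :class:`ZeroVarianceError` naming the offender.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    for name, v in (("x", x), ("y", y)):
        if np.ptp(v) == 0:
            raise ZeroVarianceError(f"vector {name} is constant; r undefined")
    res = sps.pearsonr(x, y)
    return PearsonResult(r=float(res.statistic), p=float(res.pvalue), n=x.size)


def dichotomize_density(
    values: Sequence[float], rule: str | tuple[str, float] = "median-split"
) -> np.ndarray:
    """Binary high/low labels for a continuous analyte.

    ``rule`` is ``"median-split"`` (cutoff = median of the supplied,
    i.e. analyzed, values) or ``("fixed-cutoff", c)``.  A value is high
    iff it exceeds the cutoff — ties go low.  A median split over
    all-equal values raises, since both groups would be empty or one.
    """
    v = np.asarray(values, dtype=float)
    if isinstance(rule, tuple):
        kind, cutoff = rule
        if kind != "fixed-cutoff":
            raise ValueError(f"unknown rule {rule!r}")
        cutoff = float(cutoff)
    elif rule == "median-split":
        if v.size and np.ptp(v) == 0:
            raise ValueError("median split undefined: all values equal")
        cutoff = float(np.median(v))
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return v > cutoff


def chi_square(table) -> AssociationResult:
    """Pearson chi-square test of independence on a 2-D contingency table,
    without continuity correction.

    All expected counts must be positive (an all-zero row or column is an
    error); the p value is the two-sided tail of the chi-square
    distribution with (rows-1)(cols-1) degrees of freedom.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or min(obs.shape) < 2:
        raise ValueError("contingency table must be 2-D with >= 2 rows and columns")
    if (obs < 0).any():
        raise ValueError("counts must be >= 0")
    total = obs.sum()
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / total if total else obs * 0
    if (expected <= 0).any():
        raise ValueError("zero expected count: a row or column has no observations")
    stat, p, df, _ = sps.chi2_contingency(obs, correction=False)
    return AssociationResult(
        covariate="",
        table=obs.astype(int),
        statistic=float(stat),
        df=int(df),
        p=float(p),
        n=int(total),
    )


def entity_summary(
    patient_table: pd.DataFrame,
    group_col: str = "entity",
    density_col: str = "merged_density",
    ratio_col: str = "ratio",
) -> pd.DataFrame:
    """Summary rows per group: n, percent of cohort, mean ± SD and median
    density, mean ± SD ratio; groups ordered by descending mean density.

    SDs use the n-1 denominator and are missing for n = 1; the percent
    column is recomputable from n and the analyzed cohort total.
    """
    from .quantify import percent

    df = patient_table.dropna(subset=[density_col])
    total = len(df)
    rows = []
    for group, g in df.groupby(group_col, sort=True):
        dens = g[density_col].to_numpy(dtype=float)
        ratio = g[ratio_col].dropna().to_numpy(dtype=float)
        rows.append(
            {
                group_col: group,
                "n": len(g),
                "percent": percent(len(g), total) if total else 0.0,
                "mean_density": float(dens.mean()) if dens.size else np.nan,
                "sd_density": float(dens.std(ddof=1)) if dens.size > 1 else np.nan,
                "median_density": float(np.median(dens)) if dens.size else np.nan,
                "mean_ratio": float(ratio.mean()) if ratio.size else np.nan,
                "sd_ratio": float(ratio.std(ddof=1)) if ratio.size > 1 else np.nan,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out = out.sort_values("mean_density", ascending=False, kind="stable")
    return out.reset_index(drop=True)


DEFAULT_COVARIATES = ("pT", "pN", "pdl1_tumor", "pdl1_immune", "hpv")


def association_table(
    patient_table: pd.DataFrame,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    analyte: str = "merged_density",
    rule: str | tuple[str, float] = "median-split",
) -> list[AssociationResult]:
    """Chi-square associations of the dichotomized analyte with each
    covariate.

    Patients missing the covariate or the analyte are dropped from that
    covariate's table only; the analyte median is recomputed on each
    analysis subset.  Covariates left with a single level (or a single
    analyte level) are skipped with a warning.
    """
    results = []
    for cov in covariates:
        if cov not in patient_table.columns:
            warnings.warn(f"covariate {cov!r} absent from table; skipped", stacklevel=2)
            continue
        sub = patient_table.dropna(subset=[cov, analyte])
        if len(sub) == 0:
            warnings.warn(f"covariate {cov!r} missing for all patients; skipped", stacklevel=2)
            continue
        values = sub[analyte].to_numpy(dtype=float)
        try:
            high = dichotomize_density(values, rule)
        except ValueError as exc:
            warnings.warn(f"covariate {cov!r}: {exc}; skipped", stacklevel=2)
            continue
        levels = sub[cov]
        ct = pd.crosstab(high, levels)
        if ct.shape[0] < 2 or ct.shape[1] < 2:
            warnings.warn(
                f"covariate {cov!r} has a single level after dropping missing; skipped",
                stacklevel=2,
            )
            continue
        res = chi_square(ct.to_numpy())
        results.append(
            AssociationResult(
                covariate=cov,
                table=res.table,
                statistic=res.statistic,
                df=res.df,
                p=res.p,
                n=res.n,
            )
        )
    return results


def association_frame(results: Sequence[AssociationResult]) -> pd.DataFrame:
    """Flatten association results for CSV export."""
    return pd.DataFrame(
        {
            "covariate": [r.covariate for r in results],
            "chi_square": [r.statistic for r in results],
            "df": [r.df for r in results],
            "p": [r.p for r in results],
            "n": [r.n for r in results],
        }
    )


def density_stripplot(
    patient_table: pd.DataFrame,
    path,
    group_col: str = "entity",
    density_col: str = "merged_density",
    seed: int = 0,
) -> None:
    """Per-entity density strip plot (one dot per patient, bar at the
    group mean), written as PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = patient_table.dropna(subset=[density_col])
    order = (
        df.groupby(group_col)[density_col].mean().sort_values(ascending=False).index
    )
    rng = np.random.default_rng(seed)
    fig, ax = plt.subplots(figsize=(max(6, 0.6 * len(order)), 4.5))
    for i, group in enumerate(order):
        vals = df.loc[df[group_col] == group, density_col].to_numpy(dtype=float)
        xs = i + rng.uniform(-0.18, 0.18, size=vals.size)
        ax.plot(xs, vals, "o", ms=2.5, color="0.5", alpha=0.7)
        ax.hlines(vals.mean(), i - 0.3, i + 0.3, color="k", lw=2)
    ax.set_xticks(range(len(order)))
    ax.set_xticklabels(order, rotation=60, ha="right", fontsize=7)
    ax.set_ylabel("CTLA-4+ cell density (cells/mm²)")
    ax.set_yscale("symlog", linthresh=10)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
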