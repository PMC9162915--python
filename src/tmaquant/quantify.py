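"""Densities, dual-antibody merging, CTLA-4/CD3 ratio and exclusion accounting.

The merge rule follows the dual-antibody design: for each patient the two
clone densities are averaged; if one clone's spot was excluded for
non-specific staining, only the clean clone's density is used; if both
were excluded the patient is not analyzed.  The CTLA-4/CD3 ratio is
expressed as a percentage (100 x CTLA-4 density / CD3 density).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "density",
    "merge_patient",
    "ctla4_cd3_ratio",
    "percent",
    "CloneExclusion",
    "ExclusionReport",
    "exclusion_accounting",
    "build_patient_table",
]


def _is_missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


def percent(count: int | float, total: int | float, decimals: int = 1) -> float:
    """100 * count / total, rounded half away from zero to ``decimals``.

    A zero total reports 0.0 with a warning rather than failing, so that
    accounting over an empty stratum stays well-defined.
    """
    if total == 0:
        warnings.warn("percent of zero total reported as 0.0", stacklevel=2)
        return 0.0
    raw = 100.0 * count / total
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(raw)).quantize(q, rounding=ROUND_HALF_UP))


def density(positive_count: int, area_mm2: float) -> float | None:
    """Positive-cell density in cells/mm²; ``None`` (missing) when the
    tissue area is not positive."""
    if positive_count < 0:
        raise ValueError("positive_count must be >= 0")
    if area_mm2 is None or _is_missing(area_mm2) or area_mm2 <= 0:
        warnings.warn("non-positive tissue area: density undefined", stacklevel=2)
        return None
    return positive_count / area_mm2


def merge_patient(
    density_a: float | None,
    density_b: float | None,
    excluded_a: bool,
    excluded_b: bool,
) -> float | None:
    """Merge the two clone densities for one patient.

    Both valid -> arithmetic mean; exactly one valid (the other excluded
    or missing) -> that value; neither -> missing (``None``), the patient
    is not analyzed.
    """
    a_ok = not excluded_a and not _is_missing(density_a)
    b_ok = not excluded_b and not _is_missing(density_b)
    if a_ok and b_ok:
        return 0.5 * (density_a + density_b)  # type: ignore[operator]
    if a_ok:
        return float(density_a)  # type: ignore[arg-type]
    if b_ok:
        return float(density_b)  # type: ignore[arg-type]
    return None


def ctla4_cd3_ratio(
    merged_density: float | None, cd3_density: float | None
) -> float | None:
    """CTLA-4/CD3 ratio as a percentage: 100 * merged / CD3.

    Missing when either density is missing or the CD3 density is zero
    (division guard).  Negative inputs are an error.
    """
    if _is_missing(merged_density) or _is_missing(cd3_density):
        return None
    if merged_density < 0 or cd3_density < 0:  # type: ignore[operator]
        raise ValueError("densities must be >= 0")
    if cd3_density == 0:
        return None
    return 100.0 * merged_density / cd3_density  # type: ignore[operator]


@dataclass(frozen=True)
class CloneExclusion:
    """Per-antibody exclusion tally."""

    clone_name: str
    stained_total: int
    excluded_count: int

    @property
    def excluded_percent(self) -> float:
        return percent(self.excluded_count, self.stained_total)


@dataclass(frozen=True)
class ExclusionReport:
    """Cohort-level exclusion accounting across both antibodies."""

    per_clone: tuple[CloneExclusion, ...]
    analyzed_patients: int = 0

    @property
    def total_stained(self) -> int:
        return sum(c.stained_total for c in self.per_clone)

    @property
    def total_excluded(self) -> int:
        return sum(c.excluded_count for c in self.per_clone)

    @property
    def combined_percent(self) -> float:
        return percent(self.total_excluded, self.total_stained)

    def to_dict(self) -> dict:
        return {
            "per_clone": {
                c.clone_name: {
                    "stained_total": c.stained_total,
                    "excluded_count": c.excluded_count,
                    "excluded_percent": c.excluded_percent,
                }
                for c in self.per_clone
            },
            "total_stained": self.total_stained,
            "total_excluded": self.total_excluded,
            "combined_percent": self.combined_percent,
            "analyzed_patients": self.analyzed_patients,
        }


def exclusion_accounting(
    per_clone: Mapping[str, tuple[int, int]] | Sequence[CloneExclusion],
    analyzed_patients: int = 0,
) -> ExclusionReport:
    """Build the exclusion report from per-clone (stained_total,
    excluded_count) tallies.

    Percentages are 100*excluded/total rounded half away from zero to one
    decimal; the combined percentage is recomputed from the summed counts.
    """
    if isinstance(per_clone, Mapping):
        clones = tuple(
            CloneExclusion(clone_name=k, stained_total=t, excluded_count=e)
            for k, (t, e) in per_clone.items()
        )
    else:
        clones = tuple(per_clone)
    for c in clones:
        if not 0 <= c.excluded_count <= c.stained_total:
            raise ValueError(
                f"invalid tally for {c.clone_name!r}: "
                f"{c.excluded_count} excluded of {c.stained_total}"
            )
    return ExclusionReport(per_clone=clones, analyzed_patients=analyzed_patients)


def build_patient_table(
    spot_measurements: pd.DataFrame,
    patients: pd.DataFrame,
    clone_names: tuple[str, str],
) -> pd.DataFrame:
    """Assemble the per-patient analysis table.

    ``spot_measurements`` has one row per (spot_id, clone) with columns
    ``density``, ``nonspecific_fraction`` and ``excluded``; ``patients``
    carries entity, covariates and the CD3 density (spot_id == patient_id,
    one spot pair per patient).  Adds ``merged_density`` (dual-antibody
    merge rule) and ``ratio`` (CTLA-4/CD3, percent).
    """
    a, b = clone_names
    wide = spot_measurements.pivot(index="spot_id", columns="clone")
    out = patients.set_index("patient_id").copy()
    for clone, suffix in ((a, "a"), (b, "b")):
        for col, new in (
            ("density", f"density_{suffix}"),
            ("nonspecific_fraction", f"nonspecific_fraction_{suffix}"),
            ("excluded", f"excluded_{suffix}"),
        ):
            if (col, clone) in wide.columns:
                out[new] = wide[(col, clone)]
            else:
                out[new] = np.nan
    out["excluded_a"] = out["excluded_a"].fillna(True).astype(bool)
    out["excluded_b"] = out["excluded_b"].fillna(True).astype(bool)
    out["merged_density"] = [
        merge_patient(da, db, ea, eb)
        for da, db, ea, eb in zip(
            out["density_a"], out["density_b"], out["excluded_a"], out["excluded_b"]
        )
    ]
    out["ratio"] = [
        ctla4_cd3_ratio(m, c) for m, c in zip(out["merged_density"], out["cd3_density"])
    ]
    return out.reset_index()
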