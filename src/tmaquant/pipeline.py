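"""End-to-end orchestration of the dual-antibody quantification workflow.

``run_cohort`` streams a synthetic cohort patient by patient (images are
rendered, measured and discarded, so memory stays flat), then trains and
applies the artifact classifier, applies the exclusion rule, merges the
two antibodies per patient and produces the statistical reports.

``run_truth_cohort`` runs the same statistical surface directly on the
latent ground-truth densities (no imaging) — useful for large
statistics-only simulations such as type-I-error studies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import artifacts, quantify, stats
from .config import PipelineConfig
from .segmentation import spot_cell_table
from .synthetic import COVARIATES, iter_cohort, patient_truth_frame

__all__ = ["PipelineResult", "run_cohort", "run_truth_cohort"]


@dataclass
class PipelineResult:
    """All artifacts of one cohort run."""

    config: PipelineConfig
    patient_table: pd.DataFrame
    spot_table: pd.DataFrame  # one row per (patient, clone)
    region_table: pd.DataFrame  # one row per stained region
    cell_tables: pd.DataFrame  # concatenated per-spot cell tables
    classifier: artifacts.ArtifactClassifier | None
    validation_auc: float | None
    exclusion_report: quantify.ExclusionReport
    concordance: dict[str, float]
    summary_entity: pd.DataFrame
    summary_category: pd.DataFrame
    associations_density: list[stats.AssociationResult]
    associations_ratio: list[stats.AssociationResult]


def _segment_cohort(config: PipelineConfig):
    """First pass: render + segment every spot, collecting cell, spot and
    region tables plus ground-truth region labels."""
    cohort = config.cohort
    spot_rows = []
    region_rows = []
    cell_frames = []
    truths = []
    for record in iter_cohort(cohort):
        truths.append(record.truth)
        for image, gt in zip(record.images, record.ground_truths):
            cells, area = spot_cell_table(image, config.segmentation)
            labels, feats = artifacts.extract_regions(
                image, cells, config.segmentation
            )
            truth_flags = artifacts.label_regions_with_truth(
                labels, feats, gt.nonspecific_region_mask
            )
            for f, flag in zip(feats, truth_flags):
                region_rows.append(
                    {
                        "patient_id": record.truth.patient_id,
                        "spot_id": image.spot_id,
                        "clone": image.clone_name,
                        "entity": record.truth.entity,
                        "region_id": f.region_id,
                        "area_um2": f.area_um2,
                        "circularity": f.circularity,
                        "mean_membrane_score": f.mean_membrane_score,
                        "stained_fraction": f.stained_fraction,
                        "cell_count": f.cell_count,
                        "truth_nonspecific": flag,
                    }
                )
            spot_rows.append(
                {
                    "patient_id": record.truth.patient_id,
                    "spot_id": image.spot_id,
                    "clone": image.clone_name,
                    "entity": record.truth.entity,
                    "area_mm2": area,
                    "total_count": int(len(cells)),
                    "positive_count": int(cells["positive"].sum()),
                    "true_density": gt.true_density,
                    "true_nonspecific_fraction": gt.true_nonspecific_fraction,
                }
            )
            cell_frames.append(cells)
    spot_table = pd.DataFrame(spot_rows)
    region_table = pd.DataFrame(region_rows)
    cell_tables = (
        pd.concat(cell_frames, ignore_index=True) if cell_frames else pd.DataFrame()
    )
    return truths, spot_table, region_table, cell_tables


def _spot_fractions(
    config: PipelineConfig,
    spot_table: pd.DataFrame,
    region_table: pd.DataFrame,
    cell_tables: pd.DataFrame,
    qc: str,
) -> tuple[pd.DataFrame, artifacts.ArtifactClassifier | None, float | None]:
    """Compute the per-spot non-specific fraction under the chosen QC mode
    and flag exclusions."""
    classifier = None
    auc = None
    frac_col = np.zeros(len(spot_table))
    if qc == "none" or region_table.empty:
        pass
    elif qc == "truth":
        frac_col = spot_table["true_nonspecific_fraction"].to_numpy(dtype=float)
    elif qc == "classifier":
        classifier = artifacts.train_artifact_classifier(
            region_table,
            train_fraction=config.train_fraction,
            seed=config.split_seed,
        )
        scores = classifier.score(artifacts.region_feature_matrix(region_table))
        predicted = scores > classifier.threshold
        region_table = region_table.assign(score=scores, predicted_nonspecific=predicted)
        val = region_table[
            region_table["patient_id"].isin(classifier.validation_patients)
        ]
        if val["truth_nonspecific"].nunique() == 2:
            auc = artifacts.auc_score(
                val["score"].to_numpy(), val["truth_nonspecific"].to_numpy(bool)
            )
        else:
            warnings.warn("validation split lacks a class; AUC not computed")
        bad_by_spot = {
            key: set(grp.loc[grp["predicted_nonspecific"], "region_id"])
            for key, grp in region_table.groupby(["spot_id", "clone"], sort=False)
        }
        cells_by_spot = dict(iter(cell_tables.groupby(["spot_id", "clone"], sort=False)))
        fracs = []
        for _, row in spot_table.iterrows():
            key = (row["spot_id"], row["clone"])
            sub = cells_by_spot.get(key)
            if sub is None or sub.empty:
                fracs.append(0.0)
                continue
            fracs.append(
                artifacts.nonspecific_fraction(
                    sub,
                    bad_by_spot.get(key, set()),
                    denominator=config.fraction_denominator,
                )
            )
        frac_col = np.array(fracs)
    else:
        raise ValueError(f"unknown qc mode {qc!r}")

    spot_table = spot_table.assign(nonspecific_fraction=frac_col)
    spot_table["excluded"] = (
        spot_table["nonspecific_fraction"] >= config.exclusion_threshold
    )
    spot_table["density"] = np.where(
        spot_table["area_mm2"] > 0,
        spot_table["positive_count"] / spot_table["area_mm2"].replace(0, np.nan),
        np.nan,
    )
    return spot_table, classifier, auc


def _concordance(patient_table: pd.DataFrame) -> dict[str, float]:
    """Inter-clone Pearson concordance before and after exclusion."""
    out: dict[str, float] = {}
    both = patient_table.dropna(subset=["density_a", "density_b"])
    if len(both) >= 3:
        try:
            res = stats.pearson(both["density_a"], both["density_b"])
            out["pre_r"], out["pre_p"], out["pre_n"] = res.r, res.p, res.n
        except ValueError:
            pass
    kept = both[~both["excluded_a"] & ~both["excluded_b"]]
    if len(kept) >= 3:
        try:
            res = stats.pearson(kept["density_a"], kept["density_b"])
            out["post_r"], out["post_p"], out["post_n"] = res.r, res.p, res.n
        except ValueError:
            pass
    return out


def run_cohort(config: PipelineConfig, qc: str = "classifier") -> PipelineResult:
    """Run the full pipeline on a synthetic cohort.

    ``qc`` selects how the per-spot non-specific fraction is obtained:
    ``"classifier"`` (train/apply the artifact classifier on a stratified
    75/25 patient split), ``"truth"`` (generator ground truth — an oracle
    for recovery tests) or ``"none"`` (no artifact QC).
    """
    config.validate()
    truths, spot_table, region_table, cell_tables = _segment_cohort(config)
    spot_table, classifier, auc = _spot_fractions(
        config, spot_table, region_table, cell_tables, qc
    )

    patients = patient_truth_frame(truths, config.cohort.clone_names)
    patient_table = quantify.build_patient_table(
        spot_table[
            ["spot_id", "clone", "density", "nonspecific_fraction", "excluded"]
        ],
        patients,
        config.cohort.clone_names,
    )

    per_clone = {}
    for clone in config.cohort.clone_names:
        sub = spot_table[spot_table["clone"] == clone]
        per_clone[clone] = (int(len(sub)), int(sub["excluded"].sum()))
    report = quantify.exclusion_accounting(
        per_clone,
        analyzed_patients=int(patient_table["merged_density"].notna().sum()),
    )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        summary_entity = stats.entity_summary(patient_table, "entity")
        summary_category = stats.entity_summary(patient_table, "category")
        assoc_density = stats.association_table(
            patient_table, COVARIATES, analyte="merged_density"
        )
        assoc_ratio = stats.association_table(
            patient_table, COVARIATES, analyte="ratio"
        )

    return PipelineResult(
        config=config,
        patient_table=patient_table,
        spot_table=spot_table,
        region_table=region_table,
        cell_tables=cell_tables,
        classifier=classifier,
        validation_auc=auc,
        exclusion_report=report,
        concordance=_concordance(patient_table),
        summary_entity=summary_entity,
        summary_category=summary_category,
        associations_density=assoc_density,
        associations_ratio=assoc_ratio,
    )


def run_truth_cohort(config: PipelineConfig) -> pd.DataFrame:
    """Statistics-only cohort: the patient table built directly from the
    latent truth (merged density = true density, no imaging or QC)."""
    from .synthetic import cohort_truths

    config.validate()
    truths = cohort_truths(config.cohort)
    patients = patient_truth_frame(truths, config.cohort.clone_names)
    patients["merged_density"] = patients["true_ctla4_density"]
    patients["ratio"] = [
        quantify.ctla4_cd3_ratio(m, c)
        for m, c in zip(patients["merged_density"], patients["cd3_density"])
    ]
    return patients
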