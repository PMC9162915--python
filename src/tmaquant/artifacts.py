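"""Detection and exclusion of non-specific (cross-reactive) staining.

Stained regions are extracted per spot, described by five shape/texture
features that contrast specific lymphocytic ring staining with diffuse
cross-reactive staining, and scored by a linear classifier trained on a
per-entity stratified 75/25 patient split.  The spot-level fraction of
cells in regions called non-specific drives the exclusion rule: a spot
with >= 5% non-specifically stained cells is dropped for that antibody.

The held-out classifier performance is reported as the ROC AUC, computed
as the exact probability that a random non-specific region outscores a
random specific region (ties count one half).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import gaussian
from skimage.measure import perimeter_crofton, regionprops
from .segmentation import SpotImage, _resolve_tau, binary_closing_fast

from .config import SegmentationParams

__all__ = [
    "RegionFeatures",
    "ArtifactClassifier",
    "SpotMeasurement",
    "extract_regions",
    "label_regions_with_truth",
    "region_feature_matrix",
    "train_artifact_classifier",
    "evaluate_auc",
    "auc_score",
    "permutation_null_auc",
    "nonspecific_fraction",
    "apply_exclusion",
    "discordance_score",
    "FEATURE_COLUMNS",
]

FEATURE_COLUMNS = (
    "log_area",
    "circularity",
    "mean_membrane_score",
    "stained_fraction",
    "log_cell_count",
)


@dataclass
class RegionFeatures:
    """Shape/texture summary of one stained region."""

    region_id: int
    area_um2: float
    circularity: float  # 4*pi*A/P^2, clipped to (0, 1]
    mean_membrane_score: float  # mean over member positive cells (0 if none)
    stained_fraction: float  # raw stained pixels / filled region pixels
    cell_count: int  # member positive cells


@dataclass
class SpotMeasurement:
    """Per-spot, per-antibody quantification summary."""

    spot_id: str
    clone_name: str
    positive_count: int
    total_count: int
    area_mm2: float
    density: float | None  # positive cells / mm², None when area is 0
    nonspecific_fraction: float
    excluded: bool = False


def extract_regions(
    image: SpotImage,
    cell_table: pd.DataFrame,
    params: SegmentationParams,
) -> tuple[np.ndarray, list[RegionFeatures]]:
    """Extract stained regions and their features; assign cells to regions.

    Regions are connected components of the (lightly smoothed) stain
    channel above the region threshold, after morphological closing and
    hole filling, so that a membranous ring becomes a filled disc.  Every
    cell whose centroid falls inside a retained region gets that region's
    id written into ``cell_table["region_id"]`` (at most one region per
    cell); the stained-area fraction distinguishes hollow ring staining
    from diffuse fills.

    Returns the region label raster and the feature list.
    """
    mpp = image.microns_per_pixel
    tau = _resolve_tau(params)
    thr = params.region_threshold if params.region_threshold is not None else 0.5 * tau
    smoothed = gaussian(image.stain_channel.astype(np.float64), sigma=1.0 / mpp)
    raw = smoothed > thr
    if raw.any():
        closed = binary_closing_fast(raw, max(1, int(round(2.0 / mpp))))
        filled = ndi.binary_fill_holes(closed)
    else:
        filled = raw
    labels, _ = ndi.label(filled)

    min_px = params.min_region_area_um2 / mpp**2
    features: list[RegionFeatures] = []
    cell_rows = cell_table["y_px"].to_numpy(dtype=float)
    cell_cols = cell_table["x_px"].to_numpy(dtype=float)
    ri = np.clip(np.round(cell_rows).astype(int), 0, image.shape[0] - 1)
    ci = np.clip(np.round(cell_cols).astype(int), 0, image.shape[1] - 1)
    cell_region = labels[ri, ci] if len(cell_table) else np.zeros(0, dtype=int)
    positive = (
        cell_table["positive"].to_numpy(dtype=bool)
        if len(cell_table)
        else np.zeros(0, dtype=bool)
    )
    membrane = (
        cell_table["membrane_score"].to_numpy(dtype=float)
        if len(cell_table)
        else np.zeros(0)
    )

    kept_ids = []
    for prop in regionprops(labels):
        if prop.area < min_px:
            continue
        rid = int(prop.label)
        kept_ids.append(rid)
        sub = labels[prop.slice] == rid
        perim = perimeter_crofton(sub, directions=4) or 1.0
        circ = min(1.0, 4.0 * np.pi * prop.area / perim**2)
        stained = float((raw[prop.slice] & sub).sum()) / float(prop.area)
        members = (cell_region == rid) & positive
        n_members = int(members.sum())
        mean_mem = float(membrane[members].mean()) if n_members else 0.0
        features.append(
            RegionFeatures(
                region_id=rid,
                area_um2=float(prop.area) * mpp**2,
                circularity=float(circ),
                mean_membrane_score=mean_mem,
                stained_fraction=min(1.0, stained),
                cell_count=n_members,
            )
        )
    if len(cell_table):
        kept = np.isin(cell_region, kept_ids)
        assigned = np.where(kept, cell_region, 0)
        cell_table["region_id"] = pd.array(
            [int(a) if a > 0 else None for a in assigned], dtype="Int64"
        )
    return labels, features


def label_regions_with_truth(
    region_labels: np.ndarray,
    features: Sequence[RegionFeatures],
    nonspecific_mask: np.ndarray,
    overlap: float = 0.5,
) -> list[bool]:
    """Ground-truth label per region: non-specific iff at least ``overlap``
    of its pixels lie inside the generator's non-specific territory."""
    n_labels = int(region_labels.max())
    if n_labels == 0:
        return [False for _ in features]
    flat = region_labels.ravel()
    sizes = np.bincount(flat, minlength=n_labels + 1)
    inside = np.bincount(
        flat, weights=nonspecific_mask.ravel().astype(float), minlength=n_labels + 1
    )
    frac = inside / np.maximum(sizes, 1)
    return [
        bool(sizes[f.region_id] > 0 and frac[f.region_id] >= overlap)
        for f in features
    ]


def region_feature_matrix(regions: pd.DataFrame) -> np.ndarray:
    """Assemble the (n, 5) classifier feature matrix from a region table."""
    return np.column_stack(
        [
            np.log10(np.maximum(regions["area_um2"].to_numpy(dtype=float), 1.0)),
            regions["circularity"].to_numpy(dtype=float),
            regions["mean_membrane_score"].to_numpy(dtype=float),
            regions["stained_fraction"].to_numpy(dtype=float),
            np.log10(regions["cell_count"].to_numpy(dtype=float) + 1.0),
        ]
    )


@dataclass
class ArtifactClassifier:
    """Linear scorer for stained regions (specific vs non-specific).

    ``score`` is the logit of the non-specific class; the decision
    threshold is a logit of 0 (probability one half).  Training metadata
    (split seed, train fraction and split membership) are retained so the
    held-out evaluation is reproducible.
    """

    weights: np.ndarray
    intercept: float
    feature_means: np.ndarray
    feature_scales: np.ndarray
    threshold: float = 0.0
    split_seed: int = 0
    train_fraction: float = 0.75
    train_patients: tuple[str, ...] = ()
    validation_patients: tuple[str, ...] = ()

    def score(self, X: np.ndarray) -> np.ndarray:
        Z = (np.asarray(X, dtype=float) - self.feature_means) / self.feature_scales
        return Z @ self.weights + self.intercept

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.score(X) > self.threshold

    def to_json(self) -> str:
        return json.dumps(
            {
                "weights": self.weights.tolist(),
                "intercept": self.intercept,
                "feature_means": self.feature_means.tolist(),
                "feature_scales": self.feature_scales.tolist(),
                "threshold": self.threshold,
                "split_seed": self.split_seed,
                "train_fraction": self.train_fraction,
                "train_patients": list(self.train_patients),
                "validation_patients": list(self.validation_patients),
                "features": list(FEATURE_COLUMNS),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, payload: str) -> "ArtifactClassifier":
        d = json.loads(payload)
        return cls(
            weights=np.asarray(d["weights"], dtype=float),
            intercept=float(d["intercept"]),
            feature_means=np.asarray(d["feature_means"], dtype=float),
            feature_scales=np.asarray(d["feature_scales"], dtype=float),
            threshold=float(d["threshold"]),
            split_seed=int(d["split_seed"]),
            train_fraction=float(d["train_fraction"]),
            train_patients=tuple(d["train_patients"]),
            validation_patients=tuple(d["validation_patients"]),
        )


def stratified_patient_split(
    patients: pd.DataFrame,
    train_fraction: float,
    seed: int,
) -> tuple[list[str], list[str]]:
    """Split patients into train/validation per entity.

    ``patients`` needs columns ``patient_id`` and ``entity``.  Within each
    entity the patient list is shuffled with the given seed and the first
    ``round_half_up(n * train_fraction)`` go to training — stratification
    keeps the training input balanced across entities.
    """
    rng = np.random.default_rng(seed)
    train: list[str] = []
    val: list[str] = []
    for entity, group in patients.sort_values("patient_id").groupby("entity", sort=True):
        ids = group["patient_id"].unique().tolist()
        order = rng.permutation(len(ids))
        n_train = int(np.floor(len(ids) * train_fraction + 0.5))
        for k, idx in enumerate(order):
            (train if k < n_train else val).append(ids[idx])
    return sorted(train), sorted(val)


def train_artifact_classifier(
    regions: pd.DataFrame,
    train_fraction: float = 0.75,
    seed: int = 0,
) -> ArtifactClassifier:
    """Fit the linear artifact scorer on a stratified patient split.

    ``regions`` needs ``patient_id``, ``entity``, the feature columns of
    :func:`region_feature_matrix`'s input and a boolean ``truth_nonspecific``
    label per region.  Raises ``ValueError`` naming the missing class if
    the training split contains only one class.
    """
    from sklearn.linear_model import LogisticRegression

    train_ids, val_ids = stratified_patient_split(
        regions[["patient_id", "entity"]].drop_duplicates(), train_fraction, seed
    )
    train_df = regions[regions["patient_id"].isin(train_ids)]
    y = train_df["truth_nonspecific"].to_numpy(dtype=bool)
    if y.all() or not y.any():
        missing = "specific" if y.all() else "non-specific"
        raise ValueError(
            f"training split contains no {missing} regions; cannot fit classifier"
        )
    X = region_feature_matrix(train_df)
    means = X.mean(axis=0)
    scales = X.std(axis=0)
    scales[scales == 0] = 1.0
    Z = (X - means) / scales
    model = LogisticRegression(C=1.0, max_iter=2000)
    model.fit(Z, y.astype(int))
    return ArtifactClassifier(
        weights=model.coef_[0].astype(float),
        intercept=float(model.intercept_[0]),
        feature_means=means,
        feature_scales=scales,
        split_seed=seed,
        train_fraction=train_fraction,
        train_patients=tuple(train_ids),
        validation_patients=tuple(val_ids),
    )


def auc_score(scores: np.ndarray, labels: np.ndarray) -> float:
    """Exact ROC AUC by exhaustive pairwise comparison.

    AUC = P(score of a random positive > score of a random negative), with
    ties credited one half — the Mann-Whitney U normalisation.  Raises
    ``ValueError`` when either class is absent.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos = scores[labels]
    neg = scores[~labels]
    if pos.size == 0 or neg.size == 0:
        missing = "positive" if pos.size == 0 else "negative"
        raise ValueError(f"AUC undefined: no {missing} instances in evaluation set")
    diff = pos[:, None] - neg[None, :]
    return float((np.count_nonzero(diff > 0) + 0.5 * np.count_nonzero(diff == 0)) / diff.size)


def evaluate_auc(
    classifier: ArtifactClassifier, regions: pd.DataFrame
) -> float:
    """Held-out AUC of the classifier on a validation region table."""
    X = region_feature_matrix(regions)
    return auc_score(classifier.score(X), regions["truth_nonspecific"].to_numpy(dtype=bool))


def permutation_null_auc(
    scores: np.ndarray,
    labels: np.ndarray,
    n_permutations: int = 200,
    seed: int = 0,
) -> np.ndarray:
    """AUCs after randomly permuting the labels (null distribution)."""
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels, dtype=bool)
    return np.array(
        [auc_score(scores, rng.permutation(labels)) for _ in range(n_permutations)]
    )


def nonspecific_fraction(
    cell_table: pd.DataFrame,
    nonspecific_regions: Mapping[int, bool] | set,
    denominator: str = "all_cells",
) -> float:
    """Fraction of cells lying in regions classified non-specific.

    ``nonspecific_regions`` maps region id -> bool (or is a set of
    non-specific region ids); cells without a region count as specific.
    With ``denominator="all_cells"`` the fraction is relative to every
    detected cell; ``"stained_cells"`` restricts the denominator to
    CTLA-4 positive cells.  Returns 0.0 when there are no cells.
    """
    if isinstance(nonspecific_regions, set):
        bad = nonspecific_regions
    else:
        bad = {rid for rid, flag in nonspecific_regions.items() if flag}
    if len(cell_table) == 0:
        return 0.0
    region = cell_table["region_id"]
    in_bad = region.map(lambda r: (r in bad) if pd.notna(r) else False).to_numpy(bool)
    if denominator == "stained_cells":
        sel = cell_table["positive"].to_numpy(bool)
        if not sel.any():
            return 0.0
        return float(in_bad[sel].sum() / sel.sum())
    return float(in_bad.sum() / len(cell_table))


def apply_exclusion(
    measurement: SpotMeasurement, threshold: float = 0.05
) -> SpotMeasurement:
    """Apply the exclusion rule: excluded iff the non-specific cell
    fraction is at or above the threshold (closed lower bound, i.e. a spot
    at exactly the threshold is excluded)."""
    return replace(
        measurement, excluded=measurement.nonspecific_fraction >= threshold
    )


def discordance_score(density_a: float, density_b: float) -> float:
    """Relative inter-clone density discordance |a-b| / (a+b) in [0, 1].

    0 when both densities agree (including both zero), 1 when one clone
    sees cells and the other none.  Used only to flag candidate spots for
    artifact review, never to exclude directly.
    """
    if density_a < 0 or density_b < 0:
        raise ValueError("densities must be >= 0")
    if density_a == 0 and density_b == 0:
        return 0.0
    return abs(density_a - density_b) / (density_a + density_b)
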