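"""Seeded synthetic TMA cohort generator.

Generates paired spot images for two virtual antibody clones stained on
consecutive sections of the same core, together with complete ground
truth.  The generator emulates the statistical structure the downstream
analysis assumes:

* circular 0.6 mm tissue spots on an otherwise empty canvas;
* per-patient CTLA-4+ and CD3+ densities drawn from a bivariate
  log-normal (right-skewed, correlated on the log scale);
* clinicopathological covariates (pT, pN, PD-L1, HPV) planted through a
  logistic link on the standardised log density;
* consecutive-section pairing: both clones share one latent cell field,
  with small positional jitter and random per-section cell dropout;
* clone-specific cross-reactive staining: in affected entities a
  contiguous tissue territory stains diffusely for one clone only, and
  every cell inside it counts as non-specifically stained for that clone.

Specific CTLA-4+ lymphocytes are rendered as ring-shaped (membranous)
stain around a small nucleus; cross-reactive staining is rendered as the
configured pattern (diffuse cytoplasmic fill by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .config import AntibodyProfile, CohortConfig, ConfigError, EntitySpec
from .segmentation import SpotImage

__all__ = [
    "PatientTruth",
    "GroundTruth",
    "sample_patient_truth",
    "render_spot_pair",
    "iter_cohort",
    "patient_truth_frame",
]

#: mean radius of the specific membranous ring stain, µm
RING_RADIUS_UM = 5.5
#: half width of the ring band, µm
RING_HALF_WIDTH_UM = 0.75
#: Gaussian sigma of the nuclear stamp, µm
NUCLEUS_SIGMA_UM = 2.0
#: nuclear stamp peak amplitude, OD units
NUCLEUS_AMPLITUDE = 1.0

COVARIATES = ("pT", "pN", "pdl1_tumor", "pdl1_immune", "hpv")

#: baseline prevalences of the covariates at entity-average density
_BASELINE_PT_CUM = (0.30, 0.60, 0.88)  # P(pT<=1), P(pT<=2), P(pT<=3)
_BASELINE_P = {"pN": 0.55, "pdl1_tumor": 0.20, "pdl1_immune": 0.40, "hpv": 0.43}

#: concentration of the Beta draw for the per-patient cross-reactive
#: tissue fraction (mean comes from the entity spec)
_CROSS_FRACTION_CONCENTRATION = 30.0


@dataclass
class PatientTruth:
    """Latent per-patient ground truth."""

    patient_id: str
    entity: str
    category: str
    ctla4_density: float  # cells/mm², latent (drives cell placement)
    cd3_density: float  # cells/mm², reported as an input column
    z: float  # standardised log CTLA-4 density (drives covariates)
    covariates: dict[str, object]
    crossreactive_fraction: dict[str, float]  # clone -> tissue fraction


@dataclass
class GroundTruth:
    """Per-spot, per-clone ground truth for one rendered section."""

    cell_centroids: np.ndarray  # (n, 2) float, (row, col) px
    cell_class: np.ndarray  # (n,) str: ctla4_lymphocyte | other_cell | crossreactive_cell
    nonspecific_region_mask: np.ndarray  # bool raster
    tissue_mask: np.ndarray  # bool raster
    true_density: float  # ctla4_lymphocyte count / tissue area, cells/mm²
    true_nonspecific_fraction: float  # crossreactive count / total count

    @property
    def counts(self) -> dict[str, int]:
        vals, cnt = np.unique(self.cell_class, return_counts=True)
        out = {"ctla4_lymphocyte": 0, "other_cell": 0, "crossreactive_cell": 0}
        out.update(dict(zip(vals.tolist(), cnt.tolist())))
        return out


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Moment-matched (mu, sigma) of a log-normal with given mean and sd."""
    if mean <= 0:
        return -np.inf, 0.0
    sigma2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - 0.5 * sigma2, np.sqrt(sigma2)


def _expit(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


def _logit(p: float) -> float:
    return np.log(p / (1.0 - p))


def sample_patient_truth(
    config: CohortConfig,
    entity: EntitySpec,
    rng: np.random.Generator,
    patient_id: str = "p0",
) -> PatientTruth:
    """Draw one patient's latent densities, covariates and per-clone
    cross-reactive tissue fraction.

    CTLA-4+ and CD3+ densities are a bivariate log-normal with the
    configured correlation of the log densities; a zero configured mean
    yields density exactly 0.  Covariates follow logistic (binary) or
    proportional-odds (pT) links on the standardised log CTLA-4 density so
    the planted directions of association hold in expectation.
    """
    if entity not in config.entities:
        raise ConfigError(f"entity {entity.name!r} does not belong to the config")
    ctla4_mean = entity.lymphocyte_density_mean * entity.ctla4_positive_fraction
    ctla4_sd = entity.lymphocyte_density_sd * entity.ctla4_positive_fraction
    cd3_mean = entity.lymphocyte_density_mean
    cd3_sd = entity.lymphocyte_density_sd

    rho = entity.cd3_ctla4_corr
    z1 = rng.standard_normal()
    z2 = rho * z1 + np.sqrt(max(0.0, 1.0 - rho**2)) * rng.standard_normal()

    mu_c, s_c = _lognormal_params(ctla4_mean, ctla4_sd)
    mu_d, s_d = _lognormal_params(cd3_mean, cd3_sd)
    ctla4 = float(np.exp(mu_c + s_c * z1)) if ctla4_mean > 0 else 0.0
    cd3 = float(np.exp(mu_d + s_d * z2)) if cd3_mean > 0 else 0.0

    effects = dict(entity.covariate_effects)
    covariates: dict[str, object] = {}
    # proportional-odds draw for the ordinal pT category
    shift = effects.get("pT", 0.0) * z1
    u = rng.uniform()
    pt = 4
    for k, cum in enumerate(_BASELINE_PT_CUM, start=1):
        if u <= _expit(_logit(cum) - shift):
            pt = k
            break
    covariates["pT"] = pt
    for name, base in _BASELINE_P.items():
        p = _expit(_logit(base) + effects.get(name, 0.0) * z1)
        covariates[name] = int(rng.uniform() < p)
    # missingness is drawn after the values so planted effects refer to the
    # complete-data distribution
    for name in COVARIATES:
        miss = config.covariate_missing.get(name, 0.0)
        if miss > 0 and rng.uniform() < miss:
            covariates[name] = None

    cross: dict[str, float] = {name: 0.0 for name in config.clone_names}
    if entity.crossreactive_clone is not None:
        m = entity.crossreactive_cell_fraction_mean
        if m > 0:
            k = _CROSS_FRACTION_CONCENTRATION
            cross[entity.crossreactive_clone] = float(
                rng.beta(m * k, (1.0 - m) * k)
            )

    return PatientTruth(
        patient_id=patient_id,
        entity=entity.name,
        category=entity.category,
        ctla4_density=ctla4,
        cd3_density=cd3,
        z=float(z1),
        covariates=covariates,
        crossreactive_fraction=cross,
    )


# ---------------------------------------------------------------------------
# rendering


def _disc_mask(shape: tuple[int, int], center: float, radius: float) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center) ** 2 + (cc - center) ** 2 <= radius**2


def _stamp(canvas: np.ndarray, patch: np.ndarray, row: int, col: int) -> None:
    """Add ``patch`` (odd square) centred at (row, col), clipped to canvas."""
    h = patch.shape[0] // 2
    r0, r1 = row - h, row + h + 1
    c0, c1 = col - h, col + h + 1
    pr0 = max(0, -r0)
    pc0 = max(0, -c0)
    r0c, c0c = max(0, r0), max(0, c0)
    r1c, c1c = min(canvas.shape[0], r1), min(canvas.shape[1], c1)
    if r1c <= r0c or c1c <= c0c:
        return
    canvas[r0c:r1c, c0c:c1c] += patch[
        pr0 : pr0 + (r1c - r0c), pc0 : pc0 + (c1c - c0c)
    ]


def _radial_patch(radius_px: float) -> np.ndarray:
    h = int(np.ceil(radius_px)) + 1
    rr, cc = np.mgrid[-h : h + 1, -h : h + 1]
    return np.hypot(rr, cc)


def _nucleus_patch(mpp: float) -> np.ndarray:
    sigma = NUCLEUS_SIGMA_UM / mpp
    d = _radial_patch(3.0 * sigma)
    return (NUCLEUS_AMPLITUDE * np.exp(-0.5 * (d / sigma) ** 2)).astype(np.float32)


def _ring_patch(amplitude: float, mpp: float) -> np.ndarray:
    r = RING_RADIUS_UM / mpp
    w = RING_HALF_WIDTH_UM / mpp
    d = _radial_patch(r + w)
    return (amplitude * (np.abs(d - r) <= w)).astype(np.float32)


def _blob_patch(amplitude: float, radius_um: float, mpp: float) -> np.ndarray:
    d = _radial_patch(radius_um / mpp)
    return (amplitude * (d <= radius_um / mpp)).astype(np.float32)


def _sample_positions(
    n: int, center: float, radius: float, rng: np.random.Generator
) -> np.ndarray:
    """Uniform positions within the spot disc, (n, 2) float (row, col)."""
    r = radius * np.sqrt(rng.uniform(size=n))
    theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
    return np.column_stack([center + r * np.sin(theta), center + r * np.cos(theta)])


def _halfplane_region(
    tissue: np.ndarray, fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """Contiguous sub-region of the tissue disc covering ``fraction`` of its
    pixels: a half-plane cut at a random orientation, with the offset set to
    the matching quantile of the projected coordinates (exact coverage up to
    pixel discretisation)."""
    if fraction <= 0:
        return np.zeros_like(tissue)
    if fraction >= 1:
        return tissue.copy()
    theta = rng.uniform(0.0, 2.0 * np.pi)
    u = np.array([np.sin(theta), np.cos(theta)])
    rows, cols = np.nonzero(tissue)
    proj = rows * u[0] + cols * u[1]
    t = np.quantile(proj, 1.0 - fraction)
    region = np.zeros_like(tissue)
    region[rows[proj > t], cols[proj > t]] = True
    return region


def _render_crossreactive(
    stain: np.ndarray,
    region: np.ndarray,
    profile: AntibodyProfile,
    positions: np.ndarray,
    mpp: float,
    rng: np.random.Generator,
) -> None:
    """Paint the non-specific stain of one clone inside ``region``.

    ``cytoplasmic-diffuse`` fills the region; ``membranous`` draws large
    rings at the affected cells; ``colloid-blob`` scatters large acellular
    blobs across the region.  All patterns stay inside the region mask.
    """
    amp = profile.crossreactive_stain_intensity
    if profile.crossreactive_pattern == "cytoplasmic-diffuse":
        stain[region] += amp
        return
    overlay = np.zeros_like(stain)
    if profile.crossreactive_pattern == "membranous":
        patch = _blob_patch(amp, 9.0, mpp) - _blob_patch(amp, 6.5, mpp)
        for row, col in np.round(positions).astype(int):
            _stamp(overlay, patch, row, col)
    else:  # colloid-blob
        patch = _blob_patch(amp, 14.0, mpp)
        rows, cols = np.nonzero(region)
        n_blobs = max(1, int(region.sum() * mpp**2 / 2000.0))
        idx = rng.integers(0, rows.size, size=n_blobs)
        for row, col in zip(rows[idx], cols[idx]):
            _stamp(overlay, patch, int(row), int(col))
    np.clip(overlay, 0.0, amp, out=overlay)
    overlay[~region] = 0.0
    stain += overlay


def render_spot_pair(
    truth: PatientTruth,
    config: CohortConfig,
    rng: np.random.Generator,
) -> tuple[SpotImage, SpotImage, GroundTruth, GroundTruth]:
    """Render the consecutive-section image pair for one patient.

    Both sections share one latent cell field; each section independently
    drops ``section_dropout`` of the cells and jitters positions by a
    Gaussian of sd ``section_jitter_um``.  Cells falling inside the
    clone's non-specific territory are labelled ``crossreactive_cell`` for
    that clone (their individual staining is unreadable there); the same
    cells on the clean clone keep their native class.

    With a fixed seed the output is bit-identical across runs.
    """
    mpp = config.microns_per_pixel
    radius = config.spot_radius_px
    size = config.canvas_px
    if size < 2 * radius:
        raise ConfigError(
            f"canvas of {size} px cannot contain a spot disc of radius {radius} px"
        )
    center = (size - 1) / 2.0
    tissue = _disc_mask((size, size), center, radius)
    area_mm2 = float(tissue.sum()) * mpp**2 / 1e6

    n_ctla4 = int(rng.poisson(truth.ctla4_density * area_mm2))
    n_other = int(rng.poisson(config.other_cell_density * area_mm2))
    positions = _sample_positions(n_ctla4 + n_other, center, radius - 2.0, rng)
    base_class = np.array(
        ["ctla4_lymphocyte"] * n_ctla4 + ["other_cell"] * n_other, dtype=object
    )

    nucleus = _nucleus_patch(mpp)
    images: list[SpotImage] = []
    truths: list[GroundTruth] = []
    for profile in config.antibody_profiles:
        clone = profile.clone_name
        frac = truth.crossreactive_fraction.get(clone, 0.0)
        region = _halfplane_region(tissue, frac, rng)

        keep = rng.uniform(size=positions.shape[0]) >= config.section_dropout
        jitter = rng.normal(0.0, config.section_jitter_um / mpp, size=positions.shape)
        pos = positions[keep] + jitter[keep]
        cls = base_class[keep].copy()

        ri = np.clip(np.round(pos[:, 0]).astype(int), 0, size - 1)
        ci = np.clip(np.round(pos[:, 1]).astype(int), 0, size - 1)
        in_region = region[ri, ci]
        cls[in_region] = "crossreactive_cell"

        nuclear = np.zeros((size, size), dtype=np.float32)
        stain = np.zeros((size, size), dtype=np.float32)
        nuclear[tissue] += config.tissue_background
        for row, col in zip(ri, ci):
            _stamp(nuclear, nucleus, int(row), int(col))
        ring = _ring_patch(profile.specific_stain_intensity, mpp)
        lymph = cls == "ctla4_lymphocyte"
        for row, col in zip(ri[lymph], ci[lymph]):
            _stamp(stain, ring, int(row), int(col))
        if in_region.any():
            _render_crossreactive(
                stain, region, profile, pos[in_region], mpp, rng
            )
        if profile.noise_sd > 0:
            nuclear += rng.normal(0.0, profile.noise_sd, size=nuclear.shape).astype(
                np.float32
            )
            stain += rng.normal(0.0, profile.noise_sd, size=stain.shape).astype(
                np.float32
            )
            np.clip(nuclear, 0.0, None, out=nuclear)
            np.clip(stain, 0.0, None, out=stain)

        n_total = int(cls.size)
        n_lymph = int(lymph.sum())
        n_cross = int((cls == "crossreactive_cell").sum())
        truths.append(
            GroundTruth(
                cell_centroids=pos,
                cell_class=cls,
                nonspecific_region_mask=region,
                tissue_mask=tissue,
                true_density=n_lymph / area_mm2 if area_mm2 > 0 else 0.0,
                true_nonspecific_fraction=n_cross / n_total if n_total else 0.0,
            )
        )
        images.append(
            SpotImage(
                nuclear_channel=nuclear,
                stain_channel=stain,
                microns_per_pixel=mpp,
                spot_id=truth.patient_id,
                clone_name=clone,
            )
        )
    return images[0], images[1], truths[0], truths[1]


# ---------------------------------------------------------------------------
# cohort iteration


@dataclass
class CohortSpotRecord:
    """One patient's rendered spot pair plus truth, yielded by iter_cohort."""

    truth: PatientTruth
    images: tuple[SpotImage, SpotImage]
    ground_truths: tuple[GroundTruth, GroundTruth]


def cohort_truths(config: CohortConfig) -> list[PatientTruth]:
    """Sample the latent truth for every patient of the cohort (no images).

    Patient ids are ``{entity}_{index}``; seeding is derived from the
    cohort seed so truth and rendering are jointly reproducible.
    """
    config.validate()
    truths = []
    for e_idx, entity in enumerate(config.entities):
        for p_idx in range(config.patients_per_entity):
            ss = np.random.SeedSequence(
                entropy=config.seed, spawn_key=(e_idx, p_idx)
            )
            rng = np.random.default_rng(ss)
            truths.append(
                sample_patient_truth(
                    config, entity, rng, patient_id=f"{entity.name}_{p_idx:04d}"
                )
            )
    return truths


def iter_cohort(config: CohortConfig) -> Iterator[CohortSpotRecord]:
    """Generate the cohort patient by patient (images are not retained)."""
    config.validate()
    for e_idx, entity in enumerate(config.entities):
        for p_idx in range(config.patients_per_entity):
            ss = np.random.SeedSequence(entropy=config.seed, spawn_key=(e_idx, p_idx))
            rng = np.random.default_rng(ss)
            truth = sample_patient_truth(
                config, entity, rng, patient_id=f"{entity.name}_{p_idx:04d}"
            )
            img_a, img_b, gt_a, gt_b = render_spot_pair(truth, config, rng)
            yield CohortSpotRecord(
                truth=truth, images=(img_a, img_b), ground_truths=(gt_a, gt_b)
            )


def patient_truth_frame(truths: list[PatientTruth], clone_names: tuple[str, str]):
    """Tabulate latent patient truth as a DataFrame (the ``patients.csv``
    interface of the pipeline)."""
    import pandas as pd

    rows = []
    for t in truths:
        row: dict[str, object] = {
            "patient_id": t.patient_id,
            "entity": t.entity,
            "category": t.category,
            "true_ctla4_density": t.ctla4_density,
            "cd3_density": t.cd3_density,
        }
        for name in COVARIATES:
            row[name] = t.covariates.get(name)
        for clone in clone_names:
            row[f"cross_fraction_{clone}"] = t.crossreactive_fraction.get(clone, 0.0)
        rows.append(row)
    return pd.DataFrame(rows)
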