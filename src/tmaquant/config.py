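"""Configuration objects for synthetic cohorts, segmentation and the pipeline.

All tunable parameters of the workflow live here so that a full run is
reproducible from one YAML file plus a seed.  Units are stated on every
field: lengths in microns (µm) or millimetres (mm), areas in µm² or mm²,
densities in cells/mm², stain levels in arbitrary optical-density (OD)
units.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from typing import Any, Mapping

import yaml

__all__ = [
    "ConfigError",
    "AntibodyProfile",
    "EntitySpec",
    "CohortConfig",
    "SegmentationParams",
    "PipelineConfig",
    "default_cohort_config",
    "default_entities",
    "load_config",
    "save_config",
    "config_hash",
]


class ConfigError(ValueError):
    """Raised when a configuration violates a documented invariant."""


#: Rendering patterns supported for cross-reactive (non-specific) staining.
CROSSREACTIVE_PATTERNS = ("membranous", "cytoplasmic-diffuse", "colloid-blob")

#: Default monotone effects of the standardised log CTLA-4 density on the
#: clinicopathological covariates (logistic link; sign gives the direction
#: of the planted association: denser infiltrates -> lower pT/pN, more
#: frequent PD-L1 positivity).
DEFAULT_COVARIATE_EFFECTS: dict[str, float] = {
    "pT": -0.6,
    "pN": -0.9,
    "pdl1_tumor": 0.9,
    "pdl1_immune": 0.9,
    "hpv": 0.5,
}

#: Default fraction of patients with a missing value per covariate.  Large
#: real TMA cohorts have very incomplete follow-up annotation, and the
#: association statistics must drop missing rows per covariate.
DEFAULT_COVARIATE_MISSING: dict[str, float] = {
    "pT": 0.40,
    "pN": 0.60,
    "pdl1_tumor": 0.30,
    "pdl1_immune": 0.25,
    "hpv": 0.85,
}


@dataclass(frozen=True)
class AntibodyProfile:
    """One virtual antibody clone.

    Parameters
    ----------
    clone_name:
        Identifier of the clone (e.g. ``"cloneA"``).
    specific_stain_intensity:
        Peak OD of the specific membranous ring stain on a CTLA-4+
        lymphocyte.  Must be > 0.
    crossreactive_pattern:
        Shape of non-specific staining this clone produces where it
        cross-reacts: ``membranous``, ``cytoplasmic-diffuse`` or
        ``colloid-blob``.
    crossreactive_stain_intensity:
        OD of the non-specific stain.  Must be > 0.
    noise_sd:
        Standard deviation of additive Gaussian pixel noise (OD units).
    """

    clone_name: str
    specific_stain_intensity: float = 1.0
    crossreactive_pattern: str = "cytoplasmic-diffuse"
    crossreactive_stain_intensity: float = 0.7
    noise_sd: float = 0.05

    def validate(self) -> None:
        if not self.clone_name:
            raise ConfigError("antibody clone_name must be non-empty")
        if self.specific_stain_intensity <= 0:
            raise ConfigError(
                f"specific_stain_intensity must be > 0 for clone {self.clone_name!r}"
            )
        if self.crossreactive_stain_intensity <= 0:
            raise ConfigError(
                f"crossreactive_stain_intensity must be > 0 for clone {self.clone_name!r}"
            )
        if self.crossreactive_pattern not in CROSSREACTIVE_PATTERNS:
            raise ConfigError(
                f"unknown crossreactive_pattern {self.crossreactive_pattern!r}; "
                f"expected one of {CROSSREACTIVE_PATTERNS}"
            )
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")


@dataclass(frozen=True)
class EntitySpec:
    """Statistical description of one tumor entity.

    ``lymphocyte_density_mean``/``_sd`` describe the per-patient CD3+
    T-cell density (cells/mm²); the CTLA-4+ density is the configured
    fraction of it on average, drawn jointly with the CD3 density as a
    bivariate log-normal at correlation ``cd3_ctla4_corr`` (correlation of
    the log densities).

    ``crossreactive_clone`` names the antibody clone (or ``None``) whose
    staining is non-specific in this entity; ``crossreactive_cell_fraction_mean``
    is the mean fraction of the spot's cells that lie inside the
    non-specifically stained territory for that clone.
    """

    name: str
    category: str
    lymphocyte_density_mean: float
    lymphocyte_density_sd: float
    ctla4_positive_fraction: float
    cd3_ctla4_corr: float = 0.69
    crossreactive_clone: str | None = None
    crossreactive_cell_fraction_mean: float = 0.0
    covariate_effects: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS)
    )

    def validate(self, clone_names: tuple[str, ...] = ()) -> None:
        if not self.name:
            raise ConfigError("entity name must be non-empty")
        if self.lymphocyte_density_mean < 0 or self.lymphocyte_density_sd < 0:
            raise ConfigError(f"densities must be >= 0 for entity {self.name!r}")
        if not 0.0 <= self.ctla4_positive_fraction <= 1.0:
            raise ConfigError(
                f"ctla4_positive_fraction must be in [0, 1] for entity {self.name!r}"
            )
        if not -1.0 <= self.cd3_ctla4_corr <= 1.0:
            raise ConfigError(f"cd3_ctla4_corr must be in [-1, 1] for {self.name!r}")
        if not 0.0 <= self.crossreactive_cell_fraction_mean <= 1.0:
            raise ConfigError(
                f"crossreactive_cell_fraction_mean must be in [0, 1] for {self.name!r}"
            )
        if clone_names and self.crossreactive_clone is not None:
            if self.crossreactive_clone not in clone_names:
                raise ConfigError(
                    f"entity {self.name!r} references unknown clone "
                    f"{self.crossreactive_clone!r}; configured clones: {clone_names}"
                )


@dataclass(frozen=True)
class CohortConfig:
    """Full description of a synthetic TMA cohort.

    The defaults emulate the statistical structure the analysis assumes:
    0.6 mm circular spots imaged at 1 µm/px, two antibody clones stained on
    consecutive sections of the same core (same latent cell field, small
    positional jitter, some cell dropout), per-patient log-normal densities
    and entity-specific clone-dependent cross-reactive staining.
    """

    seed: int = 0
    entities: tuple[EntitySpec, ...] = ()
    patients_per_entity: int = 10
    microns_per_pixel: float = 1.0
    spot_diameter_mm: float = 0.6
    antibody_profiles: tuple[AntibodyProfile, AntibodyProfile] = (
        AntibodyProfile(clone_name="cloneA"),
        AntibodyProfile(clone_name="cloneB"),
    )
    #: density of CTLA-4 negative nuclei (tumor/stromal cells), cells/mm²
    other_cell_density: float = 1200.0
    #: uniform OD added to the nuclear channel inside the tissue disc,
    #: making the tissue area measurable even in cell-poor spots
    tissue_background: float = 0.15
    #: per-cell positional jitter between consecutive sections, µm (sd)
    section_jitter_um: float = 2.0
    #: fraction of cells missing from an individual section
    section_dropout: float = 0.10
    #: blank margin around the spot disc, px
    canvas_margin_px: int = 50
    covariate_missing: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_MISSING)
    )

    def validate(self) -> None:
        if self.spot_diameter_mm <= 0:
            raise ConfigError("spot_diameter_mm must be > 0")
        if self.microns_per_pixel <= 0:
            raise ConfigError("microns_per_pixel must be > 0")
        if len(self.entities) < 1:
            raise ConfigError("at least one entity must be configured")
        if len(self.antibody_profiles) != 2:
            raise ConfigError("exactly two antibody profiles are required")
        names = self.clone_names
        if names[0] == names[1]:
            raise ConfigError("antibody clones must have distinct names")
        for profile in self.antibody_profiles:
            profile.validate()
        for entity in self.entities:
            entity.validate(names)
        if self.patients_per_entity < 0:
            raise ConfigError("patients_per_entity must be >= 0")
        if not 0.0 <= self.section_dropout < 1.0:
            raise ConfigError("section_dropout must be in [0, 1)")
        if self.other_cell_density < 0:
            raise ConfigError("other_cell_density must be >= 0")

    @property
    def clone_names(self) -> tuple[str, str]:
        return tuple(p.clone_name for p in self.antibody_profiles)  # type: ignore[return-value]

    @property
    def spot_radius_px(self) -> float:
        return self.spot_diameter_mm * 1000.0 / (2.0 * self.microns_per_pixel)

    @property
    def canvas_px(self) -> int:
        """Square canvas side length in pixels."""
        return 2 * (int(round(self.spot_radius_px)) + self.canvas_margin_px)

    def profile(self, clone_name: str) -> AntibodyProfile:
        for p in self.antibody_profiles:
            if p.clone_name == clone_name:
                return p
        raise ConfigError(f"unknown clone {clone_name!r}")


@dataclass(frozen=True)
class SegmentationParams:
    """Parameters of the classical nucleus/positivity segmentation.

    Cell-level stain measurements use three concentric radii around each
    detected nucleus centroid (all in µm, converted to pixels internally):
    the mean stain is taken over the disc of ``membrane_radius_um``; the
    membrane score is the stain mass in the annulus
    ``(interior_radius_um, membrane_radius_um]`` divided by the mass in the
    disc of ``support_radius_um``.
    """

    nuclear_threshold: float = 0.30
    min_cell_area_um2: float = 20.0
    max_cell_area_um2: float = 400.0
    #: CTLA-4 positivity threshold (OD units); ``None`` derives the default
    #: from the antibody profile, see :func:`default_positivity_threshold`.
    positivity_threshold: float | None = None
    tissue_threshold: float = 0.08
    #: threshold for stained-region extraction; ``None`` -> half of the
    #: positivity threshold
    region_threshold: float | None = None
    min_region_area_um2: float = 25.0
    interior_radius_um: float = 4.5
    membrane_radius_um: float = 7.0
    support_radius_um: float = 9.0
    #: minimum separation of nuclear intensity maxima used as watershed
    #: markers, µm
    peak_min_distance_um: float = 3.0

    def validate(self) -> None:
        if not 0 < self.min_cell_area_um2 < self.max_cell_area_um2:
            raise ConfigError("need 0 < min_cell_area_um2 < max_cell_area_um2")
        for name in (
            "nuclear_threshold",
            "tissue_threshold",
            "min_region_area_um2",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.positivity_threshold is not None and self.positivity_threshold < 0:
            raise ConfigError("positivity_threshold must be >= 0")
        if not 0 < self.interior_radius_um < self.membrane_radius_um <= self.support_radius_um:
            raise ConfigError(
                "need 0 < interior_radius_um < membrane_radius_um <= support_radius_um"
            )


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end pipeline configuration."""

    cohort: CohortConfig
    segmentation: SegmentationParams = SegmentationParams()
    #: spots with a non-specific cell fraction >= this are excluded
    exclusion_threshold: float = 0.05
    #: fraction of patients (per entity) used to train the artifact classifier
    train_fraction: float = 0.75
    split_seed: int = 202
    #: denominator of the non-specific fraction: all detected cells
    #: ("all_cells") or only stained cells ("stained_cells")
    fraction_denominator: str = "all_cells"

    def validate(self) -> None:
        self.cohort.validate()
        self.segmentation.validate()
        if not 0.0 <= self.exclusion_threshold <= 1.0:
            raise ConfigError("exclusion_threshold must be in [0, 1]")
        if not 0.0 < self.train_fraction < 1.0:
            raise ConfigError("train_fraction must be in (0, 1)")
        if self.fraction_denominator not in ("all_cells", "stained_cells"):
            raise ConfigError(
                "fraction_denominator must be 'all_cells' or 'stained_cells'"
            )

    def with_seed(self, seed: int) -> "PipelineConfig":
        return replace(
            self,
            cohort=replace(self.cohort, seed=int(seed)),
            split_seed=int(seed) + 101,
        )


def default_entities() -> tuple[EntitySpec, ...]:
    """Ten tumor entities spanning the density range seen on large TMA
    cohorts, with clone-dependent cross-reactive staining planted in three
    of them (one clone-A entity, two clone-B entities).

    Mean CTLA-4+ densities range from tens of cells/mm² (leiomyoma) to
    thousands (Hodgkin's lymphoma); per-patient densities are strongly
    right-skewed, hence the log-normal draw.
    """

    def ent(name, category, cd3_mean, cd3_sd, frac, cross=None, cross_frac=0.0):
        return EntitySpec(
            name=name,
            category=category,
            lymphocyte_density_mean=cd3_mean,
            lymphocyte_density_sd=cd3_sd,
            ctla4_positive_fraction=frac,
            crossreactive_clone=cross,
            crossreactive_cell_fraction_mean=cross_frac,
        )

    return (
        ent("hodgkin_lymphoma", "lymphoma", 19000.0, 12000.0, 0.30),
        ent("nhl_b_cell", "lymphoma", 15000.0, 13000.0, 0.20),
        ent("squamous_cc", "epithelial", 2100.0, 2300.0, 0.20),
        ent("urothelial_ca", "epithelial", 2800.0, 2300.0, 0.15),
        ent("adenocarcinoma", "epithelial", 1700.0, 2300.0, 0.16),
        ent("renal_cell_ca", "epithelial", 1500.0, 1600.0, 0.17),
        ent("leiomyoma", "mesenchymal", 800.0, 1900.0, 0.09),
        ent(
            "adrenal_cortical_adenoma", "epithelial", 1600.0, 2300.0, 0.14,
            cross="cloneA", cross_frac=0.58,
        ),
        ent(
            "pheochromocytoma", "epithelial", 1500.0, 1500.0, 0.17,
            cross="cloneB", cross_frac=0.66,
        ),
        ent(
            "hepatocellular_ca", "epithelial", 1600.0, 2700.0, 0.16,
            cross="cloneB", cross_frac=0.35,
        ),
    )


def default_cohort_config(seed: int = 0, patients_per_entity: int = 10) -> CohortConfig:
    return CohortConfig(
        seed=seed,
        entities=default_entities(),
        patients_per_entity=patients_per_entity,
    )


# ---------------------------------------------------------------------------
# serialisation


def _to_plain(obj: Any) -> Any:
    if isinstance(obj, (CohortConfig, EntitySpec, AntibodyProfile, SegmentationParams, PipelineConfig)):
        return {k: _to_plain(v) for k, v in asdict(obj).items()}
    if isinstance(obj, Mapping):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj


def pipeline_config_to_dict(config: PipelineConfig) -> dict:
    return _to_plain(config)


def pipeline_config_from_dict(data: Mapping[str, Any]) -> PipelineConfig:
    cohort = data.get("cohort", {})
    entities = tuple(EntitySpec(**e) for e in cohort.get("entities", ()))
    profiles = tuple(AntibodyProfile(**p) for p in cohort.get("antibody_profiles", ()))
    cohort_kwargs = {
        k: v for k, v in cohort.items() if k not in ("entities", "antibody_profiles")
    }
    cohort_cfg = CohortConfig(
        entities=entities, antibody_profiles=profiles, **cohort_kwargs  # type: ignore[arg-type]
    )
    seg = SegmentationParams(**data.get("segmentation", {}))
    other = {
        k: v for k, v in data.items() if k not in ("cohort", "segmentation")
    }
    config = PipelineConfig(cohort=cohort_cfg, segmentation=seg, **other)
    config.validate()
    return config


def save_config(config: PipelineConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(pipeline_config_to_dict(config), fh, sort_keys=False)


def load_config(path) -> PipelineConfig:
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, Mapping):
        raise ConfigError(f"config file {path} does not contain a mapping")
    try:
        return pipeline_config_from_dict(data)
    except TypeError as exc:  # unknown keys
        raise ConfigError(f"invalid config {path}: {exc}") from exc


def config_hash(config: PipelineConfig) -> str:
    """Stable SHA-256 hash of the canonical JSON form of a config."""
    payload = json.dumps(pipeline_config_to_dict(config), sort_keys=True)
    return hashlib.sha256(payload.encode("utf-8")).hexdigest()
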