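"""Shared fixtures: small, fast synthetic configurations."""

import numpy as np
import pytest

from tmaquant.config import (
    AntibodyProfile,
    CohortConfig,
    EntitySpec,
    SegmentationParams,
)


def make_entity(
    name="entity",
    category="epithelial",
    cd3_mean=1770.0,
    cd3_sd=150.0,
    frac=0.2,
    cross=None,
    cross_frac=0.0,
    **kwargs,
):
    return EntitySpec(
        name=name,
        category=category,
        lymphocyte_density_mean=cd3_mean,
        lymphocyte_density_sd=cd3_sd,
        ctla4_positive_fraction=frac,
        crossreactive_clone=cross,
        crossreactive_cell_fraction_mean=cross_frac,
        **kwargs,
    )


def noiseless_profiles():
    return (
        AntibodyProfile(clone_name="cloneA", noise_sd=0.0),
        AntibodyProfile(clone_name="cloneB", noise_sd=0.0),
    )


@pytest.fixture
def clean_config():
    """One clean entity, ~100 CTLA-4+ cells per spot, no noise/artifacts."""
    return CohortConfig(
        seed=123,
        entities=(make_entity(),),
        patients_per_entity=2,
        antibody_profiles=noiseless_profiles(),
        covariate_missing={},
    )


@pytest.fixture
def cross_config():
    """Two entities, clone-B cross-reactivity planted in the second."""
    return CohortConfig(
        seed=11,
        entities=(
            make_entity(name="clean"),
            make_entity(name="crossed", cross="cloneB", cross_frac=0.4),
        ),
        patients_per_entity=3,
        covariate_missing={},
    )


@pytest.fixture
def clean_spot(clean_config):
    """One rendered noiseless spot pair with ground truth."""
    from tmaquant.synthetic import iter_cohort

    return next(iter(iter_cohort(clean_config)))


@pytest.fixture
def params():
    return SegmentationParams()


@pytest.fixture
def rng():
    return np.random.default_rng(0)
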