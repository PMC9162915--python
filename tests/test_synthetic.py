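"""Generator contracts: latent truth, rendering, determinism, cohort I/O."""

import dataclasses

import numpy as np
import pytest
from scipy import stats as sps

from tmaquant.config import CohortConfig, ConfigError, PipelineConfig
from tmaquant.io import read_spot_image, write_cohort
from tmaquant.synthetic import (
    cohort_truths,
    iter_cohort,
    render_spot_pair,
    sample_patient_truth,
)

from conftest import make_entity


def _single_entity_config(entity, n=1, seed=0, **kwargs):
    return CohortConfig(
        seed=seed, entities=(entity,), patients_per_entity=n,
        covariate_missing={}, **kwargs
    )


class TestPatientTruth:
    def test_zero_density_entity_yields_no_positive_cells(self):
        entity = make_entity(cd3_mean=0.0, cd3_sd=0.0, frac=0.0)
        config = _single_entity_config(entity)
        rec = next(iter(iter_cohort(config)))
        assert rec.truth.ctla4_density == 0.0
        for gt in rec.ground_truths:
            assert gt.counts["ctla4_lymphocyte"] == 0
            assert gt.true_density == 0.0

    def test_perfect_correlation_makes_cd3_monotone_in_ctla4(self):
        entity = make_entity(cd3_sd=1500.0, cd3_ctla4_corr=1.0)
        config = _single_entity_config(entity, n=50)
        truths = cohort_truths(config)
        ctla4 = np.array([t.ctla4_density for t in truths])
        cd3 = np.array([t.cd3_density for t in truths])
        # rank correlation of a deterministic monotone map is exactly 1
        assert sps.spearmanr(ctla4, cd3).statistic == pytest.approx(1.0)

    def test_log_density_correlation_matches_configured_parameter(self):
        entity = make_entity(cd3_mean=2000.0, cd3_sd=1500.0, cd3_ctla4_corr=0.69)
        config = _single_entity_config(entity, n=4000, seed=9)
        truths = cohort_truths(config)
        lc = np.log([t.ctla4_density for t in truths])
        ld = np.log([t.cd3_density for t in truths])
        r = sps.pearsonr(lc, ld).statistic
        assert abs(r - 0.69) < 0.05

    def test_sample_mean_density_within_three_standard_errors(self):
        entity = make_entity(cd3_mean=2000.0, cd3_sd=800.0, frac=0.2)
        config = _single_entity_config(entity, n=1000, seed=21)
        truths = cohort_truths(config)
        dens = np.array([t.ctla4_density for t in truths])
        target = 2000.0 * 0.2
        se = dens.std(ddof=1) / np.sqrt(dens.size)
        assert abs(dens.mean() - target) < 3 * se

    def test_unknown_entity_rejected(self, clean_config, rng):
        stranger = make_entity(name="not_in_config")
        with pytest.raises(ConfigError, match="does not belong"):
            sample_patient_truth(clean_config, stranger, rng)

    def test_planted_covariate_direction(self):
        # strong negative pN effect: high-density patients less often pN+
        entity = make_entity(cd3_mean=2000.0, cd3_sd=1500.0,
                             covariate_effects={"pN": -1.5})
        config = _single_entity_config(entity, n=1500, seed=3)
        truths = cohort_truths(config)
        z = np.array([t.z for t in truths])
        pn = np.array([t.covariates["pN"] for t in truths], dtype=float)
        assert pn[z > 0].mean() < pn[z < 0].mean()


class TestRendering:
    def test_ground_truth_class_conservation(self, cross_config):
        for rec in iter_cohort(cross_config):
            for gt in rec.ground_truths:
                counts = gt.counts
                assert sum(counts.values()) == len(gt.cell_class)
                assert gt.cell_centroids.shape == (len(gt.cell_class), 2)

    def test_nonspecific_fraction_is_exact_count_ratio(self, cross_config):
        seen_cross = False
        for rec in iter_cohort(cross_config):
            for gt in rec.ground_truths:
                counts = gt.counts
                total = sum(counts.values())
                expected = counts["crossreactive_cell"] / total if total else 0.0
                assert gt.true_nonspecific_fraction == pytest.approx(expected)
                seen_cross |= counts["crossreactive_cell"] > 0
        assert seen_cross

    def test_crossreactivity_is_clone_specific(self, cross_config):
        for rec in iter_cohort(cross_config):
            gt_a, gt_b = rec.ground_truths
            # a cross-reactive territory never appears on both clones
            assert not (
                gt_a.nonspecific_region_mask.any()
                and gt_b.nonspecific_region_mask.any()
            )
            if rec.truth.entity == "crossed":
                assert gt_b.nonspecific_region_mask.any()
                assert not gt_a.nonspecific_region_mask.any()

    def test_rendering_is_bit_identical_for_fixed_seed(self, cross_config):
        first = list(iter_cohort(cross_config))
        second = list(iter_cohort(cross_config))
        for a, b in zip(first, second):
            for i in (0, 1):
                assert np.array_equal(
                    a.images[i].nuclear_channel, b.images[i].nuclear_channel
                )
                assert np.array_equal(
                    a.images[i].stain_channel, b.images[i].stain_channel
                )

    def test_consecutive_sections_share_jittered_population(self, clean_config):
        config = dataclasses.replace(clean_config, section_dropout=0.0)
        rec = next(iter(iter_cohort(config)))
        gt_a, gt_b = rec.ground_truths
        # no dropout: same cells, positions differing only by jitter
        assert len(gt_a.cell_class) == len(gt_b.cell_class)
        shifts = np.linalg.norm(gt_a.cell_centroids - gt_b.cell_centroids, axis=1)
        jitter_px = config.section_jitter_um / config.microns_per_pixel
        # two independent 2-D jitters: 6 sigma covers essentially all shifts
        assert np.percentile(shifts, 99) < 6 * jitter_px * np.sqrt(2)

    def test_dropout_removes_expected_share(self, clean_config):
        config = dataclasses.replace(
            clean_config,
            section_dropout=0.5,
            entities=(make_entity(cd3_mean=10000.0, cd3_sd=100.0),),
        )
        rec = next(iter(iter_cohort(config)))
        # ~half of the latent field kept per section (binomial, generous band)
        expected = (rec.truth.ctla4_density + config.other_cell_density) * 0.2827 * 0.5
        for gt in rec.ground_truths:
            assert 0.8 < len(gt.cell_class) / expected < 1.2

    def test_canvas_too_small_rejected(self, clean_config, rng):
        config = dataclasses.replace(clean_config, canvas_margin_px=-40)
        truth = sample_patient_truth(config, config.entities[0], rng)
        with pytest.raises(ConfigError, match="cannot contain"):
            render_spot_pair(truth, config, rng)


class TestWriteCohort:
    def test_manifest_counts_and_determinism(self, tmp_path, cross_config):
        config = dataclasses.replace(cross_config, patients_per_entity=2)
        pipe = PipelineConfig(cohort=config)
        m1 = write_cohort(pipe, tmp_path / "a")
        m2 = write_cohort(pipe, tmp_path / "b")
        # 2 entities x 2 patients x 2 clones
        assert m1["n_images"] == 8
        assert m1["manifest_sha256"] == m2["manifest_sha256"]

    def test_empty_cohort_manifest(self, tmp_path, clean_config):
        config = dataclasses.replace(clean_config, patients_per_entity=0)
        manifest = write_cohort(PipelineConfig(cohort=config), tmp_path)
        assert manifest["n_images"] == 0
        assert manifest["spots"] == []

    def test_image_roundtrip(self, tmp_path, clean_config):
        config = dataclasses.replace(clean_config, patients_per_entity=1)
        manifest = write_cohort(PipelineConfig(cohort=config), tmp_path)
        spot = manifest["spots"][0]
        image = read_spot_image(tmp_path / spot["image"])
        assert image.spot_id == spot["spot_id"]
        assert image.clone_name == spot["clone"]
        assert image.shape == (config.canvas_px, config.canvas_px)
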