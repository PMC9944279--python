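"""Generators: determinism, forward–inverse consistency, truth agreement."""

import numpy as np
import pandas as pd
import pytest

from aggsink import respiration
from aggsink.biophysics import fractal_dimension
from aggsink.census import prevalence
from aggsink.imaging import ImagingConfig, analyze_stack
from aggsink.synthetic import (
    CensusParams,
    PopulationParams,
    SceneParams,
    generate_aggregate_population,
    generate_cell_census,
    generate_image_sequence,
    generate_o2_assays,
    generate_settling_trials,
    generate_stained_micrograph,
    match_detections_to_truth,
)


class TestAggregatePopulation:
    def test_seed_determinism_byte_identical(self):
        p = PopulationParams(n_aggregates=50, velocity_noise_sd=0.2, seed=123)
        t1 = generate_aggregate_population(p)
        t2 = generate_aggregate_population(p)
        assert t1.to_csv() == t2.to_csv()

    def test_noiseless_population_yields_exact_fractal_dimension(self):
        p = PopulationParams(n_aggregates=30, D3_true=2.37, velocity_noise_sd=0.0, seed=0)
        pop = generate_aggregate_population(p)
        fd = fractal_dimension(pop["d_mm"], pop["u_m_d"])
        assert fd.d3 == pytest.approx(2.37, abs=1e-9)

    def test_noisy_population_recovers_d3_within_ols_error(self):
        p = PopulationParams(n_aggregates=200, D3_true=2.37, velocity_noise_sd=0.1, seed=1)
        pop = generate_aggregate_population(p)
        fd = fractal_dimension(pop["d_mm"], pop["u_m_d"])
        assert fd.d3 == pytest.approx(2.37, abs=0.1)

    def test_diameters_respect_range_and_poc_tracks_solid_volume(self):
        p = PopulationParams(n_aggregates=100, seed=4)
        pop = generate_aggregate_population(p)
        assert pop["d_mm"].between(*p.d_range).all()
        solid = pop["volume_mm3"] * (1 - pop["porosity"])
        assert np.allclose(pop["poc_ug"], p.poc_per_volume * solid)

    def test_invalid_params_rejected_with_all_problems(self):
        with pytest.raises(ValueError) as err:
            PopulationParams(n_aggregates=0, D3_true=4.0, velocity_noise_sd=-1)
        msg = str(err.value)
        assert "n_aggregates" in msg and "D3_true" in msg and "velocity_noise_sd" in msg


class TestImageSequence:
    def test_clean_scene_recovers_every_blob(self):
        pop = generate_aggregate_population(PopulationParams(n_aggregates=10, seed=2))
        scene = SceneParams()
        stack, truth = generate_image_sequence(pop, scene, seed=3)
        det = analyze_stack(stack, ImagingConfig(pixel_scale=scene.pixel_scale, unit="mm"))
        assert len(det) == 10
        matched = match_detections_to_truth(truth, det)
        assert matched["det_ecd"].notna().all()

    def test_truth_area_equals_rasterization_oracle(self):
        pop = generate_aggregate_population(PopulationParams(n_aggregates=5, seed=9))
        scene = SceneParams()
        stack, truth = generate_image_sequence(pop, scene, seed=1)
        for t in truth.itertuples():
            f = stack[t.frame]
            yy, xx = np.mgrid[: f.shape[0], : f.shape[1]]
            inside = (yy - t.centroid_row) ** 2 + (xx - t.centroid_col) ** 2 <= t.radius_px**2
            assert t.area_px == inside.sum()
            assert t.area == pytest.approx(inside.sum() * scene.pixel_scale**2)
            # rasterized area tracks the continuous disc area
            assert t.area_px == pytest.approx(np.pi * t.radius_px**2, rel=0.05)

    def test_empty_population_gives_background_frames(self):
        pop = generate_aggregate_population(PopulationParams(seed=0)).iloc[:0]
        scene = SceneParams()
        stack, truth = generate_image_sequence(pop, scene, seed=0)
        assert truth.empty
        assert np.ptp(stack) == 0.0

    def test_oversized_aggregate_error_names_record(self):
        pop = generate_aggregate_population(
            PopulationParams(n_aggregates=3, d_range=(20.0, 25.0), seed=0))
        with pytest.raises(ValueError, match="aggregate"):
            generate_image_sequence(pop, SceneParams(image_shape=(128, 128)), seed=0)

    def test_seed_determinism(self):
        pop = generate_aggregate_population(PopulationParams(n_aggregates=6, seed=5))
        s1, t1 = generate_image_sequence(pop, SceneParams(noise_sd=0.05), seed=8)
        s2, t2 = generate_image_sequence(pop, SceneParams(noise_sd=0.05), seed=8)
        assert np.array_equal(s1, s2)
        pd.testing.assert_frame_equal(t1, t2)


class TestStainedMicrograph:
    SCENE = SceneParams(image_shape=(256, 256), pixel_scale=1.0,
                        channel_mode="stained_rgb")
    CFG = ImagingConfig(pixel_scale=1.0, unit="um", threshold_method="fixed",
                        threshold=0.1, min_ecd=3.0)

    def test_polymer_only(self):
        rgb, truth = generate_stained_micrograph(5, 0, self.SCENE, seed=1)
        det = analyze_stack([rgb], self.CFG)
        assert len(det) == 5

    def test_red_cells_removed_by_channel_arithmetic(self):
        rgb, truth = generate_stained_micrograph(5, 3, self.SCENE, seed=2)
        det = analyze_stack([rgb], self.CFG)
        assert len(det) == 5
        matched = match_detections_to_truth(truth[truth["kind"] == "polymer"], det)
        assert matched["det_ecd"].notna().all()

    def test_all_blobs_below_size_filter(self):
        rgb, _ = generate_stained_micrograph(
            4, 0, self.SCENE, polymer_radius_px=(1.0, 1.2), seed=3)
        det = analyze_stack([rgb], self.CFG)  # ECD of ~2 px discs < 3 µm
        assert len(det) == 0

    def test_requires_stained_mode(self):
        with pytest.raises(ValueError):
            generate_stained_micrograph(1, 0, SceneParams(), seed=0)


class TestO2Assays:
    POP = generate_aggregate_population(PopulationParams(n_aggregates=8, seed=6))

    @staticmethod
    def _recover_rates(assays: pd.DataFrame) -> np.ndarray:
        controls = [respiration.RespirationAssay(
            o2_start=a.o2_start, o2_end=a.o2_end, vial_volume_ml=a.vial_volume_ml,
            duration_h=a.duration_h, is_control=True)
            for a in assays[assays["is_control"]].itertuples()]
        out = []
        for a in assays[~assays["is_control"]].itertuples():
            assay = respiration.RespirationAssay(
                o2_start=a.o2_start, o2_end=a.o2_end, vial_volume_ml=a.vial_volume_ml,
                duration_h=a.duration_h, poc_ug=a.poc_ug)
            rate = respiration.o2_consumption(assay, controls)
            out.append(respiration.c_specific_rate(rate, a.poc_ug))
        return np.asarray(out)

    def test_zero_rate_means_no_drawdown(self):
        pop = self.POP.assign(resp_rate_per_day=0.0)
        assays = generate_o2_assays(pop, seed=0)
        assert (assays["o2_start"] == assays["o2_end"]).all()

    def test_zero_noise_inversion_is_exact(self):
        """Forward model then inversion recovers the generating k."""
        assays = generate_o2_assays(self.POP, control_drift_frac=0.02, seed=0)
        k = self._recover_rates(assays)
        assert np.allclose(k, self.POP["resp_rate_per_day"], rtol=1e-9)

    def test_control_correction_unbiased_over_seeds(self):
        """With drift and noise, the mean recovered rate is unbiased."""
        means = []
        for seed in range(100):
            assays = generate_o2_assays(
                self.POP, control_drift_frac=0.02, noise_sd=1.0, seed=seed)
            means.append(self._recover_rates(assays).mean())
        true_mean = self.POP["resp_rate_per_day"].mean()
        assert np.mean(means) == pytest.approx(true_mean, rel=0.05)

    def test_anoxia_error(self):
        pop = self.POP.assign(resp_rate_per_day=50.0, poc_ug=1000.0)
        with pytest.raises(ValueError, match="anoxia"):
            generate_o2_assays(pop, seed=0)


class TestSettlingTrials:
    def test_known_velocity_gives_known_time(self):
        pop = pd.DataFrame({"aggregate_id": [0], "u_m_d": [216.0]})
        trials = generate_settling_trials(pop, distance_cm=15.0, seed=0)
        assert trials["time_s"].iloc[0] == pytest.approx(60.0)

    def test_zero_noise_inverts_exactly(self):
        pop = generate_aggregate_population(PopulationParams(n_aggregates=10, seed=3))
        trials = generate_settling_trials(pop, seed=0)
        u = trials["distance_cm"] / trials["time_s"] * 864.0
        assert np.allclose(u, pop["u_m_d"], rtol=1e-12)

    def test_noise_keeps_times_positive_and_deterministic(self):
        pop = generate_aggregate_population(
            PopulationParams(n_aggregates=50, velocity_scale_a=500.0, seed=3))
        t1 = generate_settling_trials(pop, timing_noise_sd_s=5.0, seed=7)
        t2 = generate_settling_trials(pop, timing_noise_sd_s=5.0, seed=7)
        assert (t1["time_s"] > 0).all()
        pd.testing.assert_frame_equal(t1, t2)


class TestCellCensus:
    def test_unit_enrichment_gives_matching_compartments(self):
        params = CensusParams(n_cells=50_000, aggregate_enrichment=1.0, seed=1)
        agg, amb = generate_cell_census(params)
        assert prevalence(agg) == pytest.approx(prevalence(amb), abs=1.5)

    def test_prevalence_ratio_recovers_enrichment_parameter(self):
        for seed in (1, 2, 3):
            params = CensusParams(n_cells=100_000, seed=seed)
            agg, amb = generate_cell_census(params)
            ratio = prevalence(agg) / prevalence(amb)
            assert ratio == pytest.approx(params.aggregate_enrichment, abs=0.05)

    def test_large_sample_bacterial_means_match_parameters(self):
        params = CensusParams(n_cells=100_000, seed=0)
        agg, _ = generate_cell_census(params)
        for stage, mean in params.bacteria_mean_per_stage.items():
            counts = agg.bacteria[stage]
            if len(counts) > 5000:
                assert counts.mean() == pytest.approx(mean, rel=0.02)

    def test_excessive_enrichment_is_error(self):
        with pytest.raises(ValueError, match="enrichment"):
            generate_cell_census(CensusParams(aggregate_enrichment=3.0, seed=0))

    def test_stage_mix_must_sum_to_one(self):
        with pytest.raises(ValueError):
            CensusParams(stage_mix={"non": 0.5, "early": 0.2, "mature": 0.2,
                                    "post": 0.2, "decaying": 0.0})


class TestFullRoundTrip:
    def test_population_to_images_to_biophysics_recovers_d3(self):
        """population → rendered frames → detections → matched sizes →
        settling trials → log–log fit recovers the generating D₃ ± 0.15."""
        params = PopulationParams(
            n_aggregates=200, d_range=(0.4, 5.6), D3_true=2.37,
            velocity_noise_sd=0.1, seed=1)
        pop = generate_aggregate_population(params)
        scene = SceneParams(noise_sd=0.02, background_gradient=0.05)
        stack, truth = generate_image_sequence(pop, scene, seed=2)
        det = analyze_stack(stack, ImagingConfig(
            pixel_scale=scene.pixel_scale, unit="mm", min_ecd=0.35,
            smooth_sigma=1.0))
        matched = match_detections_to_truth(truth, det)
        merged = pop.merge(matched[["aggregate_id", "det_ecd"]], on="aggregate_id")
        merged = merged.dropna(subset=["det_ecd"])
        assert len(merged) >= 0.95 * len(pop)
        trials = generate_settling_trials(merged, seed=3)
        u = trials["distance_cm"] / trials["time_s"] * 864.0
        fd = fractal_dimension(merged["det_ecd"], u)
        assert fd.d3 == pytest.approx(2.37, abs=0.15)
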