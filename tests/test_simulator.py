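"""Synthetic recording generator: design counts, determinism, effect sizes."""

import dataclasses

import numpy as np
import pytest

from lrpnet.simulate import (
    ALL_POSITIONS,
    CONCENTRATIONS_MM,
    SCREENING_CONCENTRATIONS_MM,
    LeafLevel,
    PositionLabel,
    Recording,
    Region,
    SimulatorConfig,
    default_position_effect,
    read_recording_csv,
    reduced_config,
    load_recordings_hdf5,
    save_recordings_hdf5,
    simulate_five_gradient_study,
    simulate_recording,
    simulate_screening_study,
    write_recording_csv,
)

TOP_BASAL = PositionLabel(LeafLevel.TOP, Region.BASAL)


class TestPositionLabels:
    def test_nine_distinct_positions_with_stable_keys(self):
        keys = {p.key() for p in ALL_POSITIONS}
        assert len(ALL_POSITIONS) == 9
        assert len(keys) == 9
        for p in ALL_POSITIONS:
            assert PositionLabel.from_key(p.key()) == p

    def test_default_position_effect_in_unit_interval_max_at_top_basal(self):
        eff = default_position_effect()
        assert all(0.0 <= v <= 1.0 for v in eff.values())
        assert max(eff, key=eff.get) == TOP_BASAL


class TestSimulateRecording:
    def test_length_is_rate_times_duration(self, short_config):
        rec = simulate_recording(short_config, "p", TOP_BASAL, 0, seed=0)
        assert len(rec.values) == 1800  # 60 s at 30 Hz
        full = dataclasses.replace(short_config, duration_s=7200.0)
        assert full.n_samples == 216_000

    def test_all_stochastic_terms_disabled_gives_constant_zero(self):
        cfg = reduced_config(
            duration_s=60.0, noise_sd_mV=0.0, drift_amplitude_mV=0.0,
            plant_effect_sd=0.0, baseline_mV_per_mM=0.0, sensor_noise_sd_mV=0.0,
        )
        rec = simulate_recording(cfg, "p", TOP_BASAL, 400, seed=3)
        np.testing.assert_array_equal(rec.values, 0.0)

    def test_identical_inputs_reproduce_identical_values(self, short_config):
        a = simulate_recording(short_config, "p", TOP_BASAL, 200, seed=11)
        b = simulate_recording(short_config, "p", TOP_BASAL, 200, seed=11)
        np.testing.assert_array_equal(a.values, b.values)
        c = simulate_recording(short_config, "p", TOP_BASAL, 200, seed=12)
        assert not np.array_equal(a.values, c.values)

    def test_plant_offset_shared_across_positions_within_seed(self):
        cfg = reduced_config(
            duration_s=60.0, noise_sd_mV=0.0, drift_amplitude_mV=0.0,
            baseline_mV_per_mM=0.0, sensor_noise_sd_mV=0.0, plant_effect_sd=1.0,
        )
        recs = [
            simulate_recording(cfg, "plant-x", pos, 0, seed=5)
            for pos in ALL_POSITIONS[:3]
        ]
        offsets = {float(r.values[0]) for r in recs}
        assert len(offsets) == 1

    def test_baseline_shift_matches_configured_treatment_effect(self):
        # sample-mean oracle over >= 20 seeds: configured shift is
        # 0.01 mV/mM * 400 mM * 1.0 = 4 mV between the extreme classes
        cfg = reduced_config(duration_s=60.0, baseline_mV_per_mM=0.01,
                             plant_effect_sd=0.0)
        diffs = []
        for seed in range(20):
            hi = simulate_recording(cfg, "p", TOP_BASAL, 400, seed=seed)
            lo = simulate_recording(cfg, "p", TOP_BASAL, 0, seed=seed)
            diffs.append(hi.values.mean() - lo.values.mean())
        assert np.mean(diffs) == pytest.approx(4.0, abs=0.4)

    def test_standardized_effect_size_within_15pct_of_configured(self):
        # drift disabled, envelope/frequency effects off: SMD between the
        # extreme classes is baseline*dc/noise-like SD, estimated over
        # 20 seeds of sample values
        cfg = reduced_config(
            duration_s=60.0, baseline_mV_per_mM=0.01, drift_amplitude_mV=0.0,
            plant_effect_sd=0.0, envelope_gain_per_mM=0.0,
            fluctuation_freq_gain_per_mM=0.0, sensor_noise_sd_mV=0.0,
        )
        his, los = [], []
        for seed in range(20):
            his.append(simulate_recording(cfg, "p", TOP_BASAL, 400, seed=seed).values)
            los.append(simulate_recording(cfg, "p", TOP_BASAL, 0, seed=seed).values)
        hi, lo = np.concatenate(his), np.concatenate(los)
        pooled_sd = np.sqrt((hi.var() + lo.var()) / 2)
        smd = (hi.mean() - lo.mean()) / pooled_sd
        configured = 0.01 * 400 / cfg.noise_sd_mV
        assert smd == pytest.approx(configured, rel=0.15)

    def test_unknown_concentration_rejected(self, short_config):
        with pytest.raises(ValueError, match="concentration"):
            simulate_recording(short_config, "p", TOP_BASAL, 150, seed=0)

    def test_non_integer_sample_count_rejected(self):
        with pytest.raises(ValueError, match="not a positive integer"):
            SimulatorConfig(sampling_rate_hz=30.0, duration_s=10.01)

    def test_position_multiplier_outside_unit_interval_rejected(self):
        eff = default_position_effect()
        eff[TOP_BASAL] = 1.5
        with pytest.raises(ValueError, match="multiplier"):
            SimulatorConfig(position_effect=eff)


class TestStudyDesigns:
    def test_screening_study_enumerates_54_unique_conditions(self, short_config):
        recs = simulate_screening_study(short_config, seed=0)
        assert len(recs) == 54  # 3 plants x 9 positions x 2 concentrations
        triples = {(r.plant_id, r.position, r.concentration_mM) for r in recs}
        assert len(triples) == 54
        assert {r.concentration_mM for r in recs} == set(SCREENING_CONCENTRATIONS_MM)

    def test_screening_study_reproducible_across_calls(self, short_config):
        a = simulate_screening_study(short_config, seed=7)
        b = simulate_screening_study(short_config, seed=7)
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.values, rb.values)

    def test_five_gradient_study_design(self, short_config):
        recs = simulate_five_gradient_study(short_config, TOP_BASAL, seed=0)
        assert len(recs) == 15  # 3 plants x 5 concentrations
        assert all(r.position == TOP_BASAL for r in recs)
        assert {r.concentration_mM for r in recs} == set(CONCENTRATIONS_MM)

    def test_between_class_separation_largest_at_top_basal(self):
        # empirical separation of raw window means (0 vs 100 mM) across
        # the nine candidate positions, pooled over seeds: the default
        # position-effect map must make top-basal the strict maximum
        cfg = reduced_config(duration_s=300.0, plant_effect_sd=0.0)
        sep = {}
        for pos in ALL_POSITIONS:
            means = {0: [], 100: []}
            for conc in (0, 100):
                for seed in range(10):
                    rec = simulate_recording(cfg, "p", pos, conc, seed=seed)
                    w = rec.values.reshape(-1, 900).mean(axis=1)
                    means[conc].extend(w)
            a, b = np.array(means[0]), np.array(means[100])
            pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2)
            sep[pos] = (b.mean() - a.mean()) / pooled
        best = max(sep, key=sep.get)
        assert best == TOP_BASAL
        second = max(v for k, v in sep.items() if k != TOP_BASAL)
        assert sep[TOP_BASAL] > second

    def test_class_means_monotone_in_concentration(self):
        # positive baseline slope: class-conditional means must rise with
        # concentration (averaged over seeds)
        cfg = reduced_config(duration_s=60.0, plant_effect_sd=0.0)
        means = []
        for conc in CONCENTRATIONS_MM:
            vals = [
                simulate_recording(cfg, "p", TOP_BASAL, conc, seed=s).values.mean()
                for s in range(20)
            ]
            means.append(np.mean(vals))
        assert all(a < b for a, b in zip(means, means[1:]))


class TestRecordingIO:
    def test_csv_roundtrip(self, short_config, tmp_path):
        rec = simulate_recording(short_config, "p1", TOP_BASAL, 100, seed=2)
        path = tmp_path / "rec.csv"
        write_recording_csv(rec, path)
        back = read_recording_csv(path)
        np.testing.assert_allclose(back.values, rec.values, atol=1e-10)
        assert back.position == rec.position
        assert back.concentration_mM == 100

    def test_hdf5_roundtrip_preserves_values_and_metadata(self, short_config, tmp_path):
        recs = simulate_five_gradient_study(short_config, TOP_BASAL, seed=1)
        path = tmp_path / "study.h5"
        save_recordings_hdf5(recs, path)
        back = load_recordings_hdf5(path)
        assert len(back) == len(recs)
        np.testing.assert_array_equal(back[0].values, recs[0].values)
        assert {r.concentration_mM for r in back} == set(CONCENTRATIONS_MM)
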