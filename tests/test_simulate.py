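"""Synthetic generator: distributional correctness, ground truth, determinism."""

import numpy as np
import pytest
from scipy import stats as sps

from spikewell import (
    TrainGenSpec,
    TreatmentEffect,
    apply_effect,
    detect_bursts,
    generate_bursting_train,
    generate_correlated_pair,
    generate_plate,
    generate_poisson_train,
    generate_raw_trace,
)


class TestPoissonTrain:
    def test_zero_rate_empty(self):
        assert generate_poisson_train(0.0, 1800.0, seed=3).n_spikes == 0

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            generate_poisson_train(-1.0, 10.0, seed=0)
        with pytest.raises(ValueError):
            generate_poisson_train(1.0, -10.0, seed=0)

    def test_count_and_isi_distribution(self):
        train = generate_poisson_train(2.0, 1800.0, seed=42)
        lo, hi = sps.poisson.ppf([0.0005, 0.9995], 3600)
        assert lo <= train.n_spikes <= hi
        # ISIs of a homogeneous Poisson process are exponential
        ks = sps.kstest(train.isis(), "expon", args=(0, 1 / 2.0))
        assert ks.pvalue > 0.001

    def test_determinism(self):
        a = generate_poisson_train(2.0, 100.0, seed=5)
        b = generate_poisson_train(2.0, 100.0, seed=5)
        np.testing.assert_array_equal(a.times, b.times)

    def test_count_moments_across_seeds(self):
        # n = 2000 seeds makes the +/-10% variance band a ~3 sigma check
        # (SD(s^2)/sigma^2 = sqrt(2/n) for Poisson counts)
        counts = np.array(
            [generate_poisson_train(2.0, 1800.0, seed=s).n_spikes for s in range(2000)]
        )
        assert abs(counts.mean() - 3600) / 3600 < 0.01
        assert abs(counts.var(ddof=1) - 3600) / 3600 < 0.10

    def test_all_times_in_window_and_increasing(self):
        train = generate_poisson_train(5.0, 60.0, seed=9)
        assert np.all(np.diff(train.times) > 0)
        assert train.times[0] >= 0 and train.times[-1] < 60.0


class TestBurstingTrain:
    def test_zero_burst_rate_reduces_to_poisson(self):
        spec = TrainGenSpec(background_rate=1.5, burst_rate=0.0, duration=600.0, seed=11)
        train, ann = generate_bursting_train(spec)
        ref = generate_poisson_train(1.5, 600.0, seed=11)
        np.testing.assert_array_equal(train.times, ref.times)
        assert ann == []

    def test_burst_count_matches_expectation(self):
        # generated bursts: burst_rate * duration = 10/min * 30 min = 300.
        # The detector additionally drops bursts with < 6 spikes, so the
        # detected count is compared to the truncation-corrected expectation
        # 300 * P(1 + Poisson(7) >= 6); merging losses stay inside the band.
        detected, annotated = [], []
        for s in range(10):
            spec = TrainGenSpec(
                background_rate=0.1,
                burst_rate=10.0,
                spikes_per_burst_mean=8.0,
                intra_burst_isi=0.02,
                duration=1800.0,
                seed=s,
            )
            train, ann = generate_bursting_train(spec)
            detected.append(len(detect_bursts(train)))
            annotated.append(len(ann))
        assert abs(np.mean(annotated) - 300) / 300 < 0.20
        expected_detected = 300 * sps.poisson.sf(4, 7)
        assert abs(np.mean(detected) - expected_detected) / expected_detected < 0.20

    def test_spikes_per_burst_effect_halves_annotated_mean(self):
        base = TrainGenSpec(background_rate=0.0, burst_rate=6.0, spikes_per_burst_mean=20.0, seed=2)
        scaled = apply_effect(base, TreatmentEffect(spikes_per_burst_scale=0.5))
        _, ann_base = generate_bursting_train(base)
        _, ann_scaled = generate_bursting_train(scaled)
        m0 = np.mean([a.n_spikes for a in ann_base])
        m1 = np.mean([a.n_spikes for a in ann_scaled])
        assert m1 / m0 == pytest.approx(0.5, abs=0.05)

    def test_annotations_cover_burst_spikes(self):
        spec = TrainGenSpec(seed=4, duration=300.0)
        train, ann = generate_bursting_train(spec)
        for a in ann:
            assert 0 <= a.onset <= a.offset < spec.duration
            assert a.n_spikes >= 1
        # annotation intervals are disjoint and ordered after merging
        for prev, nxt in zip(ann, ann[1:]):
            assert nxt.onset > prev.offset

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            TrainGenSpec(spikes_per_burst_mean=0.5)
        with pytest.raises(ValueError):
            TrainGenSpec(background_rate=-1)


class TestApplyEffect:
    def test_identity(self):
        spec = TrainGenSpec()
        assert apply_effect(spec, TreatmentEffect()) == spec

    def test_firing_rate_scale_halves_background(self):
        spec = apply_effect(TrainGenSpec(background_rate=2.0), TreatmentEffect(firing_rate_scale=0.5))
        assert spec.background_rate == 1.0

    def test_burst_duration_scale_halves_isi(self):
        spec = apply_effect(
            TrainGenSpec(intra_burst_isi=0.02), TreatmentEffect(burst_duration_scale=0.5)
        )
        assert spec.intra_burst_isi == 0.01
        assert spec.spikes_per_burst_mean == TrainGenSpec().spikes_per_burst_mean

    def test_pure_function(self):
        spec = TrainGenSpec()
        apply_effect(spec, TreatmentEffect(firing_rate_scale=0.1))
        assert spec == TrainGenSpec()


class TestPlate:
    def test_session_and_train_counts(self, small_plate, small_sessions):
        assert len(small_sessions) == small_plate.n_wells * len(small_plate.timepoints)
        assert all(s.n_electrodes == small_plate.electrodes_per_well for s in small_sessions)

    def test_effect_applied_only_from_onset(self, small_plate):
        # treated wells (burst_duration_scale 0.5 from "30min"): annotated burst
        # durations shrink at post-onset timepoints but not at baseline
        _, ann = generate_plate(small_plate, with_annotations=True)
        treated = [w for w, c in small_plate.condition_map.items() if c.label == "tnf"]
        control = [w for w, c in small_plate.condition_map.items() if c.label == "control"]

        def mean_dur(wells, tp):
            durs = [
                a.duration
                for (w, t, _), anns in ann.items()
                if w in wells and t == tp
                for a in anns
            ]
            return np.mean(durs)

        assert mean_dur(treated, "baseline") == pytest.approx(
            mean_dur(control, "baseline"), rel=0.15
        )
        assert mean_dur(treated, "1D") / mean_dur(control, "1D") == pytest.approx(0.5, abs=0.1)

    def test_control_wells_have_no_time_trend(self):
        from spikewell import WellCondition, PlateSpec
        from spikewell.bursts import detect_bursts
        from spikewell.features import electrode_features

        plate = PlateSpec(
            condition_map={f"w{i}": WellCondition() for i in range(6)},
            electrodes_per_well=16,
            timepoints=("baseline", "7D"),
            master_seed=13,
        )
        sessions = generate_plate(plate)
        rates = {"baseline": [], "7D": []}
        for s in sessions:
            for t in s.trains:
                rates[s.timepoint].append(
                    electrode_features(t, detect_bursts(t), s.recording_duration).firing_rate
                )
        m0, m1 = np.mean(rates["baseline"]), np.mean(rates["7D"])
        se = np.std(rates["baseline"], ddof=1) / np.sqrt(len(rates["baseline"]))
        assert abs(m1 - m0) < 4 * se

    def test_plate_determinism(self, small_plate):
        a = generate_plate(small_plate)
        b = generate_plate(small_plate)
        for sa, sb in zip(a, b):
            for ta, tb in zip(sa.trains, sb.trains):
                np.testing.assert_array_equal(ta.times, tb.times)


class TestCorrelatedPair:
    def test_identity_case(self):
        base = generate_poisson_train(2.0, 100.0, seed=1)
        _, twin = generate_correlated_pair(base, 0.0, 0.0, seed=2)
        np.testing.assert_array_equal(twin.times, base.times)

    def test_thinning_halves_count(self):
        base = generate_poisson_train(5.0, 1000.0, seed=1)
        _, twin = generate_correlated_pair(base, 0.0, 0.5, seed=2)
        assert twin.n_spikes / base.n_spikes == pytest.approx(0.5, abs=0.05)

    def test_invalid_params(self):
        base = generate_poisson_train(2.0, 10.0, seed=1)
        with pytest.raises(ValueError):
            generate_correlated_pair(base, -1.0, 0.0, seed=0)
        with pytest.raises(ValueError):
            generate_correlated_pair(base, 0.0, 1.0, seed=0)


class TestRawTrace:
    def test_empty_train_pure_noise_sd(self):
        from spikewell import SpikeTrain

        empty = SpikeTrain("e0", np.empty(0), 60.0)
        trace = generate_raw_trace(empty, noise_sd=1.0, fs=10000.0, seed=3)
        assert trace.size == 600000
        assert np.std(trace) == pytest.approx(1.0, rel=0.02)
        assert np.mean(trace) == pytest.approx(0.0, abs=0.02)

    def test_zero_amplitude_identical_to_noise(self):
        from spikewell import SpikeTrain

        train = SpikeTrain("e0", np.array([1.0, 2.0]), 10.0)
        empty = SpikeTrain("e0", np.empty(0), 10.0)
        a = generate_raw_trace(train, spike_amplitude=0.0, noise_sd=1.0, seed=5)
        b = generate_raw_trace(empty, spike_amplitude=8.0, noise_sd=1.0, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_waveform_peak_at_timestamp(self):
        from spikewell import SpikeTrain

        train = SpikeTrain("e0", np.array([0.5]), 1.0)
        trace = generate_raw_trace(train, noise_sd=0.0, amplitude_volts=3.0, fs=10000.0, seed=0)
        assert trace.min() == pytest.approx(-3.0)
        assert np.argmin(trace) == 5000
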