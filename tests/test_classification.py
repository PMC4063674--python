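"""Spike detection, burst grouping, metrics, and category assignment."""

import numpy as np
import pytest

from hcodb.classify import (ActivityLabel, Burst, burst_metrics,
                            classify_instance, detect_spikes, group_bursts,
                            instance_from_sampled, metrics_from_trace)
from hcodb.synth import SyntheticTraceSpec, gen_bursting_trace


def make_burst(times, height=0.03):
    times = np.asarray(times, float)
    return Burst(times, np.full(times.size, -0.02 + height))


def make_metrics(**overrides):
    """A clean realistic-burster metric set, with overridable fields."""
    base = dict(n_bursts=(10, 10), n_bursts_tail=(4, 4),
                period=(10.0, 10.0), period_cv=(0.01, 0.01),
                spike_frequency=(15.0, 15.0), duty_cycle=(60.0, 60.0),
                max_amp_cv=(0.02, 0.02), min_V=(-0.055, -0.055),
                phase=0.5, n_spikes=(120, 120))
    base.update(overrides)
    from hcodb.classify import BurstMetrics

    return BurstMetrics(**base)


class TestDetectSpikes:
    def test_constant_subthreshold_trace_has_no_spikes(self):
        t = np.arange(0, 1, 1e-4)
        times, _ = detect_spikes(t, np.full_like(t, -0.05))
        assert times.size == 0

    def test_oscillation_peaking_below_threshold_has_no_spikes(self):
        t = np.arange(0, 2, 1e-4)
        V = -0.0425 + 0.0175 * np.sin(2 * np.pi * 5 * t)  # peaks at -25 mV
        times, _ = detect_spikes(t, V)
        assert times.size == 0

    def test_three_excursions_give_three_spikes_at_the_peaks(self):
        t = np.arange(0, 3, 1e-4)
        V = np.full_like(t, -0.05)
        for c in (0.5, 1.5, 2.5):
            tri = 0.0 - np.abs(t - c) / 0.003 * 0.05
            V = np.maximum(V, tri)
        times, amps = detect_spikes(t, V)
        assert np.allclose(times, [0.5, 1.5, 2.5], atol=1e-4)
        assert np.allclose(amps, 0.0, atol=1e-3)

    def test_nonmonotone_time_vector_rejected(self):
        with pytest.raises(ValueError):
            detect_spikes(np.array([0.0, 2.0, 1.0]), np.zeros(3))


class TestGroupBursts:
    def test_two_clusters_split_at_the_one_second_gap(self):
        bursts, strays = group_bursts([0.0, 0.2, 0.4, 2.0, 2.2, 2.4])
        assert len(bursts) == 2 and strays.size == 0

    def test_gaps_below_one_second_never_split(self):
        bursts, _ = group_bursts([0.0, 0.9, 1.8, 2.7])
        assert len(bursts) == 1 and bursts[0].n_spikes == 4

    def test_fewer_than_three_spikes_is_not_a_burst(self):
        bursts, strays = group_bursts([0.0, 0.2])
        assert len(bursts) == 0 and strays.size == 2

    def test_unsorted_spikes_rejected(self):
        with pytest.raises(ValueError):
            group_bursts([1.0, 0.5])


class TestBurstProperties:
    def test_middle_spike_of_even_burst_is_ceil_half(self):
        b = make_burst([0.0, 0.1, 0.2, 0.3])  # n=4 -> 2nd spike (1-based)
        assert b.middle == 0.1

    def test_amplitude_cv_uses_height_above_threshold(self):
        b = Burst(np.array([0.0, 0.1, 0.2]),
                  np.array([-0.02 + h for h in (0.02, 0.03, 0.04)]))
        heights = np.array([0.02, 0.03, 0.04])
        assert b.amplitude_cv() == pytest.approx(
            heights.std(ddof=1) / heights.mean())

    def test_burst_invariants_enforced(self):
        with pytest.raises(ValueError):
            make_burst([0.0, 0.1])  # too few spikes
        with pytest.raises(ValueError):
            make_burst([0.0, 0.1, 1.5])  # internal gap >= 1 s


class TestBurstMetrics:
    def test_equal_periods_have_zero_cv(self):
        bursts = [make_burst([t - 0.2, t, t + 0.2]) for t in (10, 20, 30)]
        m = burst_metrics(bursts, bursts, window=(0.0, 40.0))
        assert m.period == (10.0, 10.0)
        assert m.period_cv == (0.0, 0.0)

    def test_duty_cycle_is_burst_share_of_period(self):
        bursts_a = [make_burst(np.linspace(t, t + 6.0, 13)) for t in (5, 15, 25)]
        m = burst_metrics(bursts_a, bursts_a, window=(0.0, 40.0))
        assert m.duty_cycle[0] == pytest.approx(60.0)

    def test_antiphase_pair_has_phase_half(self):
        bursts_a = [make_burst([t - 0.2, t, t + 0.2]) for t in (10, 20, 30)]
        bursts_b = [make_burst([t - 0.2, t, t + 0.2]) for t in (15, 25, 35)]
        m = burst_metrics(bursts_a, bursts_b, window=(0.0, 40.0))
        assert m.phase == pytest.approx(0.5)

    def test_fewer_than_two_bursts_flags_undefined_period(self):
        m = burst_metrics([make_burst([5.0, 5.2, 5.4])], [], window=(0.0, 40.0))
        assert np.isnan(m.period[0]) and np.isnan(m.period[1])

    def test_window_edge_bursts_are_excluded(self):
        """A burst cut by the window edge must not corrupt the period CV."""
        inner = [make_burst([t - 0.2, t, t + 0.2]) for t in (10, 20, 30)]
        truncated = [make_burst([0.0, 0.2, 0.4])]
        m = burst_metrics(truncated + inner, inner, window=(0.0, 40.0))
        assert m.n_bursts[0] == 3
        assert m.period[0] == pytest.approx(10.0)


class TestClassifyInstance:
    def test_realistic_burster(self):
        label = classify_instance(make_metrics(), isolated=True)
        assert label == ActivityLabel("burster", True)

    def test_realistic_hco(self):
        label = classify_instance(make_metrics(), isolated=False)
        assert label == ActivityLabel("HCO", True)

    def test_out_of_phase_pair_is_not_hco(self):
        label = classify_instance(make_metrics(phase=0.30), isolated=False)
        assert label.category != "HCO"

    def test_fast_hco_is_not_realistic(self):
        label = classify_instance(
            make_metrics(period=(4.0, 4.0)), isolated=False)
        assert label == ActivityLabel("HCO", False)

    @pytest.mark.parametrize("field, value, realistic", [
        ("period", (5.0, 5.0), True),     # closed bound: 5 s is realistic
        ("period", (15.0, 15.0), True),
        ("duty_cycle", (50.0, 50.0), True),
        ("spike_frequency", (25.0, 25.0), True),
        ("period", (4.99, 4.99), False),
    ])
    def test_realistic_bounds_are_closed(self, field, value, realistic):
        label = classify_instance(make_metrics(**{field: value}), isolated=False)
        assert label.category == "HCO"
        assert label.realistic is realistic

    @pytest.mark.parametrize("field, value", [
        ("period_cv", (0.05, 0.01)),      # 'less than 0.05' is strict
        ("max_amp_cv", (0.07, 0.02)),     # 'less than 0.07' is strict
        ("phase", 0.45),                  # open interval (0.45, 0.55)
        ("phase", 0.55),
    ])
    def test_regularity_bounds_are_strict(self, field, value):
        label = classify_instance(make_metrics(**{field: value}), isolated=False)
        assert label.category != "HCO"

    def test_isolated_never_hco_and_coupled_never_burster(self):
        assert classify_instance(make_metrics(), isolated=True).category == "burster"
        assert classify_instance(make_metrics(), isolated=False).category == "HCO"

    def test_plateau_silent_failed(self):
        assert classify_instance(
            make_metrics(max_above_threshold=(6.0, 0.0)), isolated=True
        ).category == "plateau"
        assert classify_instance(
            make_metrics(n_bursts=(0, 0), n_bursts_tail=(0, 0), n_spikes=(0, 0),
                         period=(np.nan,) * 2, period_cv=(np.nan,) * 2,
                         spike_frequency=(np.nan,) * 2, duty_cycle=(np.nan,) * 2,
                         max_amp_cv=(np.nan,) * 2, phase=np.nan),
            isolated=True).category == "silent"
        assert classify_instance(make_metrics(ok=False),
                                 isolated=True).category == "failed"

    def test_twin_neurons_on_different_attractors(self):
        m = make_metrics(n_bursts=(10, 0), n_bursts_tail=(4, 0),
                         period=(10.0, np.nan), period_cv=(0.01, np.nan),
                         n_spikes=(120, 700))
        assert classify_instance(m, isolated=True).category == "bistable-suspect"


class TestSyntheticRoundTrip:
    """The classifier must recover generator-prescribed metrics."""

    def test_metrics_recovered_within_tolerance(self):
        spec = SyntheticTraceSpec(period=10.0, duty_cycle=60.0, phase=0.5,
                                  spikes_per_burst=61, amp_cv=0.02)  # 10 Hz
        t, V, truth = gen_bursting_trace(spec, seed=1)
        m = metrics_from_trace(instance_from_sampled(t, V))
        assert m.mean_period == pytest.approx(truth["period"], abs=1e-3)
        assert m.mean_duty_cycle == pytest.approx(truth["duty_cycle"], abs=0.5)
        assert m.phase == pytest.approx(truth["phase"], abs=0.01)
        assert m.mean_spike_frequency == pytest.approx(
            truth["spike_frequency"], rel=0.01)
        assert max(m.max_amp_cv) == pytest.approx(truth["amp_cv"], abs=0.01)
        label = classify_instance(m, isolated=False)
        assert label == ActivityLabel("HCO", True)

    def test_high_amplitude_cv_fails_the_normal_spike_rule(self):
        t, V, _ = gen_bursting_trace(SyntheticTraceSpec(amp_cv=0.10), seed=2)
        m = metrics_from_trace(instance_from_sampled(t, V))
        assert max(m.max_amp_cv) > 0.07
        assert classify_instance(m, isolated=False).category != "HCO"

    def test_subthreshold_trace_is_silent(self):
        spec = SyntheticTraceSpec(amp_mean=-0.005)  # peaks below -20 mV
        t, V, _ = gen_bursting_trace(spec, seed=3)
        m = metrics_from_trace(instance_from_sampled(t, V))
        assert classify_instance(m, isolated=True).category == "silent"

    def test_classification_invariant_to_subthreshold_noise(self):
        spec = SyntheticTraceSpec()
        t, V, _ = gen_bursting_trace(spec, seed=4)
        rng = np.random.default_rng(5)
        noisy = V + rng.uniform(-5e-4, 5e-4, size=V.shape)
        # the noise never reaches the -20 mV threshold from baseline
        lab_clean = classify_instance(
            metrics_from_trace(instance_from_sampled(t, V)), isolated=False)
        lab_noisy = classify_instance(
            metrics_from_trace(instance_from_sampled(t, noisy)), isolated=False)
        assert lab_clean == lab_noisy

    @pytest.mark.parametrize("seed", range(4))
    def test_every_trace_receives_exactly_one_valid_category(self, seed):
        from hcodb.classify import CATEGORIES

        spec = SyntheticTraceSpec(period=6.0 + seed, duty_cycle=40.0 + 5 * seed,
                                  phase=0.3 + 0.05 * seed)
        t, V, _ = gen_bursting_trace(spec, seed=seed)
        m = metrics_from_trace(instance_from_sampled(t, V))
        for isolated in (True, False):
            label = classify_instance(m, isolated=isolated)
            assert label.category in CATEGORIES
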