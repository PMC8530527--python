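"""Tests of the two-state sensor: exact oracles, chain invariants, protocol."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reafference import (
    ADAPTING_SENSOR,
    NONADAPTING_SENSOR,
    SensorParams,
    SimulationGrid,
    calibrate_inhibition,
    classify_parameter_set,
    enumerate_expected_spikes,
    expected_session_counts,
    make_stimulus,
    simulate_session,
    simulate_session_mc,
    simulate_sweep,
    transition_probs,
)
from reafference.markov_sensor import _simulate_chain, expected_cycle_counts


def brute_force_expected_spikes(p_b, p_c, p0_sensitive=1.0):
    """Independent oracle: exact expectation by enumerating all state paths."""
    n = len(p_b)
    total = 0.0
    # state: 1 = sensitive, 0 = insensitive; enumerate spike/regen outcomes
    paths = [(1.0 * p0_sensitive, True, 0), (1.0 - p0_sensitive, False, 0)]
    for t in range(n):
        nxt = []
        for prob, sens, spikes in paths:
            if prob == 0:
                continue
            if sens:
                nxt.append((prob * p_b[t], False, spikes + 1))
                nxt.append((prob * (1 - p_b[t]), True, spikes))
            else:
                nxt.append((prob * p_c, True, spikes))
                nxt.append((prob * (1 - p_c), False, spikes))
        paths = nxt
    return sum(prob * spikes for prob, sens, spikes in paths)


class TestStimulus:
    def test_period_steps_and_peak(self, grid20):
        stim = make_stimulus(20.0, grid20)
        assert stim.period_steps == 100
        assert stim.values[25] == pytest.approx(1.0)  # quarter period
        assert stim.values.min() == 0.0 and stim.values.max() == pytest.approx(1.0)

    def test_unrectified_has_negative_lobe(self, grid20):
        stim = make_stimulus(20.0, grid20, rectified=False)
        assert stim.values.min() == pytest.approx(-1.0)

    def test_nyquist_error(self, grid20):
        with pytest.raises(ValueError, match="Nyquist"):
            make_stimulus(1000.0, grid20)

    def test_grid_validation(self):
        with pytest.raises(ValueError):
            SimulationGrid(stimulus_frequency=20.0, sampling_rate=100.0)


class TestTransitionProbs:
    def test_hand_evaluated_spontaneous(self, grid20):
        # (0 + 1 * 40) * 0.01 = 0.4
        tm = transition_probs(SensorParams(k1=0.0, k3=1.0, s0=40.0), 0.0, grid20)
        assert tm.p_b == pytest.approx(0.4)
        assert tm.p_a == pytest.approx(0.6)

    def test_zero_drive(self, grid20):
        tm = transition_probs(SensorParams(k1=5.0, k3=1.0, s0=0.0), 0.0, grid20)
        assert tm.p_b == 0.0

    def test_regeneration_clipping(self, grid20):
        tm = transition_probs(SensorParams(k1=1.0, k3=200.0, s0=1.0), 0.5, grid20)
        assert tm.p_c == 1.0 and tm.clipped

    @given(
        k1=st.floats(0, 100), k2=st.floats(0, 1), k3=st.floats(0.01, 500),
        s0=st.floats(0, 500), s=st.floats(0, 1),
    )
    @settings(max_examples=200, deadline=None)
    def test_rows_sum_to_one_and_bounded(self, k1, k2, k3, s0, s):
        grid = SimulationGrid(stimulus_frequency=20.0)
        tm = transition_probs(SensorParams(k1=k1, k3=k3, s0=s0, k2=k2), s, grid)
        arr = tm.as_array()
        assert np.all(arr >= 0) and np.all(arr <= 1)
        assert np.allclose(arr.sum(axis=1), 1.0)


class TestSweep:
    def test_silent_sensor_never_spikes(self, grid20):
        stim = make_stimulus(20.0, grid20)
        res = simulate_sweep(SensorParams(k1=0.0, k3=1.0, s0=0.0), stim, grid20, seed=0)
        assert res.spike_times.size == 0

    def test_empty_stimulus_error(self, grid20):
        from reafference import StimulusTrace

        empty = StimulusTrace(values=np.empty(0), period_steps=100, frequency=20.0)
        with pytest.raises(ValueError, match="empty"):
            simulate_sweep(NONADAPTING_SENSOR, empty, grid20)

    def test_schedule_length_mismatch(self, grid20):
        stim = make_stimulus(20.0, grid20)
        with pytest.raises(ValueError, match="schedule"):
            simulate_sweep(NONADAPTING_SENSOR, stim, grid20, np.ones(3))

    def test_deterministic_given_seed(self, grid20):
        stim = make_stimulus(20.0, grid20)
        a = simulate_sweep(ADAPTING_SENSOR, stim, grid20, seed=7)
        b = simulate_sweep(ADAPTING_SENSOR, stim, grid20, seed=7)
        assert np.array_equal(a.spike_times, b.spike_times)

    def test_no_spike_while_insensitive(self, grid20):
        stim = make_stimulus(20.0, grid20)
        res = simulate_sweep(
            SensorParams(k1=4.0, k3=0.5, s0=20.0), stim, grid20, seed=3,
            record_states=True,
        )
        assert res.spike_times.size > 0
        assert np.all(res.states[res.spike_steps] == 1)
        assert np.all(np.diff(res.spike_times) > 0)

    def test_instant_regeneration_bernoulli_mean(self, rng):
        # p_c = 1: Bernoulli(p) trials separated by the one-step refractory
        # spent insensitive, so the exact mean is n * p / (1 + p) -> n * p
        # in the small-p limit.
        p, n_steps, n_rep = 0.05, 200, 4000
        spikes = _simulate_chain(np.full(n_steps, p), 1.0, n_rep, rng)
        counts = spikes.sum(axis=1)
        expect = n_steps * p / (1 + p)
        se = counts.std(ddof=1) / np.sqrt(n_rep)
        assert abs(counts.mean() - expect) < 3 * se

    def test_constant_drive_stationary_rate(self, rng):
        # long-run spikes/step -> p_b p_c / (p_b + p_c)
        p_b, p_c, n_steps, n_rep = 0.08, 0.03, 3000, 300
        spikes = _simulate_chain(np.full(n_steps, p_b), p_c, n_rep, rng)
        tail = spikes[:, 500:]  # discard transient
        counts = tail.sum(axis=1)
        expect = p_b * p_c / (p_b + p_c) * tail.shape[1]
        se = counts.std(ddof=1) / np.sqrt(n_rep)
        assert abs(counts.mean() - expect) < 3 * se


class TestEnumerationOracle:
    def test_single_step(self, grid20):
        stim = make_stimulus(20.0, grid20)
        params = SensorParams(k1=0.0, k3=1.0, s0=30.0)  # p_b = 0.3
        assert enumerate_expected_spikes(params, stim, 1, grid20) == pytest.approx(0.3)

    def test_two_steps_hand_propagation(self):
        # p_b = 0.5, p_c ~ 0: 0.5 + 0.5*0.5 = 0.75
        val = brute_force_expected_spikes([0.5, 0.5], 0.0)
        assert val == pytest.approx(0.75)

    def test_cap_error(self, grid20):
        stim = make_stimulus(20.0, grid20)
        with pytest.raises(ValueError, match="cap"):
            enumerate_expected_spikes(NONADAPTING_SENSOR, stim, 17, grid20)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_paths(self, seed, grid20):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 11))
        k1, k3, s0 = rng.uniform(0.1, 5, 3)
        params = SensorParams(k1=k1, k3=k3 * 20, s0=s0 * 20)
        stim = make_stimulus(20.0, grid20)
        lam = grid20.lambda_star
        p_b = np.clip((params.k1 * stim.values[:n] + params.s0) * lam, 0, 1)
        p_c = min(params.k3 * lam, 1)
        expected = brute_force_expected_spikes(p_b, p_c)
        got = enumerate_expected_spikes(params, stim, n, grid20)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_monte_carlo_agrees_with_enumeration(self, grid20, rng):
        params = SensorParams(k1=3.0, k3=8.0, s0=25.0)
        stim = make_stimulus(20.0, grid20)
        n = 16
        exact = enumerate_expected_spikes(params, stim, n, grid20)
        lam = grid20.lambda_star
        p_b = np.clip((params.k1 * stim.values[:n] + params.s0) * lam, 0, 1)
        spikes = _simulate_chain(p_b, min(params.k3 * lam, 1), 100_000, rng)
        counts = spikes.sum(axis=1)
        se = counts.std(ddof=1) / np.sqrt(counts.size)
        assert abs(counts.mean() - exact) < 3 * se


class TestSession:
    def test_all_burn_in_when_two_sweeps(self, grid20):
        ses = simulate_session(NONADAPTING_SENSOR, grid20, n_sweeps=2, seed=0)
        assert ses.burn_in.all()
        assert ses.sweep_counts().size == 0

    def test_adapting_first_cycle_exceeds_last(self, grid20):
        ses = simulate_session_mc(ADAPTING_SENSOR, grid20, 2000, seed=2)
        cycles = ses.cycle_counts().mean(axis=0)
        assert cycles[0] > cycles[-1]

    def test_classification_of_reference_sets(self, grid20):
        assert classify_parameter_set(ADAPTING_SENSOR, grid20) == "adapting"
        assert classify_parameter_set(NONADAPTING_SENSOR, grid20) == "nonadapting"

    def test_instant_regeneration_is_nonadapting(self, grid20):
        params = SensorParams(k1=4.0, k3=500.0, s0=10.0)
        assert classify_parameter_set(params, grid20) == "nonadapting"

    def test_undriven_sensor_error(self, grid20):
        with pytest.raises(ValueError, match="undriven"):
            classify_parameter_set(SensorParams(k1=0.0, k3=1.0, s0=0.0), grid20)

    def test_rebound_after_inhibition_release(self, grid20):
        # inhibition only (no stimulus), requil half releases k2 back to 1:
        # the first post-release window beats the uninhibited baseline rate
        params = ADAPTING_SENSOR
        ses = simulate_session_mc(
            params, grid20, 1000, seed=4, k2=0.001, with_stimulus=False,
            requil_mode="release",
        )
        base = simulate_session_mc(
            params, grid20, 1000, seed=5, k2=1.0, with_stimulus=False,
            requil_mode="release",
        )
        window = grid20.period_steps * 2  # first 2 wavelengths after release
        post = ses.spikes[~ses.burn_in, ses.stim_steps : ses.stim_steps + window]
        ref = base.spikes[~base.burn_in, ses.stim_steps : ses.stim_steps + window]
        assert post.sum(axis=1).mean() > ref.sum(axis=1).mean()

    def test_spike_table_layout(self, grid20):
        ses = simulate_session(NONADAPTING_SENSOR, grid20, n_sweeps=4, seed=0)
        tab = ses.spike_table("c1")
        assert set(tab.columns) == {"cell_id", "sweep", "time_s", "step", "segment", "burn_in"}
        assert set(tab["segment"]).issubset({"stim", "requil"})
        assert tab.loc[tab.sweep < 2, "burn_in"].eq(1).all()


class TestCalibration:
    def test_no_inhibition_target(self, grid20):
        assert calibrate_inhibition(NONADAPTING_SENSOR, grid20, 1.0) == 1.0

    def test_invalid_target(self, grid20):
        with pytest.raises(ValueError):
            calibrate_inhibition(NONADAPTING_SENSOR, grid20, 0.0)

    def test_instant_regeneration_rate_linear_in_k2(self, grid20):
        # with p_c = 1 and p_b << 1 the spontaneous rate is proportional to
        # k2 * s0 (up to the one-step refractory correction 1/(1 + p_b)),
        # so the calibrated k2 approaches the target ratio itself
        params = SensorParams(k1=0.0, k3=500.0, s0=1.0)
        for target in (0.25, 0.5, 0.8):
            k2 = calibrate_inhibition(params, grid20, target, method="stationary")
            assert k2 == pytest.approx(target, rel=0.02)
            k2e = calibrate_inhibition(params, grid20, target, method="expected")
            assert k2e == pytest.approx(target, rel=0.03)

    @pytest.mark.parametrize("method", ["expected", "session"])
    def test_calibrated_suppression_is_ninety_percent(self, grid20, method):
        k2 = calibrate_inhibition(
            NONADAPTING_SENSOR, grid20, 0.1, seed=11, method=method
        )
        base = expected_session_counts(NONADAPTING_SENSOR, grid20, 1.0)[-1]
        inhib = expected_session_counts(NONADAPTING_SENSOR, grid20, k2)[-1]
        assert 100 * (1 - inhib / base) == pytest.approx(90.0, abs=2.0)

    def test_spontaneous_rate_monotone_in_k2(self, grid20):
        vals = [
            expected_session_counts(ADAPTING_SENSOR, grid20, k2)[-1]
            for k2 in np.linspace(0.0, 1.0, 9)
        ]
        assert np.all(np.diff(vals) >= 0)
        vals = [
            expected_session_counts(NONADAPTING_SENSOR, grid20, k2)[-1]
            for k2 in np.linspace(0.0, 1.0, 9)
        ]
        assert np.all(np.diff(vals) >= 0)

    def test_session_determinism(self, grid20):
        a = simulate_session(ADAPTING_SENSOR, grid20, 5, seed=9, n_chains=3)
        b = simulate_session(ADAPTING_SENSOR, grid20, 5, seed=9, n_chains=3)
        assert np.array_equal(a.spikes, b.spikes)


class TestExpectedCycleCounts:
    def test_flat_for_fast_regeneration(self, grid20):
        cycles = expected_cycle_counts(SensorParams(k1=1.0, k3=400.0, s0=10.0), grid20)
        assert cycles[1:].max() - cycles[1:].min() < 1e-6 * cycles[1:].mean()

    def test_declining_for_adapting_set(self, grid20):
        cycles = expected_cycle_counts(ADAPTING_SENSOR, grid20)
        assert cycles[0] > 5 * cycles[-1]
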