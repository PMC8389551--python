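"""Single-neuron dynamics: leak, latency curve, spike scheduling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spikelat.neuron import (
    DEFAULT_INPUT_WEIGHT,
    DEFAULT_LATENCY_SHAPE,
    LIFLNeuron,
    NeuronParams,
    NeuronState,
    SpikeEvent,
    apply_decay,
    calibrate_latency_shape,
    latency_from_state,
    receive_pulse,
    single_pulse_response,
    step,
)


class TestDecay:
    def test_resting_potential_is_a_fixed_point(self, default_params):
        st_ = NeuronState(v_m=default_params.v_rest)
        out = apply_decay(st_, default_params, 123.4)
        assert out.v_m == pytest.approx(default_params.v_rest)

    def test_closed_form_relaxation(self, default_params):
        # V = -60 mV relaxing for 50 ms at 0.02/ms: -70 + 10 e^-1
        out = apply_decay(NeuronState(v_m=-60.0), default_params, 50.0)
        assert out.v_m == pytest.approx(-70.0 + 10.0 * math.exp(-1.0), abs=1e-9)

    def test_zero_dt_is_identity(self, default_params):
        st_ = NeuronState(v_m=-61.5, i_syn=40.0)
        out = apply_decay(st_, default_params, 0.0)
        assert out.v_m == st_.v_m and out.i_syn == st_.i_syn

    def test_negative_dt_rejected(self, default_params):
        with pytest.raises(ValueError):
            apply_decay(NeuronState(), default_params, -0.1)

    def test_synaptic_current_decays_with_its_own_constant(self, default_params):
        out = apply_decay(NeuronState(v_m=-70.0, i_syn=100.0), default_params, 2.0)
        assert out.i_syn == pytest.approx(100.0 * math.exp(-1.0))


class TestLatencyCurve:
    def test_limits(self, default_params):
        eps = 1e-9
        assert latency_from_state(default_params.v_th + eps, default_params) == pytest.approx(
            default_params.sl_max, abs=1e-6
        )
        assert latency_from_state(1e6, default_params) < 1e-3

    def test_rejects_subthreshold_potential(self, default_params):
        with pytest.raises(ValueError):
            latency_from_state(default_params.v_th, default_params)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.floats(min_value=1e-6, max_value=200.0), st.floats(min_value=1e-6, max_value=200.0))
    def test_strictly_monotone_decreasing(self, default_params, a, b):
        va, vb = default_params.v_th + a, default_params.v_th + b
        la = latency_from_state(va, default_params)
        lb = latency_from_state(vb, default_params)
        if a < b:
            assert la > lb
        elif a > b:
            assert la < lb

    def test_default_pulse_evokes_half_maximum_latency(self, default_params):
        t_cross, t_spike = single_pulse_response(DEFAULT_INPUT_WEIGHT)
        assert t_spike is not None
        assert t_spike - t_cross == pytest.approx(12.5, abs=1e-6)

    def test_shipped_shape_matches_its_calibration(self):
        assert calibrate_latency_shape(DEFAULT_INPUT_WEIGHT) == pytest.approx(
            DEFAULT_LATENCY_SHAPE, rel=1e-7
        )


class TestPulseIntegration:
    def test_zero_weight_pulse_changes_nothing(self, default_params):
        st_ = NeuronState(v_m=-65.0, i_syn=10.0)
        out = receive_pulse(st_, default_params, SpikeEvent(0, 1.0, 0.0))
        assert out.v_m == st_.v_m and out.i_syn == st_.i_syn

    def test_intrinsic_excitability_scales_the_depolarisation(self, default_params):
        # same sub-threshold pulse, IE_p = 2 reaches a strictly higher peak
        peaks = {}
        for ie in (1.0, 2.0):
            state = NeuronState(v_m=default_params.v_rest, ie_p=ie)
            state = receive_pulse(state, default_params, SpikeEvent(0, 0.0, 400.0))
            vs = []
            for k in range(80):
                state, _ = step(state, default_params, [], k * 0.1, 0.1)
                vs.append(state.v_m)
            peaks[ie] = max(vs)
        assert peaks[2.0] > peaks[1.0]
        assert peaks[2.0] < default_params.v_th  # still sub-threshold: no spike

    def test_subthreshold_pulse_never_schedules_a_spike(self, default_params):
        neuron = LIFLNeuron()
        spikes = neuron.run([SpikeEvent(0, 1.0, 500.0)], 100.0)
        assert spikes == []
        assert neuron.state.mode == "under"

    def test_pulse_during_refractory_period_is_discarded(self, default_params):
        st_ = NeuronState(v_m=default_params.v_rest, mode="refractory", last_spike_time=0.0)
        out = receive_pulse(st_, default_params, SpikeEvent(0, 0.5, 1000.0))
        assert out.i_syn == 0.0


class TestSpikeScheduling:
    def test_spike_emitted_at_the_scheduled_latency(self):
        t_cross, t_spike = single_pulse_response(DEFAULT_INPUT_WEIGHT)
        neuron = LIFLNeuron()
        spikes = neuron.run([SpikeEvent(0, 0.0, DEFAULT_INPUT_WEIGHT)], 60.0, dt=0.1)
        assert len(spikes) == 1
        assert spikes[0] == pytest.approx(t_spike, abs=1e-6)

    def test_step_size_does_not_move_spike_times(self):
        # piecewise-analytic integration: coarse and fine grids agree far
        # within the 0.1 ms contract
        times = {}
        for dt in (0.1, 0.001):
            neuron = LIFLNeuron()
            spikes = neuron.run([SpikeEvent(0, 0.3, DEFAULT_INPUT_WEIGHT)], 50.0, dt=dt)
            times[dt] = spikes[0]
        assert abs(times[0.1] - times[0.001]) < 0.1

    def test_second_excitatory_pulse_advances_the_spike(self):
        base = LIFLNeuron().run([SpikeEvent(0, 0.0, DEFAULT_INPUT_WEIGHT)], 60.0)[0]
        boosted = LIFLNeuron().run(
            [SpikeEvent(0, 0.0, DEFAULT_INPUT_WEIGHT), SpikeEvent(1, 5.0, DEFAULT_INPUT_WEIGHT)],
            60.0,
        )[0]
        assert boosted < base

    def test_inhibition_below_threshold_cancels_the_scheduled_spike(self):
        spikes = LIFLNeuron().run(
            [SpikeEvent(0, 0.0, DEFAULT_INPUT_WEIGHT), SpikeEvent(1, 4.0, -3 * DEFAULT_INPUT_WEIGHT)],
            80.0,
        )
        assert spikes == []

    def test_interspike_intervals_respect_the_refractory_period(self, default_params):
        events = [SpikeEvent(0, t, DEFAULT_INPUT_WEIGHT) for t in np.arange(0.0, 60.0, 0.7)]
        spikes = LIFLNeuron().run(events, 100.0)
        assert len(spikes) >= 2
        assert np.all(np.diff(spikes) >= default_params.refractory - 1e-9)

    def test_silent_neuron_stays_at_rest_for_ten_seconds(self, default_params):
        neuron = LIFLNeuron()
        spikes = neuron.run([], 10_000.0, dt=1.0)
        assert spikes == []
        assert neuron.state.v_m <= default_params.v_rest + 1e-9


class TestParamValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"v_rest": -50.0, "v_th": -60.0},
            {"sl_max": 0.0},
            {"decay_rate": -1.0},
            {"syn_tau": 0.0},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            NeuronParams(**kwargs)

    def test_negative_event_time_rejected(self):
        with pytest.raises(ValueError):
            SpikeEvent(0, -1.0, 10.0)
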