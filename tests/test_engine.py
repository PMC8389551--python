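"""Network engine: agreement with the analytic neuron, determinism, gating."""

import numpy as np
import pytest

from spikelat.engine import ADEX, LIFL, AdExParams, Network, _adex_steady_state
from spikelat.neuron import DEFAULT_INPUT_WEIGHT, LIFLNeuron, NeuronParams, SpikeEvent
from spikelat.plasticity import PlasticityParams


def _single_lifl(dt=0.1):
    return Network(
        model=np.array([LIFL], dtype=np.int8),
        edges=(np.empty(0, int), np.empty(0, int), np.empty(0), np.empty(0)),
        dt=dt,
    )


class TestGridVsAnalytic:
    def test_single_pulse_spike_time_matches_the_analytic_path(self):
        analytic = LIFLNeuron().run([SpikeEvent(0, 5.0, DEFAULT_INPUT_WEIGHT)], 60.0)[0]
        net = _single_lifl()
        res = net.run([(0, 5.0, DEFAULT_INPUT_WEIGHT)], 60.0)
        assert res.spike_times.size == 1
        assert abs(res.spike_times[0] - analytic) < 0.1

    def test_coarse_and_fine_grids_agree_within_contract(self):
        spikes = {}
        for dt in (0.1, 0.001):
            res = _single_lifl(dt).run([(0, 2.0, DEFAULT_INPUT_WEIGHT)], 50.0)
            spikes[dt] = res.spike_times[0]
        assert abs(spikes[0.1] - spikes[0.001]) < 0.1

    def test_subthreshold_input_stays_silent(self):
        res = _single_lifl().run([(0, 1.0, 500.0)], 100.0)
        assert res.spike_times.size == 0


class TestPropagation:
    def test_edge_delay_is_honoured(self):
        # neuron 0 drives neuron 1 through a strong edge with 1 ms delay
        net = Network(
            model=np.array([LIFL, LIFL], dtype=np.int8),
            edges=(np.array([0]), np.array([1]), np.array([3 * DEFAULT_INPUT_WEIGHT]), np.array([1.0])),
        )
        res = net.run([(0, 0.0, DEFAULT_INPUT_WEIGHT)], 80.0)
        t0 = res.spike_times[res.spike_ids == 0]
        t1 = res.spike_times[res.spike_ids == 1]
        assert t0.size == 1 and t1.size == 1
        assert t1[0] > t0[0] + 1.0  # delay plus downstream latency

    def test_indegree_audit(self):
        net = Network(
            model=np.array([LIFL] * 4, dtype=np.int8),
            edges=(
                np.array([0, 1, 2]),
                np.array([3, 3, 3]),
                np.ones(3),
                np.ones(3),
            ),
        )
        assert net.indegree([3], [0, 1, 2])[0] == 3
        assert net.indegree([0], [1, 2, 3])[0] == 0


class TestNoiseAndDeterminism:
    def test_identical_seeds_produce_identical_records(self):
        def run_once():
            net = Network(
                model=np.array([ADEX] * 10, dtype=np.int8),
                edges=(np.empty(0, int), np.empty(0, int), np.empty(0), np.empty(0)),
                noise_rate=np.full(10, 2000.0),
                noise_weight=np.full(10, 30.0),
                bias=np.full(10, 520.0),
            )
            res = net.run(None, 300.0, rng=np.random.default_rng(99))
            return res.spike_times, res.spike_ids

        a_t, a_i = run_once()
        b_t, b_i = run_once()
        assert np.array_equal(a_t, b_t) and np.array_equal(a_i, b_i)
        assert a_t.size > 0  # the operating point actually fires

    def test_steady_state_initialisation_is_quiescent_below_rheobase(self):
        net = Network(
            model=np.array([ADEX], dtype=np.int8),
            edges=(np.empty(0, int), np.empty(0, int), np.empty(0), np.empty(0)),
            bias=np.array([400.0]),
        )
        res = net.run(None, 500.0)
        assert res.spike_times.size == 0

    def test_steady_state_solver_finds_a_subthreshold_fixed_point(self):
        q = AdExParams()
        v_star, w_star = _adex_steady_state(q, 300.0)
        assert q.e_l < v_star < q.v_t
        assert w_star == pytest.approx(q.a * (v_star - q.e_l))


class TestPlasticityGating:
    def _ring(self):
        src = np.array([0, 1])
        dst = np.array([1, 0])
        return Network(
            model=np.array([LIFL, LIFL], dtype=np.int8),
            edges=(src, dst, np.array([1.0, 1.0]), np.array([1.0, 1.0])),
            stim_edges=(src, dst),
            plastic=np.array([True, True]),
        )

    def test_disabled_plasticity_leaves_gains_bit_identical(self):
        net = self._ring()
        res = net.run([(0, 0.0, DEFAULT_INPUT_WEIGHT), (1, 3.0, DEFAULT_INPUT_WEIGHT)], 60.0)
        before = net.ie.copy()
        net.apply_plasticity(res, PlasticityParams(enabled=False))
        assert np.array_equal(net.ie, before)

    def test_enabled_plasticity_moves_gains_in_opposite_directions(self):
        net = self._ring()
        res = net.run([(0, 0.0, DEFAULT_INPUT_WEIGHT), (1, 3.0, DEFAULT_INPUT_WEIGHT)], 60.0)
        net.apply_plasticity(res, PlasticityParams())
        # neuron 0 fires first: its partner's pulse arrives after its spike
        # (depression); neuron 1 hears the earlier spike (potentiation)
        assert net.ie[0] < 1.0 < net.ie[1]

    def test_update_magnitude_bounded_by_lambda_per_pairing(self):
        net = self._ring()
        res = net.run([(0, 0.0, DEFAULT_INPUT_WEIGHT), (1, 3.0, DEFAULT_INPUT_WEIGHT)], 60.0)
        params = PlasticityParams()
        net.apply_plasticity(res, params)
        assert np.all(np.abs(net.ie - 1.0) <= params.lam + 1e-15)
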