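"""Sequence-detector wiring, training convergence, and specificity."""

import numpy as np
import pytest

from spikelat.mnsd import MNSD, MNSDSpec, calibrate_target_weight, _target_fires
from spikelat.neuron import NeuronParams
from spikelat.patterns import SpikePattern


class TestTopology:
    def test_node_and_edge_counts(self, trained_mnsd):
        net = trained_mnsd.network
        n = trained_mnsd.n_branches
        assert net.n == n + 1  # 4 delay neurons + 1 target (generators are inputs)
        for i in range(n):
            assert net.indegree([i], list(range(n)))[0] == 2  # ring modulators
        assert net.indegree([trained_mnsd.target_id], list(range(n)))[0] == n

    def test_too_few_branches_rejected(self):
        with pytest.raises(ValueError):
            MNSDSpec(n_branches=1, generator_times=(0.0,))

    def test_modulator_weight_must_stay_small(self):
        with pytest.raises(ValueError):
            MNSDSpec(modulator_weight=1000.0)


class TestSimultaneityCalibration:
    def test_calibrated_weight_separates_sync_from_async(self, default_params):
        w = calibrate_target_weight(4, sync_window=3.0, inter_pulse=5.0)
        sync = np.linspace(0.0, 3.0, 4)
        assert _target_fires(w, sync, default_params)
        assert not _target_fires(w, np.zeros(3), default_params)
        assert not _target_fires(w, np.linspace(0.0, 10.0, 4), default_params)


class TestTraining:
    def test_untrained_detector_rejects_its_own_pattern(self):
        model = MNSD()
        res = model.run_trial(model.default_pattern())
        assert not model._target_spiked(res)

    def test_empty_pattern_elicits_no_spikes(self):
        model = MNSD()
        res = model.run_trial(SpikePattern(np.empty(0, dtype=int), np.empty(0)))
        assert res.spike_times.size == 0

    def test_volley_span_contracts_over_training(self, trained_mnsd):
        d = trained_mnsd._fit_result.log.delta_t_out_tot
        assert np.nanmean(d[-50:]) < np.nanmean(d[:50])
        assert np.nanmean(d[-50:]) < 1.0  # near-synchronous volley at the end

    def test_final_gains_straddle_one(self, trained_mnsd):
        ie = trained_mnsd.ie_p
        assert ie.min() < 1.0 < ie.max()

    def test_target_fires_after_training(self, trained_mnsd):
        assert bool(trained_mnsd._fit_result.log.target_spiked[-1])

    def test_zero_trials_leave_the_network_untouched(self):
        model = MNSD()
        model.fit(n_trials=0)
        assert np.all(model.ie_p == 1.0)

    def test_training_log_shapes(self, trained_mnsd):
        log = trained_mnsd._fit_result.log
        assert log.ie_trajectories.shape == (300, 4)
        assert log.delta_t_out_tot.shape == (300,)
        assert log.target_spiked.shape == (300,)
        assert len(log.to_frame()) == 300


class TestRecognition:
    def test_trained_ordering_is_recognized(self, trained_mnsd):
        assert trained_mnsd.recognize(trained_mnsd.default_pattern())

    def test_no_other_ordering_is_recognized(self, trained_mnsd):
        perm = trained_mnsd.permutation_specificity()
        assert len(perm.table) == 24
        assert perm.trained_recognized
        assert perm.false_positive_fraction == 0.0

    def test_recognition_is_translation_invariant(self, trained_mnsd):
        shifted = trained_mnsd.default_pattern().shifted(13.7)
        assert trained_mnsd.recognize(shifted)

    def test_out_of_range_channel_rejected(self, trained_mnsd):
        bad = SpikePattern(np.array([9]), np.array([1.0]))
        with pytest.raises(ValueError):
            trained_mnsd.run_trial(bad)

    def test_two_branch_tie_is_symmetric(self):
        spec = MNSDSpec(n_branches=2, generator_times=(5.0, 5.0))
        model = MNSD(spec)
        a = model.recognize(SpikePattern(np.array([0, 1]), np.array([5.0, 5.0])))
        b = model.recognize(SpikePattern(np.array([1, 0]), np.array([5.0, 5.0])))
        assert a == b


class TestDeterminism:
    def test_identical_runs_produce_identical_spike_streams(self):
        streams = []
        for _ in range(2):
            model = MNSD()
            model.fit(n_trials=20)
            res = model.run_trial(model.default_pattern())
            streams.append((res.spike_times.copy(), res.spike_ids.copy()))
        assert np.array_equal(streams[0][0], streams[1][0])
        assert np.array_equal(streams[0][1], streams[1][1])


class TestSummary:
    def test_summary_mentions_the_key_quantities(self, trained_mnsd):
        text = trained_mnsd._fit_result.summary()
        assert "IE_p" in text and "trailing-50" in text
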