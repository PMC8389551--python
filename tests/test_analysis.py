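"""Rates, OSI, dipole moment, MUA, and the signal-comparison operators."""

import numpy as np
import pytest

from spikelat.analysis import (
    DENDRITE_LENGTH_M,
    EvokedSignal,
    TuningCurve,
    SweepResult,
    dipole_moment,
    firing_rate_window,
    mua,
    osi,
    similarity,
    surrogate_recorded_signal,
    tuning_curve,
    xcorr_lag,
)
from spikelat.patterns import SpikePattern


def _pattern(times, channels=None):
    times = np.asarray(times, float)
    channels = np.zeros(times.size, dtype=int) if channels is None else np.asarray(channels)
    return SpikePattern(channels, times)


class TestFiringRate:
    def test_no_spikes_is_zero(self):
        assert firing_rate_window(_pattern([])) == 0.0

    def test_ten_spikes_in_fifty_ms(self):
        pat = _pattern(np.linspace(50.0, 99.0, 10))
        assert firing_rate_window(pat) == pytest.approx(200.0)

    def test_population_filter(self):
        pat = _pattern([60.0, 60.0, 60.0], channels=[1, 2, 3])
        assert firing_rate_window(pat, population=[1]) == pytest.approx(20.0)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            firing_rate_window(_pattern([]), t_start=50.0, t_end=50.0)


class TestTuningAndOsi:
    def test_normalised_peak_is_one(self):
        curve = tuning_curve([0, 45, 90], [1.0, 5.0, 2.0])
        assert curve.normalized_rate.max() == 1.0
        assert curve.preferred_orientation == 45.0

    def test_trial_matrix_is_averaged(self):
        curve = tuning_curve([0, 90], [[1.0, 3.0], [5.0, 7.0]])
        assert curve.mean_rate == pytest.approx([2.0, 6.0])

    def test_osi_examples(self):
        assert osi(10.0, 10.0) == 0.0
        assert osi(10.0, 0.0) == 1.0
        assert osi(86.0, 14.0) == pytest.approx(0.72)

    def test_osi_undefined_for_silent_rates(self):
        assert np.isnan(osi(0.0, 0.0))

    def test_sweep_result_osi_table(self):
        orientations = np.array([0.0, 45.0, 90.0, 135.0, 180.0])
        rates = np.zeros((2, 5, 3))
        rates[0, 0] = [10, 10, 10]   # column 0, preferred
        rates[0, 2] = [2, 2, 2]      # column 0, orthogonal
        rates[1, 1] = [8, 8, 8]      # column 45, preferred
        rates[1, 3] = [0, 0, 0]
        sweep = SweepResult(orientations, (0.0, 45.0), rates)
        table = sweep.osi_table()
        col0 = table[table.column == 0.0]["osi"]
        assert np.allclose(col0, (10 - 2) / (10 + 2))
        assert np.allclose(table[table.column == 45.0]["osi"], 1.0)
        assert sweep.mean_osi() == pytest.approx((2 / 3 + 1.0) / 2)


class TestDipoleMoment:
    def test_single_layer_multiplier(self):
        sig = dipole_moment({"L23_PC": np.ones(4)}, dt=0.1)
        assert np.allclose(sig.values, DENDRITE_LENGTH_M["L23"])
        assert sig.unit == "pA*m"

    def test_sum_of_printed_multipliers(self):
        sig = dipole_moment(
            {"L23": np.ones(3), "L5": np.ones(3), "L6": np.ones(3)}, dt=0.1
        )
        assert np.allclose(sig.values, 4.82e-4 + 1.342e-3 + 9.63e-4)

    def test_linearity(self, rng):
        series = {k: rng.normal(size=50) for k in ("L23", "L5", "L6")}
        doubled = {k: 2 * v for k, v in series.items()}
        assert np.allclose(
            dipole_moment(doubled, 0.1).values, 2 * dipole_moment(series, 0.1).values
        )

    def test_zero_currents_give_zero_signal(self):
        sig = dipole_moment({"L5": np.zeros(7)}, dt=0.1)
        assert np.all(sig.values == 0.0)

    def test_mismatched_series_rejected(self):
        with pytest.raises(ValueError):
            dipole_moment({"L23": np.ones(3), "L5": np.ones(4)}, dt=0.1)

    def test_unknown_layer_rejected(self):
        with pytest.raises(ValueError):
            dipole_moment({"L9": np.ones(3)}, dt=0.1)


class TestMua:
    def test_standard_window_has_eleven_bins(self):
        sig = mua(_pattern([5.0, 15.0, 105.0]))
        assert sig.values.size == 11
        assert sig.unit == "spikes/bin"

    def test_no_spikes_give_all_zero_bins(self):
        assert np.all(mua(_pattern([])).values == 0.0)

    def test_unsmoothed_bins_conserve_the_spike_count(self):
        times = np.random.default_rng(3).uniform(0.0, 110.0, size=200)
        sig = mua(_pattern(times), smooth=False)
        assert sig.values.sum() == pytest.approx(200)

    def test_smoothing_is_a_truncated_three_bin_average(self):
        sig = mua(_pattern([5.0, 15.0, 15.0, 25.0]), t_end=40.0, smooth=True)
        # raw bins: [1, 2, 1, 0]; smoothed: [1.5, 4/3, 1, 0.5]
        assert sig.values == pytest.approx([1.5, 4 / 3, 1.0, 0.5])

    def test_bin_must_divide_window(self):
        with pytest.raises(ValueError):
            mua(_pattern([]), t_end=105.0)


class TestComparison:
    def test_identical_signals_have_zero_lag(self):
        a = surrogate_recorded_signal()
        assert xcorr_lag(a, a) == 0.0

    @pytest.mark.parametrize("shift", [8.0, -8.0, 25.0])
    def test_constructed_shift_recovered_exactly(self, shift):
        a = surrogate_recorded_signal()
        b = surrogate_recorded_signal(lag=shift)
        assert xcorr_lag(a, b) == pytest.approx(shift, abs=1e-9)

    def test_lag_antisymmetry(self):
        a = surrogate_recorded_signal()
        b = surrogate_recorded_signal(lag=11.0, noise_sd=0.01, seed=5)
        assert xcorr_lag(a, b) == pytest.approx(-xcorr_lag(b, a))

    def test_flat_signal_has_undefined_lag(self):
        a = surrogate_recorded_signal()
        flat = EvokedSignal(a.t, np.zeros_like(a.values))
        assert np.isnan(xcorr_lag(a, flat))

    def test_self_similarity_is_one(self):
        a = surrogate_recorded_signal()
        assert similarity(a, a) == pytest.approx(1.0)

    def test_inverted_signal_after_scaling_is_minus_one(self):
        a = surrogate_recorded_signal()
        b = EvokedSignal(a.t, 1.0 - a.values)
        assert similarity(a, b) == pytest.approx(-1.0)

    def test_noise_degrades_similarity_monotonically(self):
        a = surrogate_recorded_signal()
        rs = [
            similarity(a, surrogate_recorded_signal(noise_sd=sd, seed=11))
            for sd in (0.02, 0.5)
        ]
        assert 1.0 > rs[0] > rs[1]

    def test_constant_series_similarity_is_missing(self):
        a = surrogate_recorded_signal()
        flat = EvokedSignal(a.t, np.full_like(a.values, 3.3))
        assert np.isnan(similarity(a, flat))

    def test_window_coverage_required(self):
        a = surrogate_recorded_signal()
        short = EvokedSignal(a.t[:40], a.values[:40])  # ends at 39 ms
        with pytest.raises(ValueError):
            similarity(a, short)


class TestSurrogate:
    def test_deterministic_given_seed(self):
        a = surrogate_recorded_signal(noise_sd=0.1, seed=4)
        b = surrogate_recorded_signal(noise_sd=0.1, seed=4)
        assert np.array_equal(a.values, b.values)

    def test_different_seeds_share_the_waveform(self):
        a = surrogate_recorded_signal(noise_sd=0.1, seed=1)
        b = surrogate_recorded_signal(noise_sd=0.1, seed=2)
        assert not np.array_equal(a.values, b.values)
        assert similarity(a, b) > 0.8

    def test_waveform_peaks_near_80_ms(self):
        a = surrogate_recorded_signal()
        assert a.peak_time == pytest.approx(80.0, abs=1.0)

    def test_spiking_kind_uses_mua_bins(self):
        s = surrogate_recorded_signal(kind="spiking")
        assert s.values.size == 11
        assert s.dt == 10.0

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            surrogate_recorded_signal(kind="field-potential")


class TestEvokedSignalContainer:
    def test_nonuniform_sampling_rejected(self):
        with pytest.raises(ValueError):
            EvokedSignal(np.array([0.0, 1.0, 3.0]), np.zeros(3))

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            EvokedSignal(np.arange(3.0), np.zeros(4))


class TestPlotting:
    def test_plot_methods_return_matplotlib_axes(self):
        import matplotlib

        matplotlib.use("Agg")
        sig = surrogate_recorded_signal()
        ax = sig.plot()
        assert ax.get_xlabel().startswith("time")
        curve = TuningCurve(np.array([0.0, 45.0]), np.array([1.0, 2.0]))
        assert curve.plot() is not None
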