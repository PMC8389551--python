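"""Multi-neuronal spike-sequence detector (MNSD).

Architecture (for ``n`` branches): ``n`` pulse generators feed ``n`` LIFL
delay neurons one-to-one; the delay neurons project to a single LIFL target
neuron and modulate each other through weak "stimulator" edges wired in a
ring (each delay neuron hears its two neighbours).  The target fires only
when the delay-layer output spikes arrive nearly simultaneously
(*simultaneity condition*); training repeatedly presents one spike sequence
with intrinsic-excitability plasticity enabled, which adjusts each delay
neuron's spike latency until the learned sequence produces a synchronous
volley — and only that sequence makes the target fire.

``MNSD`` is a model object: build it from a spec, ``fit()`` it to a pattern
(returning an :class:`MNSDTrainingResult` with the IE and synchronisation
trajectories), then query ``recognize`` / ``permutation_specificity``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .engine import LIFL, Network, SimResult
from .neuron import (
    DEFAULT_INPUT_WEIGHT,
    LIFLNeuron,
    NeuronParams,
    SpikeEvent,
)
from .patterns import SpikePattern
from .plasticity import PlasticityParams

__all__ = [
    "MNSDSpec",
    "TrainingLog",
    "MNSD",
    "MNSDTrainingResult",
    "PermutationTable",
    "calibrate_target_weight",
]


@dataclass(frozen=True)
class MNSDSpec:
    """Wiring parameters of one sequence detector."""

    n_branches: int = 4
    generator_times: tuple = (0.0, 5.0, 10.0, 15.0)  #: ms, one per branch
    input_weight: float = DEFAULT_INPUT_WEIGHT        #: generator -> delay, pA
    modulator_weight: float = 1.0                     #: delay <-> delay, pA (small)
    target_weight: float | None = None                #: delay -> target, pA; None = calibrate
    sync_window: float = 3.0                          #: ms, simultaneity tolerance
    delay: float = 1.0                                #: synaptic delay, ms
    wiring: str = "ring"                              #: 'ring' | 'all' modulator topology

    def __post_init__(self) -> None:
        if self.n_branches < 2:
            raise ValueError("an MNSD needs at least 2 branches")
        if len(self.generator_times) != self.n_branches:
            raise ValueError("generator_times must have one entry per branch")
        if self.modulator_weight >= self.input_weight / 10:
            raise ValueError("modulator weight must be much smaller than the input weight")
        if self.wiring not in ("ring", "all"):
            raise ValueError("wiring must be 'ring' or 'all'")


@dataclass
class TrainingLog:
    """Per-trial trajectories recorded while fitting a detector."""

    ie_trajectories: np.ndarray   #: (n_trials, n_branches) IE_p after each trial
    delta_t_out: np.ndarray       #: (n_trials, n_branches-1) consecutive output diffs, ms (NaN if silent)
    delta_t_out_tot: np.ndarray   #: (n_trials,) max-min span of delay-layer outputs, ms
    target_spiked: np.ndarray     #: (n_trials,) bool

    def to_frame(self) -> pd.DataFrame:
        n_trials, n_b = self.ie_trajectories.shape
        data = {"trial": np.arange(n_trials)}
        for i in range(n_b):
            data[f"ie_p_D{i + 1}"] = self.ie_trajectories[:, i]
        for i in range(n_b - 1):
            data[f"dt_out_D{i + 2}_D{i + 1}"] = self.delta_t_out[:, i]
        data["dt_out_tot"] = self.delta_t_out_tot
        data["target_spiked"] = self.target_spiked
        return pd.DataFrame(data)


def _target_fires(weight: float, times: np.ndarray, params: NeuronParams, dt: float = 0.1) -> bool:
    """Would an isolated LIFL target spike given input pulses of ``weight``?"""
    events = [SpikeEvent(source_id=0, time=float(t), weight=weight) for t in np.sort(times)]
    neuron = LIFLNeuron(params)
    horizon = float(np.max(times)) + 2 * params.sl_max + 5.0
    return len(neuron.run(events, horizon, dt=dt)) > 0


def calibrate_target_weight(
    n_branches: int,
    sync_window: float,
    inter_pulse: float,
    params: NeuronParams | None = None,
) -> float:
    """Delay-to-target weight enforcing the simultaneity condition.

    Finds the weight range for which ``n`` spikes spread over ``sync_window``
    fire the target while (a) ``n - 1`` coincident spikes and (b) ``n``
    spikes spread over twice the inter-pulse interval do not, and returns its
    midpoint.  Raises when no such weight exists.
    """
    p = params or NeuronParams()
    sync_times = np.linspace(0.0, sync_window, n_branches)
    few_times = np.zeros(n_branches - 1)
    spread_times = np.linspace(0.0, 2.0 * inter_pulse, n_branches)

    def threshold(times: np.ndarray) -> float:
        lo, hi = 1.0, 1e6
        if _target_fires(lo, times, p) or not _target_fires(hi, times, p):
            raise ValueError("target calibration bracket failed")
        for _ in range(60):
            mid = np.sqrt(lo * hi)
            if _target_fires(mid, times, p):
                hi = mid
            else:
                lo = mid
        return hi

    w_fire = threshold(sync_times)            # must fire at or above this
    w_reject = min(threshold(few_times), threshold(spread_times))  # must stay below
    if w_fire >= w_reject:
        raise ValueError(
            "simultaneity condition unsatisfiable: "
            f"need weight >= {w_fire:.1f} to fire on a synchronous volley but "
            f"< {w_reject:.1f} to reject asynchronous input"
        )
    return 0.5 * (w_fire + w_reject)


class MNSD:
    """A multi-neuronal spike-sequence detector as a trainable model object.

    Neurons are indexed ``0 .. n-1`` (delay layer) and ``n`` (target).
    External channel ``i`` injects into delay neuron ``i`` with the input
    weight; generators are therefore represented by the input pattern itself.
    """

    def __init__(
        self,
        spec: MNSDSpec | None = None,
        neuron_params: NeuronParams | None = None,
        plasticity_params: PlasticityParams | None = None,
        dt: float = 0.1,
    ):
        self.spec = spec or MNSDSpec()
        self.neuron_params = neuron_params or NeuronParams()
        self.plasticity_params = plasticity_params or PlasticityParams()
        self.dt = dt
        n = self.spec.n_branches
        self.target_id = n

        if self.spec.target_weight is None:
            ipi = float(np.mean(np.diff(np.sort(np.asarray(self.spec.generator_times)))))
            ipi = max(ipi, self.spec.sync_window)
            w_t = calibrate_target_weight(n, self.spec.sync_window, ipi, self.neuron_params)
            self.spec = replace(self.spec, target_weight=w_t)

        src, dst, w, d = [], [], [], []
        stim_s, stim_d = [], []
        for i in range(n):
            src.append(i)
            dst.append(self.target_id)
            w.append(self.spec.target_weight)
            d.append(self.spec.delay)
            if self.spec.wiring == "ring":
                neighbours = {(i - 1) % n, (i + 1) % n} - {i}
            else:
                neighbours = set(range(n)) - {i}
            for j in sorted(neighbours):
                src.append(j)
                dst.append(i)
                w.append(self.spec.modulator_weight)
                d.append(self.spec.delay)
                stim_s.append(j)
                stim_d.append(i)

        model = np.full(n + 1, LIFL, dtype=np.int8)
        plastic = np.zeros(n + 1, dtype=bool)
        plastic[:n] = True
        self.network = Network(
            model=model,
            edges=(np.array(src), np.array(dst), np.array(w, float), np.array(d, float)),
            stim_edges=(np.array(stim_s), np.array(stim_d)),
            lifl_params=self.neuron_params,
            plastic=plastic,
            dt=dt,
        )

    # ------------------------------------------------------------------ runs

    @property
    def n_branches(self) -> int:
        return self.spec.n_branches

    @property
    def ie_p(self) -> np.ndarray:
        """Current intrinsic-excitability gains of the delay neurons."""
        return self.network.ie[: self.n_branches].copy()

    def default_pattern(self) -> SpikePattern:
        return SpikePattern(
            np.arange(self.n_branches), np.asarray(self.spec.generator_times, float)
        )

    def _auto_duration(self, pattern: SpikePattern) -> float:
        t_last = float(pattern.times.max()) if len(pattern) else 0.0
        return t_last + 2.0 * self.neuron_params.sl_max + 10.0

    def run_trial(
        self,
        pattern: SpikePattern,
        plasticity_on: bool = False,
        duration: float | None = None,
    ) -> SimResult:
        """Present one pattern from rest; optionally apply the IE update after.

        The nominal trial length is 1 s with the state reset to rest between
        trials; since the network is silent once the volley has passed, the
        simulation covers the active window only.
        """
        if len(pattern) and (pattern.channels.max() >= self.n_branches or pattern.channels.min() < 0):
            raise ValueError("pattern channels must address the generator set")
        inputs = [
            (int(c), float(t), self.spec.input_weight)
            for c, t in zip(pattern.channels, pattern.times)
        ]
        result = self.network.run(inputs, duration or self._auto_duration(pattern))
        if plasticity_on:
            self.network.apply_plasticity(result, self.plasticity_params)
        return result

    def fit(
        self,
        pattern: SpikePattern | None = None,
        n_trials: int = 300,
    ) -> "MNSDTrainingResult":
        """Train on one pattern for ``n_trials`` presentations.

        Returns a result object carrying the per-trial IE_p trajectories and
        the synchronisation measure ``delta_t_out_tot`` (the span of the
        delay-layer output volley), which decreases toward zero as the
        detector learns.
        """
        if not self.plasticity_params.enabled:
            raise ValueError("training requires plasticity to be enabled")
        pattern = pattern or self.default_pattern()
        n = self.n_branches
        ies = np.zeros((n_trials, n))
        d_out = np.full((n_trials, max(n - 1, 1)), np.nan)
        d_tot = np.full(n_trials, np.nan)
        t_spk = np.zeros(n_trials, dtype=bool)
        for trial in range(n_trials):
            res = self.run_trial(pattern, plasticity_on=True)
            outs = self._delay_spike_times(res)
            if not np.any(np.isnan(outs)):
                d_out[trial] = np.diff(outs)[: max(n - 1, 1)]
                d_tot[trial] = np.nanmax(outs) - np.nanmin(outs)
            t_spk[trial] = self._target_spiked(res)
            ies[trial] = self.ie_p
        log = TrainingLog(ies, d_out, d_tot, t_spk)
        return MNSDTrainingResult(self, pattern, log)

    def _delay_spike_times(self, res: SimResult) -> np.ndarray:
        outs = np.full(self.n_branches, np.nan)
        for i in range(self.n_branches):
            t = res.spike_times[res.spike_ids == i]
            if t.size:
                outs[i] = t.min()
        return outs

    def _target_spiked(self, res: SimResult) -> bool:
        return bool(np.any(res.spike_ids == self.target_id))

    def recognize(self, pattern: SpikePattern) -> bool:
        """True iff the target fires for ``pattern`` (plasticity off)."""
        res = self.run_trial(pattern, plasticity_on=False)
        return self._target_spiked(res)

    def permutation_specificity(
        self, base_times: np.ndarray | None = None
    ) -> "PermutationTable":
        """Exhaustively test every channel-ordering of the base times.

        The trained ordering is reported separately from the fraction of the
        remaining ``n! - 1`` orderings that (incorrectly) activate the target.
        """
        base = np.asarray(
            self.spec.generator_times if base_times is None else base_times, float
        )
        n = self.n_branches
        trained = tuple(range(n))
        rows = []
        for perm in itertools.permutations(range(n)):
            pattern = SpikePattern(np.arange(n), base[list(perm)])
            rows.append((perm, perm == trained, self.recognize(pattern)))
        table = pd.DataFrame(rows, columns=["ordering", "is_trained", "recognized"])
        return PermutationTable(table)


@dataclass
class PermutationTable:
    """Recognition outcome over all channel-orderings of a time set."""

    table: pd.DataFrame

    @property
    def trained_recognized(self) -> bool:
        sel = self.table[self.table.is_trained]
        return bool(sel.recognized.all()) and len(sel) > 0

    @property
    def false_positive_fraction(self) -> float:
        others = self.table[~self.table.is_trained]
        return float(others.recognized.mean()) if len(others) else float("nan")

    @property
    def fraction_recognized(self) -> float:
        return float(self.table.recognized.mean())


class MNSDTrainingResult:
    """Outcome of :meth:`MNSD.fit`: trajectories, diagnostics, summary."""

    def __init__(self, model: MNSD, pattern: SpikePattern, log: TrainingLog):
        self.model = model
        self.pattern = pattern
        self.log = log

    @property
    def ie_p(self) -> np.ndarray:
        return self.model.ie_p

    @property
    def converged(self) -> bool:
        """Trailing-50-trial mean volley span strictly below the leading mean."""
        d = self.log.delta_t_out_tot
        if d.size < 100 or np.all(np.isnan(d)):
            return False
        return float(np.nanmean(d[-50:])) < float(np.nanmean(d[:50]))

    def plot(self, axes=None):
        """IE_p trajectories and volley-span convergence; returns the axes pair."""
        import matplotlib.pyplot as plt

        if axes is None:
            _, axes = plt.subplots(1, 2, figsize=(9, 3.5))
        for i in range(self.model.n_branches):
            axes[0].plot(self.log.ie_trajectories[:, i], label=f"D{i + 1}")
        axes[0].set_xlabel("trial")
        axes[0].set_ylabel("IE_p")
        axes[0].legend()
        axes[1].plot(self.log.delta_t_out_tot)
        axes[1].set_xlabel("trial")
        axes[1].set_ylabel("volley span (ms)")
        return axes

    def summary(self) -> str:
        d = self.log.delta_t_out_tot
        lines = [
            "MNSD training summary",
            "=====================",
            f"branches:            {self.model.n_branches}",
            f"trials:              {d.size}",
            f"trained times (ms):  {np.asarray(self.pattern.times).tolist()}",
            f"target weight (pA):  {self.model.spec.target_weight:.2f}",
            f"IE_p (final):        {np.round(self.ie_p, 4).tolist()}",
            f"volley span first/last trial (ms): "
            f"{d[0]:.3f} / {d[-1]:.3f}",
            f"leading-50 mean span (ms):  {np.nanmean(d[:50]):.3f}",
            f"trailing-50 mean span (ms): {np.nanmean(d[-50:]):.3f}",
            f"target fired on last trial: {bool(self.log.target_spiked[-1])}",
        ]
        return "\n".join(lines)
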