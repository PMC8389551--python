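"""Orientation columns and the reduced 4-column pinwheel.

One cortical column contains four layers sized after the primate V1
microcircuit (L II/III: 324 PC + 65 inh; L IV: 324 spiny-stellate SS + 65
inh; L V: 81 PC + 16 inh; L VI: 243 PC + 49 inh; 1167 neurons in total).
The 324 retinal channels map one-to-one onto the SS cells, which are grouped
into 81 non-overlapping 2x2 retinotopic blocks; each block's four SS cells
form the delay layer of an MNSD whose four target neurons are dedicated
L II/III pyramidal cells.  All remaining connectivity is drawn randomly with
the fixed per-neuron in-degrees of the anatomical table below, at 100 pA /
1 ms; edges from inhibitory populations carry negative weight.

Layer IV SS cells are LIFL neurons with intrinsic-excitability plasticity
(the trainable element); every other population is adaptive-exponential
(AdEx).  A tonic bias plus independent Poisson background positions each
AdEx population just below the column's recurrent ignition threshold: close
enough that synchronous detector volleys (and, in the deep layers, the
L II/III burst) fire it, far enough that the column stays quiet at rest --
the operating point that lets the simultaneity condition discriminate
orientations (see docs/methods.md for the trade-off involved).

The pinwheel is four such columns with preferred orientations 0, 45, 90 and
135 degrees, sharing the retinal input but with no cross-column wiring.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .engine import ADEX, LIFL, AdExParams, Network, SimResult
from .mnsd import calibrate_target_weight
from .neuron import DEFAULT_INPUT_WEIGHT, NeuronParams
from .patterns import SpikePattern
from .plasticity import PlasticityParams
from .retina import (
    DEFAULT_CONTRAST_THRESHOLD,
    DEFAULT_T0,
    DEFAULT_WINDOW,
    GaborParams,
    encode_latency,
    make_gabor,
)

__all__ = [
    "ColumnSpec",
    "PinwheelSpec",
    "OrientationColumn",
    "Pinwheel",
    "ColumnRecord",
    "POPULATIONS",
    "TABLE_INDEGREES",
    "N_CHANNELS",
    "N_GROUPS",
]

N_CHANNELS = 324  #: retina channels = layer IV SS cells
N_GROUPS = 81     #: MNSD groups per column (324 / 4)

#: (name, size, model, is_inhibitory) per population, anatomical ordering.
POPULATIONS = (
    ("L23_PC", 324, ADEX, False),
    ("L23_inh", 65, ADEX, True),
    ("L4_SS", 324, LIFL, False),
    ("L4_inh", 65, ADEX, True),
    ("L5_PC", 81, ADEX, False),
    ("L5_inh", 16, ADEX, True),
    ("L6_PC", 243, ADEX, False),
    ("L6_inh", 49, ADEX, True),
)

#: Random-connectivity in-degrees (post -> [(pre, k), ...]).  The structured
#: MNSD pathways (retina->SS one-to-one, SS->SS within-group modulators k=3,
#: group SS -> L II/III PC targets k=4) are wired separately and complete the
#: anatomical table.
TABLE_INDEGREES = {
    "L23_PC": (("L23_PC", 36), ("L23_inh", 8)),
    "L23_inh": (("L23_PC", 35), ("L23_inh", 8)),
    "L4_SS": (("L4_inh", 6),),
    "L4_inh": (("L4_SS", 32), ("L4_inh", 6)),
    "L5_PC": (("L23_PC", 15), ("L5_PC", 10), ("L5_inh", 8)),
    "L5_inh": (("L5_PC", 30), ("L5_inh", 8)),
    "L6_PC": (("L5_PC", 20), ("L6_PC", 20), ("L6_inh", 6)),
    "L6_inh": (("L6_PC", 32), ("L6_inh", 6)),
}

#: Spec-complete in-degrees including the structured MNSD pathways, used by
#: the wiring audit.
FULL_INDEGREES = {
    "L23_PC": TABLE_INDEGREES["L23_PC"] + (("L4_SS", 4),),
    "L23_inh": TABLE_INDEGREES["L23_inh"],
    "L4_SS": TABLE_INDEGREES["L4_SS"] + (("L4_SS", 3),),
    "L4_inh": TABLE_INDEGREES["L4_inh"],
    "L5_PC": TABLE_INDEGREES["L5_PC"],
    "L5_inh": TABLE_INDEGREES["L5_inh"],
    "L6_PC": TABLE_INDEGREES["L6_PC"],
    "L6_inh": TABLE_INDEGREES["L6_inh"],
}


@dataclass(frozen=True)
class ColumnSpec:
    """Parameters of one orientation column."""

    preferred_orientation: float = 0.0  #: degrees
    weight: float = 100.0               #: generic synaptic weight, pA
    delay: float = 1.0                  #: synaptic delay, ms
    input_weight: float = DEFAULT_INPUT_WEIGHT  #: retina -> SS, pA
    modulator_weight: float = 1.0       #: within-group SS <-> SS, pA
    target_weight: float | None = None  #: group SS -> L II/III PC, pA; None = calibrate
    sync_window: float = 2.0            #: ms, simultaneity tolerance (tighter than the
                                        #  standalone detector: cortical volleys are noise-jittered)
    ss_noise_rate: float = 300.0        #: Hz, Poisson background on SS cells
    ss_noise_weight: float = 10.0       #: pA per background event on SS cells
    bg_noise_rate: float = 2000.0       #: Hz, Poisson background on AdEx cells
    bg_noise_weight: float = 30.0       #: pA per background event on AdEx cells
    bg_bias: float = 350.0              #: pA tonic drive on AdEx cells (near-threshold)
    deep_bias: float = 455.0            #: pA tonic drive on layers V/VI (prompt relay)


@dataclass(frozen=True)
class PinwheelSpec:
    """Four columns spanning 180 degrees at 45-degree steps."""

    orientations: tuple = (0.0, 45.0, 90.0, 135.0)
    column: ColumnSpec = field(default_factory=ColumnSpec)

    def __post_init__(self) -> None:
        if len(set(self.orientations)) != len(self.orientations):
            raise ValueError("column orientations must be distinct")
        if tuple(sorted(self.orientations)) != (0.0, 45.0, 90.0, 135.0):
            raise ValueError("the reduced pinwheel spans 180 deg at 45-deg steps")


@dataclass
class ColumnRecord:
    """Spikes and per-layer PC synaptic-current traces from one presentation."""

    spikes: SpikePattern
    population_of: dict            #: name -> index array
    currents: dict                 #: layer name -> pA trace per step
    dt: float
    duration: float

    def spikes_of(self, population: str) -> SpikePattern:
        return self.spikes.select(self.population_of[population])

    def to_frame(self):
        """Raster as a labelled table: neuron_id, population, ei_type, time_ms."""
        import pandas as pd

        pop_name = {}
        for name, ids in self.population_of.items():
            for i in ids:
                pop_name[int(i)] = name
        return pd.DataFrame(
            {
                "neuron_id": self.spikes.channels,
                "population": [pop_name[int(i)] for i in self.spikes.channels],
                "ei_type": [
                    "inh" if pop_name[int(i)].endswith("inh") else "exc"
                    for i in self.spikes.channels
                ],
                "time_ms": self.spikes.times,
            }
        )


def _adex_steady_bias_network(spec: ColumnSpec, adex: AdExParams) -> Network:
    """Single noiseless AdEx neuron at the column operating point.

    The probe's tonic drive is the bias plus the *mean* of the Poisson
    background, so calibrations run at the membrane potential the population
    actually fluctuates around.
    """
    tonic = spec.bg_bias + spec.bg_noise_rate * 1e-3 * spec.bg_noise_weight * adex.syn_tau
    return Network(
        model=np.array([ADEX], dtype=np.int8),
        edges=(np.empty(0, int), np.empty(0, int), np.empty(0), np.empty(0)),
        adex_params=adex,
        bias=np.array([tonic]),
    )


def calibrate_cortical_target_weight(
    spec: ColumnSpec,
    adex: AdExParams | None = None,
    n_branches: int = 4,
) -> float:
    """Group-to-target weight enforcing the simultaneity condition on AdEx targets.

    Same contract as :func:`spikelat.mnsd.calibrate_target_weight`, but the
    probe neuron is an AdEx pyramidal cell held at the column's tonic
    operating point (bias on, noise off): ``n`` spikes spread over the sync
    window must fire it, while ``n - 1`` coincident spikes or ``n`` spikes
    spread over twice the sync window must not.  The tighter rejection case
    (versus the standalone detector) keeps partially aligned volleys -- which
    non-preferred orientations produce in abundance -- from triggering the
    target.
    """
    adex = adex or AdExParams()

    def fires(weight: float, times: np.ndarray) -> bool:
        net = _adex_steady_bias_network(spec, adex)
        settle = 100.0
        inputs = [(0, settle + float(t), float(weight)) for t in times]
        res = net.run(inputs, settle + float(times.max()) + 50.0)
        return bool(np.any(res.spike_times > settle))

    def threshold(times: np.ndarray) -> float:
        lo, hi = 1.0, 1e6
        if fires(lo, times) or not fires(hi, times):
            raise ValueError("cortical target calibration bracket failed")
        for _ in range(50):
            mid = np.sqrt(lo * hi)
            if fires(mid, times):
                hi = mid
            else:
                lo = mid
        return hi

    sync_times = np.linspace(0.0, spec.sync_window, n_branches)
    few_times = np.zeros(n_branches - 1)
    spread_times = np.linspace(0.0, 2.0 * spec.sync_window, n_branches)
    w_fire = threshold(sync_times)
    w_reject = min(threshold(few_times), threshold(spread_times))
    if w_fire >= w_reject:
        raise ValueError("simultaneity condition unsatisfiable for the AdEx target")
    return 0.5 * (w_fire + w_reject)


class OrientationColumn:
    """One cortical column as a trainable model object.

    ``fit()`` presents the column's preferred-orientation Gabor pattern
    repeatedly with intrinsic-excitability plasticity enabled on the SS
    cells; afterwards plasticity is off and ``present()`` records evoked
    activity.
    """

    def __init__(
        self,
        spec: ColumnSpec | None = None,
        seed: int | np.random.SeedSequence = 0,
        neuron_params: NeuronParams | None = None,
        adex_params: AdExParams | None = None,
        plasticity_params: PlasticityParams | None = None,
        dt: float = 0.1,
    ):
        self.spec = spec or ColumnSpec()
        self.neuron_params = neuron_params or NeuronParams()
        self.adex_params = adex_params or AdExParams()
        self.plasticity_params = plasticity_params or PlasticityParams()
        self.dt = dt
        self.trained = False

        if self.spec.target_weight is None:
            w_t = calibrate_cortical_target_weight(self.spec, self.adex_params)
            self.spec = replace(self.spec, target_weight=w_t)

        seq = (
            seed
            if isinstance(seed, np.random.SeedSequence)
            else np.random.SeedSequence(seed)
        )
        self._wiring_rng = np.random.default_rng(seq)
        self._build()

    # ------------------------------------------------------------------ build

    def _build(self) -> None:
        spec = self.spec
        self.populations: dict[str, np.ndarray] = {}
        model = []
        inhibitory = np.zeros(0, dtype=bool)
        offset = 0
        inh_flags = []
        for name, size, kind, is_inh in POPULATIONS:
            self.populations[name] = np.arange(offset, offset + size)
            model.extend([kind] * size)
            inh_flags.extend([is_inh] * size)
            offset += size
        self.n = offset
        model = np.asarray(model, dtype=np.int8)
        inh_flags = np.asarray(inh_flags, dtype=bool)

        src, dst, w, d = [], [], [], []
        stim_s, stim_d = [], []

        # structured MNSD pathways ------------------------------------------
        ss = self.populations["L4_SS"]
        pc23 = self.populations["L23_PC"]
        grid = np.arange(N_CHANNELS).reshape(18, 18)
        self.groups = []
        for br in range(9):
            for bc in range(9):
                block = grid[2 * br : 2 * br + 2, 2 * bc : 2 * bc + 2].ravel()
                self.groups.append(block)
        for g, block in enumerate(self.groups):
            members = ss[block]
            targets = pc23[4 * g : 4 * g + 4]
            for i in members:
                for j in members:
                    if i != j:
                        src.append(i)
                        dst.append(j)
                        w.append(spec.modulator_weight)
                        d.append(spec.delay)
                        stim_s.append(i)
                        stim_d.append(j)
                for t in targets:
                    src.append(i)
                    dst.append(t)
                    w.append(spec.target_weight)
                    d.append(spec.delay)

        # random connectivity at fixed in-degree ----------------------------
        rng = self._wiring_rng
        for post_name, rules in TABLE_INDEGREES.items():
            post_ids = self.populations[post_name]
            for pre_name, k in rules:
                pre_ids = self.populations[pre_name]
                sign = -1.0 if pre_name.endswith("inh") else 1.0
                for pid in post_ids:
                    pool = pre_ids[pre_ids != pid]
                    chosen = rng.choice(pool, size=k, replace=False)
                    src.extend(chosen.tolist())
                    dst.extend([pid] * k)
                    w.extend([sign * spec.weight] * k)
                    d.extend([spec.delay] * k)

        noise_rate = np.where(model == LIFL, spec.ss_noise_rate, spec.bg_noise_rate)
        noise_weight = np.where(model == LIFL, spec.ss_noise_weight, spec.bg_noise_weight)
        bias = np.where(model == ADEX, spec.bg_bias, 0.0)
        for deep in ("L5_PC", "L5_inh", "L6_PC", "L6_inh"):
            bias[self.populations[deep]] = spec.deep_bias
        plastic = np.zeros(self.n, dtype=bool)
        plastic[ss] = True

        self.inhibitory = inh_flags
        self.network = Network(
            model=model,
            edges=(
                np.asarray(src),
                np.asarray(dst),
                np.asarray(w, float),
                np.asarray(d, float),
            ),
            stim_edges=(np.asarray(stim_s), np.asarray(stim_d)),
            lifl_params=self.neuron_params,
            adex_params=self.adex_params,
            noise_rate=noise_rate,
            noise_weight=noise_weight,
            bias=bias,
            plastic=plastic,
            dt=self.dt,
        )

    # ------------------------------------------------------------------ runs

    def _inputs_from_pattern(self, pattern: SpikePattern) -> list[tuple[int, float, float]]:
        ss = self.populations["L4_SS"]
        if len(pattern) and pattern.channels.max() >= N_CHANNELS:
            raise ValueError("pattern channels exceed the 324 retina channels")
        return [
            (int(ss[c]), float(t), self.spec.input_weight)
            for c, t in zip(pattern.channels, pattern.times)
        ]

    def preferred_pattern(
        self,
        gabor: GaborParams | None = None,
        t0: float = DEFAULT_T0,
        window: float = DEFAULT_WINDOW,
        contrast_threshold: float = DEFAULT_CONTRAST_THRESHOLD,
    ) -> SpikePattern:
        base = gabor or GaborParams()
        params = replace(base, orientation=self.spec.preferred_orientation)
        return encode_latency(make_gabor(params), t0, window, contrast_threshold)

    def fit(
        self,
        n_presentations: int = 500,
        rng: np.random.Generator | None = None,
        pattern: SpikePattern | None = None,
        noise: bool = True,
    ) -> "OrientationColumn":
        """Train the SS layer on the preferred orientation; plasticity then off.

        The nominal protocol presents the patch at 200 ms intervals; the
        simulation covers the active part of each interval (input wave plus
        maximal latencies) since the state is reset between presentations.
        """
        pattern = pattern or self.preferred_pattern()
        inputs = self._inputs_from_pattern(pattern)
        duration = float(pattern.times.max()) + 2 * self.neuron_params.sl_max + 10.0 if len(pattern) else 50.0
        rng = rng or np.random.default_rng()
        net = self.network
        saved = self._training_view()
        for _ in range(n_presentations):
            res = net.run(inputs, duration, rng=rng)
            net.apply_plasticity(res, self.plasticity_params)
        self._restore_training_view(saved)
        self.trained = True
        return self

    def _training_view(self):
        """Silence the layers downstream of L IV during training.

        L IV receives no feedback from the other layers (the anatomical table
        has no edges into L IV from outside it), so training only needs the
        retina -> SS -> L IV-inhibition loop; the remaining populations are
        temporarily disconnected from their background drive to save work.
        """
        keep = np.zeros(self.n, dtype=bool)
        keep[self.populations["L4_SS"]] = True
        keep[self.populations["L4_inh"]] = True
        saved = (self.network.noise_rate.copy(), self.network.bias.copy())
        self.network.noise_rate = np.where(keep, self.network.noise_rate, 0.0)
        self.network.bias = np.where(keep, self.network.bias, 0.0)
        return saved

    def _restore_training_view(self, saved) -> None:
        self.network.noise_rate, self.network.bias = saved

    def present(
        self,
        pattern: SpikePattern,
        duration: float = 200.0,
        rng: np.random.Generator | None = None,
        record_currents: bool = True,
    ) -> ColumnRecord:
        """Record one full presentation (stimulus onset at t = 0)."""
        record = (
            {
                "L23_PC": self.populations["L23_PC"],
                "L5_PC": self.populations["L5_PC"],
                "L6_PC": self.populations["L6_PC"],
            }
            if record_currents
            else {}
        )
        res = self.network.run(
            self._inputs_from_pattern(pattern),
            duration,
            rng=rng or np.random.default_rng(),
            record_groups=record,
        )
        return ColumnRecord(
            spikes=res.pattern,
            population_of=self.populations,
            currents=res.currents,
            dt=self.dt,
            duration=duration,
        )

    @property
    def ss_ie(self) -> np.ndarray:
        """Intrinsic-excitability gains of the 324 SS cells."""
        return self.network.ie[self.populations["L4_SS"]].copy()


class Pinwheel:
    """The reduced pinwheel: four independent orientation columns.

    The columns share the 324 retinal input channels but have no
    cross-column edges, so presenting a pattern to the pinwheel simulates
    each column on the same input.
    """

    def __init__(
        self,
        spec: PinwheelSpec | None = None,
        seed: int | np.random.SeedSequence = 0,
        **column_kwargs,
    ):
        self.spec = spec or PinwheelSpec()
        seq = (
            seed
            if isinstance(seed, np.random.SeedSequence)
            else np.random.SeedSequence(seed)
        )
        children = seq.spawn(len(self.spec.orientations))
        # calibrate the shared target weight once; all columns use it
        base = self.spec.column
        if base.target_weight is None:
            w_t = calibrate_cortical_target_weight(base)
            base = replace(base, target_weight=w_t)
        self.columns = [
            OrientationColumn(
                replace(base, preferred_orientation=theta), seed=child, **column_kwargs
            )
            for theta, child in zip(self.spec.orientations, children)
        ]

    @property
    def orientations(self) -> tuple:
        return self.spec.orientations

    def column(self, orientation: float) -> OrientationColumn:
        for col in self.columns:
            if col.spec.preferred_orientation == orientation:
                return col
        raise KeyError(f"no column with preferred orientation {orientation}")

    def fit(
        self,
        n_presentations: int = 500,
        rng: np.random.Generator | None = None,
        **pattern_kwargs,
    ) -> "Pinwheel":
        """Train every column on its own preferred orientation."""
        rng = rng or np.random.default_rng()
        for col in self.columns:
            col.fit(
                n_presentations=n_presentations,
                rng=rng,
                pattern=col.preferred_pattern(**pattern_kwargs),
            )
        return self

    def present(
        self,
        pattern: SpikePattern,
        duration: float = 200.0,
        rng: np.random.Generator | None = None,
        record_currents: bool = True,
    ) -> dict[float, ColumnRecord]:
        rng = rng or np.random.default_rng()
        return {
            col.spec.preferred_orientation: col.present(
                pattern, duration, rng, record_currents=record_currents
            )
            for col in self.columns
        }

    def sweep(
        self,
        n_trials: int = 30,
        step: float = 5.0,
        rng: np.random.Generator | None = None,
        duration: float = 200.0,
        window: tuple[float, float] = (50.0, 100.0),
        gabor: GaborParams | None = None,
    ):
        """Present the full orientation sweep and collect L II/III rates.

        Returns a :class:`spikelat.analysis.SweepResult` with the
        (column, orientation, trial) rate tensor measured in the evoked
        window (default 50-100 ms post-onset).
        """
        from .analysis import SweepResult, firing_rate_window

        rng = rng or np.random.default_rng()
        orientations, patterns = _sweep_patterns(step, gabor)
        rates = np.zeros((len(self.columns), orientations.size, n_trials))
        for oi, pattern in enumerate(patterns):
            for trial in range(n_trials):
                records = self.present(pattern, duration, rng, record_currents=False)
                for ci, col in enumerate(self.columns):
                    rec = records[col.spec.preferred_orientation]
                    rates[ci, oi, trial] = firing_rate_window(
                        rec.spikes_of("L23_PC"), t_start=window[0], t_end=window[1]
                    )
        return SweepResult(orientations, self.orientations, rates)

    def evoked(
        self,
        pattern: SpikePattern | None = None,
        n_trials: int = 30,
        rng: np.random.Generator | None = None,
        duration: float = 200.0,
        baseline_end: float = 35.0,
    ):
        """Trial-averaged dipole moment and MUA of the whole pinwheel.

        The default stimulus is a 45-degree Gabor patch.  The dipole moment
        weights each pyramidal layer's summed postsynaptic current (pooled
        over the four columns) by its apical-dendrite length; the pre-input
        baseline (mean over t < ``baseline_end``, before the retinal
        wave reaches cortex) is subtracted.  MUA pools every spike of the pinwheel
        into 10 ms bins over 0-110 ms.
        """
        from .analysis import EvokedSignal, dipole_moment, mua

        rng = rng or np.random.default_rng()
        if pattern is None:
            pattern = encode_latency(make_gabor(GaborParams(orientation=45.0)))
        dipole_acc: np.ndarray | None = None
        mua_acc: np.ndarray | None = None
        t_dip = t_mua = None
        for _ in range(n_trials):
            records = self.present(pattern, duration, rng, record_currents=True)
            layer_currents = {"L23_PC": 0.0, "L5_PC": 0.0, "L6_PC": 0.0}
            all_times = []
            for rec in records.values():
                for layer in layer_currents:
                    layer_currents[layer] = layer_currents[layer] + rec.currents[layer]
                all_times.append(rec.spikes.times)
            dip = dipole_moment(layer_currents, dt=self.columns[0].dt)
            baseline = dip.values[dip.t < baseline_end].mean()
            pooled = SpikePattern(
                np.zeros(sum(len(t) for t in all_times), dtype=np.int64),
                np.concatenate(all_times) if all_times else np.empty(0),
            )
            m = mua(pooled)
            dipole_acc = dip.values - baseline if dipole_acc is None else dipole_acc + dip.values - baseline
            mua_acc = m.values if mua_acc is None else mua_acc + m.values
            t_dip, t_mua = dip.t, m.t
        return (
            EvokedSignal(t_dip, dipole_acc / n_trials, unit="pA*m"),
            EvokedSignal(t_mua, mua_acc / n_trials, unit="spikes/bin"),
        )


def _sweep_patterns(step: float, gabor: GaborParams | None):
    from .retina import orientation_sweep

    return orientation_sweep(step=step, gabor=gabor)
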