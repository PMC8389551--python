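"""Leaky integrate-and-fire neuron with spike latency (LIFL).

The LIFL neuron has two operating regimes separated by a fixed threshold
``V_th``:

* **under-threshold** — a leaky integrator: the membrane potential relaxes
  exponentially toward the resting potential ``V_rest`` while exponential
  synaptic currents (time constant ``syn_tau``) push it around;
* **over-threshold** — once ``V_m`` crosses ``V_th`` the spike is not emitted
  immediately but after a *spike latency*: a strictly decreasing function of
  the membrane state, approaching ``SL_max`` (25 ms) for barely
  supra-threshold drive and 0 for very strong drive.  The membrane keeps the
  same leaky dynamics throughout; crossing *commits* the neuron to fire at
  ``t_cross + SL(V_max)``, where ``V_max`` is the largest potential reached
  since the crossing.  Later excitatory input raises ``V_max`` and advances
  the spike; the commitment survives passive decay (as in the underlying
  spike-generation picture, the upswing is self-sustaining) but inhibitory
  input that actively drives ``V_m`` back below ``V_th`` cancels it.

Input currents are multiplied by the neuron's intrinsic-excitability gain
``IE_p`` (see :mod:`spikelat.plasticity`), so a potentiated neuron reaches a
higher membrane potential — and hence a shorter latency — for the same pulse.

The integration here is piecewise analytic (the under- and over-threshold
ODEs are linear), so single-neuron spike times are exact up to root-finding
tolerance; the grid-based network engine in :mod:`spikelat.engine` applies the
same closed forms once per time step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from scipy.optimize import brentq

__all__ = [
    "NeuronParams",
    "NeuronState",
    "SpikeEvent",
    "DEFAULT_INPUT_WEIGHT",
    "DEFAULT_LATENCY_SHAPE",
    "latency_from_state",
    "apply_decay",
    "receive_pulse",
    "step",
    "LIFLNeuron",
    "single_pulse_response",
    "calibrate_latency_shape",
]

#: Default amplitude (pA) of the input pulse driving a sequence-detector delay
#: neuron.  With ``IE_p = 1`` this pulse evokes a 12.5 ms spike latency (half
#: the 25 ms maximum), leaving headroom for intrinsic-excitability training to
#: shift the latency in either direction.
DEFAULT_INPUT_WEIGHT = 2450.0

#: Steepness of the latency curve, calibrated once (see
#: :func:`calibrate_latency_shape`) so that ``DEFAULT_INPUT_WEIGHT`` at
#: ``IE_p = 1`` yields exactly 12.5 ms of latency with the default membrane
#: parameters.
DEFAULT_LATENCY_SHAPE = 0.09871226509850285


@dataclass(frozen=True)
class NeuronParams:
    """Membrane parameters of the LIFL neuron.

    Defaults are the bio-plausible operating range [-70, -54.4] mV with a
    per-ms under-threshold relaxation rate of 0.02 (membrane time constant
    50 ms) and a maximum spike latency of 25 ms.
    """

    v_rest: float = -70.0       #: resting potential, mV
    v_th: float = -54.4         #: threshold potential, mV
    decay_rate: float = 0.02    #: under-threshold relaxation rate, 1/ms
    sl_max: float = 25.0        #: maximum spike latency, ms
    syn_tau: float = 2.0        #: exponential synapse time constant, ms
    refractory: float = 2.0     #: absolute refractory period, ms
    latency_shape: float = DEFAULT_LATENCY_SHAPE  #: latency-curve steepness
    c_m: float = 250.0          #: membrane capacitance, pF

    def __post_init__(self) -> None:
        if not self.v_rest < self.v_th:
            raise ValueError("V_rest must be below V_th")
        if self.sl_max <= 0 or self.decay_rate <= 0 or self.syn_tau <= 0:
            raise ValueError("SL_max, decay_rate and syn_tau must be positive")
        if self.latency_shape <= 0 or self.c_m <= 0:
            raise ValueError("latency_shape and c_m must be positive")

    @property
    def v_span(self) -> float:
        """Threshold-to-rest span (mV), the normalisation of the latency curve."""
        return self.v_th - self.v_rest


@dataclass
class NeuronState:
    """Mutable dynamical state of one LIFL neuron."""

    v_m: float = -70.0
    i_syn: float = 0.0
    ie_p: float = 1.0
    mode: str = "under"  #: 'under' | 'over' | 'refractory'
    scheduled_spike_time: float | None = None
    last_spike_time: float | None = None
    #: time of the most recent upward threshold crossing (ms); latency is
    #: measured from here.
    t_cross: float | None = None
    #: largest potential reached since the crossing; sets the latency.
    v_max: float | None = None

    def copy(self) -> "NeuronState":
        return replace(self)


@dataclass(frozen=True)
class SpikeEvent:
    """A presynaptic pulse: source label, arrival time (ms) and weight (pA)."""

    source_id: int
    time: float
    weight: float

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("event time must be non-negative")


def latency_from_state(v_m: float, params: NeuronParams) -> float:
    """Spike latency (ms) as a function of the over-threshold potential.

    Rectangular hyperbola in the normalised over-threshold state
    ``S = (V_m - V_th)/(V_th - V_rest)``::

        latency = SL_max / (1 + S / latency_shape)

    strictly decreasing, with limit ``SL_max`` as ``V_m -> V_th+`` and 0 as
    ``V_m -> inf``.
    """
    if v_m <= params.v_th:
        raise ValueError("latency is defined only for V_m > V_th")
    s = (v_m - params.v_th) / params.v_span
    return params.sl_max / (1.0 + s / params.latency_shape)


# ---------------------------------------------------------------------------
# closed-form propagators
# ---------------------------------------------------------------------------

def _under_propagate(v: float, i: float, dt: float, p: NeuronParams) -> tuple[float, float]:
    """Advance (V, I) by dt in the under-threshold (leaky) regime."""
    a, b = p.decay_rate, 1.0 / p.syn_tau
    ea = math.exp(-a * dt)
    eb = math.exp(-b * dt)
    v_new = p.v_rest + (v - p.v_rest) * ea + (i / (p.c_m * (b - a))) * (ea - eb)
    return v_new, i * eb


def apply_decay(state: NeuronState, params: NeuronParams, dt: float) -> NeuronState:
    """Relax an under-threshold neuron toward rest for ``dt`` ms.

    ``V_m <- V_rest + (V_m - V_rest) * exp(-decay_rate * dt)`` plus the
    exponential-synapse contribution; ``I_syn`` decays with ``syn_tau``.
    """
    if dt < 0:
        raise ValueError("dt must be non-negative")
    if state.mode != "under":
        raise ValueError("apply_decay requires under-threshold mode")
    out = state.copy()
    out.v_m, out.i_syn = _under_propagate(state.v_m, state.i_syn, dt, params)
    return out


def receive_pulse(state: NeuronState, params: NeuronParams, event: SpikeEvent) -> NeuronState:
    """Add a presynaptic pulse to the synaptic current, gated by ``IE_p``.

    Pulses arriving during the refractory period are discarded (the state is
    returned unchanged).  The current increment is ``IE_p * weight``; the
    exponential-synapse kernel then drives ``V_m`` during integration.
    """
    if state.mode == "refractory":
        return state.copy()
    out = state.copy()
    out.i_syn += out.ie_p * event.weight
    return out


# ---------------------------------------------------------------------------
# piecewise-analytic advance
# ---------------------------------------------------------------------------

_SCAN_DT = 0.005  # ms; bracketing resolution for root-finding


def _advance(state: NeuronState, params: NeuronParams, t0: float, t1: float) -> float | None:
    """Advance ``state`` in place from ``t0`` to ``t1`` with no input events.

    Returns an emitted spike time, or None.
    """
    p = params
    t = t0
    emitted: float | None = None
    while t < t1 - 1e-12:
        if state.mode == "refractory":
            t_free = state.last_spike_time + p.refractory
            if t_free >= t1:
                return emitted
            state.mode = "under"
            state.v_m = p.v_rest
            t = t_free
            continue
        if state.mode == "under":
            # quick upper bound: can the remaining current reach threshold?
            v_ub = max(state.v_m, p.v_rest) + max(state.i_syn, 0.0) * p.syn_tau / p.c_m
            if v_ub <= p.v_th or state.i_syn <= 0.0:
                state.v_m, state.i_syn = _under_propagate(state.v_m, state.i_syn, t1 - t, p)
                return emitted
            t_c = _find_crossing(state.v_m, state.i_syn, t1 - t, p)
            if t_c is None:
                state.v_m, state.i_syn = _under_propagate(state.v_m, state.i_syn, t1 - t, p)
                return emitted
            state.v_m, state.i_syn = _under_propagate(state.v_m, state.i_syn, t_c, p)
            state.v_m = p.v_th + 1e-12
            state.mode = "over"
            state.t_cross = t + t_c
            state.v_max = state.v_m
            t = t + t_c
            continue
        # over-threshold: same leaky dynamics, spike committed at
        # t_cross + SL(V_max); inhibition-driven descent below V_th cancels
        spike_t, revert_t = _over_segment(state, p, t, t1)
        if revert_t is not None and (spike_t is None or revert_t < spike_t):
            dt_seg = revert_t - t
            state.v_m, state.i_syn = _under_propagate(state.v_m, state.i_syn, dt_seg, p)
            state.v_m = min(state.v_m, p.v_th - 1e-12)
            state.mode = "under"
            state.scheduled_spike_time = None
            state.t_cross = None
            state.v_max = None
            t = revert_t
            continue
        if spike_t is None:
            v_new, i_new = _under_propagate(state.v_m, state.i_syn, t1 - t, p)
            state.v_max = max(state.v_max, _peak_potential(state.v_m, state.i_syn, t1 - t, p))
            state.v_m, state.i_syn = v_new, i_new
            state.scheduled_spike_time = state.t_cross + latency_from_state(state.v_max, p)
            return emitted
        state.v_m = p.v_rest
        state.i_syn = 0.0
        state.mode = "refractory"
        state.last_spike_time = spike_t
        state.scheduled_spike_time = None
        state.t_cross = None
        state.v_max = None
        if emitted is None:
            emitted = spike_t
        t = spike_t
    return emitted


def _find_crossing(v0: float, i0: float, horizon: float, p: NeuronParams) -> float | None:
    """First time in (0, horizon] at which the under-threshold V reaches V_th."""

    def f(dt: float) -> float:
        return _under_propagate(v0, i0, dt, p)[0] - p.v_th

    lo = 0.0
    step_len = _SCAN_DT
    while lo < horizon:
        hi = min(lo + step_len, horizon)
        if f(hi) >= 0.0:
            if hi - lo < 1e-12 or f(lo) >= 0.0:
                return hi
            return brentq(f, lo, hi, xtol=1e-10)
        lo = hi
    return None


def _peak_time(v0: float, i0: float, horizon: float, p: NeuronParams) -> float:
    """Time in [0, horizon] at which the leaky trajectory from (v0, i0) peaks."""

    def vprime(s: float) -> float:
        v, i = _under_propagate(v0, i0, s, p)
        return -p.decay_rate * (v - p.v_rest) + i / p.c_m

    if i0 <= 0.0 or vprime(0.0) <= 0.0:
        return 0.0
    if vprime(horizon) >= 0.0:
        return horizon
    return brentq(vprime, 0.0, horizon, xtol=1e-12)


def _peak_potential(v0: float, i0: float, horizon: float, p: NeuronParams) -> float:
    s_pk = _peak_time(v0, i0, horizon, p)
    return _under_propagate(v0, i0, s_pk, p)[0]


def _over_segment(
    state: NeuronState, p: NeuronParams, t: float, t1: float
) -> tuple[float | None, float | None]:
    """Resolve the over-threshold segment [t, t1].

    Returns ``(spike_time, revert_time)``: the time at which the committed
    schedule ``t_cross + SL(V_max)`` fires, and/or the time at which
    inhibition (negative synaptic current) drags ``V`` below ``V_th``; each
    None when it does not occur before ``t1``.
    """
    t_cross = state.t_cross
    v0, i0 = state.v_m, state.i_syn
    vmax0 = state.v_max if state.v_max is not None else max(v0, p.v_th + 1e-12)
    seg = t1 - t
    s_pk = _peak_time(v0, i0, seg, p)

    def vmax_at(s: float) -> float:
        return max(vmax0, _under_propagate(v0, i0, min(s, s_pk), p)[0])

    def f(s: float) -> float:
        return (t + s) - t_cross - latency_from_state(max(vmax_at(s), p.v_th + 1e-12), p)

    spike_abs: float | None = None
    if f(0.0) >= 0.0:
        spike_abs = t
    elif f(seg) >= 0.0:
        spike_abs = t + brentq(f, 0.0, seg, xtol=1e-10)

    revert_abs: float | None = None
    if i0 < 0.0:  # only active inhibition can cancel the committed spike
        def g(s: float) -> float:
            return _under_propagate(v0, i0, s, p)[0] - p.v_th

        if g(0.0) <= 0.0:
            revert_abs = t
        elif g(seg) < 0.0:
            revert_abs = t + brentq(g, 0.0, seg, xtol=1e-10)
    return spike_abs, revert_abs


def step(
    state: NeuronState,
    params: NeuronParams,
    events: list[SpikeEvent],
    t: float,
    dt: float,
) -> tuple[NeuronState, float | None]:
    """Advance one neuron by ``dt`` ms, integrating ``events`` at their times.

    Events must lie in ``[t, t + dt)`` and be sorted by time.  Returns the new
    state and the first emitted spike time in the step (or None).  Spike
    emission resets ``V_m`` to rest, clears the synaptic current and enters
    the refractory period.
    """
    if dt < 0:
        raise ValueError("dt must be non-negative")
    out = state.copy()
    emitted: float | None = None
    now = t
    for ev in events:
        if not (t - 1e-9 <= ev.time < t + dt + 1e-9):
            raise ValueError("event outside the step window")
        sp = _advance(out, params, now, ev.time)
        if sp is not None and emitted is None:
            emitted = sp
        out = receive_pulse(out, params, ev)
        now = ev.time
    sp = _advance(out, params, now, t + dt)
    if sp is not None and emitted is None:
        emitted = sp
    return out, emitted


class LIFLNeuron:
    """Convenience wrapper pairing a :class:`NeuronState` with its parameters."""

    def __init__(self, params: NeuronParams | None = None, ie_p: float = 1.0):
        self.params = params or NeuronParams()
        self.state = NeuronState(v_m=self.params.v_rest, ie_p=ie_p)

    def run(self, events: list[SpikeEvent], duration: float, dt: float = 0.1) -> list[float]:
        """Run for ``duration`` ms in steps of ``dt``; return emitted spike times."""
        events = sorted(events, key=lambda e: e.time)
        spikes: list[float] = []
        t = 0.0
        i = 0
        n_steps = int(round(duration / dt))
        for k in range(n_steps):
            t = k * dt
            batch = []
            while i < len(events) and events[i].time < t + dt - 1e-12:
                batch.append(events[i])
                i += 1
            self.state, sp = step(self.state, self.params, batch, t, dt)
            if sp is not None:
                spikes.append(sp)
        return spikes


def single_pulse_response(
    weight: float,
    params: NeuronParams | None = None,
    ie_p: float = 1.0,
    horizon: float = 100.0,
) -> tuple[float | None, float | None]:
    """Deliver one pulse at t = 0 to a resting neuron; return (t_cross, t_spike).

    Both are None when the pulse is sub-threshold.  The latency evoked by the
    pulse is ``t_spike - t_cross``.
    """
    p = params or NeuronParams()
    st = NeuronState(v_m=p.v_rest, ie_p=ie_p)
    st = receive_pulse(st, p, SpikeEvent(source_id=0, time=0.0, weight=weight))
    sp = _advance(st, p, 0.0, horizon)
    if sp is None:
        return (st.t_cross, None)
    # t_cross was cleared on emission; recompute by re-running up to the spike
    st2 = NeuronState(v_m=p.v_rest, ie_p=ie_p)
    st2 = receive_pulse(st2, p, SpikeEvent(source_id=0, time=0.0, weight=weight))
    _advance(st2, p, 0.0, max(sp - 1e-6, 0.0))
    return (st2.t_cross, sp)


def calibrate_latency_shape(
    pulse_weight: float = DEFAULT_INPUT_WEIGHT,
    target_latency: float = 12.5,
    params: NeuronParams | None = None,
    tol: float = 1e-9,
) -> float:
    """Find the latency-curve steepness giving ``target_latency`` for a pulse.

    Bisects ``latency_shape`` so that a single pulse of ``pulse_weight`` pA at
    ``IE_p = 1`` evokes exactly ``target_latency`` ms between threshold
    crossing and spike emission.
    """
    base = params or NeuronParams()

    def measured(shape: float) -> float:
        p = replace(base, latency_shape=shape)
        t_cross, t_spike = single_pulse_response(pulse_weight, p)
        if t_spike is None:
            raise ValueError("pulse does not reach threshold; cannot calibrate")
        return t_spike - t_cross

    lo, hi = 1e-4, 20.0
    if not (measured(lo) < target_latency < measured(hi)):
        raise ValueError("target latency not bracketed by the shape range")
    return brentq(lambda s: measured(s) - target_latency, lo, hi, xtol=tol)
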