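"""Vectorized grid-based simulator for mixed LIFL / AdEx spiking networks.

The engine advances every neuron on a fixed grid (default 0.1 ms) using the
same closed-form propagators as the analytic single-neuron path in
:mod:`spikelat.neuron`: under-threshold leak and exponential synaptic decay
are integrated exactly over each step, so the only grid artefacts are the
quantisation of input-event delivery to step boundaries and the linear
interpolation of threshold-crossing times.  Spike *emission* times of LIFL
neurons are kept continuous (the scheduled latency is a float), while
deliveries to postsynaptic targets are rounded to the grid through per-edge
delay buffers.

Non-layer-IV cortical populations use an adaptive-exponential
integrate-and-fire (AdEx) neuron with exponential current synapses, advanced
by forward Euler within the same loop.

Connectivity is stored CSR-style (``indptr``/``targets``/``weights``/
``delay_steps``).  Designated "stimulator" (modulator) edges additionally
drive the intrinsic-excitability update, applied once per trial from the
recorded spike times (each neuron fires at most once per presentation in this
model, so per-trial application is equivalent to the online rule).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import math

import numpy as np

from .neuron import NeuronParams, latency_from_state
from .plasticity import IE_P_FLOOR, PlasticityParams
from .patterns import SpikePattern

__all__ = ["AdExParams", "Network", "SimResult", "LIFL", "ADEX"]

LIFL = 0
ADEX = 1

_STEADY_CACHE: dict = {}


def _adex_steady_state(q: "AdExParams", tonic: float) -> tuple[float, float]:
    """Stable subthreshold fixed point of the AdEx under a tonic current.

    Solves the coupled nullcline equation (with the adaptation variable at
    its own fixed point ``w = a (V - E_L)``); when the tonic drive exceeds
    rheobase there is no subthreshold fixed point and the leak reversal is
    returned (the neuron fires tonically regardless of its start state).
    """
    key = (id(q), round(tonic, 9))
    if key in _STEADY_CACHE:
        return _STEADY_CACHE[key]

    def f(v: float) -> float:
        expo = math.exp(min((v - q.v_t) / q.delta_t, 20.0))
        return -q.g_l * (v - q.e_l) + q.g_l * q.delta_t * expo - q.a * (v - q.e_l) + tonic

    from scipy.optimize import brentq as _brentq

    lo = q.e_l - 30.0
    out = (q.e_l, 0.0)
    v_prev, f_prev = lo, f(lo)
    v_grid = lo
    while v_grid < q.v_peak:
        v_grid += 0.25
        f_now = f(v_grid)
        if f_prev > 0 >= f_now:
            v_star = float(_brentq(f, v_prev, v_grid, xtol=1e-10))
            out = (v_star, q.a * (v_star - q.e_l))
            break
        v_prev, f_prev = v_grid, f_now
    _STEADY_CACHE[key] = out
    return out


@dataclass(frozen=True)
class AdExParams:
    """Adaptive-exponential integrate-and-fire parameters (textbook values)."""

    c_m: float = 281.0        #: membrane capacitance, pF
    g_l: float = 30.0         #: leak conductance, nS
    e_l: float = -70.6        #: leak reversal, mV
    v_t: float = -50.4        #: exponential threshold, mV
    delta_t: float = 2.0      #: threshold slope factor, mV
    tau_w: float = 144.0      #: adaptation time constant, ms
    a: float = 4.0            #: subthreshold adaptation, nS
    b: float = 80.5           #: spike-triggered adaptation increment, pA
    v_reset: float = -60.0    #: reset potential, mV
    v_peak: float = 0.0       #: spike detection potential, mV
    refractory: float = 2.0   #: ms
    syn_tau: float = 2.0      #: exponential synapse time constant, ms


@dataclass
class SimResult:
    """Spike raster plus optional per-group synaptic-current traces."""

    spike_times: np.ndarray            #: ms, continuous
    spike_ids: np.ndarray              #: neuron indices
    duration: float
    dt: float
    currents: dict = field(default_factory=dict)  #: group -> pA trace per step

    def spikes_of(self, ids) -> SpikePattern:
        mask = np.isin(self.spike_ids, np.asarray(list(ids)))
        return SpikePattern(self.spike_ids[mask], self.spike_times[mask])

    @property
    def pattern(self) -> SpikePattern:
        return SpikePattern(self.spike_ids, self.spike_times)


class Network:
    """A fixed wiring of LIFL and AdEx neurons with per-neuron IE gains.

    Parameters
    ----------
    model : array of int
        Per-neuron model flag (``LIFL`` or ``ADEX``).
    edges : (src, dst, weight, delay_ms) arrays
        Directed connections; weights in pA (negative = inhibitory).
    stim_edges : (src, dst) arrays
        Modulator edges driving the intrinsic-excitability update of ``dst``.
    noise_rate, noise_weight : per-neuron arrays
        Independent Poisson background (Hz, pA per event).
    bias : per-neuron array
        Tonic current (pA), used to hold AdEx populations near threshold.
    """

    def __init__(
        self,
        model: np.ndarray,
        edges: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray],
        stim_edges: tuple[np.ndarray, np.ndarray] | None = None,
        lifl_params: NeuronParams | None = None,
        adex_params: AdExParams | None = None,
        noise_rate: np.ndarray | None = None,
        noise_weight: np.ndarray | None = None,
        bias: np.ndarray | None = None,
        plastic: np.ndarray | None = None,
        dt: float = 0.1,
    ):
        self.model = np.asarray(model, dtype=np.int8)
        self.n = self.model.size
        self.lifl_params = lifl_params or NeuronParams()
        self.adex_params = adex_params or AdExParams()
        self.dt = float(dt)

        src, dst, w, d = (np.asarray(a) for a in edges)
        order = np.argsort(src, kind="stable")
        self._src = src[order].astype(np.int64)
        self._dst = dst[order].astype(np.int64)
        self._w = w[order].astype(np.float64)
        self._delay_steps = np.maximum(np.rint(d[order] / self.dt).astype(np.int64), 1)
        self.indptr = np.searchsorted(self._src, np.arange(self.n + 1))
        self.max_delay_steps = int(self._delay_steps.max()) if self._delay_steps.size else 1

        if stim_edges is None:
            self.stim_src = np.empty(0, dtype=np.int64)
            self.stim_dst = np.empty(0, dtype=np.int64)
        else:
            self.stim_src = np.asarray(stim_edges[0], dtype=np.int64)
            self.stim_dst = np.asarray(stim_edges[1], dtype=np.int64)

        zeros = np.zeros(self.n)
        self.noise_rate = zeros.copy() if noise_rate is None else np.asarray(noise_rate, float)
        self.noise_weight = zeros.copy() if noise_weight is None else np.asarray(noise_weight, float)
        self.bias = zeros.copy() if bias is None else np.asarray(bias, float)
        self.plastic = (
            np.zeros(self.n, dtype=bool) if plastic is None else np.asarray(plastic, bool)
        )
        #: per-neuron intrinsic-excitability gain (meaningful for LIFL neurons)
        self.ie = np.ones(self.n)

        self._is_lifl = self.model == LIFL
        self._is_adex = self.model == ADEX
        self._lifl_idx = np.flatnonzero(self._is_lifl)
        self._adex_idx = np.flatnonzero(self._is_adex)

    # -- wiring audit helpers -------------------------------------------------

    def indegree(self, dst_ids, src_ids) -> np.ndarray:
        """Realized in-degree of each neuron in ``dst_ids`` from ``src_ids``."""
        dst_ids = np.asarray(dst_ids)
        src_set = np.isin(self._src, np.asarray(src_ids))
        counts = np.bincount(self._dst[src_set], minlength=self.n)
        return counts[dst_ids]

    def edge_weights_from(self, src_ids) -> np.ndarray:
        return self._w[np.isin(self._src, np.asarray(src_ids))]

    # -- simulation -----------------------------------------------------------

    def run(
        self,
        inputs: list[tuple[int, float, float]] | None,
        duration: float,
        rng: np.random.Generator | None = None,
        record_groups: dict | None = None,
    ) -> SimResult:
        """Simulate ``duration`` ms from rest.

        ``inputs`` is a list of external injections ``(neuron, time_ms,
        weight_pA)`` — e.g. a retinal spike pattern mapped onto layer IV —
        delivered through the same exponential synapses as internal spikes.
        ``record_groups`` maps a name to an index array; the summed synaptic
        current of each group is recorded at every step.
        """
        p, q = self.lifl_params, self.adex_params
        dt = self.dt
        n_steps = int(round(duration / dt))
        rng = rng or np.random.default_rng()

        # closed-form step coefficients (LIFL) and Euler constants (AdEx)
        a_, b_ = p.decay_rate, 1.0 / p.syn_tau
        ea = math.exp(-a_ * dt)
        eb = math.exp(-b_ * dt)
        c_under = (ea - eb) / (p.c_m * (b_ - a_))
        eb_adex = math.exp(-dt / q.syn_tau)

        # state, initialised at the tonic operating point (bias + mean
        # background current): trials represent excerpts of a continuously
        # running network, so responses are invariant to the stimulus time
        noise_mean = self.noise_rate * 1e-3 * self.noise_weight * (
            np.where(self._is_lifl, p.syn_tau, q.syn_tau)
        )
        v = np.where(self._is_lifl, p.v_rest, q.e_l)
        i_syn = noise_mean.copy()
        w_adapt = np.zeros(self.n)
        if self._lifl_idx.size:
            idx = self._lifl_idx
            v[idx] = np.minimum(
                p.v_rest + noise_mean[idx] / (p.c_m * p.decay_rate), p.v_th - 0.5
            )
        if self._adex_idx.size:
            tonic_all = self.bias[self._adex_idx] + noise_mean[self._adex_idx]
            for tonic in np.unique(tonic_all):
                v_star, w_star = _adex_steady_state(q, float(tonic))
                sel = self._adex_idx[tonic_all == tonic]
                v[sel] = v_star
                w_adapt[sel] = w_star
        over = np.zeros(self.n, dtype=bool)
        t_cross = np.full(self.n, np.nan)
        v_max = np.full(self.n, np.nan)
        t_sched = np.full(self.n, np.inf)
        refract_until = np.full(self.n, -np.inf)

        ring_len = self.max_delay_steps + 1
        ring = np.zeros((ring_len, self.n))

        # external inputs, quantised to grid steps
        ext_by_step: dict[int, list[tuple[int, float]]] = {}
        for neuron_id, t_ev, weight in inputs or []:
            k = int(round(t_ev / dt))
            ext_by_step.setdefault(k, []).append((int(neuron_id), float(weight)))

        noisy = np.flatnonzero(self.noise_rate > 0)
        lam = self.noise_rate[noisy] * dt * 1e-3  # Hz -> events per step

        record_groups = record_groups or {}
        currents = {name: np.zeros(n_steps) for name in record_groups}

        spike_t: list[float] = []
        spike_i: list[int] = []
        li = self._lifl_idx
        ai = self._adex_idx

        has_noise = noisy.size > 0
        for k in range(n_steps):
            t = k * dt
            t_next = t + dt

            # 1) deliver due synaptic arrivals (IE-gated) and external events
            slot = k % ring_len
            arr = ring[slot]
            if arr.any():
                i_syn += self.ie * arr
                arr[:] = 0.0
            if k in ext_by_step:
                for neuron_id, weight in ext_by_step[k]:
                    if t >= refract_until[neuron_id]:
                        i_syn[neuron_id] += self.ie[neuron_id] * weight
            if has_noise:
                counts = rng.poisson(lam)
                if counts.any():
                    i_syn[noisy] += self.ie[noisy] * self.noise_weight[noisy] * counts

            if record_groups:
                for name, idx in record_groups.items():
                    currents[name][k] = i_syn[idx].sum()

            spikers_t: list[float] = []
            spikers_i: list[int] = []

            # 2) LIFL update: one leaky propagation for every regime; a
            # threshold crossing commits the neuron to fire at
            # t_cross + SL(V_max), cancellable only by active inhibition
            if li.size:
                vl = v[li]
                il = i_syn[li]
                refr = t < refract_until[li]
                ovr = over[li]

                # refractory: clamp at rest, discard accumulated input
                if refr.any():
                    vl[refr] = p.v_rest
                    il[refr] = 0.0

                v_new = vl.copy()
                active = np.flatnonzero(~refr)
                if active.size:
                    v_new[active] = (
                        p.v_rest + (vl[active] - p.v_rest) * ea + il[active] * c_under
                    )
                idx_u = np.flatnonzero(~ovr & ~refr)
                if idx_u.size:
                    crossed = v_new[idx_u] > p.v_th
                    if crossed.any():
                        ci = idx_u[crossed]
                        frac = (p.v_th - vl[ci]) / np.maximum(v_new[ci] - vl[ci], 1e-30)
                        g = li[ci]
                        t_cross[g] = t + dt * np.clip(frac, 0.0, 1.0)
                        v_max[g] = np.maximum(v_new[ci], p.v_th + 1e-12)
                        over[g] = True
                        ovr = over[li]
                idx_o = np.flatnonzero(ovr & ~refr)
                if idx_o.size:
                    g = li[idx_o]
                    vg = v_new[idx_o]
                    cancelled = (vg <= p.v_th) & (il[idx_o] < 0.0)
                    if cancelled.any():
                        gc = g[cancelled]
                        over[gc] = False
                        t_cross[gc] = np.nan
                        t_sched[gc] = np.inf
                        v_max[gc] = np.nan
                    alive = ~cancelled
                    if alive.any():
                        ga = g[alive]
                        v_max[ga] = np.maximum(v_max[ga], vg[alive])
                        s = (v_max[ga] - p.v_th) / p.v_span
                        lat = p.sl_max / (1.0 + s / p.latency_shape)
                        t_sched[ga] = t_cross[ga] + lat
                        firing = t_sched[ga] <= t_next
                        if firing.any():
                            gfire = ga[firing]
                            times = np.maximum(t_sched[gfire], t)
                            for gi, ts_ in zip(gfire, times):
                                spikers_i.append(int(gi))
                                spikers_t.append(float(ts_))
                            v_new[np.isin(li, gfire)] = p.v_rest
                            il[np.isin(li, gfire)] = 0.0
                            over[gfire] = False
                            t_cross[gfire] = np.nan
                            t_sched[gfire] = np.inf
                            v_max[gfire] = np.nan
                            refract_until[gfire] = times + p.refractory
                v[li] = v_new
                i_syn[li] = il * eb

            # 3) AdEx update (forward Euler)
            if ai.size:
                va = v[ai]
                ia = i_syn[ai]
                wa = w_adapt[ai]
                refr = t < refract_until[ai]
                expo = np.exp(np.minimum((va - q.v_t) / q.delta_t, 20.0))
                dv = (
                    -q.g_l * (va - q.e_l)
                    + q.g_l * q.delta_t * expo
                    - wa
                    + ia
                    + self.bias[ai]
                ) / q.c_m
                dw = (q.a * (va - q.e_l) - wa) / q.tau_w
                va = va + dt * dv
                wa = wa + dt * dw
                va[refr] = q.v_reset
                fired = va >= q.v_peak
                if fired.any():
                    gf = ai[fired]
                    for gi in gf:
                        spikers_i.append(int(gi))
                        spikers_t.append(t_next)
                    va[fired] = q.v_reset
                    wa[fired] += q.b
                    refract_until[gf] = t_next + q.refractory
                v[ai] = va
                w_adapt[ai] = wa
                i_syn[ai] = ia * eb_adex

            # 4) propagate spikes through the delay buffers
            for gi, ts_ in zip(spikers_i, spikers_t):
                lo, hi = self.indptr[gi], self.indptr[gi + 1]
                if hi > lo:
                    slots = (k + self._delay_steps[lo:hi]) % ring_len
                    np.add.at(ring, (slots, self._dst[lo:hi]), self._w[lo:hi])
                spike_t.append(ts_)
                spike_i.append(gi)

        return SimResult(
            spike_times=np.asarray(spike_t),
            spike_ids=np.asarray(spike_i, dtype=np.int64),
            duration=duration,
            dt=dt,
            currents=currents,
        )

    # -- plasticity -----------------------------------------------------------

    def apply_plasticity(self, result: SimResult, params: PlasticityParams) -> None:
        """Update IE gains of plastic neurons from one trial's spike record.

        Each modulator (stimulator) edge pairs the presynaptic *emission*
        times with the postsynaptic neuron's nearest own spike; the summed
        signed exponential updates are applied at once (per-trial application
        is equivalent to the online rule when neurons fire at most once per
        trial, as here).
        """
        if not params.enabled or self.stim_src.size == 0:
            return
        times_by_neuron: dict[int, np.ndarray] = {}
        for gi in np.unique(result.spike_ids):
            times_by_neuron[int(gi)] = result.spike_times[result.spike_ids == gi]
        delta = np.zeros(self.n)
        for s, d in zip(self.stim_src, self.stim_dst):
            if not self.plastic[d]:
                continue
            t_posts = times_by_neuron.get(int(d))
            t_pres = times_by_neuron.get(int(s))
            if t_posts is None or t_pres is None:
                continue
            for tp in t_pres:
                t_post = t_posts[np.argmin(np.abs(t_posts - tp))]
                dt_pair = tp - t_post
                mag = params.lam * math.exp(-abs(dt_pair) / params.tau)
                if params.sign_convention == "convergent":
                    delta[d] += mag if dt_pair <= 0 else -mag
                else:
                    delta[d] += -mag if dt_pair <= 0 else mag
        self.ie = np.maximum(self.ie + delta, IE_P_FLOOR)
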