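# Methods

This note documents the model equations, the parameter choices and their
rationale, the numerical scheme, and the known limitations of `spikelat`.
Everything quantitative stated here is computed by the test suite or by
`scripts/acceptance.py`; nothing is asserted from memory.

## Neuron models

### LIFL (layer IV spiny-stellate cells, detector delay and target neurons)

Below threshold the membrane is a leaky integrator driven by
exponential-current synapses:

    dV/dt = -a (V - V_rest) + I_syn(t) / C_m,     dI_syn/dt = -I_syn / tau_s

with `V_rest = -70 mV`, `V_th = -54.4 mV`, relaxation rate `a = 0.02 /ms`
(membrane time constant 50 ms), `tau_s = 2 ms`, `C_m = 250 pF`. A presynaptic
pulse of weight `w` (pA) increments the current by `IE_p * w`, where `IE_p`
is the neuron's intrinsic-excitability gain (dimensionless, initially 1).
Both equations are linear, so the package integrates them in closed form.

Above threshold the neuron expresses *spike latency*. The latency curve is a
rectangular hyperbola in the normalised over-threshold state
`S = (V - V_th)/(V_th - V_rest)`:

    SL(V) = SL_max / (1 + S / s),    SL_max = 25 ms

The analytic form of the original over-threshold dynamics is not part of the
public record, so the curve above is this package's own construction,
designed to honour three constraints: strict monotonicity, the 25 ms limit
for barely supra-threshold drive, and a 12.5 ms latency for the default
detector input pulse. The steepness `s = 0.0987` is not hand-set: it is the
output of `calibrate_latency_shape`, which bisects `s` until the shipped
default pulse (2450 pA at `IE_p = 1`) yields exactly 12.5 ms; a test pins the
shipped constant to its calibration.

**Commitment semantics.** The membrane follows the *same leaky ODE* in both
regimes. An upward crossing of `V_th` at `t_cross` commits the neuron to
fire at `t_cross + SL(V_max)`, where `V_max` is the running maximum
potential since the crossing. Later excitatory input raises `V_max` and
advances the spike; passive decay does not revoke the commitment (the
biological upswing is self-sustaining), but active inhibition — negative
synaptic current that drags `V` below `V_th` — cancels it. This design was
chosen over a leak-free "frozen upswing" variant because only the leaky
form reproduces the exact `SL -> SL_max` limit for barely supra-threshold
input: in a leak-free upswing, the residual synaptic current that balances
the leak at a tangency crossing (~78 pA at these parameters) always adds
~0.6 mV after the crossing, capping the latency near 21 ms. On spike
emission the potential resets to `V_rest`, the synaptic current clears, and
a 2 ms absolute refractory period begins during which input is discarded.
`tau_s`, the refractory period and the reset rule are conventional values,
exposed in the configuration.

### AdEx (all other cortical populations)

Layers II/III, V, VI and every inhibitory pool use the adaptive-exponential
integrate-and-fire neuron with textbook parameters (`C = 281 pF`,
`g_L = 30 nS`, `E_L = -70.6 mV`, `V_T = -50.4 mV`, `Delta_T = 2 mV`,
`a = 4 nS`, `b = 80.5 pA`, `tau_w = 144 ms`, reset -60 mV), exponential
current synapses, forward-Euler integration at the global 0.1 ms step. Each
trial starts at the neuron's tonic steady state `(V*, w*)` under its mean
drive — the adaptation variable's 144 ms time constant would otherwise make
the evoked response depend on where the stimulus falls within the trial.

## Intrinsic-excitability plasticity

Each (modulator pulse, own spike) pair changes the postsynaptic neuron's
gain by

    delta IE_p = +/- lambda * exp(-|dt| / tau),   lambda = 5e-4, tau = 12.5 ms

Only pulses from registered "stimulator" sources trigger updates; `IE_p`
is floored at 0.01; there is no upper bound (training is finite).

Two deliberate choices:

* **Sign convention.** The rule as commonly written (potentiation for
  `dt = t_pre - t_post > 0`) makes the earliest neuron of a mutually
  modulating group accelerate away — the group diverges. The default here is
  the *convergent* convention: a modulator pulse preceding the neuron's own
  spike potentiates (laggards speed up), one following it depresses
  (leaders slow down). The opposite sign remains available
  (`sign_convention="printed"`).
* **Pairing time.** Pairings use the modulator's *emission* time, not its
  arrival time. With arrival-time pairing, the 1 ms conduction delay means
  that once the group is synchronized every modulator pulse arrives just
  *after* the neuron's own spike, producing a common-mode depression of the
  whole group that eventually silences its weakest member (verified
  numerically). Emission-time pairing makes synchronized emission the rule's
  fixed point: near synchrony, the pair of updates between two neurons is
  antisymmetric and cancels.

Updates are applied once per trial from the recorded spike times; because
every neuron fires at most once per presentation in this model, this is
equivalent to the online per-arrival rule.

## The sequence detector (MNSD)

Four generators feed four LIFL delay neurons one-to-one (weight 2450 pA);
the delay neurons modulate each other in a ring (weight 1 pA — enough to
time-stamp, too weak to depolarise) and converge on one LIFL target. The
target weight is not a free parameter: `calibrate_target_weight` bisects it
so that four spikes spread over the 3 ms sync window fire the target while
three coincident spikes, or four spikes spread over twice the inter-pulse
interval, do not; the midpoint of the feasible interval is used. Training
presents the pattern (0, 5, 10, 15 ms) 300 times with plasticity on; the
delay-layer volley span contracts from 15 ms to well under 1 ms, the final
gains straddle 1, and recognition is specific: the trained ordering fires
the target, the other 23 permutations do not. Nominal trials last 1 s with
a state reset in between; since the network is provably silent once the
volley and maximal latencies have passed, the simulation covers only the
active window.

The input-pulse amplitude (2450 pA) is the one genuinely free constant; it
was chosen once so that the training loop converges without silencing any
delay neuron (too-steep latency curves let depression push a neuron's peak
potential below threshold, after which it can never recover because it no
longer spikes).

## Retina and LGN surrogate

The package replaces a full retina simulator with the one property the
cortical model consumes: an orientation-specific spatio-temporal first-spike
pattern inside a 20 ms window. Pixel `i` of an 18x18 Gabor patch (intensity
in [0, 1], background 0.5) has local contrast `c_i = 2 |I_i - 0.5|`;
channels below contrast 0.1 stay silent, the rest fire once at
`t0 + 20 * (1 - c_i / c_max)` ms. `t0` (retina + LGN conduction, 30 ms)
is a calibration constant: it was set so that the simulated dipole-moment
response peaks at the empirically observed ~80 ms post-stimulus given the
model's own cortical processing time (~50 ms from retinal wave to the
deep-layer current peak).

Gabor defaults: 2.6 cycles/patch, phase 0, envelope sigma 4 px, contrast 1.
The spatial frequency matters more than it looks: at 3 cycles/patch the
carrier period (6 px) is commensurate with the 2x2 retinotopic blocks that
form the detector groups, so 0- and 90-degree gratings produce degenerate
within-block timing and those two columns cannot be told apart. 2.6
cycles/patch breaks the commensurability; every orientation then drives
roughly half the channels with non-degenerate block timing, and all four
columns discriminate equivalently. Phase 0 keeps the carrier even-symmetric
so that theta and theta + 180 degrees are identical stimuli.

What the surrogate does *not* emulate: centre-surround receptive fields,
transient/sustained ganglion-cell classes, contrast adaptation, photoreceptor
noise, and any retinotopic magnification. Tests passing on this input show
that the cortical model decodes orientation from relative first-spike
timing; they do not show robustness to realistic retinal variability.

## The cortical column and pinwheel

Population sizes (per column, 1167 neurons): L II/III 324 PC + 65 inh,
L IV 324 SS + 65 inh, L V 81 PC + 16 inh, L VI 243 PC + 49 inh. All
connectivity uses 100 pA (sign-inverted for inhibitory sources) and 1 ms
delay, with fixed per-neuron in-degrees:

| to \ from        | L23 PC | L23 inh | SS | L4 inh | L5 PC | L5 inh | L6 PC | L6 inh |
|------------------|--------|---------|----|--------|-------|--------|-------|--------|
| L II/III PC      | 36     | 8       | 4* | -      | -     | -      | -     | -      |
| L II/III inh     | 35     | 8       | -  | -      | -     | -      | -     | -      |
| L IV SS          | -      | -       | 3* | 6      | -     | -      | -     | -      |
| L IV inh         | -      | -       | 32 | 6      | -     | -      | -     | -      |
| L V PC           | 15     | -       | -  | -      | 10    | 8      | -     | -      |
| L V inh          | -      | -       | -  | -      | 30    | 8      | -     | -      |
| L VI PC          | -      | -       | -  | -      | 20    | -      | 20    | 6      |
| L VI inh         | -      | -       | -  | -      | -     | -      | 32    | 6      |

Starred entries are structured rather than random: the 324 retina channels
map one-to-one onto the SS cells; the SS cells tile into 81 row-major 2x2
blocks; within a block the four SS are all-to-all modulators (in-degree 3,
1 pA, stimulator-flagged), and each block projects to its four dedicated
L II/III PC targets (in-degree 4) at the calibrated group-target weight.
A wiring audit asserts every realized in-degree exactly.

### Operating points

Three tonic drives position the AdEx populations (all exposed in
`ColumnSpec`):

* `bg_bias = 350 pA` for L II/III and L IV inhibition. The recurrent
  excitation of L II/III (in-degree 36 at 100 pA) gives the column a sharp
  ignition threshold near 425-430 pA of bias: above it the column fires
  spontaneously at several Hz *and responds at ceiling to every
  orientation*, below it the spontaneous rate is essentially zero. An
  intended operating point with 1-3 Hz spontaneous pyramidal firing is
  therefore incompatible with orientation discrimination in this
  architecture; the model runs just below ignition, trading spontaneous
  activity for selectivity. This is a known limitation, not a tuned value:
  the orientation-selectivity index reported by the acceptance pipeline is
  an emergent consequence of this operating point, the noise, and the
  simultaneity calibration.
* `deep_bias = 455 pA` for layers V/VI (and their inhibition). At the
  uniform 350 pA point the L II/III -> L V -> L VI cascade is too weak to
  fire the deep layers, which contradicts the intended behaviour (deep
  layers relay the detection); 455 pA lets the cascade follow promptly while
  remaining silent at rest and for non-preferred stimuli. Because the
  anatomical table has no feedback from L V/VI to L II/III, this choice
  cannot affect the OSI.
* Poisson backgrounds: 300 Hz x 10 pA onto SS cells (latency jitter of a
  few ms without spontaneous SS firing), 2000 Hz x 30 pA onto AdEx cells
  (membrane fluctuations of ~1.4 mV). Calibrations of the group-target
  weight run on a probe neuron held at bias *plus the Poisson mean*, i.e.
  at the potential the population actually fluctuates around.

The cortical group-target calibration mirrors the detector's but with a
2 ms sync window and a rejection case at twice the window (instead of twice
the inter-pulse interval): cortical volleys are noise-jittered and
partially aligned volleys are common at non-preferred orientations, so the
acceptance/rejection boundary must sit tighter than in the noiseless
standalone detector.

### Protocols

Training: each column sees its preferred-orientation patch repeatedly
(published protocol 500 presentations at 200 ms intervals; the package
default tests and the acceptance script use 100, which suffices for group
synchronization) with plasticity on SS cells only. Because no pathway
feeds back into L IV, training simulates only the L IV subnetwork (the
other populations' drives are temporarily silenced) — an exact
optimisation, not an approximation.

Test: plasticity off; 37 orientations (0-180 in 5-degree steps) presented
for 200 ms each, repeated trials (published 30; reduced runs use 10);
L II/III PC rates measured in the 50-100 ms window;
`OSI = (R_pref - R_orth)/(R_pref + R_orth)` per trial and column, averaged.

Evoked response: the dipole moment is the sum over the four columns of each
pyramidal layer's summed synaptic current weighted by mean apical-dendrite
length (L II/III 4.82e-4 m, L V 1.342e-3 m, L VI 9.63e-4 m), baseline-
corrected by the pre-arrival mean (t < 35 ms) and averaged over 30 trials.
MUA pools every spike of the pinwheel into 10 ms bins over 0-110 ms and
smooths with a centred 3-bin moving average, truncated at the edges so the
unsmoothed bin sum equals the spike count.

## Numerical choices

* Global step 0.1 ms. LIFL state is advanced with the exact closed-form
  propagator per step, so the only grid artefacts are event delivery
  quantised to step boundaries and threshold-crossing interpolation; LIFL
  spike *times* are kept continuous. A property test holds 0.1 ms vs
  0.001 ms spike times to within 0.1 ms (they agree far more tightly).
* The single-neuron path (`spikelat.neuron`) is piecewise analytic with
  Brent root-finding (tolerance 1e-10 ms) for crossings, peaks and committed
  spike times; it serves as the reference for the grid engine.
* Ties: an exactly simultaneous modulator pulse and own spike counts as
  potentiation at full magnitude (measure-zero after delay compensation);
  cross-correlation lag ties resolve to the smallest |lag|.
* Degenerate inputs: a uniform image encodes to an empty pattern; an empty
  pattern elicits only noise-driven activity; OSI with both rates zero, the
  lag of a flat signal, and the similarity of a constant series are
  reported as missing (NaN), never as 0.
* Determinism: all stochastic draws (wiring, Poisson noise) flow from
  caller-supplied seeds/generators; identical seeds give bit-identical
  spike streams.

## Problem sizes in the shipped checks

The test suite and acceptance script train each column with 100
presentations, sweep 37 orientations at 10 trials each, and average the
evoked response over 30 trials — reductions of the published 500/30
protocol chosen to keep a full from-scratch run around ten minutes on one
CPU while preserving every qualitative regime (group synchronization
saturates well before 100 presentations; the OSI estimate's trial noise at
10 trials is small against the acceptance tolerance).

## Known limitations

* The spontaneous-activity regime and the selective regime are mutually
  exclusive at the published connectivity and weight (see Operating points);
  the model runs quiet-but-selective.
* The evoked-response waveform is bimodal on single trials (an early
  L II/III lobe and a later deep-layer lobe); the trial-averaged peak is
  stable but single-trial peak times can alternate between lobes.
* Orientation discrimination rests on relative first-spike timing produced
  by a deliberately simple retinal surrogate; absolute latencies and
  contrast dependence are not biologically calibrated.
* One detector learns one pattern; learning multiple patterns per group and
  weight/delay-based detector variants are out of scope.
* The pinwheel's four columns are independent by construction — no
  horizontal connections, no shared inhibition — so cross-column
  normalisation phenomena cannot emerge.
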