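"""Spike-timing-dependent plasticity of intrinsic excitability (IE).

Instead of changing synaptic weights, this rule changes a multiplicative gain
``IE_p`` on the *postsynaptic neuron's own* input current (non-synaptic
plasticity).  Designated presynaptic "stimulator" (modulator) sources trigger
the update: each (modulator pulse, own spike) pair changes ``IE_p`` by

    delta = +/- lambda * exp(-|dt| / tau),        dt = t_pre - t_post

with ``lambda`` the maximum per-pulse change and ``tau`` the plasticity time
window.

Two sign conventions are available:

* ``"convergent"`` (default): a modulator pulse arriving *before* the
  neuron's own spike potentiates (the laggard speeds up), one arriving
  *after* depresses (the leader slows down).  In a ring of mutually
  modulating neurons this drives the output spikes together, which is the
  behaviour the sequence detector relies on.
* ``"printed"``: the opposite assignment (potentiation for dt > 0), kept as
  an option for comparison; it makes the earliest neuron accelerate further
  and does not converge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .neuron import NeuronState

__all__ = ["PlasticityParams", "ie_delta", "update_on_pair", "IE_P_FLOOR"]

#: Lower bound on IE_p, preventing sign inversion of input currents.
IE_P_FLOOR = 0.01


@dataclass(frozen=True)
class PlasticityParams:
    """Parameters of the intrinsic-excitability update rule."""

    lam: float = 0.0005       #: maximum per-pulse change (dimensionless)
    tau: float = 12.5         #: plasticity time window, ms
    stimulators: frozenset = field(default_factory=frozenset)
    enabled: bool = True      #: master on/off switch for the rule
    sign_convention: str = "convergent"  #: 'convergent' | 'printed'

    def __post_init__(self) -> None:
        if self.lam <= 0 or self.tau <= 0:
            raise ValueError("lam and tau must be positive")
        if self.sign_convention not in ("convergent", "printed"):
            raise ValueError("sign_convention must be 'convergent' or 'printed'")


def ie_delta(delta_t: float, params: PlasticityParams) -> float:
    """Signed IE_p change for one modulator-pulse / own-spike pair.

    ``delta_t = t_pre - t_post`` (modulator arrival minus own spike time).
    Magnitude ``lam * exp(-|delta_t|/tau)``; under the convergent convention
    the change is positive (potentiation) when the modulator pulse precedes
    the spike (``delta_t < 0``).  An exact tie (``delta_t == 0``) counts as
    potentiation with the full magnitude ``lam``.
    """
    magnitude = params.lam * math.exp(-abs(delta_t) / params.tau)
    pre_first = delta_t <= 0.0
    if params.sign_convention == "convergent":
        return magnitude if pre_first else -magnitude
    return -magnitude if pre_first else magnitude


def update_on_pair(
    state: NeuronState,
    t_pre: float,
    t_post: float,
    source_id: int,
    params: PlasticityParams,
) -> NeuronState:
    """Apply one pairing to a neuron's IE_p; no-op for non-stimulator sources.

    Returns a new state with ``IE_p <- max(IE_p + ie_delta(t_pre - t_post),
    floor)``.  When plasticity is disabled or the source is not a registered
    stimulator the state is returned unchanged.
    """
    out = state.copy()
    if not params.enabled or source_id not in params.stimulators:
        return out
    out.ie_p = max(out.ie_p + ie_delta(t_pre - t_post, params), IE_P_FLOOR)
    return out
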