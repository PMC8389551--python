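"""Tuning curves, orientation selectivity, and synthetic evoked signals.

This module turns raw simulation records into the quantities used to compare
the model with electrophysiology:

* orientation tuning curves from layer II/III firing rates in the 50-100 ms
  post-stimulus window, and the orientation selectivity index
  ``OSI = (R_pref - R_orth) / (R_pref + R_orth)``;
* a current dipole moment (pA*m) obtained by weighting each pyramidal
  layer's postsynaptic current by its mean apical-dendrite length
  (4.82e-4 m for L II/III, 1.342e-3 m for L V, 9.63e-4 m for L VI), the
  quantity comparable to source-reconstructed MEG activity;
* multi-unit activity (MUA): pooled spike counts in 10 ms bins over
  0-110 ms, lightly smoothed;
* comparison statistics: cross-correlation lag and windowed Pearson
  similarity (25-100 ms, min-max scaled), plus a surrogate recorded-signal
  generator so the comparison path can be exercised without external
  recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .patterns import SpikePattern

__all__ = [
    "TuningCurve",
    "EvokedSignal",
    "SweepResult",
    "DENDRITE_LENGTH_M",
    "firing_rate_window",
    "tuning_curve",
    "osi",
    "dipole_moment",
    "mua",
    "xcorr_lag",
    "similarity",
    "surrogate_recorded_signal",
]

#: Mean apical-dendrite length per pyramidal layer (metres).
DENDRITE_LENGTH_M = {"L23": 4.82e-4, "L5": 1.342e-3, "L6": 9.63e-4}


@dataclass
class TuningCurve:
    """Mean firing rate per stimulus orientation, plus the peak-normalised curve."""

    orientations: np.ndarray   #: degrees
    mean_rate: np.ndarray      #: spikes/s
    normalized_rate: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.orientations = np.asarray(self.orientations, float)
        self.mean_rate = np.asarray(self.mean_rate, float)
        if self.orientations.shape != self.mean_rate.shape:
            raise ValueError("orientations and rates must align")
        peak = self.mean_rate.max() if self.mean_rate.size else 0.0
        self.normalized_rate = (
            self.mean_rate / peak if peak > 0 else np.zeros_like(self.mean_rate)
        )

    @property
    def preferred_orientation(self) -> float:
        return float(self.orientations[int(np.argmax(self.mean_rate))])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "orientation_deg": self.orientations,
                "mean_rate": self.mean_rate,
                "normalized_rate": self.normalized_rate,
            }
        )

    def plot(self, ax=None, normalized: bool = True, **kwargs):
        """Plot the tuning curve; returns the matplotlib axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        y = self.normalized_rate if normalized else self.mean_rate
        ax.plot(self.orientations, y, marker="o", **kwargs)
        ax.set_xlabel("orientation (deg)")
        ax.set_ylabel("normalized FR" if normalized else "FR (spikes/s)")
        return ax


@dataclass
class EvokedSignal:
    """A uniformly sampled time series referenced to stimulus onset (t = 0)."""

    t: np.ndarray          #: ms
    values: np.ndarray
    unit: str = "a.u."     #: 'pA*m' | 'spikes/bin' | 'a.u.'

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, float)
        self.values = np.asarray(self.values, float)
        if self.t.shape != self.values.shape:
            raise ValueError("t and values must align")
        if self.t.size >= 2:
            steps = np.diff(self.t)
            if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
                raise ValueError("sampling must be uniform")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0]) if self.t.size >= 2 else np.nan

    @property
    def peak_time(self) -> float:
        return float(self.t[int(np.argmax(self.values))])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ms": self.t, "value": self.values, "unit": self.unit})

    def plot(self, ax=None, **kwargs):
        """Plot the signal against post-stimulus time; returns the axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.t, self.values, **kwargs)
        ax.set_xlabel("time from stimulus onset (ms)")
        ax.set_ylabel(self.unit)
        return ax


# ---------------------------------------------------------------------------
# rates, tuning, OSI
# ---------------------------------------------------------------------------

def firing_rate_window(
    spikes: SpikePattern,
    population=None,
    t_start: float = 50.0,
    t_end: float = 100.0,
) -> float:
    """Population spike rate (spikes/s) in ``[t_start, t_end)``.

    ``population`` restricts the count to the given neuron ids; None counts
    every spike in the pattern.
    """
    if not t_start < t_end:
        raise ValueError("empty rate window")
    pat = spikes if population is None else spikes.select(population)
    return pat.count_in_window(t_start, t_end) / (t_end - t_start) * 1000.0


def tuning_curve(orientations, rates) -> TuningCurve:
    """Average trial rates per orientation and normalise to the curve peak.

    ``rates`` may be (n_orientations,) or (n_orientations, n_trials).
    """
    rates = np.asarray(rates, float)
    if rates.ndim == 2:
        rates = rates.mean(axis=1)
    return TuningCurve(np.asarray(orientations, float), rates)


def osi(r_pref: float, r_orth: float) -> float:
    """Orientation selectivity index ``(R_pref - R_orth)/(R_pref + R_orth)``.

    Undefined (NaN) when both rates are zero.
    """
    total = r_pref + r_orth
    if total <= 0:
        return float("nan")
    return (r_pref - r_orth) / total


class SweepResult:
    """Firing rates from an orientation sweep over the pinwheel columns.

    ``rates`` has shape (n_columns, n_orientations, n_trials): layer II/III
    pyramidal population rate in the evoked window for every presentation.
    """

    def __init__(self, orientations, preferred, rates):
        self.orientations = np.asarray(orientations, float)
        self.preferred = tuple(preferred)
        self.rates = np.asarray(rates, float)
        if self.rates.shape[0] != len(self.preferred):
            raise ValueError("one rate block per column required")
        if self.rates.shape[1] != self.orientations.size:
            raise ValueError("one rate row per orientation required")

    def tuning_curve(self, column: int | float) -> TuningCurve:
        idx = self._column_index(column)
        return tuning_curve(self.orientations, self.rates[idx])

    def _column_index(self, column: int | float) -> int:
        if isinstance(column, (int, np.integer)) and column < len(self.preferred):
            return int(column)
        for i, theta in enumerate(self.preferred):
            if theta == column:
                return i
        raise KeyError(f"unknown column {column}")

    def _orientation_index(self, theta: float) -> int:
        matches = np.flatnonzero(np.isclose(self.orientations % 180.0, theta % 180.0))
        if matches.size == 0:
            raise KeyError(f"orientation {theta} not in the sweep")
        return int(matches[0])

    def osi_table(self) -> pd.DataFrame:
        """Per-trial, per-column OSI from the preferred/orthogonal rates."""
        rows = []
        n_trials = self.rates.shape[2]
        for i, theta in enumerate(self.preferred):
            ip = self._orientation_index(theta)
            io = self._orientation_index(theta + 90.0)
            for trial in range(n_trials):
                r_pref = self.rates[i, ip, trial]
                r_orth = self.rates[i, io, trial]
                rows.append(
                    {
                        "column": theta,
                        "trial": trial,
                        "r_pref": r_pref,
                        "r_orth": r_orth,
                        "osi": osi(r_pref, r_orth),
                    }
                )
        return pd.DataFrame(rows)

    def mean_osi(self) -> float:
        """Mean OSI across trials and columns (NaN-aware)."""
        return float(np.nanmean(self.osi_table()["osi"].to_numpy()))

    def plot(self, ax=None):
        """Overlay every column's normalized tuning curve; returns the axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for i, theta in enumerate(self.preferred):
            self.tuning_curve(i).plot(ax=ax, label=f"column {theta:g}")
        ax.legend()
        return ax

    def summary(self) -> str:
        lines = [
            "Orientation sweep summary",
            "=========================",
            f"orientations: {self.orientations.size} "
            f"({self.orientations[0]:.0f}-{self.orientations[-1]:.0f} deg)",
            f"trials per orientation: {self.rates.shape[2]}",
        ]
        for i, theta in enumerate(self.preferred):
            curve = self.tuning_curve(i)
            lines.append(
                f"column {theta:>5.1f}: peak at {curve.preferred_orientation:6.1f} deg, "
                f"peak rate {curve.mean_rate.max():8.1f} spikes/s"
            )
        lines.append(f"mean layer II/III OSI: {self.mean_osi():.3f}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# synthetic electrophysiology
# ---------------------------------------------------------------------------

def dipole_moment(currents: dict, dt: float) -> EvokedSignal:
    """Weight per-layer pyramidal postsynaptic currents by dendrite length.

    ``currents`` maps layer names (prefix 'L23', 'L5', 'L6'; trailing
    '_PC' accepted) to aligned pA traces sampled at ``dt`` ms; the output is
    their dendrite-length-weighted sum in pA*m.
    """
    resolved: dict[str, np.ndarray] = {}
    for name, series in currents.items():
        key = name.split("_")[0]
        if key not in DENDRITE_LENGTH_M:
            raise ValueError(f"unknown pyramidal layer {name!r}")
        resolved[key] = np.asarray(series, float)
    lengths = {len(v) for v in resolved.values()}
    if len(lengths) != 1:
        raise ValueError("current series must be aligned on the same time base")
    n = lengths.pop()
    out = np.zeros(n)
    for key, series in resolved.items():
        out += DENDRITE_LENGTH_M[key] * series
    return EvokedSignal(np.arange(n) * dt, out, unit="pA*m")


def mua(
    spikes: SpikePattern,
    t_start: float = 0.0,
    t_end: float = 110.0,
    bin_width: float = 10.0,
    smooth: bool = True,
) -> EvokedSignal:
    """Pooled spike counts in fixed bins, optionally smoothed.

    Smoothing is a centred 3-bin moving average truncated at the edges, so
    the unsmoothed bin sum equals the total spike count in the window.
    """
    n_bins = (t_end - t_start) / bin_width
    if abs(round(n_bins) - n_bins) > 1e-9:
        raise ValueError("bin width must divide the window")
    n_bins = int(round(n_bins))
    edges = t_start + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(spikes.times, bins=edges)
    values = counts.astype(float)
    if smooth and n_bins >= 2:
        padded = np.concatenate(([np.nan], values, [np.nan]))
        stacked = np.vstack([padded[:-2], padded[1:-1], padded[2:]])
        values = np.nanmean(stacked, axis=0)
    centers = edges[:-1] + bin_width / 2.0
    return EvokedSignal(centers, values, unit="spikes/bin")


# ---------------------------------------------------------------------------
# signal comparison
# ---------------------------------------------------------------------------

def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def xcorr_lag(a: EvokedSignal, b: EvokedSignal, max_lag: float | None = None) -> float:
    """Lag (ms) maximising the normalised cross-correlation of two signals.

    Positive lag means ``b`` leads ``a`` (``b(t) = a(t + lag)``).  The
    correlation is linear (non-circular), computed per lag on the
    full-overlap segment with Pearson normalisation; flat signals yield NaN.
    Ties resolve to the smallest |lag|.
    """
    if not np.isclose(a.dt, b.dt):
        raise ValueError("signals must share the sampling interval")
    dt = a.dt
    base = int(round((b.t[0] - a.t[0]) / dt))
    na, nb = a.values.size, b.values.size
    min_overlap = max(4, min(na, nb) // 4)
    lag_cap = (
        max(na, nb) - min_overlap
        if max_lag is None
        else int(round(max_lag / dt))
    )
    best_r = -np.inf
    best_lag = float("nan")
    for k in range(-lag_cap, lag_cap + 1):
        shift = k + base
        j0 = max(0, -shift)
        j1 = min(nb, na - shift)
        if j1 - j0 < min_overlap:
            continue
        r = _pearson(a.values[j0 + shift : j1 + shift], b.values[j0:j1])
        if np.isnan(r):
            continue
        lag_ms = k * dt
        if r > best_r + 1e-12 or (
            np.isclose(r, best_r) and abs(lag_ms) < abs(best_lag)
        ):
            best_r = r
            best_lag = lag_ms
    return best_lag if np.isfinite(best_r) else float("nan")


def _minmax(x: np.ndarray) -> np.ndarray:
    lo, hi = x.min(), x.max()
    if hi - lo == 0:
        return np.full_like(x, np.nan)
    return (x - lo) / (hi - lo)


def similarity(
    a: EvokedSignal,
    b: EvokedSignal,
    t_start: float = 25.0,
    t_end: float = 100.0,
) -> float:
    """Pearson correlation of two evoked signals in a post-stimulus window.

    Both signals are restricted to ``[t_start, t_end]``, resampled onto the
    coarser signal's grid, and min-max scaled to [0, 1] before correlating.
    Constant series yield NaN (reported missing).
    """
    for sig in (a, b):
        if sig.t[0] > t_start + 1e-9 or sig.t[-1] < t_end - 1e-9:
            raise ValueError("both signals must cover the comparison window")
    ref, other = (a, b) if a.dt >= b.dt else (b, a)
    mask = (ref.t >= t_start) & (ref.t <= t_end)
    grid = ref.t[mask]
    x = ref.values[mask]
    y = np.interp(grid, other.t, other.values)
    if ref is b:
        x, y = y, x
    xs, ys = _minmax(x), _minmax(y)
    if np.isnan(xs).any() or np.isnan(ys).any():
        return float("nan")
    return _pearson(xs, ys)


def surrogate_recorded_signal(
    kind: str = "postsynaptic",
    lag: float = 0.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
    duration: float = 200.0,
) -> EvokedSignal:
    """Synthetic stand-in for a recorded evoked response.

    A gamma-shaped waveform rising from ~60 ms and peaking near 80 ms
    post-onset (the canonical early visual evoked component), time-advanced
    by ``lag`` ms and degraded with white noise of ``noise_sd`` (relative to
    a unit peak).  ``kind`` selects the sampling: 'postsynaptic' (1 ms grid)
    or 'spiking' (10 ms MUA bins over 0-110 ms).  Deterministic given
    ``seed``.
    """
    if kind == "postsynaptic":
        t = np.arange(0.0, duration + 1e-9, 1.0)
    elif kind == "spiking":
        t = np.arange(5.0, 110.0, 10.0)
    else:
        raise ValueError("kind must be 'postsynaptic' or 'spiking'")
    waveform = stats.gamma.pdf(t + lag, a=4.0, loc=50.0, scale=10.0)
    peak = stats.gamma.pdf(50.0 + 30.0, a=4.0, loc=50.0, scale=10.0)
    values = waveform / peak
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_sd, size=t.size)
    unit = "a.u." if kind == "postsynaptic" else "spikes/bin"
    return EvokedSignal(t, values, unit=unit)
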