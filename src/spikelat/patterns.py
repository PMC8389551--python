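"""Parallel spike sequences: the lingua franca between retina, MNSD and cortex."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SpikePattern"]


@dataclass
class SpikePattern:
    """A set of (channel, time) spike events with a stimulus-onset reference.

    ``channels`` and ``times`` are parallel arrays; times are in ms.  The
    retinal first-spike code additionally guarantees at most one event per
    channel within a 20 ms window (see
    :func:`spikelat.retina.encode_latency`); generic spike records (network
    output rasters) do not.
    """

    channels: np.ndarray
    times: np.ndarray
    onset: float = 0.0

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=np.int64)
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.channels.shape != self.times.shape:
            raise ValueError("channels and times must have equal length")
        if self.times.size and np.any(self.times < 0):
            raise ValueError("spike times must be non-negative")

    @classmethod
    def from_events(cls, events: list[tuple[int, float]], onset: float = 0.0) -> "SpikePattern":
        if not events:
            return cls(np.empty(0, dtype=np.int64), np.empty(0), onset=onset)
        ch, t = zip(*events)
        return cls(np.asarray(ch), np.asarray(t, dtype=float), onset=onset)

    def __len__(self) -> int:
        return int(self.times.size)

    def sorted(self) -> "SpikePattern":
        order = np.lexsort((self.channels, self.times))
        return SpikePattern(self.channels[order], self.times[order], self.onset)

    def shifted(self, dt: float) -> "SpikePattern":
        """Translate every event (and the onset) by ``dt`` ms."""
        return SpikePattern(self.channels.copy(), self.times + dt, self.onset + dt)

    def events(self) -> list[tuple[int, float]]:
        return list(zip(self.channels.tolist(), self.times.tolist()))

    def select(self, channel_ids) -> "SpikePattern":
        """Restrict to events whose channel is in ``channel_ids``."""
        mask = np.isin(self.channels, np.asarray(list(channel_ids)))
        return SpikePattern(self.channels[mask], self.times[mask], self.onset)

    def count_in_window(self, t_start: float, t_end: float) -> int:
        return int(np.count_nonzero((self.times >= t_start) & (self.times < t_end)))

    def is_first_spike_code(self, window: float = 20.0) -> bool:
        """True when no channel repeats and all events span at most ``window`` ms."""
        if len(self) == 0:
            return True
        unique = np.unique(self.channels).size == self.channels.size
        span = float(self.times.max() - self.times.min())
        return unique and span <= window + 1e-9

    def __eq__(self, other) -> bool:
        if not isinstance(other, SpikePattern):
            return NotImplemented
        # channel-major ordering: robust to float ties in the time sort
        oa = np.lexsort((self.times, self.channels))
        ob = np.lexsort((other.times, other.channels))
        a = SpikePattern(self.channels[oa], self.times[oa], self.onset)
        b = SpikePattern(other.channels[ob], other.times[ob], other.onset)
        return (
            np.array_equal(a.channels, b.channels)
            and np.allclose(a.times, b.times)
            and abs(a.onset - b.onset) < 1e-12
        )
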