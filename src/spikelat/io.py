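"""Readers and writers for the package's plain-text formats.

Formats (all diffable text):

* spike patterns — two-column TSV ``channel_id<TAB>time_ms`` with an
  optional ``# onset`` header comment;
* evoked signals — CSV ``time_ms,value,unit``;
* tuning curves — CSV ``orientation_deg,mean_rate,normalized_rate``;
* grayscale patches — PGM (P2, text) or flat CSV;
* trained-state snapshots — NumPy ``.npz`` holding every column's
  intrinsic-excitability gains plus the column orientations, checked on
  load against the pinwheel the snapshot is restored into.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .analysis import EvokedSignal, TuningCurve
from .patterns import SpikePattern

__all__ = [
    "write_spike_pattern",
    "read_spike_pattern",
    "write_evoked_signal",
    "read_evoked_signal",
    "write_tuning_curve",
    "read_tuning_curve",
    "write_pgm",
    "read_pgm",
    "write_png",
    "write_image_csv",
    "save_trained_state",
    "load_trained_state",
]


class FormatError(ValueError):
    """Malformed file content; the message names the offending line."""


# ---------------------------------------------------------------------------
# spike patterns (TSV)
# ---------------------------------------------------------------------------

def write_spike_pattern(pattern: SpikePattern, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# onset\t{pattern.onset}\n")
        fh.write("channel_id\ttime_ms\n")
        for ch, t in zip(pattern.channels, pattern.times):
            fh.write(f"{int(ch)}\t{float(t)!r}\n")


def read_spike_pattern(path) -> SpikePattern:
    path = Path(path)
    onset = 0.0
    channels: list[int] = []
    times: list[float] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split()
                if len(parts) == 2 and parts[0] == "onset":
                    onset = float(parts[1])
                continue
            if line.startswith("channel_id"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 tab-separated fields")
            try:
                ch = int(parts[0])
                t = float(parts[1])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            if t < 0:
                raise FormatError(f"{path}:{lineno}: negative spike time {t}")
            if ch < 0:
                raise FormatError(f"{path}:{lineno}: negative channel id {ch}")
            channels.append(ch)
            times.append(t)
    return SpikePattern(np.asarray(channels, dtype=np.int64), np.asarray(times), onset=onset)


# ---------------------------------------------------------------------------
# evoked signals / tuning curves (CSV)
# ---------------------------------------------------------------------------

def write_evoked_signal(signal: EvokedSignal, path) -> None:
    signal.to_frame().to_csv(path, index=False)


def read_evoked_signal(path) -> EvokedSignal:
    frame = pd.read_csv(path)
    for col in ("time_ms", "value"):
        if col not in frame.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    unit = str(frame["unit"].iloc[0]) if "unit" in frame.columns and len(frame) else "a.u."
    return EvokedSignal(frame["time_ms"].to_numpy(), frame["value"].to_numpy(), unit=unit)


def write_tuning_curve(curve: TuningCurve, path) -> None:
    curve.to_frame().to_csv(path, index=False)


def read_tuning_curve(path) -> TuningCurve:
    frame = pd.read_csv(path)
    for col in ("orientation_deg", "mean_rate"):
        if col not in frame.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    return TuningCurve(frame["orientation_deg"].to_numpy(), frame["mean_rate"].to_numpy())


# ---------------------------------------------------------------------------
# grayscale patches
# ---------------------------------------------------------------------------

def write_pgm(image: np.ndarray, path, max_val: int = 255) -> None:
    """Plain-text (P2) portable graymap of an intensity image in [0, 1]."""
    img = np.asarray(image, float)
    quantised = np.rint(np.clip(img, 0.0, 1.0) * max_val).astype(int)
    path = Path(path)
    with path.open("w") as fh:
        fh.write("P2\n")
        fh.write(f"{img.shape[1]} {img.shape[0]}\n{max_val}\n")
        for row in quantised:
            fh.write(" ".join(str(v) for v in row) + "\n")


def read_pgm(path) -> np.ndarray:
    """Read a P2 graymap back to intensities in [0, 1]."""
    tokens: list[str] = []
    with Path(path).open() as fh:
        for raw in fh:
            line = raw.split("#")[0].strip()
            if line:
                tokens.extend(line.split())
    if not tokens or tokens[0] != "P2":
        raise FormatError(f"{path}: not a plain (P2) PGM file")
    width, height, max_val = (int(v) for v in tokens[1:4])
    data = np.asarray([int(v) for v in tokens[4:]], dtype=float)
    if data.size != width * height:
        raise FormatError(f"{path}: expected {width * height} pixels, found {data.size}")
    return (data / max_val).reshape(height, width)


def write_png(image: np.ndarray, path) -> None:
    """Grayscale PNG of an intensity image in [0, 1]."""
    import matplotlib

    matplotlib.use("Agg")
    from matplotlib import image as mpimg

    mpimg.imsave(path, np.asarray(image, float), cmap="gray", vmin=0.0, vmax=1.0)


def write_image_csv(image: np.ndarray, path) -> None:
    np.savetxt(path, np.asarray(image, float), delimiter=",", fmt="%.6f")


# ---------------------------------------------------------------------------
# trained-state snapshots
# ---------------------------------------------------------------------------

def save_trained_state(pinwheel, path) -> None:
    """Snapshot every column's intrinsic-excitability gains to ``.npz``.

    The snapshot stores, per column, the full per-neuron IE vector plus the
    preferred orientation, so it can be restored into a pinwheel rebuilt
    from the same configuration and wiring seed.
    """
    arrays = {}
    meta = {"orientations": [], "trained": []}
    for i, col in enumerate(pinwheel.columns):
        arrays[f"ie_{i}"] = col.network.ie
        meta["orientations"].append(col.spec.preferred_orientation)
        meta["trained"].append(bool(col.trained))
    arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_trained_state(pinwheel, path) -> None:
    """Restore IE gains saved by :func:`save_trained_state` (exact values)."""
    data = np.load(path)
    meta = json.loads(bytes(data["meta"].tobytes()).decode())
    if list(meta["orientations"]) != [c.spec.preferred_orientation for c in pinwheel.columns]:
        raise FormatError(f"{path}: snapshot columns do not match the pinwheel")
    for i, col in enumerate(pinwheel.columns):
        ie = data[f"ie_{i}"]
        if ie.shape != col.network.ie.shape:
            raise FormatError(f"{path}: IE vector length mismatch for column {i}")
        col.network.ie = ie.copy()
        col.trained = bool(meta["trained"][i])
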