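"""Gabor patches and their first-spike-latency retinal encoding.

The visual front end stands in for a full retina simulation: an 18x18 Gabor
patch is mapped to 324 ganglion-cell channels, and each channel emits at most
one spike whose latency decreases with the local contrast of its pixel.  All
spikes fall inside a 20 ms window — the short first-spike wave that carries
the orientation information the cortical model decodes.  A fixed
retina-to-cortex conduction delay ``t0`` (retina + LGN relay, default 30 ms)
positions the wave so that the cortical response peaks at the empirically
observed post-stimulus time (~80 ms).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .patterns import SpikePattern

__all__ = [
    "GaborParams",
    "make_gabor",
    "encode_latency",
    "orientation_sweep",
    "DEFAULT_T0",
    "DEFAULT_WINDOW",
    "DEFAULT_CONTRAST_THRESHOLD",
]

#: Retina + LGN conduction delay to cortex, ms.
DEFAULT_T0 = 30.0
#: First-spike latency window, ms.
DEFAULT_WINDOW = 20.0
#: Local-contrast threshold below which a channel stays silent.
DEFAULT_CONTRAST_THRESHOLD = 0.1


@dataclass(frozen=True)
class GaborParams:
    """Parameters of an oriented Gabor patch on the fixed 18x18 grid.

    Defaults (2.6 cycles/patch, sigma 4 px, full contrast)
    drive roughly half of the 324 channels above the contrast threshold; the
    carrier period and phase are deliberately incommensurate with the 2x2
    retinotopic blocks of the cortical model, so axis-aligned gratings do not
    produce degenerate within-block timing.
    """

    size: int = 18
    orientation: float = 0.0          #: degrees in [0, 180)
    spatial_frequency: float = 2.6    #: cycles per patch
    phase: float = 0.0                #: degrees
    envelope_sigma: float = 4.0       #: pixels
    contrast: float = 1.0             #: in [0, 1]

    def __post_init__(self) -> None:
        if self.size != 18:
            raise ValueError("the reduced visual model uses a fixed 18x18 patch")
        if not 0.0 <= self.contrast <= 1.0:
            raise ValueError("contrast must lie in [0, 1]")


def make_gabor(params: GaborParams) -> np.ndarray:
    """Oriented sinusoid under a Gaussian envelope, intensities in [0, 1].

    The background level is 0.5; the carrier is even-symmetric (cosine), so
    orientations theta and theta + 180 deg produce identical images.
    """
    n = params.size
    half = (n - 1) / 2.0
    coords = np.arange(n) - half
    y, x = np.meshgrid(coords, coords, indexing="ij")
    theta = np.deg2rad(params.orientation)
    # coordinate along the carrier axis (perpendicular to the bar orientation)
    x_r = x * np.cos(theta) + y * np.sin(theta)
    carrier = np.cos(
        2.0 * np.pi * params.spatial_frequency * x_r / n + np.deg2rad(params.phase)
    )
    envelope = np.exp(-(x**2 + y**2) / (2.0 * params.envelope_sigma**2))
    img = 0.5 + 0.5 * params.contrast * envelope * carrier
    return np.clip(img, 0.0, 1.0)


def encode_latency(
    image: np.ndarray,
    t0: float = DEFAULT_T0,
    window: float = DEFAULT_WINDOW,
    contrast_threshold: float = DEFAULT_CONTRAST_THRESHOLD,
) -> SpikePattern:
    """Convert an intensity image to a 324-channel first-spike pattern.

    Per-pixel local contrast ``c_i = 2 * |I_i - 0.5|`` (bright and dark bars
    both excite their channel); channels below ``contrast_threshold`` stay
    silent, and firing channels spike at::

        t_i = t0 + window * (1 - c_i / max_j c_j)

    so the strongest-contrast pixel fires exactly at ``t0`` and weaker ones
    later.  A uniform image yields an empty pattern.
    """
    img = np.asarray(image, dtype=float)
    if img.min() < -1e-9 or img.max() > 1.0 + 1e-9:
        raise ValueError("image intensities must lie in [0, 1]")
    c = 2.0 * np.abs(img.ravel() - 0.5)
    active = c >= contrast_threshold
    if not active.any():
        return SpikePattern(np.empty(0, dtype=np.int64), np.empty(0), onset=t0)
    c_max = c.max()
    channels = np.flatnonzero(active)
    times = t0 + window * (1.0 - c[channels] / c_max)
    return SpikePattern(channels, times, onset=t0).sorted()


def orientation_sweep(
    step: float = 5.0,
    gabor: GaborParams | None = None,
    t0: float = DEFAULT_T0,
    window: float = DEFAULT_WINDOW,
    contrast_threshold: float = DEFAULT_CONTRAST_THRESHOLD,
) -> tuple[np.ndarray, list[SpikePattern]]:
    """Encode Gabor patches rotated from 0 to 180 deg inclusive.

    Returns ``(orientations, patterns)``; the default 5 deg step gives the
    standard 37-orientation sweep.  All non-orientation Gabor parameters are
    taken from ``gabor``.
    """
    if abs(round(180.0 / step) * step - 180.0) > 1e-9:
        raise ValueError("step must divide 180 degrees")
    base = gabor or GaborParams()
    orientations = np.arange(0.0, 180.0 + step / 2, step)
    patterns = []
    for theta in orientations:
        p = GaborParams(
            size=base.size,
            orientation=float(theta),
            spatial_frequency=base.spatial_frequency,
            phase=base.phase,
            envelope_sigma=base.envelope_sigma,
            contrast=base.contrast,
        )
        patterns.append(encode_latency(make_gabor(p), t0, window, contrast_threshold))
    return orientations, patterns
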