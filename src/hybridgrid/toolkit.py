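"""Probability scaling and packed-integer color utilities."""

from __future__ import annotations

import numpy as np


def prob_scale(p: float, duration: float) -> float:
    """Probability that a rate-``p``-per-unit-time event occurs at least
    once within ``duration``: ``1 - (1 - p)**duration``.

    Used to rescale per-day event probabilities to per-tick probabilities
    so that the expected value per day is preserved.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0,1], got {p}")
    if duration < 0:
        raise ValueError(f"duration must be >= 0, got {duration}")
    return 1.0 - (1.0 - p) ** duration


def rgb(r: float, g: float, b: float) -> int:
    """Pack floating components in [0,1] into a 24-bit 0xRRGGBB integer.

    Components outside [0,1] are clamped.  The packed value doubles as a
    categorical label in models (distinct colors are distinct labels).
    """
    def chan(v: float) -> int:
        return int(round(min(max(v, 0.0), 1.0) * 255))

    return (chan(r) << 16) | (chan(g) << 8) | chan(b)


def rgb_unpack(color: int) -> tuple:
    """Inverse of :func:`rgb`, returning 8-bit-quantized floats."""
    return (((color >> 16) & 0xFF) / 255.0,
            ((color >> 8) & 0xFF) / 255.0,
            (color & 0xFF) / 255.0)


def heat_map_rgb(v: float) -> int:
    """Map a value in [0,1] to the black->red->yellow->white heat ramp.

    The ramp raises one channel per third: red on [0,1/3), green on
    [1/3,2/3), blue on [2/3,1].  Monotone in luminance; values outside
    [0,1] are clamped.
    """
    v = min(max(v, 0.0), 1.0)
    if v < 1.0 / 3.0:
        return rgb(3.0 * v, 0.0, 0.0)
    if v < 2.0 / 3.0:
        return rgb(1.0, 3.0 * v - 1.0, 0.0)
    return rgb(1.0, 1.0, 3.0 * v - 2.0)


def heat_map_rgb_array(values: np.ndarray) -> np.ndarray:
    """Vectorized :func:`heat_map_rgb` for whole lattices."""
    v = np.clip(np.asarray(values, dtype=float), 0.0, 1.0)
    r = np.clip(3.0 * v, 0.0, 1.0)
    g = np.clip(3.0 * v - 1.0, 0.0, 1.0)
    b = np.clip(3.0 * v - 2.0, 0.0, 1.0)
    to8 = lambda c: np.rint(c * 255).astype(np.int64)
    return (to8(r) << 16) | (to8(g) << 8) | to8(b)
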