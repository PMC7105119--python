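"""Headless raster rendering: per-pixel grids, PNG snapshots, GIFs.

A :class:`Raster` is a logical grid of packed 0xRRGGBB pixels with an
integer magnification applied at export.  The origin convention is fixed
once for the whole library: pixel (0, 0) is the top-left corner of the
exported image, with y increasing downward.

These replace the interactive grid windows of a GUI for desk-scale runs;
``tick_pause`` exists for interface parity and is a no-op in headless
mode (the default).
"""

from __future__ import annotations

import time

import numpy as np
from PIL import Image


class Raster:
    """Logical pixel grid exported at ``scale``-fold magnification."""

    def __init__(self, width: int, height: int, scale: int = 1, *,
                 headless: bool = True):
        if width < 1 or height < 1 or scale < 1:
            raise ValueError("width, height and scale must be >= 1")
        self.width = width
        self.height = height
        self.scale = scale
        self.headless = headless
        self._px = np.zeros((height, width), dtype=np.int64)  # row-major: [y, x]
        self._last_tick = None

    def set_pix(self, x: int, y: int, color: int) -> None:
        if not (0 <= x < self.width and 0 <= y < self.height):
            raise IndexError(f"pixel ({x},{y}) out of bounds")
        self._px[y, x] = color

    def get_pix(self, x: int, y: int) -> int:
        if not (0 <= x < self.width and 0 <= y < self.height):
            raise IndexError(f"pixel ({x},{y}) out of bounds")
        return int(self._px[y, x])

    def set_pix_array(self, colors: np.ndarray, x0: int = 0, y0: int = 0) -> None:
        """Blit a (height, width) block of packed colors at (x0, y0)."""
        h, w = colors.shape
        if x0 < 0 or y0 < 0 or x0 + w > self.width or y0 + h > self.height:
            raise IndexError("block out of bounds")
        self._px[y0:y0 + h, x0:x0 + w] = colors

    def _to_image(self) -> Image.Image:
        rgb = np.empty((self.height, self.width, 3), dtype=np.uint8)
        rgb[..., 0] = (self._px >> 16) & 0xFF
        rgb[..., 1] = (self._px >> 8) & 0xFF
        rgb[..., 2] = self._px & 0xFF
        img = Image.fromarray(rgb, mode="RGB")
        if self.scale != 1:
            img = img.resize((self.width * self.scale, self.height * self.scale),
                             Image.NEAREST)
        return img

    def to_png(self, path) -> None:
        """Write the current pixels as a lossless PNG."""
        self._to_image().save(path, format="PNG")

    def tick_pause(self, ms: int) -> None:
        """Wall-clock pacing between successive calls (interactive mode).

        In headless mode (default) this returns immediately; pacing never
        enters any numerical result.
        """
        if ms < 0:
            raise ValueError("ms must be >= 0")
        if self.headless or ms == 0:
            return
        now = time.monotonic()
        if self._last_tick is not None:
            remain = ms / 1000.0 - (now - self._last_tick)
            if remain > 0:
                time.sleep(remain)
        self._last_tick = time.monotonic()


class GifMaker:
    """Collects raster snapshots and writes an animated GIF."""

    def __init__(self):
        self._frames: list = []

    @property
    def frame_count(self) -> int:
        return len(self._frames)

    def gif_add_frame(self, raster: Raster) -> None:
        self._frames.append(raster._to_image())

    def gif_save(self, path, frameMs: int = 100) -> None:
        if not self._frames:
            raise ValueError("no frames added")
        first, rest = self._frames[0], self._frames[1:]
        first.save(path, format="GIF", save_all=True, append_images=rest,
                   duration=frameMs, loop=0)
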