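"""Index arithmetic, wrapping and neighborhood generation for lattice grids.

Every spatial container in the library shares one flattened-index
convention, declared once here and used consistently everywhere:

    i = (x * yDim + y) * zDim + z

which reduces to ``i = x * yDim + y`` in 2D (zDim == 1).  This matches
C-order flattening of an array of shape ``(xDim, yDim, zDim)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


@dataclass(frozen=True)
class GridShape:
    """Dimensions and per-axis wrap (periodicity) flags of a lattice.

    ``zDim == 1`` for 1D/2D grids.  Wrapping is off by default: the worked
    tumor model lives on a bounded domain.
    """

    xDim: int
    yDim: int = 1
    zDim: int = 1
    wrapX: bool = False
    wrapY: bool = False
    wrapZ: bool = False

    def __post_init__(self) -> None:
        for name in ("xDim", "yDim", "zDim"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")

    @property
    def length(self) -> int:
        """Total number of lattice positions."""
        return self.xDim * self.yDim * self.zDim

    @property
    def ndim(self) -> int:
        if self.zDim > 1:
            return 3
        if self.yDim > 1:
            return 2
        return 1

    def in_bounds(self, x: int, y: int = 0, z: int = 0) -> bool:
        return (0 <= x < self.xDim) and (0 <= y < self.yDim) and (0 <= z < self.zDim)


def flatten(x: int, y: int, shape: GridShape, z: int = 0) -> int:
    """Flattened index of integer coordinates; raises on out-of-range input."""
    if not shape.in_bounds(x, y, z):
        raise IndexError(f"coordinate ({x},{y},{z}) out of bounds for {shape}")
    return (x * shape.yDim + y) * shape.zDim + z


def unflatten(i: int, shape: GridShape) -> tuple:
    """Inverse of :func:`flatten`.  Returns (x, y) in 2D, (x, y, z) in 3D."""
    if not 0 <= i < shape.length:
        raise IndexError(f"index {i} out of bounds for {shape}")
    z = i % shape.zDim
    rest = i // shape.zDim
    y = rest % shape.yDim
    x = rest // shape.yDim
    if shape.zDim > 1:
        return (x, y, z)
    return (x, y)


@dataclass
class Neighborhood:
    """A reusable set of relative lattice offsets plus a mapping buffer.

    ``offsets`` is an ordered tuple of ``(dx, dy)`` pairs.  Mapping against a
    grid center writes flattened in-bounds indices into ``indexBuffer`` and
    sets ``count``; order follows offset order.  ``altOffsets``, when
    present, replaces ``offsets`` at centers of odd parity (hex rows,
    triangle up/down cells) under the documented even-row-shift convention.
    """

    offsets: tuple
    altOffsets: tuple | None = None
    parity: str | None = None  # None, "row" (y % 2), or "cell" ((x+y) % 2)
    indexBuffer: list = field(default_factory=list)
    count: int = 0

    def __post_init__(self) -> None:
        n = max(len(self.offsets), len(self.altOffsets or ()))
        if len(self.indexBuffer) < n:
            self.indexBuffer = [0] * n

    def __len__(self) -> int:
        return len(self.offsets)

    def offsets_at(self, x: int, y: int) -> tuple:
        """Offset set effective at a given center (handles parity rules)."""
        if self.altOffsets is None:
            return self.offsets
        if self.parity == "row":
            return self.offsets if y % 2 == 0 else self.altOffsets
        return self.offsets if (x + y) % 2 == 0 else self.altOffsets

    def mapped(self) -> list:
        """The valid indices written by the last map_hood call."""
        return self.indexBuffer[: self.count]


def moore_hood(includeOrigin: bool = False) -> Neighborhood:
    """The 8 lattice squares surrounding the origin (9 with the origin)."""
    offs = [(dx, dy) for dx in (-1, 0, 1) for dy in (-1, 0, 1) if (dx, dy) != (0, 0)]
    if includeOrigin:
        offs.insert(0, (0, 0))
    return Neighborhood(tuple(offs))


def von_neumann_hood(includeOrigin: bool = False) -> Neighborhood:
    """The 4 axis-adjacent squares."""
    offs = [(1, 0), (-1, 0), (0, 1), (0, -1)]
    if includeOrigin:
        offs.insert(0, (0, 0))
    return Neighborhood(tuple(offs))


def hex_hood(includeOrigin: bool = False) -> Neighborhood:
    """Six neighbors on a hexagonal lattice in offset coordinates.

    Convention: rows of even y are shifted half a cell left of odd rows
    ("even-row-shift"), so the two diagonal neighbors lie at dx = -1 on even
    rows and dx = +1 on odd rows.
    """
    even = [(1, 0), (-1, 0), (0, 1), (0, -1), (-1, 1), (-1, -1)]
    odd = [(1, 0), (-1, 0), (0, 1), (0, -1), (1, 1), (1, -1)]
    if includeOrigin:
        even.insert(0, (0, 0))
        odd.insert(0, (0, 0))
    return Neighborhood(tuple(even), tuple(odd), parity="row")


def triangle_hood(includeOrigin: bool = False) -> Neighborhood:
    """Three edge neighbors on a triangular lattice.

    Cells alternate upward/downward by parity of x + y: even-parity
    (upward) triangles share their base with the cell below (dy = +1),
    odd-parity ones with the cell above (dy = -1).
    """
    up = [(1, 0), (-1, 0), (0, 1)]
    down = [(1, 0), (-1, 0), (0, -1)]
    if includeOrigin:
        up.insert(0, (0, 0))
        down.insert(0, (0, 0))
    return Neighborhood(tuple(up), tuple(down), parity="cell")


def circle_hood(includeOrigin: bool, radius: float) -> Neighborhood:
    """All integer offsets whose centers lie within ``radius`` of the origin.

    Uses the inclusive comparison dx^2 + dy^2 <= radius^2.  Offsets are
    ordered by (dx, dy) lexicographically, origin first when included.
    """
    if radius < 0:
        raise ValueError(f"radius must be >= 0, got {radius}")
    r = int(math.floor(radius))
    r2 = radius * radius
    offs = []
    for dx in range(-r, r + 1):
        for dy in range(-r, r + 1):
            if (dx, dy) == (0, 0):
                continue
            if dx * dx + dy * dy <= r2:
                offs.append((dx, dy))
    if includeOrigin:
        offs.insert(0, (0, 0))
    return Neighborhood(tuple(offs))


def map_hood(nbhd: Neighborhood, x: int, y: int, shape: GridShape) -> int:
    """Map a neighborhood onto a grid center.

    Writes the flattened indices of offsets that land in bounds (wrapped
    where the shape wraps) into ``nbhd.indexBuffer`` preserving offset
    order, sets and returns ``nbhd.count``.  Out-of-bounds offsets along a
    non-wrapping axis are skipped.
    """
    if not shape.in_bounds(x, y):
        raise IndexError(f"center ({x},{y}) out of bounds for {shape}")
    xDim, yDim = shape.xDim, shape.yDim
    buf = nbhd.indexBuffer
    n = 0
    for dx, dy in nbhd.offsets_at(x, y):
        nx, ny = x + dx, y + dy
        if nx < 0 or nx >= xDim:
            if not shape.wrapX:
                continue
            nx %= xDim
        if ny < 0 or ny >= yDim:
            if not shape.wrapY:
                continue
            ny %= yDim
        buf[n] = (nx * yDim + ny) * shape.zDim
        n += 1
    nbhd.count = n
    return n
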