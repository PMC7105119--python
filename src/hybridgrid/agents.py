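"""Spatial agent containers: lattice-bound squares, off-lattice points and
adhesion–repulsion spheres.

A grid is two coupled structures: an ordered agent list driving iteration
and a per-position occupancy index driving spatial queries.  Disposed
agents are pooled and handed back by the next ``new_agent_*`` call, so the
number of objects ever constructed is bounded by the peak population.

Iteration uses snapshot (birth-exclusion) semantics: a sweep visits
exactly the agents alive when it began, minus any disposed before being
reached.  Agents born during the sweep wait for the next one, which is
what prevents runaway proliferation loops in birth models.

Note on recycling: a recycled agent keeps whatever user-defined fields its
previous life assigned.  Built-in fields are reset; everything else is the
caller's job to re-initialize.
"""

from __future__ import annotations

import math

from .errors import OccupancyError, StateError
from .lattice import GridShape, Neighborhood, flatten
from .rng import RandomSource


class Agent:
    """Lattice-bound square agent.  Extend with user fields as needed."""

    def __init__(self):
        self.G: "AgentGrid | None" = None
        self.i: int = -1
        self.birthTick: int = 0
        self.alive: bool = False
        self._slot: int = -1  # index of this agent's entry in the grid list

    # -- position ---------------------------------------------------------
    @property
    def xsq(self) -> int:
        return self.i // self.G.shape.yDim

    @property
    def ysq(self) -> int:
        return self.i % self.G.shape.yDim

    @property
    def x(self) -> float:
        """Continuous x of the square's center."""
        return self.xsq + 0.5

    @property
    def y(self) -> float:
        return self.ysq + 0.5

    def isq(self) -> int:
        """Flattened index of the occupied square."""
        return self.i

    def age(self) -> int:
        return self.G.tick - self.birthTick

    # -- conveniences mirroring the container API -------------------------
    def dispose(self) -> None:
        self.G.dispose(self)

    def map_empty_hood(self, nbhd: Neighborhood) -> int:
        return self.G.map_empty_hood(nbhd, self)

    def move_sq(self, newIndex: int) -> None:
        self.G.move_sq(self, newIndex)


class PointAgent(Agent):
    """Off-lattice agent with continuous coordinates and no volume."""

    def __init__(self):
        super().__init__()
        self.xPt: float = 0.0
        self.yPt: float = 0.0

    @property
    def x(self) -> float:
        return self.xPt

    @property
    def y(self) -> float:
        return self.yPt

    @property
    def bucketIndex(self) -> int:
        return self.i

    def move_pt(self, x: float, y: float) -> None:
        self.G.move_pt(self, x, y)


class SphericalAgent(PointAgent):
    """Point agent with a radius and velocity: Newtonian adhesion-repulsion."""

    def __init__(self):
        super().__init__()
        self.radius: float = 0.5
        self.vx: float = 0.0
        self.vy: float = 0.0

    def sum_forces(self, interactionRadius: float, forceLaw, rng: RandomSource | None = None):
        """Accumulate pairwise contact forces into the velocity.

        For every neighbor within ``interactionRadius``, the overlap is
        ``r_i + r_j - distance``; when positive, a force of magnitude
        ``forceLaw(overlap)`` pushes this agent along the center-to-center
        unit vector away from the neighbor.  Coincident centers get a
        random unit direction (``rng`` required then, else the grid's rng).
        Returns the (fx, fy) sum that was added.
        """
        fx = fy = 0.0
        for other in self.G.agents_in_radius(self.xPt, self.yPt, interactionRadius):
            if other is self:
                continue
            dx = self.xPt - other.xPt
            dy = self.yPt - other.yPt
            dist = math.hypot(dx, dy)
            overlap = self.radius + getattr(other, "radius", 0.0) - dist
            if overlap <= 0:
                continue
            mag = forceLaw(overlap)
            if dist > 0:
                fx += mag * dx / dist
                fy += mag * dy / dist
            else:
                r = rng if rng is not None else self.G.rng
                if r is None:
                    raise ValueError("coincident centers need an rng for a fallback direction")
                theta = r.next_double() * 2 * math.pi
                fx += mag * math.cos(theta)
                fy += mag * math.sin(theta)
        self.vx += fx
        self.vy += fy
        return fx, fy

    def integrate_motion(self, friction: float) -> None:
        """Scale velocity by ``friction`` and advance one unit timestep.

        At non-wrapping walls the position is clamped just inside the
        domain and the wall-normal velocity zeroed.
        """
        self.vx *= friction
        self.vy *= friction
        nx = self.xPt + self.vx
        ny = self.yPt + self.vy
        shape = self.G.shape
        eps = 1e-9
        if shape.wrapX:
            nx %= shape.xDim
        elif nx < 0 or nx > shape.xDim - eps:
            nx = min(max(nx, 0.0), shape.xDim - eps)
            self.vx = 0.0
        if shape.wrapY:
            ny %= shape.yDim
        elif ny < 0 or ny > shape.yDim - eps:
            ny = min(max(ny, 0.0), shape.yDim - eps)
            self.vy = 0.0
        self.G.move_pt(self, nx, ny)


def linear_spring(k: float = 0.5, adhesion: float = 0.0):
    """Default contact law: repulsive force proportional to overlap.

    ``adhesion`` subtracts a constant attraction, giving a simple
    adhesion-repulsion ring; the default is pure repulsion.
    """

    def law(overlap: float) -> float:
        return k * overlap - adhesion

    return law


class AgentGrid:
    """Container of agents on (or over) a lattice.

    ``latticeBound`` grids hold square agents created by index;
    off-lattice grids hold point/spherical agents created by continuous
    coordinates (their occupancy index is the unit cell containing them,
    used for fast radius queries).  ``stackable`` controls whether one
    position can hold several agents; off-lattice grids are always
    stackable.
    """

    def __init__(self, xDim: int, yDim: int = 1, agentClass=Agent, *,
                 stackable: bool = False, latticeBound: bool = True,
                 wrapX: bool = False, wrapY: bool = False,
                 rng: RandomSource | None = None):
        self.shape = GridShape(xDim, yDim, 1, wrapX, wrapY, False)
        self.agentClass = agentClass
        self.latticeBound = latticeBound
        self.stackable = stackable or not latticeBound
        self.tick = 0
        self.rng = rng
        self._list: list = []          # live agents; disposal nulls the slot
        self._dead_in_list = 0
        self._pop = 0
        self._recycle: list = []
        self._constructed = 0          # objects ever built (recycling bound)
        self._active_sweeps = 0
        if self.stackable:
            self._occ: list = [None] * self.shape.length  # lazily made lists
        else:
            self._occ = [None] * self.shape.length

    # -- bookkeeping -------------------------------------------------------
    def population(self) -> int:
        return self._pop

    def get_tick(self) -> int:
        return self.tick

    def increment_tick(self) -> None:
        self.tick += 1

    @property
    def objects_constructed(self) -> int:
        return self._constructed

    def _fresh(self):
        if self._recycle:
            a = self._recycle.pop()
        else:
            a = self.agentClass()
            self._constructed += 1
        a.G = self
        a.birthTick = self.tick
        a.alive = True
        return a

    def _occ_insert(self, agent, i: int) -> None:
        if self.stackable:
            slot = self._occ[i]
            if slot is None:
                self._occ[i] = [agent]
            else:
                slot.append(agent)
        else:
            if self._occ[i] is not None:
                raise OccupancyError(f"position {i} already occupied on unstackable grid")
            self._occ[i] = agent

    def _occ_remove(self, agent, i: int) -> None:
        if self.stackable:
            self._occ[i].remove(agent)
        else:
            self._occ[i] = None

    # -- creation / disposal ----------------------------------------------
    def new_agent_sq(self, i: int, y: int | None = None):
        """Create an agent at flattened index ``i`` (or coordinates x, y)."""
        if not self.latticeBound:
            raise StateError("new_agent_sq on an off-lattice grid")
        if y is not None:
            i = flatten(i, y, self.shape)
        if not 0 <= i < self.shape.length:
            raise IndexError(f"index {i} out of bounds")
        if not self.stackable and self._occ[i] is not None:
            raise OccupancyError(f"position {i} already occupied on unstackable grid")
        a = self._fresh()
        a.i = i
        self._occ_insert(a, i)
        a._slot = len(self._list)
        self._list.append(a)
        self._pop += 1
        return a

    def new_agent_pt(self, x: float, y: float):
        if self.latticeBound:
            raise StateError("new_agent_pt on a lattice-bound grid")
        if not (0 <= x < self.shape.xDim and 0 <= y < self.shape.yDim):
            raise IndexError(f"point ({x},{y}) out of bounds")
        a = self._fresh()
        a.xPt = x
        a.yPt = y
        a.i = flatten(int(x), int(y), self.shape)
        self._occ_insert(a, a.i)
        a._slot = len(self._list)
        self._list.append(a)
        self._pop += 1
        return a

    def dispose(self, agent) -> None:
        if not agent.alive or agent.G is not self:
            raise StateError("dispose of an agent that is not alive on this grid")
        agent.alive = False
        self._occ_remove(agent, agent.i)
        self._list[agent._slot] = None  # tombstone the list entry, O(1)
        agent._slot = -1
        self._recycle.append(agent)
        self._pop -= 1
        self._dead_in_list += 1

    # -- iteration ---------------------------------------------------------
    def _compact(self) -> None:
        if self._dead_in_list and self._active_sweeps == 0:
            self._list = [a for a in self._list if a is not None]
            for k, a in enumerate(self._list):
                a._slot = k
            self._dead_in_list = 0

    def __iter__(self):
        if self._dead_in_list > max(16, self._pop):
            self._compact()
        return self._sweep(len(self._list))

    def _sweep(self, n: int):
        self._active_sweeps += 1
        try:
            lst = self._list
            for k in range(n):
                a = lst[k]
                if a is not None:
                    yield a
        finally:
            self._active_sweeps -= 1

    def iterate_agents(self):
        """Snapshot sweep over live agents (alias of iteration)."""
        return iter(self)

    def shuffle_agents(self, rng: RandomSource) -> None:
        """Randomize iteration order (uniform permutation from ``rng``)."""
        self._compact()
        lst = self._list
        n = len(lst)
        if n > 1:
            perm = rng.shuffle_indices(n)
            self._list = [lst[j] for j in perm]
            for k, a in enumerate(self._list):
                if a is not None:
                    a._slot = k

    # -- spatial queries ---------------------------------------------------
    def get_agent(self, x: int, y: int = None):
        """Occupant of a position (first occupant on stackable grids)."""
        i = flatten(x, y, self.shape) if y is not None else x
        slot = self._occ[i]
        if slot is None:
            return None
        if self.stackable:
            return slot[0] if slot else None
        return slot

    def get_agents(self, x: int, y: int = None) -> list:
        i = flatten(x, y, self.shape) if y is not None else x
        slot = self._occ[i]
        if slot is None:
            return []
        return list(slot) if self.stackable else [slot]

    def map_hood(self, nbhd: Neighborhood, x: int, y: int) -> int:
        from .lattice import map_hood as _map
        return _map(nbhd, x, y, self.shape)

    def map_empty_hood(self, nbhd: Neighborhood, agent) -> int:
        """Map a neighborhood around ``agent`` keeping only empty positions."""
        shape = self.shape
        xDim, yDim = shape.xDim, shape.yDim
        x, y = agent.i // yDim, agent.i % yDim
        occ = self._occ
        buf = nbhd.indexBuffer
        n = 0
        offs = nbhd.offsets if nbhd.altOffsets is None else nbhd.offsets_at(x, y)
        for dx, dy in offs:
            nx, ny = x + dx, y + dy
            if nx < 0 or nx >= xDim:
                if not shape.wrapX:
                    continue
                nx %= xDim
            if ny < 0 or ny >= yDim:
                if not shape.wrapY:
                    continue
                ny %= yDim
            i = nx * yDim + ny
            slot = occ[i]
            if slot is None or (self.stackable and not slot):
                buf[n] = i
                n += 1
        nbhd.count = n
        return n

    # -- movement ----------------------------------------------------------
    def move_sq(self, agent, newIndex: int) -> None:
        if not 0 <= newIndex < self.shape.length:
            raise IndexError(f"index {newIndex} out of bounds")
        if newIndex == agent.i:
            return
        if not self.stackable and self._occ[newIndex] is not None:
            raise OccupancyError(f"position {newIndex} already occupied")
        self._occ_remove(agent, agent.i)
        self._occ_insert(agent, newIndex)
        agent.i = newIndex

    def move_pt(self, agent, x: float, y: float) -> None:
        if not (0 <= x < self.shape.xDim and 0 <= y < self.shape.yDim):
            raise IndexError(f"point ({x},{y}) out of bounds")
        newBucket = flatten(int(x), int(y), self.shape)
        if newBucket != agent.i:
            self._occ_remove(agent, agent.i)
            self._occ_insert(agent, newBucket)
            agent.i = newBucket
        agent.xPt = x
        agent.yPt = y

    def agents_in_radius(self, x: float, y: float, r: float) -> list:
        """All agents within Euclidean distance ``r`` of (x, y).

        Bucket search over the ceil(r)-neighborhood of the containing unit
        cell; wrap-aware along periodic axes.
        """
        if r < 0:
            raise ValueError(f"radius must be >= 0, got {r}")
        shape = self.shape
        cx, cy = int(x), int(y)
        reach = int(math.ceil(r))
        r2 = r * r
        out = []
        for bx in range(cx - reach, cx + reach + 1):
            wx = bx
            ox = 0.0
            if wx < 0 or wx >= shape.xDim:
                if not shape.wrapX:
                    continue
                ox = (wx // shape.xDim) * shape.xDim
                wx %= shape.xDim
            for by in range(cy - reach, cy + reach + 1):
                wy = by
                oy = 0.0
                if wy < 0 or wy >= shape.yDim:
                    if not shape.wrapY:
                        continue
                    oy = (wy // shape.yDim) * shape.yDim
                    wy %= shape.yDim
                slot = self._occ[wx * shape.yDim + wy]
                if slot is None:
                    continue
                group = slot if self.stackable else [slot]
                for a in group:
                    dx = (a.x + ox) - x
                    dy = (a.y + oy) - y
                    if dx * dx + dy * dy <= r2:
                        out.append(a)
        return out
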