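"""Lattices of huge homogeneous populations evolved by binomial events.

A :class:`PopulationField` stores a nonnegative integer count per lattice
position (int64, so up to ~9e18 individuals) instead of individual agent
objects.  Stochastic events — death, division, migration, mutation — are
drawn from binomial/multinomial distributions over the committed counts
and scheduled as signed deltas, committed simultaneously by ``update()``.
This bridges agent-based stochasticity and PDE density models: symmetric
nearest-neighbor migration at per-neighbor probability q converges, in
ensemble mean, to explicit diffusion at rate q.

Events within one step are always drawn from the counts committed at step
start, never from freshly arrived individuals (the population analogue of
agent birth-exclusion).
"""

from __future__ import annotations

import numpy as np

from .errors import StateError
from .lattice import GridShape, Neighborhood
from .rng import RandomSource


class PopulationField:
    """Per-position population counts with transactional integer deltas."""

    def __init__(self, xDim: int, yDim: int = 1, *, wrapX: bool = False,
                 wrapY: bool = False):
        self.shape = GridShape(xDim, yDim, 1, wrapX, wrapY, False)
        self._c = np.zeros((xDim, yDim), dtype=np.int64)
        self._d = np.zeros((xDim, yDim), dtype=np.int64)
        self._cflat = self._c.ravel()
        self._dflat = self._d.ravel()

    @property
    def counts(self) -> np.ndarray:
        """Committed counts, shape (xDim, yDim)."""
        return self._c

    def get_pop(self, i: int) -> int:
        return int(self._cflat[i])

    def set_pop(self, i: int, n: int) -> None:
        """Immediately overwrite a committed count (initialization)."""
        if n < 0:
            raise ValueError("counts must be >= 0")
        self._cflat[i] = n

    def add_pop(self, i: int, n: int) -> None:
        """Schedule a signed change, committed (and checked) at update()."""
        if not 0 <= i < self.shape.length:
            raise IndexError(f"index {i} out of bounds")
        self._dflat[i] += n

    def total(self) -> int:
        return int(self._c.sum())

    # -- stochastic events -------------------------------------------------
    def draw_event(self, i: int, p: float, rng: RandomSource) -> int:
        """Binomial(count(i), p) draw: how many individuals the event hits.

        The caller decides what the draw means and schedules the deltas.
        """
        return rng.binomial(int(self._cflat[i]), p)

    def distribute(self, i: int, nbhd: Neighborhood, probs, rng: RandomSource) -> list:
        """Multinomially scatter count(i) over a mapped neighborhood.

        ``probs`` gives the per-destination move probabilities (sum <= 1;
        the remainder stays put).  Schedules -movers at ``i`` and +movers
        at each destination in ``nbhd.mapped()``; returns the mover counts.
        """
        dests = nbhd.mapped()
        probs = list(probs)
        if len(probs) != len(dests):
            raise ValueError("need one probability per mapped destination")
        movers = rng.multinomial(int(self._cflat[i]), probs)
        for dest, k in zip(dests, movers):
            if k:
                self._dflat[dest] += k
                self._dflat[i] -= k
        return movers

    def distribute_all(self, nbhd: Neighborhood, probs, rng: RandomSource) -> None:
        """Vectorized :meth:`distribute` over every lattice position.

        All positions use the same offset set (parity-free neighborhoods
        only) and the same probabilities; offsets that fall outside a
        non-wrapping border keep their movers in place, so the totals are
        conserved exactly.  One multinomial array draw per call.
        """
        if nbhd.altOffsets is not None:
            raise ValueError("distribute_all needs a parity-free neighborhood")
        probs = np.asarray(list(probs), dtype=float)
        if probs.sum() > 1.0 + 1e-9:
            raise ValueError("probabilities sum to > 1")
        pvals = np.append(probs, 1.0 - probs.sum())
        movers = rng.multinomial_array(self._cflat, pvals)  # (ncells, k+1)
        nx, ny = self.shape.xDim, self.shape.yDim
        xs = np.arange(nx)[:, None]
        ys = np.arange(ny)[None, :]
        for col, (dx, dy) in enumerate(nbhd.offsets):
            m = movers[:, col].reshape(nx, ny)
            valid = np.ones((nx, ny), dtype=bool)
            if not self.shape.wrapX:
                valid &= (xs + dx >= 0) & (xs + dx < nx)
            if not self.shape.wrapY:
                valid &= (ys + dy >= 0) & (ys + dy < ny)
            moved = np.where(valid, m, 0)
            shifted = np.roll(np.roll(moved, dx, axis=0), dy, axis=1)
            self._d += shifted
            self._d -= moved

    # -- between-field shifts ----------------------------------------------
    def shift_state(self, dst: "PopulationField", i: int, p: float,
                    rng: RandomSource) -> int:
        """Move a Binomial(count(i), p) draw from this field into ``dst``.

        Models state changes such as mutation during division; totals over
        the two fields are conserved.
        """
        if dst.shape != self.shape:
            raise ValueError("fields must share a shape")
        k = rng.binomial(int(self._cflat[i]), p)
        if k:
            self._dflat[i] -= k
            dst._dflat[i] += k
        return k

    def update(self) -> None:
        """Commit all pending deltas simultaneously.

        If any resulting count would be negative the whole commit is
        rejected (field unchanged) and a :class:`StateError` is raised.
        """
        new = self._c + self._d
        if (new < 0).any():
            self._d[...] = 0
            raise StateError("commit would drive a population count negative")
        self._c[...] = new
        self._d[...] = 0
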