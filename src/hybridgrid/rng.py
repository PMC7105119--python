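"""Seedable random source with the distribution samplers the library needs.

A single :class:`RandomSource` object owns every draw a model makes, so a
seed fixes the entire simulation trajectory.  The generator is numpy's
PCG64; the reproducibility contract is stream stability for a given seed
and library version, not any particular bit stream.
"""

from __future__ import annotations

import math

import numpy as np

# Above this population size the binomial sampler switches from the exact
# generator to a rounded normal approximation.  At the threshold
# n*p*(1-p) is astronomically large for any p not within ~1e-10 of 0 or 1,
# so the approximation error is negligible; degenerate p near 0/1 falls
# through to a Poisson limit.
_BINOMIAL_NORMAL_THRESHOLD = 2**40


class RandomSource:
    """Deterministic random number generator and distribution sampler."""

    def __init__(self, seed: int = 0):
        self.seed = seed
        self._gen = np.random.Generator(np.random.PCG64(seed))
        self._buf = np.empty(0)
        self._pos = 0

    # -- uniform -----------------------------------------------------------
    def next_double(self) -> float:
        """Uniform draw in [0, 1).

        Served from an internal pre-drawn block (refilled from the
        generator in chunks of 4096) to keep scalar draws cheap in agent
        loops; the sequence is still a pure function of the seed.
        """
        pos = self._pos
        if pos >= len(self._buf):
            self._buf = self._gen.random(4096)
            pos = 0
        self._pos = pos + 1
        return self._buf[pos]

    def doubles(self, n: int) -> np.ndarray:
        """``n`` uniform draws in [0, 1) as an array (one stream advance)."""
        return self._gen.random(n)

    def next_int(self, n: int) -> int:
        """Uniform integer in {0, ..., n-1}."""
        if n <= 0:
            raise ValueError(f"next_int requires n >= 1, got {n}")
        return int(self._gen.integers(0, n))

    # -- classic distributions --------------------------------------------
    def gaussian(self, mean: float = 0.0, sd: float = 1.0) -> float:
        if sd < 0:
            raise ValueError(f"sd must be >= 0, got {sd}")
        return mean + sd * self._gen.standard_normal()

    def poisson(self, lam: float) -> int:
        if lam < 0:
            raise ValueError(f"lambda must be >= 0, got {lam}")
        return int(self._gen.poisson(lam))

    def binomial(self, n: int, p: float) -> int:
        """Binomial(n, p) draw, valid for n up to ~9e18.

        Uses the exact sampler below ``2**40`` trials and a rounded
        normal approximation above (mean np, variance np(1-p)), clipped
        into [0, n].
        """
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p must be in [0,1], got {p}")
        if n < 0:
            raise ValueError(f"n must be >= 0, got {n}")
        if n == 0 or p == 0.0:
            return 0
        if p == 1.0:
            return n
        if n <= _BINOMIAL_NORMAL_THRESHOLD:
            return int(self._gen.binomial(n, p))
        return self._binomial_approx(n, p)

    def _binomial_approx(self, n: int, p: float) -> int:
        mean = n * p
        var = n * p * (1.0 - p)
        if var < 1e6:
            # p so extreme that successes (or failures) are Poisson-rare
            if p < 0.5:
                return min(n, int(self._gen.poisson(mean)))
            return n - min(n, int(self._gen.poisson(n * (1.0 - p))))
        k = round(mean + math.sqrt(var) * self._gen.standard_normal())
        return int(min(max(k, 0), n))

    def multinomial(self, n: int, probs) -> list:
        """Split ``n`` trials over categories with the given probabilities.

        Probabilities may sum to less than 1; the remainder is an implicit
        final category whose count is ``n - sum(result)``.  Implemented as
        sequential conditional binomials, so it inherits the huge-n support
        of :meth:`binomial`.
        """
        probs = list(probs)
        if any(p < 0 for p in probs):
            raise ValueError("probabilities must be >= 0")
        total = sum(probs)
        if total > 1.0 + 1e-9:
            raise ValueError(f"probabilities sum to {total} > 1")
        remaining_n = n
        remaining_p = 1.0
        counts = []
        for p in probs:
            if remaining_n == 0 or remaining_p <= 0:
                counts.append(0)
                continue
            cond = min(1.0, p / remaining_p)
            k = self.binomial(remaining_n, cond)
            counts.append(k)
            remaining_n -= k
            remaining_p -= p
        return counts

    # -- vectorized helpers (batch draws advance the same stream) ----------
    def binomial_array(self, n, p) -> np.ndarray:
        """Elementwise Binomial draws for count arrays (n_i <= 2**40 each)."""
        return self._gen.binomial(np.asarray(n, dtype=np.int64), p)

    def multinomial_array(self, n, pvals) -> np.ndarray:
        """Row-wise multinomial draws; ``pvals`` must sum to 1 exactly."""
        return self._gen.multinomial(np.asarray(n, dtype=np.int64), pvals)

    def shuffle_indices(self, n: int) -> np.ndarray:
        """A uniform random permutation of range(n)."""
        return self._gen.permutation(n)
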