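"""Finite-difference reaction-diffusion/advection fields.

All schemes schedule their changes on a separate delta lattice; nothing is
visible to ``get`` until ``update()`` commits everything simultaneously.
That is what lets agents react with a field mid-step without order
effects.

Rates and velocities are dimensionless per step and per lattice unit;
physical scaling (um^2/s to lattice units etc.) is the caller's job.

Schemes
-------
* explicit diffusion — forward Euler in time, 2nd-order central in space;
  stable only for rate <= 1/(2*ndim).
* ADI diffusion — alternating-direction implicit (Peaceman–Rachford in
  2D, implicit half-steps in 1D), unconditionally stable; tridiagonal systems
  solved by the Thomas algorithm, cyclically (Sherman–Morrison) for
  periodic fields.
* 1st-order upwind advection, cell-centered velocities (incompressible).
* 1st-order finite-volume upwind advection, face velocities
  (compressible, conservative by construction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import StabilityError
from .lattice import GridShape


@dataclass(frozen=True)
class BoundaryCondition:
    """Boundary family of a field: zero-flux, dirichlet(value) or periodic."""

    kind: str
    value: float = 0.0

    def __post_init__(self):
        if self.kind not in ("zero_flux", "dirichlet", "periodic"):
            raise ValueError(f"unknown boundary kind {self.kind!r}")


ZERO_FLUX = BoundaryCondition("zero_flux")
PERIODIC = BoundaryCondition("periodic")


def dirichlet(value: float) -> BoundaryCondition:
    return BoundaryCondition("dirichlet", value)


def _thomas(a: float, b: float, c: float, d: np.ndarray,
            b_first: float, b_last: float) -> np.ndarray:
    """Solve tridiagonal systems with constant coefficients.

    Interior rows are (a, b, c); the first/last diagonal entries may
    differ (reflective boundaries).  ``d`` has shape (m, n): m independent
    right-hand sides solved along the last axis.
    """
    n = d.shape[-1]
    if n == 1:
        # both boundary modifications act on the single row
        return d / (b_first + b_last - b)
    cp = np.empty(n)
    x = np.array(d, dtype=float, copy=True)
    cp[0] = c / b_first
    x[..., 0] = x[..., 0] / b_first
    for k in range(1, n):
        bk = b_last if k == n - 1 else b
        denom = bk - a * cp[k - 1]
        cp[k] = c / denom
        x[..., k] = (x[..., k] - a * x[..., k - 1]) / denom
    for k in range(n - 2, -1, -1):
        x[..., k] -= cp[k] * x[..., k + 1]
    return x


def _thomas_cyclic(a: float, b: float, c: float, d: np.ndarray) -> np.ndarray:
    """Cyclic constant-coefficient tridiagonal solve (Sherman–Morrison)."""
    n = d.shape[-1]
    if n == 1:
        return d / (a + b + c)
    gamma = -b
    # modified system: b0 -> b - gamma, b_{n-1} -> b - a*c/gamma
    y = _thomas(a, b, c, d, b - gamma, b - a * c / gamma)
    u = np.zeros(n)
    u[0] = gamma
    u[-1] = c
    q = _thomas(a, b, c, u[None, :], b - gamma, b - a * c / gamma)[0]
    fact = (y[..., 0] + (a / gamma) * y[..., -1]) / (1.0 + q[0] + (a / gamma) * q[-1])
    return y - fact[..., None] * q[None, :]


class PDEField:
    """Concentration lattice with deferred (simultaneous) updates."""

    def __init__(self, xDim: int, yDim: int = 1, *,
                 boundary: BoundaryCondition = ZERO_FLUX):
        wrap = boundary.kind == "periodic"
        self.shape = GridShape(xDim, yDim, 1, wrap, wrap and yDim > 1, False)
        self.boundary = boundary
        self._v = np.zeros((xDim, yDim))
        self._d = np.zeros((xDim, yDim))
        self._vflat = self._v.ravel()
        self._dflat = self._d.ravel()
        self._sets: dict = {}

    # -- point access ------------------------------------------------------
    @property
    def ndim(self) -> int:
        return self.shape.ndim

    @property
    def values(self) -> np.ndarray:
        """Committed values, shape (xDim, yDim).  Read-only by convention."""
        return self._v

    def get(self, i: int, y: int | None = None) -> float:
        if y is not None:
            i = i * self.shape.yDim + y
        return self._vflat[i]

    def set(self, i: int, v: float) -> None:
        """Schedule the committed value to become exactly ``v`` at update().

        A set overrides any pending adds at the same position (applied
        last in the commit).  ``i`` is a flattened index.
        """
        if not 0 <= i < self.shape.length:
            raise IndexError(f"index {i} out of bounds")
        self._sets[i] = v

    def add(self, i: int, v: float) -> None:
        if not 0 <= i < self.shape.length:
            raise IndexError(f"index {i} out of bounds")
        self._dflat[i] += v

    def mul(self, i: int, v: float) -> None:
        """Schedule a delta of committed(i) * v (e.g. fractional uptake)."""
        if not 0 <= i < self.shape.length:
            raise IndexError(f"index {i} out of bounds")
        self._dflat[i] += self._vflat[i] * v

    def set_all(self, v) -> None:
        """Immediately overwrite the committed lattice (initialization)."""
        self._v[...] = v

    def total(self) -> float:
        return float(self._v.sum())

    # -- ghost padding -----------------------------------------------------
    def _pad(self, u: np.ndarray, boundary: BoundaryCondition) -> np.ndarray:
        axes = [0, 1] if self.ndim == 2 else [0]
        pad_width = [(1, 1) if ax in axes else (0, 0) for ax in range(2)]
        if boundary.kind == "periodic":
            return np.pad(u, pad_width, mode="wrap")
        if boundary.kind == "dirichlet":
            return np.pad(u, pad_width, mode="constant", constant_values=boundary.value)
        return np.pad(u, pad_width, mode="edge")

    # -- diffusion ---------------------------------------------------------
    def diffusion_explicit(self, rate: float,
                           boundary: BoundaryCondition | None = None) -> None:
        """Schedule one forward-Euler 2nd-order central diffusion step."""
        nd = self.ndim
        if rate < 0:
            raise ValueError(f"rate must be >= 0, got {rate}")
        if rate > 1.0 / (2 * nd) + 1e-12:
            raise StabilityError(
                f"explicit diffusion rate {rate} exceeds stability bound {1.0/(2*nd)}")
        bc = boundary if boundary is not None else self.boundary
        up = self._pad(self._v, bc)
        if nd == 2:
            lap = (up[:-2, 1:-1] + up[2:, 1:-1] + up[1:-1, :-2] + up[1:-1, 2:]
                   - 4.0 * up[1:-1, 1:-1])
        else:
            lap = up[:-2, :] + up[2:, :] - 2.0 * up[1:-1, :]
        self._d += rate * lap

    def _adi_half(self, u: np.ndarray, r: float, axis: int,
                  bc: BoundaryCondition) -> np.ndarray:
        """One PR half-step: implicit along ``axis``, explicit along the other."""
        other = 1 - axis
        h = r / 2.0
        # explicit part along the other axis (skip if that axis is flat)
        if u.shape[other] > 1:
            up = np.moveaxis(self._pad_axis(np.moveaxis(u, other, 0), bc), 0, other)
            idx_lo = [slice(None)] * 2
            idx_hi = [slice(None)] * 2
            idx_mid = [slice(None)] * 2
            idx_lo[other] = slice(0, -2)
            idx_hi[other] = slice(2, None)
            idx_mid[other] = slice(1, -1)
            rhs = u + h * (up[tuple(idx_lo)] + up[tuple(idx_hi)] - 2.0 * u)
        else:
            rhs = u.copy()
        # implicit solve along `axis`
        d = np.moveaxis(rhs, axis, 1)  # systems along last axis
        if bc.kind == "periodic":
            sol = _thomas_cyclic(-h, 1.0 + 2.0 * h, -h, d)
        elif bc.kind == "dirichlet":
            d = d.copy()
            d[..., 0] += h * bc.value
            d[..., -1] += h * bc.value
            sol = _thomas(-h, 1.0 + 2.0 * h, -h, d, 1.0 + 2.0 * h, 1.0 + 2.0 * h)
        else:  # zero-flux: mirror ghost folds into the diagonal
            sol = _thomas(-h, 1.0 + 2.0 * h, -h, d, 1.0 + h, 1.0 + h)
        return np.moveaxis(sol, 1, axis)

    def _pad_axis(self, u: np.ndarray, bc: BoundaryCondition) -> np.ndarray:
        """Pad one ghost layer along axis 0 only."""
        if bc.kind == "periodic":
            return np.concatenate([u[-1:], u, u[:1]], axis=0)
        if bc.kind == "dirichlet":
            ghost = np.full_like(u[:1], bc.value)
            return np.concatenate([ghost, u, ghost], axis=0)
        return np.concatenate([u[:1], u, u[-1:]], axis=0)

    def diffusion_adi(self, rate: float, boundaryValue: float | None = None) -> None:
        """Schedule one alternating-direction implicit diffusion step.

        Unconditionally stable.  With one argument the borders are
        reflective (or periodic, if the field itself is periodic); passing
        ``boundaryValue`` switches to Dirichlet borders holding that
        value, so it diffuses in from the domain edge.
        """
        if rate < 0:
            raise ValueError(f"rate must be >= 0, got {rate}")
        if boundaryValue is not None:
            bc = dirichlet(boundaryValue)
        elif self.boundary.kind == "periodic":
            bc = PERIODIC
        else:
            bc = ZERO_FLUX
        u = self._v
        if self.ndim == 2:
            half = self._adi_half(u, rate, 0, bc)
            new = self._adi_half(half, rate, 1, bc)
        else:
            # 1D: two implicit (backward-Euler) half-steps
            new = self._adi_half(self._adi_half(u, rate, 0, bc), rate, 0, bc)
        self._d += new - u

    # -- advection ---------------------------------------------------------
    def advection_incompressible(self, vx, vy=0.0) -> None:
        """Schedule a 1st-order upwind advection step, cell velocities.

        Velocities may be scalars or per-cell arrays; the CFL bound
        max|vx| + max|vy| <= 1 is enforced.
        """
        vx = np.broadcast_to(np.asarray(vx, dtype=float), self._v.shape)
        vy = np.broadcast_to(np.asarray(vy, dtype=float), self._v.shape)
        cfl = np.abs(vx).max() + np.abs(vy).max()
        if cfl > 1.0 + 1e-12:
            raise StabilityError(f"advection CFL {cfl} exceeds 1")
        up = self._pad(self._v, self.boundary)
        if self.ndim == 2:
            c = up[1:-1, 1:-1]
            dxm = c - up[:-2, 1:-1]
            dxp = up[2:, 1:-1] - c
            dym = c - up[1:-1, :-2]
            dyp = up[1:-1, 2:] - c
            self._d += -(np.where(vx > 0, vx * dxm, vx * dxp)
                         + np.where(vy > 0, vy * dym, vy * dyp))
        else:
            c = up[1:-1, :]
            dxm = c - up[:-2, :]
            dxp = up[2:, :] - c
            self._d += -np.where(vx > 0, vx * dxm, vx * dxp)

    def advection_compressible(self, vxFace, vyFace=None) -> None:
        """Schedule a conservative finite-volume upwind advection step.

        ``vxFace`` has shape (xDim+1, yDim) and ``vyFace`` (xDim, yDim+1):
        velocities live on cell faces.  Each face's flux leaves one cell
        and enters its neighbor, so total mass is conserved exactly.
        Under non-periodic boundaries the domain-edge faces carry zero
        flux.
        """
        nx, ny = self._v.shape
        vxFace = np.asarray(vxFace, dtype=float)
        if vxFace.ndim == 0:
            vxFace = np.full((nx + 1, ny), float(vxFace))
        if vyFace is None:
            vyFace = np.zeros((nx, ny + 1))
        else:
            vyFace = np.asarray(vyFace, dtype=float)
            if vyFace.ndim == 0:
                vyFace = np.full((nx, ny + 1), float(vyFace))
        if vxFace.shape != (nx + 1, ny) or vyFace.shape != (nx, ny + 1):
            raise ValueError("face velocity arrays must have shapes (x+1,y) and (x,y+1)")
        cfl = np.abs(vxFace).max() + np.abs(vyFace).max()
        if cfl > 1.0 + 1e-12:
            raise StabilityError(f"advection CFL {cfl} exceeds 1")
        u = self._v
        periodic = self.boundary.kind == "periodic"
        # upwind donor values on x-faces
        left = np.empty((nx + 1, ny))
        right = np.empty((nx + 1, ny))
        left[1:], left[0] = u, u[-1] if periodic else 0.0
        right[:-1], right[-1] = u, u[0] if periodic else 0.0
        fx = np.where(vxFace > 0, vxFace * left, vxFace * right)
        if not periodic:
            fx[0] = 0.0
            fx[-1] = 0.0
        lo = np.empty((nx, ny + 1))
        hi = np.empty((nx, ny + 1))
        lo[:, 1:], lo[:, 0] = u, u[:, -1] if periodic else 0.0
        hi[:, :-1], hi[:, -1] = u, u[:, 0] if periodic else 0.0
        fy = np.where(vyFace > 0, vyFace * lo, vyFace * hi)
        if not periodic:
            fy[:, 0] = 0.0
            fy[:, -1] = 0.0
        self._d += (fx[:-1] - fx[1:]) + (fy[:, :-1] - fy[:, 1:])

    # -- commit ------------------------------------------------------------
    def update(self) -> None:
        """Apply all pending deltas at once (sets win); clear them."""
        self._v += self._d
        self._d[...] = 0.0
        if self._sets:
            for i, v in self._sets.items():
                self._vflat[i] = v
            self._sets.clear()
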