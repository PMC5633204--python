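"""Uniform 2-D node-centered grid, scalar fields and finite-difference operators.

All geometry is in cm.  Fields store one float64 value per node with a loose
unit tag.  The discrete operators (:func:`laplacian`, :func:`gradient`,
:func:`div_coef_grad`) implement standard second-order stencils with ghost
nodes supplied by a :class:`BoundaryCondition`:

* ``no_flux`` ghosts mirror the boundary node across the outer face, so the
  flux through every outer face is exactly zero (conservative).
* ``dirichlet`` ghosts hold a fixed value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Grid",
    "ScalarField",
    "BoundaryCondition",
    "no_flux",
    "dirichlet",
    "laplacian",
    "gradient",
    "div_coef_grad",
]

_UNITS = {"dimensionless", "mmHg", "cm/s", "1/s", "concentration"}


@dataclass(frozen=True)
class Grid:
    """Uniform square-lattice grid of ``nx`` x ``ny`` nodes with spacing ``h`` (cm)."""

    nx: int
    ny: int
    h: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.nx < 3 or self.ny < 3:
            raise ValueError(f"grid needs at least 3x3 nodes, got {self.nx}x{self.ny}")
        if not (self.h > 0):
            raise ValueError(f"grid spacing must be positive, got {self.h}")

    @property
    def shape(self) -> tuple[int, int]:
        """Array shape of node values, ``(ny, nx)`` (row = y index)."""
        return (self.ny, self.nx)

    @property
    def extent(self) -> tuple[float, float]:
        """Physical extent ``((nx-1)*h, (ny-1)*h)`` in cm."""
        return ((self.nx - 1) * self.h, (self.ny - 1) * self.h)

    @property
    def center(self) -> tuple[float, float]:
        ex, ey = self.extent
        return (self.origin[0] + ex / 2.0, self.origin[1] + ey / 2.0)

    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Node coordinate arrays ``(X, Y)``, each of shape ``(ny, nx)``."""
        x = self.origin[0] + self.h * np.arange(self.nx)
        y = self.origin[1] + self.h * np.arange(self.ny)
        return np.meshgrid(x, y)

    def radius_from_center(self) -> np.ndarray:
        X, Y = self.coords()
        cx, cy = self.center
        return np.hypot(X - cx, Y - cy)


@dataclass
class ScalarField:
    """One real value per grid node plus a unit tag."""

    grid: Grid
    values: np.ndarray
    unit: str = "dimensionless"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"field shape {self.values.shape} does not match grid {self.grid.shape}"
            )

    @classmethod
    def full(cls, grid: Grid, value: float, unit: str = "dimensionless") -> "ScalarField":
        return cls(grid, np.full(grid.shape, float(value)), unit)

    @classmethod
    def zeros(cls, grid: Grid, unit: str = "dimensionless") -> "ScalarField":
        return cls.full(grid, 0.0, unit)

    @classmethod
    def from_function(cls, grid: Grid, fn, unit: str = "dimensionless") -> "ScalarField":
        X, Y = grid.coords()
        return cls(grid, np.asarray(fn(X, Y), dtype=np.float64), unit)

    def copy(self) -> "ScalarField":
        return ScalarField(self.grid, self.values.copy(), self.unit)

    def clamp_nonnegative(self) -> int:
        """Clamp negative node values to zero in place; return the count clamped."""
        neg = self.values < 0.0
        count = int(neg.sum())
        if count:
            self.values[neg] = 0.0
        return count


@dataclass(frozen=True)
class BoundaryCondition:
    kind: str  # "dirichlet" | "no_flux"
    value: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("dirichlet", "no_flux"):
            raise ValueError(f"unknown boundary kind {self.kind!r}")
        if not np.isfinite(self.value):
            raise ValueError("boundary value must be finite")


def no_flux() -> BoundaryCondition:
    return BoundaryCondition("no_flux")


def dirichlet(value: float) -> BoundaryCondition:
    return BoundaryCondition("dirichlet", float(value))


def _check_finite(f: ScalarField, what: str) -> None:
    bad = ~np.isfinite(f.values)
    if bad.any():
        j, i = np.argwhere(bad)[0]
        raise ValueError(f"non-finite {what} value at node (ix={i}, iy={j})")


def _pad(values: np.ndarray, bc: BoundaryCondition) -> np.ndarray:
    """Add a one-node ghost layer on every side."""
    if bc.kind == "dirichlet":
        return np.pad(values, 1, mode="constant", constant_values=bc.value)
    # no_flux: mirror across the outer face (ghost equals the boundary node)
    return np.pad(values, 1, mode="edge")


def laplacian(f: ScalarField, bc: BoundaryCondition) -> ScalarField:
    """5-point Laplacian of ``f``; result carries unit ``f.unit + '/cm^2'``."""
    _check_finite(f, "field")
    p = _pad(f.values, bc)
    h2 = f.grid.h ** 2
    out = (p[1:-1, 2:] + p[1:-1, :-2] + p[2:, 1:-1] + p[:-2, 1:-1] - 4.0 * p[1:-1, 1:-1]) / h2
    return ScalarField(f.grid, out, f.unit + "/cm^2")


def gradient(f: ScalarField, bc: BoundaryCondition) -> tuple[ScalarField, ScalarField]:
    """Central-difference gradient ``(df/dx, df/dy)`` using ghost nodes at edges."""
    _check_finite(f, "field")
    p = _pad(f.values, bc)
    h2 = 2.0 * f.grid.h
    gx = (p[1:-1, 2:] - p[1:-1, :-2]) / h2
    gy = (p[2:, 1:-1] - p[:-2, 1:-1]) / h2
    unit = f.unit + "/cm"
    return ScalarField(f.grid, gx, unit), ScalarField(f.grid, gy, unit)


def div_coef_grad(coef: ScalarField, f: ScalarField, bc: BoundaryCondition) -> ScalarField:
    """Conservative divergence of a coefficient-weighted gradient.

    Flux form: the face coefficient is the arithmetic mean of the two adjacent
    node values; the result is the net flux divergence per node.  With a
    ``no_flux`` boundary the outer-face fluxes vanish, so the discrete
    integral of the result is zero to round-off.
    """
    _check_finite(f, "field")
    _check_finite(coef, "coefficient")
    if (coef.values < 0.0).any():
        j, i = np.argwhere(coef.values < 0.0)[0]
        raise ValueError(f"negative coefficient at node (ix={i}, iy={j})")
    if coef.grid != f.grid:
        raise ValueError("coefficient and field must share a grid")
    pf = _pad(f.values, bc)
    pc = _pad(coef.values, bc) if bc.kind == "no_flux" else np.pad(coef.values, 1, mode="edge")
    c = pc[1:-1, 1:-1]
    h2 = f.grid.h ** 2
    out = np.zeros_like(f.values)
    # east / west / north / south faces
    out += 0.5 * (c + pc[1:-1, 2:]) * (pf[1:-1, 2:] - pf[1:-1, 1:-1])
    out += 0.5 * (c + pc[1:-1, :-2]) * (pf[1:-1, :-2] - pf[1:-1, 1:-1])
    out += 0.5 * (c + pc[2:, 1:-1]) * (pf[2:, 1:-1] - pf[1:-1, 1:-1])
    out += 0.5 * (c + pc[:-2, 1:-1]) * (pf[:-2, 1:-1] - pf[1:-1, 1:-1])
    out /= h2
    return ScalarField(f.grid, out, f.unit + "/cm^2")
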