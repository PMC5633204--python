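"""Tumor-cell and vessel-density dynamics with explicit time integration.

Tumor cells obey a reaction-diffusion equation with logistic growth, a
vessel-assisted proliferation term and a drug kill term:

    dn/dt = D_n lap(n) + r n (1 - n/n_lim) + alpha_mn n m - d_r n d

Vessel density obeys a bistable cubic (stable states m=0 and m=1) plus two
angiogenesis couplings and an antiangiogenic kill term:

    dm/dt = D_m lap(m) + m (alpha + beta m + gamma m^2)
            + beta_nm div(m grad n) + alpha_nm n (1 - n/n_lim) m - A_r m A

Rates carry units of 1/day except the drug kill rates ``d_r`` and ``A_r``
which are given per hour and converted internally.  An optional
growth-inhibition drug variant multiplies the proliferation terms by
``(1 - d/d_max)`` instead of applying the kill term.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .grid_core import (
    BoundaryCondition,
    Grid,
    ScalarField,
    div_coef_grad,
    laplacian,
    no_flux,
)

__all__ = [
    "GrowthParams",
    "tumor_rhs",
    "vessel_rhs",
    "step_growth",
    "max_stable_dt",
    "init_tumor_gaussian",
    "init_vessel_islands",
]

log = logging.getLogger(__name__)

HOURS_PER_DAY = 24.0


@dataclass(frozen=True)
class GrowthParams:
    """Growth and angiogenesis rate constants.

    The constants not fixed by the transport tables (``D_n``, ``r``,
    ``n_lim``, ``alpha_mn``, ``D_m``, ``alpha``, ``beta``, ``gamma``) have
    external provenance: the defaults below are calibration choices made so
    that an untreated tumor started from a 0.2 mm seed reaches roughly a
    13.5 mm radius at day 30 while producing a leaky vascular rim and a
    vessel-depleted core.  All are config-overridable; ``r`` is normally set
    by :func:`angionorm.treatment_scheduler.calibrate_growth`.
    """

    D_n: float = 1e-3          # cell diffusivity, cm^2/day
    r: float = 0.28            # logistic growth rate, 1/day
    n_lim: float = 2.0         # carrying capacity, dimensionless
    alpha_mn: float = 0.45     # vessel-assisted proliferation, 1/day per unit m
    d_r: float = 1.0           # chemotherapy kill rate, 1/hour
    D_m: float = 1e-5          # vessel diffusivity, cm^2/day
    alpha: float = -0.15       # cubic island coefficients, 1/day
    beta: float = 0.6
    gamma: float = -0.45
    beta_nm: float = 0.5       # vessel chemotaxis-like coefficient (dimensionless)
    beta_nm_scale: float = 0.002  # reference area (cm^2) converting beta_nm to cm^2/day
    alpha_nm: float = 0.25     # angiogenesis production rate, 1/day
    A_r: float = 1.0           # antiangiogenic kill rate, 1/hour
    d_max: float | None = None  # inhibition-variant normalization; None = running max
    inhibition_keep_kill: bool = False  # variant keeps -d_r n d too when True

    def __post_init__(self) -> None:
        if self.n_lim <= 0:
            raise ValueError("n_lim must be positive")
        if self.r < 0 or self.D_n < 0 or self.D_m < 0:
            raise ValueError("rates and diffusivities must be non-negative")
        s = self.alpha + self.beta + self.gamma
        if abs(s) > 1e-12:
            raise ValueError(
                f"cubic coefficients must satisfy alpha+beta+gamma=0 (got {s:.3e}) "
                "so that m=1 is a fixed point"
            )
        if self.alpha >= 0:
            raise ValueError("alpha must be negative so that m=0 is stable")
        # stability of m=1: f'(1) = alpha + 2 beta + 3 gamma < 0
        if self.alpha + 2 * self.beta + 3 * self.gamma >= 0:
            raise ValueError("m=1 must be a stable root of the vessel cubic")

    @property
    def d_r_per_day(self) -> float:
        return self.d_r * HOURS_PER_DAY

    @property
    def A_r_per_day(self) -> float:
        return self.A_r * HOURS_PER_DAY

    @property
    def beta_nm_eff(self) -> float:
        """Effective cross-diffusion coefficient of the beta_nm term, cm^2/day."""
        return self.beta_nm * self.beta_nm_scale


def _check_same_grid(*fields: ScalarField) -> Grid:
    grid = fields[0].grid
    for f in fields[1:]:
        if f.grid != grid:
            raise ValueError("fields must share a grid")
    return grid


def tumor_rhs(
    n: ScalarField,
    m: ScalarField,
    d: ScalarField,
    p: GrowthParams,
    inhibition_variant: bool = False,
) -> ScalarField:
    """Right-hand side of the tumor-cell equation, in 1/day."""
    _check_same_grid(n, m, d)
    if (d.values < 0).any():
        raise ValueError("drug concentration must be non-negative")
    nv, mv, dv = n.values, m.values, d.values
    diff = p.D_n * laplacian(n, no_flux()).values
    growth = p.r * nv * (1.0 - nv / p.n_lim) + p.alpha_mn * nv * mv
    if inhibition_variant:
        if p.d_max is None or p.d_max <= 0:
            raise ValueError("inhibition variant requires d_max > 0")
        growth = growth * np.clip(1.0 - dv / p.d_max, a_min=None, a_max=1.0)
        kill = p.d_r_per_day * nv * dv if p.inhibition_keep_kill else 0.0
    else:
        kill = p.d_r_per_day * nv * dv
    return ScalarField(n.grid, diff + growth - kill, "1/day")


def vessel_rhs(
    m: ScalarField,
    n: ScalarField,
    A: ScalarField,
    p: GrowthParams,
) -> ScalarField:
    """Right-hand side of the vessel-density equation, in 1/day."""
    _check_same_grid(m, n, A)
    mv, nv, Av = m.values, n.values, A.values
    diff = p.D_m * laplacian(m, no_flux()).values
    cubic = mv * (p.alpha + p.beta * mv + p.gamma * mv * mv)
    chemotaxis = p.beta_nm_eff * div_coef_grad(m, n, no_flux()).values
    angio = p.alpha_nm * nv * (1.0 - nv / p.n_lim) * mv
    kill = p.A_r_per_day * mv * Av
    return ScalarField(m.grid, diff + cubic + chemotaxis + angio - kill, "1/day")


def max_stable_dt(grid: Grid, p: GrowthParams) -> float:
    """Diffusive forward-Euler stability bound dt <= h^2 / (4 max(D_n, D_m))."""
    dmax = max(p.D_n, p.D_m)
    if dmax == 0:
        return np.inf
    return grid.h ** 2 / (4.0 * dmax)


def step_growth(
    state: dict[str, ScalarField],
    drugs: dict[str, ScalarField],
    p: GrowthParams,
    dt: float,
    inhibition_variant: bool = False,
) -> dict[str, ScalarField]:
    """One forward-Euler step of size ``dt`` (days); negatives clamped to 0."""
    n, m = state["n"], state["m"]
    A, d = drugs["A"], drugs["d"]
    if dt < 0:
        raise ValueError("dt must be non-negative")
    bound = max_stable_dt(n.grid, p)
    if dt > bound:
        raise ValueError(
            f"dt={dt:g} violates the diffusive stability bound; use dt <= {bound:g} days"
        )
    if dt == 0:
        return {"n": n.copy(), "m": m.copy()}
    dn = tumor_rhs(n, m, d, p, inhibition_variant=inhibition_variant)
    dm = vessel_rhs(m, n, A, p)
    n_new = ScalarField(n.grid, n.values + dt * dn.values, n.unit)
    m_new = ScalarField(m.grid, m.values + dt * dm.values, m.unit)
    clamped = n_new.clamp_nonnegative() + m_new.clamp_nonnegative()
    if clamped:
        log.debug("step_growth clamped %d negative nodes to zero", clamped)
    return {"n": n_new, "m": m_new}


def init_tumor_gaussian(
    grid: Grid,
    center: tuple[float, float] | None = None,
    radius0: float = 0.02,
    peak: float = 1.0,
) -> ScalarField:
    """Gaussian tumor seed whose ``n > 0.1*peak`` contour has radius ``radius0`` (cm)."""
    if radius0 <= 0:
        raise ValueError("radius0 must be positive")
    ex, ey = grid.extent
    if radius0 > min(ex, ey) / 2.0:
        raise ValueError(f"radius0={radius0:g} cm exceeds half the domain extent")
    if center is None:
        center = grid.center
    # peak * exp(-r0^2 / (2 sigma^2)) = 0.1 * peak  =>  sigma = r0 / sqrt(2 ln 10)
    sigma = radius0 / np.sqrt(2.0 * np.log(10.0))
    X, Y = grid.coords()
    r2 = (X - center[0]) ** 2 + (Y - center[1]) ** 2
    return ScalarField(grid, peak * np.exp(-r2 / (2.0 * sigma ** 2)), "dimensionless")


def init_vessel_islands(
    grid: Grid,
    seed: int,
    p: GrowthParams,
    relax_time: float = 60.0,
    island_scale: int = 1,
    dt: float | None = None,
) -> ScalarField:
    """Random bistable vessel islands.

    Node values are drawn i.i.d. uniform(0, 1) from ``seed`` (optionally on a
    coarser lattice of ``island_scale`` x ``island_scale`` node blocks to make
    larger islands), then relaxed under :func:`vessel_rhs` with ``n = A = 0``
    for ``relax_time`` days so the bistable cubic carves the values towards
    the stable states 0 and 1.  Relaxation is reaction-only (vessel
    diffusivity suppressed) so lattice-scale island boundaries are not pinned
    at intermediate values; diffusion acts again once the simulation proper
    starts.  Deterministic given the seed.
    """
    if relax_time < 0:
        raise ValueError("relax_time must be non-negative")
    if island_scale < 1:
        raise ValueError("island_scale must be >= 1")
    rng = np.random.default_rng(seed)
    if island_scale == 1:
        raw = rng.random(grid.shape)
    else:
        cy = -(-grid.ny // island_scale)
        cx = -(-grid.nx // island_scale)
        coarse = rng.random((cy, cx))
        raw = np.kron(coarse, np.ones((island_scale, island_scale)))[: grid.ny, : grid.nx]
    m = ScalarField(grid, raw, "dimensionless")
    if relax_time == 0:
        return m
    p_relax = replace(p, D_m=0.0)
    if dt is None:
        dt = min(0.1, max_stable_dt(grid, p_relax), relax_time)
    zero = ScalarField.zeros(grid)
    t = 0.0
    while t < relax_time - 1e-12:
        step = min(dt, relax_time - t)
        dm = vessel_rhs(m, zero, zero, p_relax)
        m = ScalarField(grid, m.values + step * dm.values, m.unit)
        m.clamp_nonnegative()
        t += step
    return m
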