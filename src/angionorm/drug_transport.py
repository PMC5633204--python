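"""Plasma bolus pharmacokinetics and quasi-steady tissue drug fields.

The plasma concentration of each drug after a bolus decays exponentially,
``peak * exp(-t / t_half)`` with the printed time constant acting directly
(an optional flag interprets it as a true half-life, ``exp(-t ln2 / t_half)``).
Repeat dosing superposes linearly.

Tissue fields are solved in steady state because drug transport is much
faster than tumor growth:

* antiangiogenic agent (diffusion-dominated):
  ``0 = D_A lap(A) + lambda_A(x) m (A_v - A) - Gamma_l_rate A - k_A A``
* liposomal chemotherapy (convection-dominated, transvascular diffusion
  neglected):
  ``0 = D_d lap(d) + div(k_E d K grad P) + Gamma_b^+ (1 - sigma_d) d_v
       - Gamma_l_rate d - d_r n d - k_d d``

Both are assembled as sparse M-matrices (first-order upwinding of the
interstitial convection term) so the solved concentrations are non-negative.
All rates here are in 1/s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .grid_core import BoundaryCondition, Grid, ScalarField, no_flux
from .growth_dynamics import GrowthParams
from .interstitial_fluid import ConductivityFields, FluidParams, starling_source

__all__ = [
    "AgentParams",
    "LiposomeParams",
    "DoseEvent",
    "reflection_coefficient",
    "plasma_concentration",
    "solve_agent",
    "solve_liposome",
    "extravasation_coefficient",
]

SECONDS_PER_HOUR = 3600.0


def reflection_coefficient(drug_radius: float, pore_radius: float) -> float:
    """Solvent-drag reflection coefficient from the pore-exclusion formula.

    sigma_d = (1 - (1 - alpha)^2)^2 with alpha = drug_radius / pore_radius.
    """
    if drug_radius < 0 or pore_radius <= 0:
        raise ValueError("radii must be positive")
    if drug_radius > pore_radius:
        raise ValueError("drug radius exceeds pore radius: particle cannot pass")
    alpha = drug_radius / pore_radius
    return (1.0 - (1.0 - alpha) ** 2) ** 2


@dataclass(frozen=True)
class AgentParams:
    """Antiangiogenic agent transport parameters."""

    D_A: float = 4e-7            # tissue diffusivity, cm^2/s
    lambda_A_tumor: float = 4e-6     # transvascular diffusion per unit m, 1/s
    lambda_A_normal: float = 1.4e-7
    k_A: float = 1.65e-6         # decay rate, 1/s
    t_half_A: float = 20.0       # plasma time constant, hours

    def __post_init__(self) -> None:
        if min(self.D_A, self.lambda_A_tumor, self.lambda_A_normal, self.k_A) < 0:
            raise ValueError("agent parameters must be non-negative")
        if self.t_half_A <= 0:
            raise ValueError("t_half_A must be positive")


@dataclass(frozen=True)
class LiposomeParams:
    """Liposomal chemotherapy transport parameters.

    ``P_d`` (diffusional wall permeability) is recorded for completeness but
    unused: transvascular diffusion of liposomes is neglected.  The
    reflection coefficient is always derived from the pore formula.
    """

    D_d: float = 2.5e-9          # tissue diffusivity, cm^2/s
    k_E: float = 0.35            # convective retardation coefficient
    P_d: float = 0.05 * 3.42e-7  # recorded, unused (cm/s)
    k_d: float = 1.65e-6         # decay rate, 1/s
    t_half_d: float = 45.2       # plasma time constant, hours
    drug_radius: float = 100.0   # nm
    pore_radius: float = 500.0   # nm

    def __post_init__(self) -> None:
        if not (0.0 <= self.k_E <= 1.0):
            raise ValueError("k_E must lie in [0, 1]")
        if min(self.D_d, self.k_d) < 0:
            raise ValueError("diffusivity and decay must be non-negative")
        sd = self.sigma_d  # validates radii as a side effect
        if not (0.0 <= sd <= 1.0):
            raise ValueError("sigma_d must lie in [0, 1]")

    @property
    def sigma_d(self) -> float:
        return reflection_coefficient(self.drug_radius, self.pore_radius)


@dataclass(frozen=True)
class DoseEvent:
    """A bolus injection: simulation day, drug kind and peak plasma value."""

    day: float
    kind: str  # "antiangiogenic" | "chemo"
    peak: float

    def __post_init__(self) -> None:
        if self.day < 0:
            raise ValueError("dose day must be non-negative")
        if self.peak < 0:
            raise ValueError("dose peak must be non-negative")
        if self.kind not in ("antiangiogenic", "chemo"):
            raise ValueError(f"unknown dose kind {self.kind!r}")


def plasma_concentration(
    t: float,
    events: list[DoseEvent],
    time_constant: float,
    halflife_ln2: bool = False,
) -> float:
    """Superposed plasma concentration at time ``t`` (hours since day 0).

    Each past event contributes ``peak * exp(-(t - t_event)/tau)`` where
    ``t_event = 24 * day`` and ``tau = time_constant`` hours (or
    ``time_constant / ln 2`` when ``halflife_ln2`` is set).  Zero before the
    first event.
    """
    if time_constant <= 0:
        raise ValueError("time_constant must be positive")
    tau = time_constant / np.log(2.0) if halflife_ln2 else time_constant
    total = 0.0
    for ev in events:
        t0 = ev.day * 24.0
        if t >= t0:
            total += ev.peak * np.exp(-(t - t0) / tau)
    return total


def _lambda_A_field(n: ScalarField, ap: AgentParams) -> np.ndarray:
    # transvascular agent permeability switches between the tissue columns on
    # the tumor mask (tumor vessels stay agent-avid whether or not their wall
    # hydraulic conductivity has normalized)
    w = np.clip(n.values / 0.1, 0.0, 1.0)
    return ap.lambda_A_normal + w * (ap.lambda_A_tumor - ap.lambda_A_normal)


def _drainage_rate(cf: ConductivityFields, P: ScalarField | None) -> np.ndarray:
    if P is None:
        return np.zeros(cf.lambda_l.grid.shape)
    return np.maximum(cf.lambda_l.values * P.values, 0.0)


def _solve_reaction_diffusion(
    grid: Grid,
    D: float,
    sink: np.ndarray,
    source: np.ndarray,
    conv_flux=None,
) -> np.ndarray:
    """Assemble and solve ``-D lap(c) - div(v c) + sink c = source`` with no-flux bc.

    ``conv_flux`` supplies upwinded face velocities (east, north) in cm/s when
    the convection term is present.  The discretization is an M-matrix.
    """
    ny, nx = grid.shape
    N = nx * ny
    h = grid.h
    h2 = h * h
    idx = np.arange(N).reshape(ny, nx)

    diag = sink.ravel().astype(np.float64).copy()
    rows = [np.arange(N)]
    cols = [np.arange(N)]
    data = [diag]

    def couple(center_sl, nb_sl, coeff_center, coeff_nb):
        ci = idx[center_sl].ravel()
        ni = idx[nb_sl].ravel()
        data[0][ci] += coeff_center.ravel()
        rows.append(ci)
        cols.append(ni)
        data.append(coeff_nb.ravel())

    # diffusion on interior faces only (no-flux outer boundary)
    for center_sl, nb_sl in (
        (np.s_[:, :-1], np.s_[:, 1:]),
        (np.s_[:, 1:], np.s_[:, :-1]),
        (np.s_[:-1, :], np.s_[1:, :]),
        (np.s_[1:, :], np.s_[:-1, :]),
    ):
        shape = idx[center_sl].shape
        cc = np.full(shape, D / h2)
        couple(center_sl, nb_sl, cc, -cc)

    if conv_flux is not None:
        ve, vn = conv_flux  # face velocities: ve[j, i] between (i, i+1); vn between (j, j+1)
        # east faces: outflow from left cell if ve > 0, from right cell if ve < 0
        vp = np.maximum(ve, 0.0) / h
        vm = np.maximum(-ve, 0.0) / h
        couple(np.s_[:, :-1], np.s_[:, 1:], vp, -vm)
        couple(np.s_[:, 1:], np.s_[:, :-1], vm, -vp)
        wp = np.maximum(vn, 0.0) / h
        wm = np.maximum(-vn, 0.0) / h
        couple(np.s_[:-1, :], np.s_[1:, :], wp, -wm)
        couple(np.s_[1:, :], np.s_[:-1, :], wm, -wp)

    A = sp.csr_matrix(
        (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))), shape=(N, N)
    )
    b = source.ravel()
    x = spla.spsolve(A.tocsc(), b, permc_spec="MMD_AT_PLUS_A")
    bnorm = np.linalg.norm(b)
    if bnorm > 0:
        res = np.linalg.norm(A @ x - b) / bnorm
        if res > 1e-10:
            raise RuntimeError(f"steady drug solve residual {res:.2e} exceeds 1e-10")
    return x.reshape(grid.shape)


def solve_agent(
    A_v: float,
    m: ScalarField,
    n: ScalarField,
    cf: ConductivityFields,
    ap: AgentParams,
    bc: BoundaryCondition | None = None,
    P: ScalarField | None = None,
) -> ScalarField:
    """Steady antiangiogenic agent field for plasma concentration ``A_v``.

    The lymphatic drainage rate requires the pressure field; when ``P`` is
    omitted drainage is dropped (it is a small correction against ``k_A``).
    """
    if A_v < 0:
        raise ValueError("plasma concentration must be non-negative")
    if bc is not None and bc.kind != "no_flux":
        raise ValueError("agent transport uses no-flux boundary conditions")
    lam_A = _lambda_A_field(n, ap)
    uptake = lam_A * m.values                      # 1/s
    sink = uptake + _drainage_rate(cf, P) + ap.k_A
    source = uptake * A_v
    vals = _solve_reaction_diffusion(m.grid, ap.D_A, sink, source)
    return ScalarField(m.grid, np.maximum(vals, 0.0), "concentration")


def solve_liposome(
    d_v: float,
    m: ScalarField,
    n: ScalarField,
    P: ScalarField,
    cf: ConductivityFields,
    lp: LiposomeParams,
    gp: GrowthParams,
    fp: FluidParams,
    bc: BoundaryCondition | None = None,
) -> ScalarField:
    """Steady liposomal drug field for plasma concentration ``d_v``.

    Extravasation is one-way: the convective source uses ``max(Gamma_b, 0)``
    so fluid resorption does not withdraw drug back into vessels.  The
    interstitial convection by the retarded Darcy velocity ``k_E u`` is
    discretized with first-order upwinding.
    """
    if d_v < 0:
        raise ValueError("plasma concentration must be non-negative")
    if bc is not None and bc.kind != "no_flux":
        raise ValueError("liposome transport uses no-flux boundary conditions")
    grid = m.grid
    h = grid.h
    Pv = P.values

    gamma_b = starling_source(m, P, cf, fp).values
    source = np.maximum(gamma_b, 0.0) * (1.0 - lp.sigma_d) * d_v

    d_r_si = gp.d_r / SECONDS_PER_HOUR             # 1/s per unit n
    sink = _drainage_rate(cf, P) + d_r_si * n.values + lp.k_d

    # face velocities of the retarded interstitial convection v = -k_E K grad P
    ve = -lp.k_E * fp.K * (Pv[:, 1:] - Pv[:, :-1]) / h   # cm/s, east faces
    vn = -lp.k_E * fp.K * (Pv[1:, :] - Pv[:-1, :]) / h   # north faces

    vals = _solve_reaction_diffusion(grid, lp.D_d, sink, source, conv_flux=(ve, vn))
    return ScalarField(grid, np.maximum(vals, 0.0), "concentration")


def extravasation_coefficient(
    m: ScalarField,
    P: ScalarField,
    cf: ConductivityFields,
    lp: LiposomeParams,
    fp: FluidParams,
    clamp: bool = True,
) -> ScalarField:
    """Convective drug extravasation rate per unit plasma concentration, 1/s.

    Gamma_b (1 - sigma_d); with ``clamp`` (default) resorbing regions where
    Gamma_b < 0 report zero, matching the one-way drug source.
    """
    gamma_b = starling_source(m, P, cf, fp).values
    if clamp:
        gamma_b = np.maximum(gamma_b, 0.0)
    return ScalarField(m.grid, gamma_b * (1.0 - lp.sigma_d), "1/s")
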