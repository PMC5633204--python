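"""Interstitial fluid pressure: normalization switching, elliptic solve, Darcy flow.

Steady interstitial fluid balance (Darcy + Starling + continuity):

    -K lap(P) = lambda_b(x) m(x) [P_v - P - osm(x)] - lambda_l(x) P

Vessel-wall properties switch dynamically with the local vessel density:
``m <= 1`` vessels are normal, ``m >= 1 + delta`` vessels are angiogenic and
leaky, with a linear ramp in between that keeps the elliptic coefficients
continuous.  Lymphatics are suppressed inside the tumor (where the cell
density exceeds ``n_tum``).  All pressures are in mmHg, conductivities in
1/(mmHg s), K in cm^2/(mmHg s).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.special import i0e, i1e, k0e, k1e

from .grid_core import BoundaryCondition, ScalarField, dirichlet, gradient

__all__ = [
    "FluidParams",
    "ConductivityFields",
    "effective_conductivities",
    "starling_source",
    "lymph_sink",
    "solve_ifp",
    "analytic_ifp_radial",
    "darcy_velocity",
    "boundary_outflux",
]

#: default width of the linear leakiness ramp above m = 1
RAMP_DELTA = 0.1

#: cell-density threshold of the whole-tumor mask (lymphatic suppression)
N_TUMOR = 0.1


@dataclass(frozen=True)
class FluidParams:
    """Interstitial fluid transport parameters (tumor / normal columns).

    Derived quantities (``lambda_b``, ``P_eff``) are always computed from the
    primary entries, never stored independently.
    """

    K: float = 2.5e-7                 # interstitial hydraulic conductivity, cm^2/mmHg/s
    L_p_tumor: float = 1.86e-6        # vessel-wall conductivity, cm/mmHg/s
    L_p_normal: float = 3.6e-8
    SV_tumor: float = 200.0           # vessel surface density, cm^2/cm^3
    SV_normal: float = 70.0
    lambda_l_normal: float = 6.66e-4  # lymphatic conductivity, 1/mmHg/s
    P_v: float = 15.0                 # vascular pressure, mmHg
    osmotic_term_tumor: float = 2.2e-4   # sigma_v (pi_c - pi_i), mmHg
    osmotic_term_normal: float = 9.1
    lymph_pressure: float = 0.0
    # width of the leakiness ramp above m = 1: walls are fully tumor-like
    # only when the local vessel excess reaches m = 1 + ramp_delta
    ramp_delta: float = 0.1

    def __post_init__(self) -> None:
        for name in ("K", "L_p_tumor", "L_p_normal", "SV_tumor", "SV_normal", "lambda_l_normal"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def lambda_b_tumor(self) -> float:
        """L_p * SV for the tumor column, 1/(mmHg s)."""
        return self.L_p_tumor * self.SV_tumor

    @property
    def lambda_b_normal(self) -> float:
        return self.L_p_normal * self.SV_normal

    @property
    def p_eff_tumor(self) -> float:
        """Effective microvascular pressure P_v - sigma_v (pi_c - pi_i), mmHg."""
        return self.P_v - self.osmotic_term_tumor

    @property
    def p_eff_normal(self) -> float:
        return self.P_v - self.osmotic_term_normal

    @property
    def normal_equilibrium_pressure(self) -> float:
        """Far-field IFP where normal Starling supply balances lymph drainage.

        With m = 1: lambda_b,n (P_eff,n - P) = lambda_l,n P.
        """
        lb, ll = self.lambda_b_normal, self.lambda_l_normal
        if lb + ll == 0:
            return 0.0
        return lb * self.p_eff_normal / (lb + ll)


@dataclass
class ConductivityFields:
    """Per-node effective wall conductivity, lymphatic conductivity and osmotic term."""

    lambda_b: ScalarField   # 1/(mmHg s), per unit vessel density
    lambda_l: ScalarField   # 1/(mmHg s)
    osmotic_term: ScalarField  # mmHg
    leakiness: ScalarField  # ramp weight in [0, 1]; 0 = normal, 1 = leaky


def leakiness_ramp(m_values: np.ndarray, delta: float) -> np.ndarray:
    """Weight 0 for m <= 1, 1 for m >= 1 + delta, linear in between."""
    return np.clip((m_values - 1.0) / delta, 0.0, 1.0)


def effective_conductivities(
    n: ScalarField,
    m: ScalarField,
    fp: FluidParams,
    delta: float | None = None,
    n_tum: float = N_TUMOR,
) -> ConductivityFields:
    """Per-node wall/lymph conductivities and osmotic term from the current n, m.

    Vessel-wall conductivity, surface density and the osmotic term all switch
    from their normal to their tumor values on the same linear ramp over
    ``1 < m < 1 + delta``.  The returned ``lambda_b`` is the per-unit-vessel
    product L_p * SV; the factor ``m`` enters the Starling source separately.
    Lymphatic conductivity fades out linearly as the cell density approaches
    ``n_tum`` and is zero inside the tumor mask.
    """
    if (n.values < 0).any() or (m.values < 0).any():
        raise ValueError("n and m must be non-negative")
    if delta is None:
        delta = fp.ramp_delta
    w = leakiness_ramp(m.values, delta)
    L_p = fp.L_p_normal + w * (fp.L_p_tumor - fp.L_p_normal)
    SV = fp.SV_normal + w * (fp.SV_tumor - fp.SV_normal)
    osm = fp.osmotic_term_normal + w * (fp.osmotic_term_tumor - fp.osmotic_term_normal)
    lam_l = fp.lambda_l_normal * np.clip(1.0 - n.values / n_tum, 0.0, 1.0)
    g = n.grid
    return ConductivityFields(
        lambda_b=ScalarField(g, L_p * SV, "1/s"),
        lambda_l=ScalarField(g, lam_l, "1/s"),
        osmotic_term=ScalarField(g, osm, "mmHg"),
        leakiness=ScalarField(g, w, "dimensionless"),
    )


def starling_source(
    m: ScalarField,
    P: ScalarField,
    cf: ConductivityFields,
    fp: FluidParams,
) -> ScalarField:
    """Transvascular fluid source Gamma_b = lambda_b m [P_v - P - osm], 1/s.

    May be negative where P exceeds the local effective microvascular
    pressure (fluid resorption into vessels).
    """
    vals = cf.lambda_b.values * m.values * (fp.P_v - P.values - cf.osmotic_term.values)
    return ScalarField(P.grid, vals, "1/s")


def lymph_sink(P: ScalarField, cf: ConductivityFields) -> ScalarField:
    """Lymphatic drainage Gamma_l = lambda_l P, 1/s (lymph pressure is 0 mmHg)."""
    return ScalarField(P.grid, cf.lambda_l.values * P.values, "1/s")


def _assemble_ifp(
    m: ScalarField,
    cf: ConductivityFields,
    fp: FluidParams,
    bc: BoundaryCondition,
) -> tuple[sp.csr_matrix, np.ndarray]:
    grid = m.grid
    ny, nx = grid.shape
    N = nx * ny
    h2 = grid.h ** 2
    K = fp.K

    lam_bm = cf.lambda_b.values * m.values          # 1/(mmHg s)
    lam_l = cf.lambda_l.values
    rhs_field = lam_bm * (fp.P_v - cf.osmotic_term.values)

    idx = np.arange(N).reshape(ny, nx)
    interior = np.ones((ny, nx), dtype=bool)
    if bc.kind == "dirichlet":
        interior[0, :] = interior[-1, :] = False
        interior[:, 0] = interior[:, -1] = False
    else:
        if not (lam_bm.max() > 0 or lam_l.max() > 0):
            raise ValueError(
                "pure no-flux IFP problem with all conductivities zero is singular "
                "(constant pressures form a null space)"
            )

    rows, cols, data = [], [], []
    b = np.zeros(N)

    # diagonal: reaction + accumulated face conductances
    diag = (lam_bm + lam_l).ravel().copy()
    b[:] = rhs_field.ravel()

    def add_faces(sl_center, sl_nb):
        ci = idx[sl_center].ravel()
        nix = idx[sl_nb].ravel()
        rows.append(ci)
        cols.append(nix)
        data.append(np.full(ci.size, -K / h2))

    # count of in-domain neighbors per node (no_flux: missing faces carry no flux)
    nnb = np.full((ny, nx), 4.0)
    if bc.kind == "no_flux":
        nnb[0, :] -= 1
        nnb[-1, :] -= 1
        nnb[:, 0] -= 1
        nnb[:, -1] -= 1
    diag += (K / h2) * nnb.ravel()

    add_faces(np.s_[:, :-1], np.s_[:, 1:])
    add_faces(np.s_[:, 1:], np.s_[:, :-1])
    add_faces(np.s_[:-1, :], np.s_[1:, :])
    add_faces(np.s_[1:, :], np.s_[:-1, :])

    rows = np.concatenate([np.arange(N)] + rows)
    cols = np.concatenate([np.arange(N)] + cols)
    data = np.concatenate([diag] + data)

    A = sp.csr_matrix((data, (rows, cols)), shape=(N, N))
    if bc.kind == "dirichlet":
        bnodes = idx[~interior].ravel()
        # rebuild with identity rows on the boundary
        keep = ~np.isin(rows, bnodes)
        A = sp.csr_matrix(
            (np.concatenate([data[keep], np.ones(bnodes.size)]),
             (np.concatenate([rows[keep], bnodes]),
              np.concatenate([cols[keep], bnodes]))),
            shape=(N, N),
        )
        b[bnodes] = bc.value
    return A, b


def solve_ifp(
    m: ScalarField,
    cf: ConductivityFields,
    fp: FluidParams,
    bc: BoundaryCondition,
) -> ScalarField:
    """Solve the steady IFP equation by sparse direct factorization.

    The linear elliptic problem (5-point Laplacian plus diagonal Starling and
    lymphatic reaction terms) is assembled in flux form and solved directly;
    the residual is verified to satisfy ||r|| <= 1e-10 ||b||.
    """
    if fp.K <= 0:
        raise ValueError("K must be positive")
    A, b = _assemble_ifp(m, cf, fp, bc)
    x = spla.spsolve(A.tocsc(), b, permc_spec="MMD_AT_PLUS_A")
    bnorm = np.linalg.norm(b)
    if bnorm > 0:
        res = np.linalg.norm(A @ x - b) / bnorm
        if res > 1e-10:
            raise RuntimeError(f"IFP solve residual {res:.2e} exceeds 1e-10")
    return ScalarField(m.grid, x.reshape(m.grid.shape), "mmHg")


def analytic_ifp_radial(R: float, fp: FluidParams, r_values) -> np.ndarray:
    """Closed-form radial IFP for a disc tumor with piecewise-uniform coefficients.

    Inside ``r < R``: leaky tumor vessels with m = 1 and no lymphatics;
    outside: normal vessels with m = 1 plus lymphatic drainage.  The solution
    is built from modified Bessel functions I0/K0 with continuity of P and of
    the radial flux at ``r = R``, decaying to the far-field normal
    equilibrium pressure.  Exponentially scaled Bessel functions keep the
    evaluation stable for R much larger than the decay lengths.
    """
    if R <= 0:
        raise ValueError("R must be positive")
    r = np.asarray(r_values, dtype=np.float64)
    K = fp.K
    lam_t = fp.lambda_b_tumor
    lam_n = fp.lambda_b_normal
    lam_l = fp.lambda_l_normal
    P_t = fp.p_eff_tumor
    P_inf = fp.normal_equilibrium_pressure

    Lt = np.sqrt(K / lam_t)              # tumor decay length, cm
    Ln = np.sqrt(K / (lam_n + lam_l))    # normal decay length, cm

    # interface pressure from continuity of P and K dP/dr
    a = i1e(R / Lt) / (Lt * i0e(R / Lt))
    bq = k1e(R / Ln) / (Ln * k0e(R / Ln))
    P_R = (a * P_t + bq * P_inf) / (a + bq)

    out = np.empty_like(r)
    inside = r <= R
    ri = r[inside]
    # I0(r/Lt)/I0(R/Lt) via scaled functions: i0e(x) = e^-x I0(x)
    ratio_in = i0e(ri / Lt) / i0e(R / Lt) * np.exp((ri - R) / Lt)
    out[inside] = P_t + (P_R - P_t) * ratio_in
    ro = r[~inside]
    ratio_out = k0e(ro / Ln) / k0e(R / Ln) * np.exp((R - ro) / Ln)
    out[~inside] = P_inf + (P_R - P_inf) * ratio_out
    return out


def darcy_velocity(P: ScalarField, fp: FluidParams) -> tuple[ScalarField, ScalarField]:
    """Interstitial fluid velocity u = -K grad(P), cm/s."""
    gx, gy = gradient(P, dirichlet(fp.normal_equilibrium_pressure))
    ux = ScalarField(P.grid, -fp.K * gx.values, "cm/s")
    uy = ScalarField(P.grid, -fp.K * gy.values, "cm/s")
    return ux, uy


def boundary_outflux(P: ScalarField, fp: FluidParams) -> float:
    """Discrete conductive outflux through the boundary node layer.

    For the 5-point scheme with Dirichlet boundary rows this equals the total
    interior fluid source integral ``sum (Gamma_b - Gamma_l) h^2`` exactly (up
    to solver round-off), which is the discrete statement of mass
    conservation.  Units: (1/s) * cm^2 (source rate integrated over area).
    """
    v = P.values
    flux = 0.0
    # faces between boundary nodes and the adjacent interior layer
    flux += np.sum(v[1:-1, 1] - v[1:-1, 0])
    flux += np.sum(v[1:-1, -2] - v[1:-1, -1])
    flux += np.sum(v[1, 1:-1] - v[0, 1:-1])
    flux += np.sum(v[-2, 1:-1] - v[-1, 1:-1])
    return fp.K * flux  # positive = fluid leaving through the boundary
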