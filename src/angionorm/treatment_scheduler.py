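"""Regimen construction, dose/growth calibration and the master simulation loop.

The four reference regimens (all chemotherapy boluses on days 23/25/27):

* case1 — antiangiogenic agent alone, every other day from day 23, 4 pulses;
* case2 — chemotherapy alone;
* case3 — antiangiogenic lead-in from day 19 (5 pulses) plus chemotherapy;
* case4 — concurrent: antiangiogenic from day 23 (4 pulses) plus chemotherapy.

Antiangiogenic peaks taper multiplicatively pulse by pulse.  The
antiangiogenic peak dose is normally calibrated so that the microvascular
density inside the tumor drops by about 50% by the end of the
administrations; the growth rate ``r`` is calibrated so the untreated tumor
reaches a 13.5 mm radius at day 30.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .drug_transport import (
    AgentParams,
    DoseEvent,
    LiposomeParams,
    plasma_concentration,
    solve_agent,
    solve_liposome,
    extravasation_coefficient,
)
from .grid_core import Grid, ScalarField, dirichlet
from .growth_dynamics import (
    GrowthParams,
    init_tumor_gaussian,
    init_vessel_islands,
    max_stable_dt,
    step_growth,
)
from .interstitial_fluid import (
    FluidParams,
    effective_conductivities,
    solve_ifp,
)
from .metrics_reporting import (
    INTERIOR_THRESHOLD,
    TUMOR_THRESHOLD,
    MetricRecord,
    masked_average,
    mvd_reduction,
    tumor_radius,
)

__all__ = [
    "Regimen",
    "GridSpec",
    "SimConfig",
    "SimResult",
    "build_regimen",
    "run_simulation",
    "calibrate_aa_dose",
    "calibrate_growth",
]

log = logging.getLogger(__name__)

CASE_LABELS = ("case1", "case2", "case3", "case4", "custom")
DEFAULT_CHEMO_DAYS = (23.0, 25.0, 27.0)


@dataclass(frozen=True)
class Regimen:
    """Ordered bolus events plus the antiangiogenic taper factor."""

    events: tuple[DoseEvent, ...] = ()
    taper_factor: float = 0.8
    label: str = "custom"

    def __post_init__(self) -> None:
        if self.label not in CASE_LABELS:
            raise ValueError(f"unknown regimen label {self.label!r}")
        if not (0.0 < self.taper_factor <= 1.0):
            raise ValueError("taper_factor must lie in (0, 1]")
        days = [ev.day for ev in self.events]
        if days != sorted(days):
            raise ValueError("events must be sorted by day")

    @property
    def aa_events(self) -> list[DoseEvent]:
        return [ev for ev in self.events if ev.kind == "antiangiogenic"]

    @property
    def chemo_events(self) -> list[DoseEvent]:
        return [ev for ev in self.events if ev.kind == "chemo"]

    @property
    def last_aa_day(self) -> float | None:
        days = [ev.day for ev in self.aa_events]
        return max(days) if days else None

    def scale_aa(self, factor: float) -> "Regimen":
        """Return a copy with every antiangiogenic peak multiplied by ``factor``."""
        events = tuple(
            replace(ev, peak=ev.peak * factor) if ev.kind == "antiangiogenic" else ev
            for ev in self.events
        )
        return replace(self, events=events)


def build_regimen(
    label: str,
    chemo_days: tuple[float, ...] = DEFAULT_CHEMO_DAYS,
    aa_start_day: float | None = None,
    aa_pulses: int | None = None,
    aa_peak: float = 0.05,
    chemo_peak: float = 0.05,
    taper_factor: float = 0.8,
) -> Regimen:
    """Build one of the reference regimens (or a custom one).

    Antiangiogenic pulses are given every other day starting at
    ``aa_start_day``; the peak of pulse k is ``aa_peak * taper_factor**k``.
    """
    if label not in CASE_LABELS:
        raise ValueError(f"unknown regimen label {label!r}; choose from {CASE_LABELS}")
    if label == "case1":
        aa_start_day = 23.0 if aa_start_day is None else aa_start_day
        aa_pulses = 4 if aa_pulses is None else aa_pulses
        chemo_days = ()
    elif label == "case2":
        aa_pulses = 0
    elif label == "case3":
        aa_start_day = 19.0 if aa_start_day is None else aa_start_day
        aa_pulses = 5 if aa_pulses is None else aa_pulses
    elif label == "case4":
        aa_start_day = 23.0 if aa_start_day is None else aa_start_day
        aa_pulses = 4 if aa_pulses is None else aa_pulses
    aa_pulses = aa_pulses or 0
    if not (0 <= aa_pulses <= 6):
        raise ValueError("aa_pulses must lie in 0..6")
    if aa_pulses and aa_start_day is None:
        raise ValueError("aa_start_day required when aa_pulses > 0")

    events: list[DoseEvent] = [
        DoseEvent(day=float(d), kind="chemo", peak=chemo_peak) for d in chemo_days
    ]
    for k in range(aa_pulses):
        events.append(
            DoseEvent(
                day=float(aa_start_day + 2 * k),
                kind="antiangiogenic",
                peak=aa_peak * taper_factor ** k,
            )
        )
    events.sort(key=lambda ev: (ev.day, ev.kind))
    return Regimen(events=tuple(events), taper_factor=taper_factor, label=label)


@dataclass(frozen=True)
class GridSpec:
    nx: int = 151
    ny: int = 151
    h: float = 0.02
    origin: tuple[float, float] = (0.0, 0.0)

    def build(self) -> Grid:
        return Grid(self.nx, self.ny, self.h, self.origin)


@dataclass
class SimConfig:
    """Full configuration of a simulation run."""

    grid: GridSpec = field(default_factory=GridSpec)
    growth: GrowthParams = field(default_factory=GrowthParams)
    fluid: FluidParams = field(default_factory=FluidParams)
    agent: AgentParams = field(default_factory=AgentParams)
    liposome: LiposomeParams = field(default_factory=LiposomeParams)
    regimen: Regimen = field(default_factory=Regimen)
    seed: int = 1234
    t_end: float = 30.0
    dt_max: float = 0.01
    # initial conditions
    tumor_radius0: float = 0.02
    tumor_peak: float = 1.0
    vessel_relax_time: float = 60.0
    island_scale: int = 1
    # sampling cadences (days)
    pk_dt_dosing: float = 0.05
    pk_dt_idle: float = 0.25
    snapshot_dt: float = 5.0
    # switches
    inhibition_variant: bool = False
    halflife_ln2: bool = False
    boundary_mode: str = "normal_equilibrium"  # or "vascular" (literal P_v)
    solve_fluid: bool = True

    def __post_init__(self) -> None:
        if self.regimen.events and self.t_end <= max(ev.day for ev in self.regimen.events):
            raise ValueError("t_end must exceed the last dose day")
        if self.boundary_mode not in ("normal_equilibrium", "vascular"):
            raise ValueError("boundary_mode must be 'normal_equilibrium' or 'vascular'")
        if self.dt_max <= 0 or self.pk_dt_dosing <= 0 or self.pk_dt_idle <= 0:
            raise ValueError("time steps must be positive")

    @property
    def boundary_pressure(self) -> float:
        if self.boundary_mode == "vascular":
            return self.fluid.P_v
        return self.fluid.normal_equilibrium_pressure


@dataclass
class SimResult:
    """Metric records plus field snapshots of one run."""

    config: SimConfig
    grid: Grid
    metrics: pd.DataFrame
    snapshots: dict[float, dict[str, ScalarField]]
    final_state: dict[str, ScalarField]
    t_final: float
    d_max_seen: float = 0.0

    @property
    def final_radius(self) -> float:
        return tumor_radius(self.final_state["n"])


def _initial_state(cfg: SimConfig, grid: Grid) -> dict[str, ScalarField]:
    n = init_tumor_gaussian(grid, radius0=cfg.tumor_radius0, peak=cfg.tumor_peak)
    m = init_vessel_islands(
        grid,
        seed=cfg.seed,
        p=cfg.growth,
        relax_time=cfg.vessel_relax_time,
        island_scale=cfg.island_scale,
    )
    return {"n": n, "m": m}


def _dosing_window(regimen: Regimen, pad: float = 3.0) -> tuple[float, float]:
    if not regimen.events:
        return (np.inf, -np.inf)
    days = [ev.day for ev in regimen.events]
    return (min(days), max(days) + pad)


def _safe_masked_average(f: ScalarField, mask: ScalarField, threshold: float) -> float:
    try:
        return masked_average(f, mask, threshold)
    except ValueError:
        return float("nan")


def run_simulation(
    cfg: SimConfig,
    initial_state: dict[str, ScalarField] | None = None,
    t_start: float = 0.0,
) -> SimResult:
    """Run the coupled growth / IFP / drug-transport loop from ``t_start`` to ``t_end``.

    Per growth step: effective conductivities from the current (n, m); at the
    PK sampling cadence the IFP is re-solved, plasma concentrations are
    evaluated and the quasi-steady drug fields recomputed (fields are held
    between samples); then the growth state advances by forward Euler.  Fully
    deterministic given the config seed.
    """
    grid = cfg.grid.build()
    state = initial_state if initial_state is not None else _initial_state(cfg, grid)
    state = {k: v.copy() for k, v in state.items()}
    if state["n"].grid != grid:
        raise ValueError("initial state grid does not match config grid")

    dt = min(cfg.dt_max, max_stable_dt(grid, cfg.growth))
    regimen = cfg.regimen
    window = _dosing_window(regimen)
    aa_events = regimen.aa_events
    chemo_events = regimen.chemo_events
    has_doses = bool(aa_events or chemo_events)

    A = ScalarField.zeros(grid, "concentration")
    d = ScalarField.zeros(grid, "concentration")
    P = ScalarField.zeros(grid, "mmHg")
    extrav = ScalarField.zeros(grid, "1/s")

    gp = cfg.growth
    d_max_seen = 0.0
    records: list[MetricRecord] = []
    snapshots: dict[float, dict[str, ScalarField]] = {}
    cumulative_exposure = 0.0
    prev_sample_t: float | None = None
    prev_interior_d = 0.0
    next_snapshot = t_start

    t = t_start
    next_sample = t_start
    n_steps = 0
    while t < cfg.t_end - 1e-9:
        n, m = state["n"], state["m"]
        if not (np.isfinite(n.values).all() and np.isfinite(m.values).all()):
            raise RuntimeError(
                f"simulation became unstable at t={t:.3f} d "
                f"(last metric at t={records[-1].t if records else t_start})"
            )

        if t >= next_sample - 1e-9:
            cf = effective_conductivities(n, m, cfg.fluid)
            if cfg.solve_fluid:
                P = solve_ifp(m, cf, cfg.fluid, dirichlet(cfg.boundary_pressure))
            plasma_A = plasma_concentration(
                t * 24.0, aa_events, cfg.agent.t_half_A, cfg.halflife_ln2
            )
            plasma_d = plasma_concentration(
                t * 24.0, chemo_events, cfg.liposome.t_half_d, cfg.halflife_ln2
            )
            if cfg.solve_fluid and has_doses:
                if plasma_A > 0:
                    A = solve_agent(plasma_A, m, n, cf, cfg.agent, P=P)
                else:
                    A = ScalarField.zeros(grid, "concentration")
                if plasma_d > 0:
                    d = solve_liposome(
                        plasma_d, m, n, P, cf, cfg.liposome, gp, cfg.fluid
                    )
                    d_max_seen = max(d_max_seen, float(d.values.max()))
                else:
                    d = ScalarField.zeros(grid, "concentration")
                extrav = extravasation_coefficient(m, P, cf, cfg.liposome, cfg.fluid)
            interior_d = _safe_masked_average(d, n, INTERIOR_THRESHOLD)
            extrav_rate = _safe_masked_average(extrav, n, INTERIOR_THRESHOLD)
            if np.isfinite(extrav_rate):
                extrav_rate *= plasma_d
            id_now = interior_d if np.isfinite(interior_d) else 0.0
            if prev_sample_t is not None:
                cumulative_exposure += 0.5 * (id_now + prev_interior_d) * (t - prev_sample_t)
            prev_sample_t, prev_interior_d = t, id_now
            records.append(
                MetricRecord(
                    t=t,
                    radius=tumor_radius(n),
                    avg_ifp=_safe_masked_average(P, n, TUMOR_THRESHOLD),
                    avg_interior_density=_safe_masked_average(n, n, INTERIOR_THRESHOLD),
                    avg_interior_m=_safe_masked_average(m, n, INTERIOR_THRESHOLD),
                    avg_interior_extrav=extrav_rate,
                    interior_mean_d=interior_d,
                    cumulative_exposure=cumulative_exposure,
                    plasma_A=plasma_A,
                    plasma_d=plasma_d,
                )
            )
            in_window = window[0] - 1e-9 <= t <= window[1]
            next_sample = t + (cfg.pk_dt_dosing if in_window else cfg.pk_dt_idle)

        if t >= next_snapshot - 1e-9:
            snapshots[round(t, 6)] = {
                "n": n.copy(), "m": m.copy(), "P": P.copy(), "A": A.copy(), "d": d.copy()
            }
            next_snapshot = t + cfg.snapshot_dt

        if cfg.inhibition_variant and gp.d_max is None:
            gp_step = replace(gp, d_max=max(d_max_seen, 1e-12))
        else:
            gp_step = gp
        # fixed step size regardless of the sampling cadence, so a zero-dose
        # regimen reproduces the control trajectory bit-exactly; samples land
        # on the first step boundary at or past their nominal time
        step = min(dt, cfg.t_end - t)
        step = max(step, 1e-9)
        state = step_growth(
            state, {"A": A, "d": d}, gp_step, step,
            inhibition_variant=cfg.inhibition_variant,
        )
        t += step
        n_steps += 1

    # final sample at t_end
    n, m = state["n"], state["m"]
    cf = effective_conductivities(n, m, cfg.fluid)
    if cfg.solve_fluid:
        P = solve_ifp(m, cf, cfg.fluid, dirichlet(cfg.boundary_pressure))
    plasma_A = plasma_concentration(t * 24.0, aa_events, cfg.agent.t_half_A, cfg.halflife_ln2)
    plasma_d = plasma_concentration(t * 24.0, chemo_events, cfg.liposome.t_half_d, cfg.halflife_ln2)
    interior_d = _safe_masked_average(d, n, INTERIOR_THRESHOLD)
    id_now = interior_d if np.isfinite(interior_d) else 0.0
    if prev_sample_t is not None and t > prev_sample_t:
        cumulative_exposure += 0.5 * (id_now + prev_interior_d) * (t - prev_sample_t)
    extrav_rate = _safe_masked_average(extrav, n, INTERIOR_THRESHOLD)
    if np.isfinite(extrav_rate):
        extrav_rate *= plasma_d
    records.append(
        MetricRecord(
            t=t,
            radius=tumor_radius(n),
            avg_ifp=_safe_masked_average(P, n, TUMOR_THRESHOLD),
            avg_interior_density=_safe_masked_average(n, n, INTERIOR_THRESHOLD),
            avg_interior_m=_safe_masked_average(m, n, INTERIOR_THRESHOLD),
            avg_interior_extrav=extrav_rate,
            interior_mean_d=interior_d,
            cumulative_exposure=cumulative_exposure,
            plasma_A=plasma_A,
            plasma_d=plasma_d,
        )
    )
    snapshots[round(t, 6)] = {
        "n": n.copy(), "m": m.copy(), "P": P.copy(), "A": A.copy(), "d": d.copy()
    }
    log.info("run complete: %d growth steps, %d samples", n_steps, len(records))
    metrics = pd.DataFrame([r.as_dict() for r in records])
    return SimResult(
        config=cfg,
        grid=grid,
        metrics=metrics,
        snapshots=snapshots,
        final_state=state,
        t_final=t,
        d_max_seen=d_max_seen,
    )


def calibrate_aa_dose(
    cfg: SimConfig,
    initial_state: dict[str, ScalarField] | None = None,
    t_start: float = 0.0,
    target_mvd_reduction: float = 0.5,
    tol: float = 0.02,
    upper: float = 2.0,
    max_iter: int = 40,
) -> float:
    """Bisect the antiangiogenic peak until the tumor MVD drops by the target.

    The reduction is measured as 1 - mean(m over the tumor mask at the end of
    the administrations) / mean(m over the tumor mask at the first
    administration); each average uses the tumor mask (n > 0.1) of its own
    time point, so the measurement tracks the growing tumor rather than the
    initial footprint.  Returns the calibrated absolute peak.
    """
    if not cfg.regimen.aa_events:
        raise ValueError("regimen contains no antiangiogenic events")
    if target_mvd_reduction == 0:
        return 0.0
    if initial_state is None:
        initial_state = _initial_state(cfg, cfg.grid.build())
    nominal = cfg.regimen.aa_events[0].peak
    aa_days = [ev.day for ev in cfg.regimen.aa_events]
    t_first, t_last = min(aa_days), max(aa_days)
    t_admin_end = min(cfg.t_end, t_last)

    # advance once (drug-free, deterministic) to the first administration
    if t_first > t_start:
        pre_cfg = replace(cfg)
        pre_cfg.regimen = Regimen(label="custom")
        pre_cfg.t_end = t_first
        pre_cfg.snapshot_dt = 2 * cfg.t_end
        pre = run_simulation(pre_cfg, initial_state=initial_state, t_start=t_start)
        state0, t0 = pre.final_state, pre.t_final
    else:
        state0, t0 = initial_state, t_start
    mvd_before = masked_average(state0["m"], state0["n"], TUMOR_THRESHOLD)
    if mvd_before == 0:
        raise ValueError("baseline MVD is zero at the first administration")

    def reduction_at(scale: float) -> float:
        sub = replace(cfg)
        sub.regimen = cfg.regimen.scale_aa(scale)
        sub.t_end = t_admin_end
        sub.snapshot_dt = 2 * cfg.t_end
        res = run_simulation(sub, initial_state=state0, t_start=t0)
        mvd_after = masked_average(res.final_state["m"], res.final_state["n"], TUMOR_THRESHOLD)
        return 1.0 - mvd_after / mvd_before

    lo, red_lo = 0.0, 0.0
    hi = 1.0
    red_hi = reduction_at(hi)
    grow_iter = 0
    while red_hi < target_mvd_reduction and hi * nominal < upper:
        lo, red_lo = hi, red_hi
        hi = min(2.0 * hi, upper / nominal)
        red_hi = reduction_at(hi)
        grow_iter += 1
        if grow_iter > 20:
            break
    if red_hi < target_mvd_reduction - tol:
        raise ValueError(
            f"target MVD reduction {target_mvd_reduction:.2f} unreachable below peak "
            f"{upper:g}; achieved at most {red_hi:.3f}"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        red = reduction_at(mid)
        if red < red_lo - 5 * tol:
            log.warning("MVD reduction not monotone at scale %.4f", mid)
        if abs(red - target_mvd_reduction) <= tol:
            return mid * nominal
        if red < target_mvd_reduction:
            lo, red_lo = mid, red
        else:
            hi, red_hi = mid, red
    return 0.5 * (lo + hi) * nominal


def run_case_comparison(
    cfg: SimConfig,
    cases: tuple[str, ...] = ("case1", "case2", "case3", "case4"),
    treat_start: float = 19.0,
    aa_peak: float | None = None,
    chemo_peak: float = 0.05,
    taper_factor: float = 0.8,
) -> dict:
    """Grow a control tumor, calibrate the antiangiogenic doses and run cases.

    The control is grown (fluid solve off, for speed) to ``treat_start``;
    unless ``aa_peak`` is given, each case's antiangiogenic peak is
    calibrated on its own full regimen (concurrent chemotherapy included) to
    a 50% MVD reduction at the end of its administrations; every case then
    runs from the same grown state.  Returns a
    dict with the per-case :class:`SimResult` map (``results``), the grown
    state, the calibrated peaks and the control run.
    """
    pre_cfg = replace(cfg)
    pre_cfg.regimen = Regimen(label="custom")
    pre_cfg.t_end = treat_start
    pre_cfg.solve_fluid = False
    pre_cfg.snapshot_dt = 2 * cfg.t_end
    pre = run_simulation(pre_cfg)
    state = {"n": pre.final_state["n"], "m": pre.final_state["m"]}

    peaks: dict[str, float] = {}
    results: dict[str, SimResult] = {}
    for case in cases:
        regimen = build_regimen(
            case, aa_peak=aa_peak if aa_peak is not None else 0.05,
            chemo_peak=chemo_peak, taper_factor=taper_factor,
        )
        if regimen.aa_events and aa_peak is None:
            cal_cfg = replace(cfg)
            cal_cfg.regimen = regimen
            peak = calibrate_aa_dose(cal_cfg, initial_state=state, t_start=treat_start)
            log.info("calibrated antiangiogenic peak (%s): %.4f", case, peak)
        else:
            peak = aa_peak if aa_peak is not None else 0.0
        peaks[case] = peak
        case_cfg = replace(cfg)
        case_cfg.regimen = build_regimen(
            case, aa_peak=peak, chemo_peak=chemo_peak, taper_factor=taper_factor
        )
        results[case] = run_simulation(case_cfg, initial_state=state, t_start=treat_start)

    control_cfg = replace(cfg)
    control_cfg.regimen = Regimen(label="custom")
    control = run_simulation(control_cfg, initial_state=state, t_start=treat_start)
    return {
        "results": results,
        "control": control,
        "aa_peaks": peaks,
        "grown_state": state,
        "treat_start": treat_start,
    }


def calibrate_growth(
    cfg: SimConfig,
    target_radius: float = 1.35,
    target_day: float = 30.0,
    tol: float = 0.05,
    r_bounds: tuple[float, float] = (0.05, 3.0),
    max_iter: int = 30,
) -> float:
    """Bisect the logistic growth rate ``r`` to hit the day-30 control radius.

    Uses drug-free control runs with the fluid solve disabled (IFP does not
    feed back into growth).  Returns the calibrated ``r`` (1/day).
    """
    if cfg.regimen.events:
        raise ValueError("growth calibration requires a control (no-treatment) config")

    def radius_at(r: float) -> float:
        sub = replace(cfg)
        sub.growth = replace(cfg.growth, r=r)
        sub.t_end = target_day
        sub.solve_fluid = False
        sub.snapshot_dt = 2 * target_day
        res = run_simulation(sub)
        return res.final_radius

    lo, hi = r_bounds
    rad_lo, rad_hi = radius_at(lo), radius_at(hi)
    if abs(rad_lo - target_radius) <= tol:
        return lo
    if abs(rad_hi - target_radius) <= tol:
        return hi
    if not (rad_lo < target_radius < rad_hi):
        raise ValueError(
            f"target radius {target_radius} cm not bracketed by r in {r_bounds}: "
            f"radii ({rad_lo:.3f}, {rad_hi:.3f}) cm"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        rad = radius_at(mid)
        if abs(rad - target_radius) <= tol:
            return mid
        if rad < target_radius:
            lo, rad_lo = mid, rad
        else:
            hi, rad_hi = mid, rad
    raise ValueError(
        f"growth calibration did not converge to {target_radius} +/- {tol} cm; "
        f"best bracket r in ({lo:.4f}, {hi:.4f})"
    )
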