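"""Configuration parsing/validation, HDF5 snapshot store and test fixtures.

Config files are TOML (canonical) or YAML, with nested sections mirroring
:class:`~angionorm.treatment_scheduler.SimConfig`:

.. code-block:: toml

    seed = 7
    t_end = 30.0

    [grid]
    nx = 151
    ny = 151
    h = 0.02

    [growth]
    r = 0.65

    [regimen]
    label = "case3"
    aa_peak = 0.05

Unknown keys are rejected with an error listing them; derived transport
quantities (lambda_b, P_eff, sigma_d) are computed from the primary entries
and logged, never read from the file.
"""

from __future__ import annotations

import dataclasses
import logging
import tomllib
from pathlib import Path

import h5py
import numpy as np
import yaml

from .drug_transport import AgentParams, LiposomeParams
from .grid_core import Grid, ScalarField
from .growth_dynamics import GrowthParams
from .interstitial_fluid import FluidParams
from .treatment_scheduler import (
    GridSpec,
    Regimen,
    SimConfig,
    build_regimen,
    run_simulation,
)

__all__ = [
    "SCHEMA_VERSION",
    "load_config",
    "config_from_dict",
    "config_to_dict",
    "SnapshotStore",
    "make_fixture",
]

log = logging.getLogger(__name__)

SCHEMA_VERSION = 1

_SECTION_TYPES = {
    "grid": GridSpec,
    "growth": GrowthParams,
    "fluid": FluidParams,
    "agent": AgentParams,
    "liposome": LiposomeParams,
}

_REGIMEN_KEYS = {
    "label", "chemo_days", "aa_start_day", "aa_pulses", "aa_peak",
    "chemo_peak", "taper_factor",
}

_TOP_KEYS = {
    "seed", "t_end", "dt_max", "tumor_radius0", "tumor_peak",
    "vessel_relax_time", "island_scale", "pk_dt_dosing", "pk_dt_idle",
    "snapshot_dt", "inhibition_variant", "halflife_ln2", "boundary_mode",
    "solve_fluid",
}


def _build_section(cls, data: dict, section: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown keys in [{section}]: {sorted(unknown)}")
    if "origin" in data:
        data = {**data, "origin": tuple(data["origin"])}
    return cls(**data)


def config_from_dict(raw: dict) -> SimConfig:
    """Build and validate a :class:`SimConfig` from a nested plain dict."""
    raw = dict(raw)
    kwargs = {}
    for section, cls in _SECTION_TYPES.items():
        data = raw.pop(section, {})
        if not isinstance(data, dict):
            raise ValueError(f"section [{section}] must be a table")
        kwargs[section] = _build_section(cls, data, section)
    reg = raw.pop("regimen", None)
    if reg is not None:
        unknown = set(reg) - _REGIMEN_KEYS
        if unknown:
            raise ValueError(f"unknown keys in [regimen]: {sorted(unknown)}")
        reg = dict(reg)
        if "chemo_days" in reg:
            reg["chemo_days"] = tuple(reg["chemo_days"])
        kwargs["regimen"] = build_regimen(**reg)
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
    kwargs.update(raw)
    cfg = SimConfig(**kwargs)
    log.info(
        "config loaded: lambda_b tumor/normal = %.3e / %.3e 1/(mmHg s) [derived L_p*SV], "
        "P_eff tumor/normal = %.4f / %.2f mmHg [derived P_v - osm], "
        "sigma_d = %.4f [derived pore formula]; growth constants carry external provenance",
        cfg.fluid.lambda_b_tumor,
        cfg.fluid.lambda_b_normal,
        cfg.fluid.p_eff_tumor,
        cfg.fluid.p_eff_normal,
        cfg.liposome.sigma_d,
    )
    return cfg


def config_to_dict(cfg: SimConfig) -> dict:
    """Inverse of :func:`config_from_dict` (regimen dumped as explicit fields)."""
    out: dict = {}
    for section, cls in _SECTION_TYPES.items():
        obj = getattr(cfg, section)
        d = dataclasses.asdict(obj)
        if "origin" in d:
            d["origin"] = list(d["origin"])
        out[section] = d
    reg = cfg.regimen
    aa = reg.aa_events
    out["regimen"] = {
        "label": reg.label,
        "chemo_days": [ev.day for ev in reg.chemo_events],
        "taper_factor": reg.taper_factor,
        "aa_start_day": aa[0].day if aa else None,
        "aa_pulses": len(aa),
        "aa_peak": aa[0].peak if aa else 0.0,
        "chemo_peak": reg.chemo_events[0].peak if reg.chemo_events else 1.0,
    }
    if not aa:
        out["regimen"].pop("aa_start_day")
    for key in _TOP_KEYS:
        out[key] = getattr(cfg, key)
    return out


def load_config(path: str | Path) -> SimConfig:
    """Load a TOML or YAML configuration file; missing keys take defaults."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        raw = yaml.safe_load(text) or {}
    else:
        raw = tomllib.loads(text)
    return config_from_dict(raw)


class SnapshotStore:
    """HDF5 store of time-stamped field snapshots.

    Layout: one group per time point under ``/snapshots/t=<day>`` holding one
    dataset per field with ``unit``, ``h`` and ``origin`` attributes; float64
    payloads round-trip bit-exactly.
    """

    def __init__(self, path: str | Path, mode: str = "r"):
        self.path = Path(path)
        self._file = h5py.File(self.path, mode)
        if mode in ("w", "w-", "x"):
            self._file.attrs["schema_version"] = SCHEMA_VERSION
        else:
            version = int(self._file.attrs.get("schema_version", -1))
            if version != SCHEMA_VERSION:
                raise ValueError(
                    f"snapshot schema version {version} != supported {SCHEMA_VERSION}"
                )

    def __enter__(self) -> "SnapshotStore":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    def close(self) -> None:
        self._file.close()

    @staticmethod
    def _group_name(t: float) -> str:
        return f"snapshots/t={t:.6f}"

    def write_fields(self, t: float, fields: dict[str, ScalarField]) -> None:
        grp = self._file.require_group(self._group_name(t))
        for name, f in fields.items():
            if name in grp:
                del grp[name]
            ds = grp.create_dataset(name, data=f.values)
            ds.attrs["unit"] = f.unit
            ds.attrs["h"] = f.grid.h
            ds.attrs["origin"] = list(f.grid.origin)

    def times(self) -> list[float]:
        if "snapshots" not in self._file:
            return []
        return sorted(float(k.split("=")[1]) for k in self._file["snapshots"])

    def read_fields(self, t: float) -> dict[str, ScalarField]:
        grp = self._file[self._group_name(t)]
        out = {}
        for name, ds in grp.items():
            values = ds[()]
            ny, nx = values.shape
            grid = Grid(nx, ny, float(ds.attrs["h"]), tuple(ds.attrs["origin"]))
            out[name] = ScalarField(grid, values, str(ds.attrs["unit"]))
        return out

    def export_csv(self, t: float, name: str, path: str | Path) -> None:
        """Write one field as a tidy (x, y, value) CSV for plotting."""
        f = self.read_fields(t)[name]
        X, Y = f.grid.coords()
        data = np.column_stack([X.ravel(), Y.ravel(), f.values.ravel()])
        np.savetxt(path, data, delimiter=",", header="x,y,value", comments="")


_FIXTURE_KINDS = ("uniform_vessels", "disc_tumor", "grown_tumor_small")


def make_fixture(kind: str, seed: int = 0) -> tuple[SimConfig, dict[str, ScalarField]]:
    """Deterministic test scaffolding: config plus initial fields.

    * ``uniform_vessels`` — m = 1 everywhere with n = 1 so lymphatics are
      suppressed (IFP constant-solution checks: with a Dirichlet boundary at
      P_eff the constant P_eff solves the equation exactly);
    * ``disc_tumor`` — indicator tumor with uniform leaky vessels inside a
      0.5 cm disc (radial-oracle comparisons);
    * ``grown_tumor_small`` — a 65x65 state grown quickly to day 19 for
      scheduler tests (odd node counts put a node at the domain center,
      which the 0.2 mm Gaussian seed needs to be resolved).
    """
    if kind not in _FIXTURE_KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}; choose from {_FIXTURE_KINDS}")
    if kind == "uniform_vessels":
        cfg = config_from_dict({"grid": {"nx": 41, "ny": 41, "h": 0.05}, "seed": seed})
        grid = cfg.grid.build()
        return cfg, {
            "n": ScalarField.full(grid, 1.0),
            "m": ScalarField.full(grid, 1.0),
        }
    if kind == "disc_tumor":
        cfg = config_from_dict({"grid": {"nx": 121, "ny": 121, "h": 0.01}, "seed": seed})
        grid = cfg.grid.build()
        R = 0.5
        r = grid.radius_from_center()
        inside = (r <= R).astype(float)
        return cfg, {
            "n": ScalarField(grid, inside.copy()),
            # m = 1.5 inside the disc: fully on the leaky branch of the ramp
            "m": ScalarField(grid, 1.0 + 0.5 * inside),
        }
    # grown_tumor_small: fast-grown 65x65 state for scheduler tests
    cfg = config_from_dict(
        {
            "grid": {"nx": 65, "ny": 65, "h": 3.0 / 64},
            "seed": seed,
            "t_end": 19.0,
            "snapshot_dt": 100.0,
            "pk_dt_idle": 0.5,
        }
    )
    res = run_simulation(cfg)
    state = res.final_state
    return cfg, {"n": state["n"], "m": state["m"]}
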