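"""CSV and YAML interchange.

CSV (comma, UTF-8, header row) is the single tabular format: trajectories
as ``t,Y1,Y2`` with a companion ``*.meta.csv`` carrying
``death_time,terminated_by_death,horizon``; measured series as
``t,Z1,Z2`` (the same layout accepts real observed data); reference
tables as ``c1,c3,tau,<summary names...>,death_time,flags``.  Times are
integer days everywhere; fractional times are rejected on read.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibration import DEFAULT_LEVELS, CalibrationConfig
from .measurement import MeasuredSeries, MeasurementModel
from .model import PARAM_NAMES, PriorSpec, SimulationSettings, Trajectory
from .summaries import FULL_NAMES, set_names
from .abc import ReferenceTable

__all__ = [
    "write_trajectory",
    "read_trajectory",
    "write_series",
    "read_series",
    "write_reference_table",
    "read_reference_table",
    "load_config",
    "dump_config",
    "RunConfig",
]


def _meta_path(path) -> Path:
    p = Path(path)
    return p.with_suffix(p.suffix + ".meta.csv")


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


def _int_times(values, path) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if np.any(arr != np.floor(arr)):
        bad = int(np.argmax(arr != np.floor(arr)))
        raise ValueError(
            f"{path}: times must be integer days (row {bad + 1}: t={arr[bad]})"
        )
    return arr.astype(np.int64)


def write_trajectory(traj: Trajectory, path) -> None:
    pd.DataFrame({"t": traj.t, "Y1": traj.y1, "Y2": traj.y2}).to_csv(
        path, index=False
    )
    meta = pd.DataFrame(
        {
            "death_time": [np.nan if traj.death_time is None else traj.death_time],
            "terminated_by_death": [traj.terminated_by_death],
            "horizon": [traj.horizon],
        }
    )
    meta.to_csv(_meta_path(path), index=False)


def read_trajectory(path) -> Trajectory:
    df = pd.read_csv(path)
    _require_columns(df, ("t", "Y1", "Y2"), path)
    t = _int_times(df["t"], path)
    death_time = None
    horizon = int(t[-1]) if len(t) else 0
    mp = _meta_path(path)
    if mp.exists():
        meta = pd.read_csv(mp)
        _require_columns(meta, ("death_time", "terminated_by_death", "horizon"), mp)
        horizon = int(meta["horizon"].iloc[0])
        if bool(meta["terminated_by_death"].iloc[0]):
            death_time = int(meta["death_time"].iloc[0])
    return Trajectory(
        t=t,
        y1=df["Y1"].to_numpy(np.int64),
        y2=df["Y2"].to_numpy(np.int64),
        death_time=death_time,
        horizon=horizon,
    )


def write_series(series: MeasuredSeries, path) -> None:
    pd.DataFrame({"t": series.t, "Z1": series.z1, "Z2": series.z2}).to_csv(
        path, index=False
    )
    meta = pd.DataFrame(
        {
            "death_time": [
                np.nan if series.death_time is None else series.death_time
            ],
            "terminated_by_death": [series.death_time is not None],
            "horizon": [series.horizon],
        }
    )
    meta.to_csv(_meta_path(path), index=False)


def read_series(path, horizon: int | None = None) -> MeasuredSeries:
    df = pd.read_csv(path)
    _require_columns(df, ("t", "Z1", "Z2"), path)
    t = _int_times(df["t"], path)
    death_time = None
    h = horizon if horizon is not None else (int(t[-1]) if len(t) else 0)
    mp = _meta_path(path)
    if mp.exists():
        meta = pd.read_csv(mp)
        h = int(meta["horizon"].iloc[0])
        if bool(meta["terminated_by_death"].iloc[0]):
            death_time = int(meta["death_time"].iloc[0])
    return MeasuredSeries(
        t=t,
        z1=df["Z1"].to_numpy(np.int64),
        z2=df["Z2"].to_numpy(np.int64),
        death_time=death_time,
        horizon=h,
    )


def write_reference_table(table: ReferenceTable, path) -> None:
    table.to_frame().to_csv(path, index=False)


def read_reference_table(path, prior: PriorSpec | None = None) -> ReferenceTable:
    df = pd.read_csv(path)
    _require_columns(df, PARAM_NAMES, path)
    known = {1: set_names(1), 2: set_names(2), 3: set_names(3), None: FULL_NAMES}
    names = None
    set_id = None
    for sid, cand in sorted(
        known.items(), key=lambda kv: -len(kv[1])
    ):
        if all(c in df.columns for c in cand):
            names, set_id = cand, sid
            break
    if names is None:
        raise ValueError(f"{path}: no recognisable summary columns")
    return ReferenceTable(
        theta=df[list(PARAM_NAMES)].to_numpy(float),
        summaries=df[list(names)].to_numpy(float),
        names=names,
        set_id=set_id,
        flags=df["flags"].to_numpy(np.int64) if "flags" in df else None,
        death_time=df["death_time"].to_numpy(float) if "death_time" in df else None,
        prior=prior or PriorSpec(),
    )


class RunConfig:
    """Structured configuration tying the pipeline blocks together."""

    def __init__(
        self,
        prior: PriorSpec,
        sim: SimulationSettings,
        measurement: MeasurementModel,
        calibration: CalibrationConfig,
        accept_fraction: float = 0.10,
        adjust: bool = False,
        transform: bool = True,
        ridge_lambda: float = 1e-3,
        seed: int | None = None,
    ) -> None:
        self.prior = prior
        self.sim = sim
        self.measurement = measurement
        self.calibration = calibration
        self.accept_fraction = accept_fraction
        self.adjust = adjust
        self.transform = transform
        self.ridge_lambda = ridge_lambda
        self.seed = seed

    def __eq__(self, other) -> bool:
        return isinstance(other, RunConfig) and dump_dict(self) == dump_dict(other)


def load_config(path_or_dict) -> RunConfig:
    """Build a RunConfig from a YAML file (or an already-parsed dict)."""
    if isinstance(path_or_dict, dict):
        raw = path_or_dict
    else:
        with open(path_or_dict) as fh:
            raw = yaml.safe_load(fh) or {}
    pr = raw.get("prior", {})
    prior = PriorSpec(
        c1=tuple(pr.get("c1", (1e-6, 1e-3))),
        c3=tuple(pr.get("c3", (3e-5, 1e-3))),
        tau=tuple(pr.get("tau", (0.5, 1.0))),
    )
    ini = raw.get("init", {})
    simblk = raw.get("simulate", {})
    sim = SimulationSettings(
        y1_0=int(ini.get("y1", 400)),
        y2_0=int(ini.get("y2", 600)),
        horizon=int(simblk.get("horizon_days", 36_500)),
        engine=simblk.get("engine", "daily"),
    )
    ms = raw.get("measure", {})
    schedule = ms.get("schedule", "daily")
    if schedule != "daily":
        schedule = int(schedule)
    measurement = MeasurementModel(
        n_observed=int(ms.get("n_observed", 300)),
        sigma_log10=float(ms.get("sigma_log10", 0.20)),
        schedule=schedule,
        noise_on=ms.get("noise_on", "counts"),
    )
    ab = raw.get("abc", {})
    cal = raw.get("calibration", {})
    calibration = CalibrationConfig(
        n_rep=int(cal.get("n_rep", 1000)),
        n_sim=int(cal.get("n_sim", 1000)),
        accept_fraction=float(ab.get("accept_fraction", 0.10)),
        levels=tuple(cal.get("levels", DEFAULT_LEVELS)),
        set_ids=tuple(cal.get("set_ids", (1, 2, 3))),
        adjust=bool(ab.get("adjust", False)),
        transform=bool(ab.get("transform", True)),
        ridge_lambda=float(ab.get("ridge_lambda", 1e-3)),
        prior=prior,
        sim=sim,
        measurement=measurement,
    )
    return RunConfig(
        prior=prior,
        sim=sim,
        measurement=measurement,
        calibration=calibration,
        accept_fraction=calibration.accept_fraction,
        adjust=calibration.adjust,
        transform=calibration.transform,
        ridge_lambda=calibration.ridge_lambda,
        seed=simblk.get("seed"),
    )


def dump_dict(config: RunConfig) -> dict:
    return {
        "prior": {
            "c1": list(config.prior.c1),
            "c3": list(config.prior.c3),
            "tau": list(config.prior.tau),
        },
        "init": {"y1": config.sim.y1_0, "y2": config.sim.y2_0},
        "simulate": {
            "horizon_days": config.sim.horizon,
            "engine": config.sim.engine,
            "seed": config.seed,
        },
        "measure": {
            "n_observed": config.measurement.n_observed,
            "sigma_log10": config.measurement.sigma_log10,
            "schedule": config.measurement.schedule,
            "noise_on": config.measurement.noise_on,
        },
        "abc": {
            "accept_fraction": config.accept_fraction,
            "adjust": config.adjust,
            "transform": config.transform,
            "ridge_lambda": config.ridge_lambda,
        },
        "calibration": {
            "n_rep": config.calibration.n_rep,
            "n_sim": config.calibration.n_sim,
            "levels": list(config.calibration.levels),
            "set_ids": list(config.calibration.set_ids),
        },
    }


def dump_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dump_dict(config), fh, sort_keys=False)
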