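"""Bundled synthetic fixtures generated by the package itself.

The source study's patient data is not public, so small synthetic stand-ins
are produced deterministically from a seed: a sparse 13-point measured
series from a known theta, a 200-row reference table per candidate set,
and a small calibration config.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .abc import build_reference_table
from .calibration import CalibrationConfig
from .io import RunConfig, dump_config, write_reference_table, write_series
from .measurement import MeasurementModel, observe
from .model import PriorSpec, SimulationSettings, ThetaParams, simulate

__all__ = ["make_fixtures", "FIXTURE_THETA"]

#: known parameters behind the fixture series (mid-prior, death in ~2 years)
FIXTURE_THETA = ThetaParams(c1=5e-4, c3=5e-4, tau=0.8)


def make_fixtures(seed: int, outdir) -> dict[str, Path]:
    """Write the fixture bundle; regeneration with the same seed is idempotent."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    rng_series, rng_table = (np.random.default_rng(c) for c in ss.spawn(2))
    paths: dict[str, Path] = {}

    sim = SimulationSettings()
    traj = simulate(FIXTURE_THETA, sim, rng_series)
    series = observe(traj, MeasurementModel(schedule=13), rng_series)
    p = outdir / "observed_series_synthetic.csv"
    write_series(series, p)
    paths["series"] = p

    prior = PriorSpec()
    table = build_reference_table(prior, 200, rng_table, sim, MeasurementModel())
    for set_id in (1, 2, 3):
        p = outdir / f"reference_table_set{set_id}_synthetic.csv"
        write_reference_table(table.select_set(set_id), p)
        paths[f"table_set{set_id}"] = p

    cfg = RunConfig(
        prior=prior,
        sim=sim,
        measurement=MeasurementModel(),
        calibration=CalibrationConfig(n_rep=20, n_sim=100, prior=prior, sim=sim),
        seed=seed,
    )
    p = outdir / "coverage_config_small.yaml"
    dump_config(cfg, p)
    paths["config"] = p
    return paths
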