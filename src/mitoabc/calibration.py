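"""Coverage calibration of the ABC posterior and summary-set selection.

The auxiliary simulation procedure repeats, ``n_rep`` times:

A. draw ``n_sim`` parameter vectors from the prior, simulate and
   summarise each (a fresh reference table per replication);
B. draw one further "true" theta from the prior, simulate and observe it
   once as pseudo-observed data, and run rejection ABC (optionally with
   ridge adjustment) against the table;
C. record the posterior-mean estimate and whether the true theta falls in
   the equal-tailed posterior intervals at nine nominal levels
   (95, 90, 80, 60, 50, 40, 20, 10, 5 %).

Two figures of merit are computed per parameter:

* ``RMSE_1``: RMS over the nine levels of (observed coverage - nominal),
  where observed coverage aggregates the containment indicators across
  replications;
* ``RMSE_2``: RMS of (posterior mean - true theta) across replications.

Candidate summary sets are compared by "majority rule": the set with the
smallest RMSE_1 and/or RMSE_2 for the most parameters wins; ties are
reported, never silently broken.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .abc import RejectionABC, build_reference_table
from .measurement import MeasurementModel, observe
from .model import (
    PARAM_NAMES,
    PriorSpec,
    SimulationSettings,
    ThetaParams,
    simulate,
)
from .summaries import SET_COLUMNS, all_summaries

__all__ = [
    "DEFAULT_LEVELS",
    "CalibrationConfig",
    "ReplicationRecord",
    "CoverageReport",
    "run_replication",
    "run_coverage_study",
    "observed_coverage",
    "rmse1",
    "rmse2",
    "select_summary_set",
    "SelectionResult",
    "repeat_and_rank",
    "RankStability",
]

logger = logging.getLogger(__name__)

DEFAULT_LEVELS = (0.95, 0.90, 0.80, 0.60, 0.50, 0.40, 0.20, 0.10, 0.05)


@dataclass(frozen=True)
class CalibrationConfig:
    """Settings of one coverage-calibration study."""

    n_rep: int = 1000
    n_sim: int = 1000
    accept_fraction: float = 0.10
    levels: tuple[float, ...] = DEFAULT_LEVELS
    set_ids: tuple[int, ...] = (1, 2, 3)
    adjust: bool = False
    transform: bool = True
    ridge_lambda: float = 1e-3
    prior: PriorSpec = field(default_factory=PriorSpec)
    sim: SimulationSettings = field(default_factory=SimulationSettings)
    measurement: MeasurementModel = field(default_factory=MeasurementModel)
    max_redraw_factor: int = 5

    def __post_init__(self) -> None:
        if self.n_rep < 1 or self.n_sim < 10:
            raise ValueError("need n_rep >= 1 and n_sim >= 10")
        if not (0 < self.accept_fraction <= 1):
            raise ValueError("accept_fraction must be in (0, 1]")
        lv = np.asarray(self.levels)
        if np.any(lv <= 0) or np.any(lv >= 1) or np.any(np.diff(lv) >= 0):
            raise ValueError("levels must be strictly decreasing, each in (0, 1)")
        for s in self.set_ids:
            if s not in SET_COLUMNS:
                raise ValueError(f"unknown summary set {s}")


@dataclass
class ReplicationRecord:
    """One replication: truth, per-set estimates and containment flags."""

    theta_true: np.ndarray
    theta_hat: dict[int, np.ndarray]  # set_id -> (3,)
    contained: dict[int, np.ndarray]  # set_id -> (n_levels, 3) bool
    n_accepted: int


def _pseudo_observed(config: CalibrationConfig, rng: np.random.Generator):
    theta_true = config.prior.sample_array(1, rng)[0]
    traj = simulate(ThetaParams(*theta_true), config.sim, rng)
    series = observe(traj, config.measurement, rng)
    s_full, _ = all_summaries(series, config.sim.horizon)
    return theta_true, s_full


def run_replication(
    config: CalibrationConfig, rng: np.random.Generator
) -> ReplicationRecord:
    """Steps A-C once: fresh reference table, pseudo-observed data, ABC."""
    table = build_reference_table(
        config.prior, config.n_sim, rng, config.sim, config.measurement
    )
    theta_true, s_full = _pseudo_observed(config, rng)
    levels = np.asarray(config.levels)
    theta_hat: dict[int, np.ndarray] = {}
    contained: dict[int, np.ndarray] = {}
    n_accepted = 0
    for set_id in config.set_ids:
        cols = list(SET_COLUMNS[set_id])
        sub = table.select_set(set_id)
        res = RejectionABC(sub, s_full[cols]).fit(
            accept_fraction=config.accept_fraction,
            adjust=config.adjust,
            transform=config.transform,
            ridge_lambda=config.ridge_lambda,
        )
        n_accepted = res.n_accepted
        theta_hat[set_id] = res.params
        ind = np.empty((len(levels), 3), dtype=bool)
        for i, lv in enumerate(levels):
            if res.n_accepted >= 2:
                ci = res.conf_int(lv)
            else:  # single accepted draw: degenerate point interval
                v = res._draws(None)[0]
                ci = np.column_stack([v, v])
                logger.warning("single accepted draw; degenerate intervals")
            ind[i] = (theta_true >= ci[:, 0]) & (theta_true <= ci[:, 1])
        contained[set_id] = ind
    return ReplicationRecord(theta_true, theta_hat, contained, n_accepted)


@dataclass
class CoverageReport:
    """Aggregated calibration results for one candidate summary set."""

    set_id: int
    adjusted: bool
    levels: np.ndarray
    theta_true: np.ndarray  # (n_rep, 3)
    theta_hat: np.ndarray  # (n_rep, 3)
    contained: np.ndarray  # (n_rep, n_levels, 3) bool
    prior: PriorSpec
    seed: int | None = None
    n_redrawn: int = 0

    @property
    def n_rep(self) -> int:
        return len(self.theta_true)

    def coverage(self) -> np.ndarray:
        """Observed coverage per (level, parameter), shape (n_levels, 3)."""
        return self.contained.mean(axis=0)

    def rmse1(self, per_indicator: bool = False) -> np.ndarray:
        """Coverage-calibration RMSE per parameter.

        Default: RMS over the nine levels of (aggregated observed coverage
        minus nominal).  ``per_indicator=True`` instead averages squared
        deviations of the binary containment indicators, a variant kept
        for comparison.
        """
        nominal = self.levels[None, :, None]
        if per_indicator:
            dev2 = (self.contained.astype(float) - nominal) ** 2
            return np.sqrt(dev2.mean(axis=(0, 1)))
        cov = self.coverage()
        return np.sqrt(((cov - self.levels[:, None]) ** 2).mean(axis=0))

    def rmse2(self, scale: str = "natural") -> np.ndarray:
        """Estimation RMSE of the posterior mean per parameter.

        ``scale``: 'natural' (default), 'log10' (log10 errors for the
        rates c1/c3, natural for tau), or 'range' (errors divided by the
        prior range width).
        """
        err = self.theta_hat - self.theta_true
        if scale == "natural":
            pass
        elif scale == "log10":
            err = err.copy()
            for j in (0, 1):
                err[:, j] = np.log10(self.theta_hat[:, j]) - np.log10(
                    self.theta_true[:, j]
                )
        elif scale == "range":
            width = self.prior.bounds[:, 1] - self.prior.bounds[:, 0]
            err = err / width
        else:
            raise ValueError("scale must be 'natural', 'log10' or 'range'")
        return np.sqrt((err**2).mean(axis=0))

    def coverage_frame(self) -> pd.DataFrame:
        cov = self.coverage()
        rows = []
        for i, lv in enumerate(self.levels):
            for j, p in enumerate(PARAM_NAMES):
                rows.append(
                    {
                        "set_id": self.set_id,
                        "param": p,
                        "level": lv,
                        "observed": cov[i, j],
                    }
                )
        return pd.DataFrame(rows)

    def metrics(self) -> dict:
        return {
            "set_id": self.set_id,
            "adjusted": self.adjusted,
            "n_rep": self.n_rep,
            "n_redrawn": self.n_redrawn,
            "seed": self.seed,
            "rmse1": dict(zip(PARAM_NAMES, self.rmse1().tolist())),
            "rmse2": dict(zip(PARAM_NAMES, self.rmse2().tolist())),
            "rmse2_log10": dict(zip(PARAM_NAMES, self.rmse2("log10").tolist())),
            "rmse2_range": dict(zip(PARAM_NAMES, self.rmse2("range").tolist())),
        }

    def save_metrics(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.metrics(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    def summary(self) -> str:
        m = self.metrics()
        lines = [
            f"Coverage calibration, summary set {self.set_id} "
            f"({'ridge-adjusted' if self.adjusted else 'unadjusted'}), "
            f"n_rep={self.n_rep}",
            "RMSE_1 (coverage): "
            + ", ".join(f"{p}={v:.4g}" for p, v in m["rmse1"].items()),
            "RMSE_2 (natural):  "
            + ", ".join(f"{p}={v:.4g}" for p, v in m["rmse2"].items()),
        ]
        return "\n".join(lines)


def observed_coverage(report: CoverageReport, level: float) -> np.ndarray:
    """Observed per-parameter coverage at one nominal level."""
    i = int(np.argmin(np.abs(report.levels - level)))
    if not np.isclose(report.levels[i], level):
        raise ValueError(f"level {level} not in report levels {report.levels}")
    return report.coverage()[i]


def rmse1(report: CoverageReport, per_indicator: bool = False) -> np.ndarray:
    return report.rmse1(per_indicator)


def rmse2(report: CoverageReport, scale: str = "natural") -> np.ndarray:
    return report.rmse2(scale)


def run_coverage_study(
    config: CalibrationConfig, seed: int | None = None
) -> dict[int, CoverageReport]:
    """Run the full n_rep-replication study; one report per summary set.

    Replications use independent substreams spawned from ``seed``, so the
    study is deterministic given (config, seed) and replications are
    order-independent.  A replication that raises is re-drawn with the
    next substream; the event is counted in ``n_redrawn``.
    """
    ss = np.random.SeedSequence(seed)
    n_levels = len(config.levels)
    truth = np.empty((config.n_rep, 3))
    hats = {s: np.empty((config.n_rep, 3)) for s in config.set_ids}
    inds = {
        s: np.empty((config.n_rep, n_levels, 3), dtype=bool) for s in config.set_ids
    }
    n_redrawn = 0
    max_draws = config.max_redraw_factor * config.n_rep
    children = iter(ss.spawn(max_draws))
    done = 0
    while done < config.n_rep:
        child = next(children)
        try:
            rec = run_replication(config, np.random.default_rng(child))
        except Exception:  # noqa: BLE001 - re-drawn and counted
            n_redrawn += 1
            logger.exception("replication failed; re-drawing with next substream")
            if n_redrawn > max_draws - config.n_rep:
                raise
            continue
        truth[done] = rec.theta_true
        for s in config.set_ids:
            hats[s][done] = rec.theta_hat[s]
            inds[s][done] = rec.contained[s]
        done += 1
        if done % 50 == 0:
            logger.info("calibration: %d/%d replications", done, config.n_rep)
    if n_redrawn:
        logger.warning("calibration: %d replications re-drawn", n_redrawn)
    return {
        s: CoverageReport(
            set_id=s,
            adjusted=config.adjust,
            levels=np.asarray(config.levels),
            theta_true=truth,
            theta_hat=hats[s],
            contained=inds[s],
            prior=config.prior,
            seed=seed,
            n_redrawn=n_redrawn,
        )
        for s in config.set_ids
    }


@dataclass
class SelectionResult:
    """Majority-rule comparison of candidate summary sets."""

    cells: pd.DataFrame  # param x criterion -> winning set(s)
    scores: dict[int, int]
    chosen: int | None
    tied_sets: tuple[int, ...]
    screened_out: tuple[int, ...] = ()

    def summary(self) -> str:
        lines = [self.cells.to_string(index=False)]
        lines.append(
            "scores: " + ", ".join(f"set {s}: {v}" for s, v in self.scores.items())
        )
        if self.chosen is not None:
            lines.append(f"chosen set: {self.chosen}")
        else:
            lines.append(f"tie between sets {self.tied_sets}; no unique winner")
        if self.screened_out:
            lines.append(f"screened out (poor calibration): {self.screened_out}")
        return "\n".join(lines)


def select_summary_set(
    reports: dict[int, CoverageReport] | dict[int, dict],
    rmse1_screen: float | None = None,
) -> SelectionResult:
    """Majority rule over (parameter x {RMSE_1, RMSE_2}) cells.

    A set wins a cell when it attains the smallest value there (ties count
    for every tied set).  Sets failing the optional calibration screen
    (max RMSE_1 over parameters above ``rmse1_screen``) are excluded
    first.  The chosen set is the one winning the most cells; a tie at
    the top is reported, not broken.
    """
    if len(reports) < 2:
        raise ValueError("need at least 2 candidate sets to compare")
    metrics = {}
    for s, rep in reports.items():
        m = rep.metrics() if isinstance(rep, CoverageReport) else rep
        metrics[s] = {
            "rmse1": np.array([m["rmse1"][p] for p in PARAM_NAMES]),
            "rmse2": np.array([m["rmse2"][p] for p in PARAM_NAMES]),
        }
    screened = []
    eligible = list(metrics)
    if rmse1_screen is not None:
        eligible = [s for s in metrics if metrics[s]["rmse1"].max() <= rmse1_screen]
        screened = [s for s in metrics if s not in eligible]
        if not eligible:
            eligible = list(metrics)
            screened = []
    rows = []
    scores = {s: 0 for s in eligible}
    for crit in ("rmse1", "rmse2"):
        for j, p in enumerate(PARAM_NAMES):
            vals = {s: metrics[s][crit][j] for s in eligible}
            best = min(vals.values())
            winners = tuple(s for s, v in vals.items() if np.isclose(v, best))
            for s in winners:
                scores[s] += 1
            rows.append(
                {
                    "criterion": crit,
                    "param": p,
                    **{f"set{s}": vals[s] for s in eligible},
                    "winners": winners,
                }
            )
    top = max(scores.values())
    tied = tuple(s for s, v in scores.items() if v == top)
    return SelectionResult(
        cells=pd.DataFrame(rows),
        scores=scores,
        chosen=tied[0] if len(tied) == 1 else None,
        tied_sets=tied,
        screened_out=tuple(screened),
    )


@dataclass
class RankStability:
    """Win distribution across outer repetitions of the whole study."""

    winners: list[tuple[int, ...]]
    win_fraction: dict[int, float]
    best: int | None
    threshold: float
    underpowered: bool

    def summary(self) -> str:
        lines = [
            "win fraction (RMSE_1 majority rule): "
            + ", ".join(f"set {s}: {f:.2f}" for s, f in self.win_fraction.items())
        ]
        if self.best is not None:
            lines.append(
                f"set {self.best} wins > {self.threshold:.0%} of repetitions"
            )
        else:
            lines.append("no set wins a majority of repetitions")
        if self.underpowered:
            lines.append("WARNING: too few outer repetitions for a stable ranking")
        return "\n".join(lines)


def repeat_and_rank(
    config: CalibrationConfig,
    n_outer: int,
    seed: int | None = None,
    win_threshold: float = 0.5,
) -> RankStability:
    """Repeat the whole study n_outer times; rank sets by RMSE_1.

    Per repetition the sets are compared by majority rule restricted to
    the RMSE_1 cells; a set is declared significantly better when it is
    the sole winner in more than ``win_threshold`` of the repetitions.
    """
    if n_outer < 2:
        raise ValueError("need n_outer >= 2")
    ss = np.random.SeedSequence(seed)
    outer_seeds = [int(c.generate_state(1)[0] & 0x7FFFFFFF) for c in ss.spawn(n_outer)]
    winners: list[tuple[int, ...]] = []
    counts = {s: 0 for s in config.set_ids}
    for sd in outer_seeds:
        reports = run_coverage_study(config, sd)
        r1 = {s: reports[s].rmse1() for s in config.set_ids}
        scores = {s: 0 for s in config.set_ids}
        for j in range(3):
            best = min(v[j] for v in r1.values())
            for s, v in r1.items():
                if np.isclose(v[j], best):
                    scores[s] += 1
        top = max(scores.values())
        tied = tuple(s for s, v in scores.items() if v == top)
        winners.append(tied)
        if len(tied) == 1:
            counts[tied[0]] += 1
    frac = {s: counts[s] / n_outer for s in config.set_ids}
    best = next((s for s, f in frac.items() if f > win_threshold), None)
    return RankStability(
        winners=winners,
        win_fraction=frac,
        best=best,
        threshold=win_threshold,
        underpowered=n_outer < 10,
    )
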