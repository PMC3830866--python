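"""Observation model: subsampling and multiplicative log10-scale noise.

Mimics a measurement process in which only ``n_observed`` of the cell's
mtDNA copies are inspected at each scheduled day (a hypergeometric draw
without replacement, splitting the draw into healthy/mutant subcounts
S1, S2) and the counts are then measured with a relative error of SD
``sigma_log10`` on the log10 scale.

Two readings of where that error acts are supported:

* ``noise_on="counts"`` (default): each subcount is measured with its own
  independent multiplicative error, ``Z_i = round(S_i * 10**eps_i)``.
  The measured counts then carry separate information about healthy and
  mutant dynamics, as required for the count-change regressions (with a
  shared error the two predictors Z and Z/(Z1+Z2) are exactly collinear).
* ``noise_on="fraction"``: the healthy *fraction* S1/(S1+S2) is perturbed
  by a single ``10**eps`` factor, clipped to (0, 1], and re-integerised
  so that ``Z1 + Z2`` equals the draw size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .model import Trajectory

__all__ = [
    "MeasurementModel",
    "MeasuredSeries",
    "subsample_cells",
    "add_fraction_noise",
    "observe",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MeasurementModel:
    """Observation settings.

    Parameters
    ----------
    n_observed : int
        Copies inspected per time point (default 300 of the ~1000 present).
    sigma_log10 : float
        SD of the additive Gaussian error on log10(healthy fraction);
        0 disables the noise.
    schedule : str | int
        ``"daily"`` measures every observable day; an integer k draws k
        distinct days uniformly at random over the run (default when the
        sparse design of the source data is wanted: k = 13).
    noise_on : str
        ``"counts"`` (independent error per measured count, default) or
        ``"fraction"`` (single error on the shared healthy fraction).
    """

    n_observed: int = 300
    sigma_log10: float = 0.20
    schedule: str | int = "daily"
    noise_on: str = "counts"

    def __post_init__(self) -> None:
        if self.n_observed <= 0:
            raise ValueError("n_observed must be positive")
        if self.sigma_log10 < 0:
            raise ValueError("sigma_log10 must be >= 0")
        if self.noise_on not in ("counts", "fraction"):
            raise ValueError("noise_on must be 'counts' or 'fraction'")
        if isinstance(self.schedule, str):
            if self.schedule != "daily":
                raise ValueError(f"unknown schedule {self.schedule!r}")
        elif int(self.schedule) < 2:
            raise ValueError("random schedules need k >= 2 times")


@dataclass
class MeasuredSeries:
    """Noisy, possibly sparsely sampled series of measured counts.

    ``death_time`` carries the generating run's death day (None when the
    run was censored at ``horizon``); summary statistics need it for the
    steps-to-death component.
    """

    t: np.ndarray
    z1: np.ndarray
    z2: np.ndarray
    death_time: int | None = None
    horizon: int = 36_500
    noisy: bool = True
    subsampled: bool = True
    truncated_schedule: bool = False

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=np.int64)
        self.z1 = np.asarray(self.z1, dtype=np.int64)
        self.z2 = np.asarray(self.z2, dtype=np.int64)
        if not (len(self.t) == len(self.z1) == len(self.z2)):
            raise ValueError("t, z1, z2 must have equal length")
        if len(self.t) > 1 and np.any(np.diff(self.t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.z1 < 0) or np.any(self.z2 < 0):
            raise ValueError("measured counts must be non-negative")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def healthy_fraction(self) -> np.ndarray:
        """Measured healthy fraction Z1/(Z1+Z2) per time point."""
        tot = self.z1 + self.z2
        return self.z1 / tot


def subsample_cells(
    state, n_observed: int, rng: np.random.Generator
) -> tuple[int, int]:
    """Observe min(n_observed, Y1+Y2) copies without replacement.

    Returns the hypergeometric split (Z1, Z2) of the draw between healthy
    and mutant copies.
    """
    y1, y2 = state.y1, state.y2
    tot = y1 + y2
    if tot == 0:
        raise ValueError("cannot sample an empty (dead) population")
    m = min(n_observed, tot)
    z1 = int(rng.hypergeometric(y1, y2, m))
    return z1, m - z1


def add_fraction_noise(
    true_fraction: float, sigma_log10: float, rng: np.random.Generator
) -> float:
    """Multiply the fraction by 10**eps, eps ~ N(0, sigma), clip to (0, 1].

    sigma_log10 = 0 is the identity.
    """
    if not (0 < true_fraction <= 1):
        raise ValueError(f"fraction must be in (0, 1], got {true_fraction}")
    if sigma_log10 == 0:
        return float(true_fraction)
    f = true_fraction * 10.0 ** rng.normal(0.0, sigma_log10)
    return float(min(f, 1.0))


def _pick_schedule(
    days: np.ndarray, schedule: str | int, rng: np.random.Generator
) -> tuple[np.ndarray, bool]:
    if isinstance(schedule, str):  # daily
        return days, False
    k = int(schedule)
    if k >= len(days):
        if k > len(days):
            logger.warning(
                "schedule requested %d times but only %d observable days; truncating",
                k,
                len(days),
            )
        return days, k > len(days)
    chosen = rng.choice(days, size=k, replace=False)
    chosen.sort()
    return chosen, False


def observe(
    trajectory: Trajectory,
    model: MeasurementModel,
    rng: np.random.Generator,
) -> MeasuredSeries:
    """Turn a latent trajectory into a measured series.

    At each scheduled day the population is subsampled (hypergeometric,
    min(n_observed, Y1+Y2) copies) and the subcounts are perturbed on the
    log10 scale according to ``model.noise_on``.  A count or fraction of
    exactly 0 passes through unchanged (the multiplicative noise fixes
    0).  The death-day state is never sampled; a run that dies at day 0
    yields an empty series.
    """
    if trajectory.n_days < 1:
        raise ValueError("trajectory has no recorded states")
    idx = trajectory.observable_days()
    days = trajectory.t[idx]
    days, truncated = _pick_schedule(days, model.schedule, rng)
    if len(days) == 0:
        return MeasuredSeries(
            t=np.empty(0, np.int64),
            z1=np.empty(0, np.int64),
            z2=np.empty(0, np.int64),
            death_time=trajectory.death_time,
            horizon=trajectory.horizon,
            noisy=model.sigma_log10 > 0,
            subsampled=True,
            truncated_schedule=truncated,
        )
    pos = np.searchsorted(trajectory.t, days)
    y1 = trajectory.y1[pos]
    y2 = trajectory.y2[pos]
    tot = y1 + y2
    m = np.minimum(model.n_observed, tot)
    s1 = rng.hypergeometric(y1, y2, m)
    s2 = m - s1
    if model.sigma_log10 == 0:
        z1i, z2i = s1, s2
    elif model.noise_on == "counts":
        eps = rng.normal(0.0, model.sigma_log10, size=(2, len(m)))
        z1i = np.rint(s1 * 10.0 ** eps[0]).astype(np.int64)
        z2i = np.rint(s2 * 10.0 ** eps[1]).astype(np.int64)
        # guard against both counts rounding to zero (a >10-sigma event)
        empty = (z1i + z2i) == 0
        z1i[empty] = s1[empty]
        z2i[empty] = s2[empty]
    else:  # single multiplicative error on the shared healthy fraction
        f = s1 / m
        eps = rng.normal(0.0, model.sigma_log10, size=len(f))
        f = np.where(f > 0, np.minimum(f * 10.0**eps, 1.0), 0.0)
        z1i = np.rint(f * m).astype(np.int64)
        z2i = m - z1i
    return MeasuredSeries(
        t=days,
        z1=z1i,
        z2=z2i,
        death_time=trajectory.death_time,
        horizon=trajectory.horizon,
        noisy=model.sigma_log10 > 0,
        subsampled=True,
        truncated_schedule=truncated,
    )
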