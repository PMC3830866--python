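"""Candidate summary-statistic sets for the measured series.

Three nested candidate sets are compared by the calibration study:

* set 1: average rate of change of the measured healthy fraction
  Z1/(Z1+Z2), and the slopes (b1, b2) of an OLS regression of the per-day
  change in Z1 on the current Z1 and the current healthy fraction;
* set 2: set 1 plus the maximum observed healthy fraction and the number
  of days until cell death (the horizon for censored runs);
* set 3: set 1 plus the analogous slopes (b1, b2) for Z2.

All rates are per day: consecutive differences are divided by the actual
time gap, so daily and irregular (e.g. 13-random-times) sampling are
directly comparable; with daily data this coincides with lag-one changes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .measurement import MeasuredSeries

__all__ = [
    "SummaryVector",
    "avg_rate_of_change",
    "delta_regression",
    "max_ratio",
    "steps_to_death",
    "summarize",
    "all_summaries",
    "FULL_NAMES",
    "SET_COLUMNS",
    "set_names",
]

FULL_NAMES = (
    "avg_rate",
    "b1_Z1",
    "b2_Z1",
    "max_ratio",
    "steps_to_death",
    "b1_Z2",
    "b2_Z2",
)

#: column indices into the full 7-vector for each candidate set
SET_COLUMNS = {
    1: (0, 1, 2),
    2: (0, 1, 2, 3, 4),
    3: (0, 1, 2, 5, 6),
}

# flag bits
FLAG_DEGENERATE = 1  # fewer than 2 observation times
FLAG_RANK_Z1 = 2  # degenerate predictor in the Z1 regression
FLAG_RANK_Z2 = 4  # degenerate predictor in the Z2 regression
FLAG_CENSORED = 8  # generating run censored at the horizon

#: relative spread below which a regression predictor counts as constant
_CONST_TOL = 1e-10


def set_names(set_id: int) -> tuple[str, ...]:
    return tuple(FULL_NAMES[i] for i in SET_COLUMNS[set_id])


@dataclass(frozen=True)
class SummaryVector:
    """Named summary statistics of one series under one candidate set."""

    set_id: int
    names: tuple[str, ...]
    values: np.ndarray
    flags: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if len(self.names) != len(self.values):
            raise ValueError("names and values must have equal length")
        if self.set_id in SET_COLUMNS and len(self.values) != len(
            SET_COLUMNS[self.set_id]
        ):
            raise ValueError(
                f"set {self.set_id} has dimension {len(SET_COLUMNS[self.set_id])}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("summary values must be finite")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def degenerate(self) -> bool:
        return bool(self.flags & FLAG_DEGENERATE)


def avg_rate_of_change(series: MeasuredSeries) -> float:
    """Mean over consecutive pairs of (f_{i+1}-f_i)/(t_{i+1}-t_i)."""
    if len(series) < 2:
        raise ValueError("need at least 2 points with distinct times")
    f = series.healthy_fraction
    dt = np.diff(series.t)
    return float(np.mean(np.diff(f) / dt))


def _ols_slopes(x1: np.ndarray, x2: np.ndarray, y: np.ndarray) -> tuple[float, float, bool]:
    """Slopes of y ~ 1 + x1 + x2; constant predictors get slope 0.

    Returns (b1, b2, degenerate_flag).
    """
    cols = []
    keep = []
    for j, x in enumerate((x1, x2)):
        spread = np.ptp(x)
        if spread <= _CONST_TOL * max(1.0, float(np.max(np.abs(x)))):
            keep.append(False)
        else:
            keep.append(True)
            cols.append(x)
    if not cols:
        return 0.0, 0.0, True
    X = np.column_stack([np.ones(len(y))] + cols)
    # modest rcond so a numerically collinear pair resolves to the stable
    # least-norm solution instead of a noise-amplified one
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=1e-9)
    if rank < X.shape[1]:
        # collinear beyond the constant-column rule: least-norm solution
        flag = True
    else:
        flag = not all(keep)
    out = [0.0, 0.0]
    k = 1
    for j in range(2):
        if keep[j]:
            out[j] = float(beta[k])
            k += 1
    return out[0], out[1], flag


def delta_regression(series: MeasuredSeries, which: str = "Z1") -> tuple[float, float]:
    """Slopes (b1, b2) of the per-day change in Z on (current Z, current f).

    The response for interval i is (Z_{i+1} - Z_i)/(t_{i+1} - t_i); the
    predictors are the count Z and the healthy fraction f at the start of
    the interval.  The intercept is fitted and discarded.  A constant
    predictor gets slope 0.
    """
    if which not in ("Z1", "Z2"):
        raise ValueError("which must be 'Z1' or 'Z2'")
    if len(series) < 4:
        raise ValueError("need at least 4 points for the delta regression")
    z = series.z1 if which == "Z1" else series.z2
    f = series.healthy_fraction
    dt = np.diff(series.t)
    y = np.diff(z) / dt
    b1, b2, _ = _ols_slopes(z[:-1].astype(float), f[:-1], y)
    return b1, b2


def max_ratio(series: MeasuredSeries) -> float:
    """Maximum observed healthy fraction Z1/(Z1+Z2)."""
    if len(series) < 1:
        raise ValueError("need at least 1 point")
    return float(np.max(series.healthy_fraction))


def steps_to_death(series: MeasuredSeries, horizon: int | None = None) -> float:
    """Death day of the generating run; the horizon when censored."""
    if series.death_time is not None:
        return float(series.death_time)
    return float(horizon if horizon is not None else series.horizon)


def all_summaries(series: MeasuredSeries, horizon: int | None = None) -> tuple[np.ndarray, int]:
    """Full 7-vector (avg_rate, b1_Z1, b2_Z1, max_ratio, steps, b1_Z2, b2_Z2).

    Degenerate series (fewer than 2 observation times, e.g. death before
    the second measurement) yield the sentinel vector of zeros with
    steps_to_death = 0 and max_ratio equal to the single observed ratio
    when one point exists; such runs stay in the reference table.  Series
    too short for the regressions (2-3 points) get zero slopes with a
    rank flag.
    """
    n = len(series)
    flags = 0
    if series.death_time is None:
        flags |= FLAG_CENSORED
    if n < 2:
        v = np.zeros(7)
        if n == 1:
            v[3] = series.healthy_fraction[0]
        return v, flags | FLAG_DEGENERATE
    v = np.empty(7)
    v[0] = avg_rate_of_change(series)
    v[3] = max_ratio(series)
    v[4] = steps_to_death(series, horizon)
    if n < 4:
        v[1] = v[2] = v[5] = v[6] = 0.0
        flags |= FLAG_RANK_Z1 | FLAG_RANK_Z2
    else:
        f = series.healthy_fraction
        dt = np.diff(series.t)
        b1, b2, d1 = _ols_slopes(
            series.z1[:-1].astype(float), f[:-1], np.diff(series.z1) / dt
        )
        b3, b4, d2 = _ols_slopes(
            series.z2[:-1].astype(float), f[:-1], np.diff(series.z2) / dt
        )
        v[1], v[2], v[5], v[6] = b1, b2, b3, b4
        if d1:
            flags |= FLAG_RANK_Z1
        if d2:
            flags |= FLAG_RANK_Z2
    return v, flags


def summarize(
    series: MeasuredSeries, set_id: int, horizon: int | None = None
) -> SummaryVector:
    """Assemble the named summary vector for one candidate set."""
    if set_id not in SET_COLUMNS:
        raise ValueError(f"set_id must be one of {sorted(SET_COLUMNS)}")
    full, flags = all_summaries(series, horizon)
    cols = SET_COLUMNS[set_id]
    return SummaryVector(
        set_id=set_id,
        names=set_names(set_id),
        values=full[list(cols)],
        flags=flags,
    )
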