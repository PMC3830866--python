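"""Five-reaction stochastic model of mtDNA deletion accumulation.

A single cell carries ``Y1`` healthy and ``Y2`` mutant (deletion-bearing)
mtDNA copies.  Healthy copies mutate at rate ``c1`` per copy per day;
copies of either type are synthesised in proportion to their share of the
population with total synthesis rate ``1000*c3`` (a soft carrying capacity
of 1000 copies) and degrade at rate ``c3`` per copy.  The cell dies when
its mutant fraction ``Y2/(Y1+Y2)`` strictly exceeds a lethal threshold
``tau``.  The synthesis rates ``c2`` and ``c4`` are known multiples of
``c3`` (both ``1000*c3``), so the free parameters are ``theta =
{c1, c3, tau}``.

Two simulators are provided: :func:`simulate_ssa` (exact, event-driven
Gillespie) and :func:`simulate_daily` (Poisson leap with 1-day steps, the
default engine for calibration experiments).  Both record the state on the
integer-day grid and apply the death rule once per day.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernels import daily_kernel, ssa_kernel

__all__ = [
    "ThetaParams",
    "PriorSpec",
    "PopulationState",
    "Trajectory",
    "SimulationSettings",
    "propensities",
    "check_death",
    "simulate_ssa",
    "simulate_daily",
    "sample_prior",
]

#: soft carrying capacity: total synthesis rate is CAPACITY * c3 per day
CAPACITY = 1000.0

PARAM_NAMES = ("c1", "c3", "tau")


@dataclass(frozen=True)
class ThetaParams:
    """Calibration parameters theta = {c1, c3, tau}.

    Parameters
    ----------
    c1 : float
        Mutation rate per healthy copy, per day.  Must be positive
        (``c1 = 0`` is accepted as the degenerate no-mutation limit).
    c3 : float
        Degradation rate per copy, per day.
    tau : float
        Lethal mutant-fraction threshold in (0, 1].
    """

    c1: float
    c3: float
    tau: float

    def __post_init__(self) -> None:
        if not (self.c1 >= 0 and np.isfinite(self.c1)):
            raise ValueError(f"c1 must be finite and >= 0, got {self.c1}")
        if not (self.c3 >= 0 and np.isfinite(self.c3)):
            raise ValueError(f"c3 must be finite and >= 0, got {self.c3}")
        if not (0 < self.tau <= 1):
            raise ValueError(f"tau must be in (0, 1], got {self.tau}")

    @property
    def c2(self) -> float:
        """Healthy synthesis rate coefficient, a fixed multiple of c3."""
        return CAPACITY * self.c3

    @property
    def c4(self) -> float:
        """Mutant synthesis rate coefficient, a fixed multiple of c3."""
        return CAPACITY * self.c3

    def as_array(self) -> np.ndarray:
        return np.array([self.c1, self.c3, self.tau])


@dataclass(frozen=True)
class PriorSpec:
    """Independent uniform priors, one (low, high) range per parameter."""

    c1: tuple[float, float] = (1e-6, 1e-3)
    c3: tuple[float, float] = (3e-5, 1e-3)
    tau: tuple[float, float] = (0.5, 1.0)

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            lo, hi = getattr(self, name)
            if not (np.isfinite(lo) and np.isfinite(hi) and lo <= hi):
                raise ValueError(f"invalid prior range for {name}: ({lo}, {hi})")

    @property
    def bounds(self) -> np.ndarray:
        """(3, 2) array of (low, high) in the order (c1, c3, tau)."""
        return np.array([self.c1, self.c3, self.tau])

    def sample_array(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n parameter vectors as an (n, 3) array."""
        if n < 1:
            raise ValueError("n must be >= 1")
        b = self.bounds
        return rng.uniform(b[:, 0], b[:, 1], size=(n, 3))

    def contains(self, theta: np.ndarray) -> np.ndarray:
        b = self.bounds
        t = np.atleast_2d(theta)
        return np.all((t >= b[:, 0]) & (t <= b[:, 1]), axis=1)


@dataclass(frozen=True)
class PopulationState:
    """Population state at time t (days): healthy/mutant copy counts."""

    t: float
    y1: int
    y2: int

    def __post_init__(self) -> None:
        if self.y1 < 0 or self.y2 < 0:
            raise ValueError(f"counts must be non-negative, got ({self.y1}, {self.y2})")
        if self.t < 0:
            raise ValueError(f"time must be >= 0, got {self.t}")

    @property
    def total(self) -> int:
        return self.y1 + self.y2

    @property
    def mutant_fraction(self) -> float:
        if self.total == 0:
            raise ZeroDivisionError("mutant fraction undefined for empty population")
        return self.y2 / self.total


@dataclass(frozen=True)
class SimulationSettings:
    """Initial condition, horizon and engine for one simulation run."""

    y1_0: int = 400
    y2_0: int = 600
    horizon: int = 36_500
    engine: str = "daily"

    def __post_init__(self) -> None:
        if self.horizon <= 0:
            raise ValueError("horizon must be positive")
        if self.y1_0 < 0 or self.y2_0 < 0:
            raise ValueError("initial counts must be non-negative")
        if self.engine not in ("daily", "ssa"):
            raise ValueError(f"engine must be 'daily' or 'ssa', got {self.engine!r}")

    @property
    def init(self) -> PopulationState:
        return PopulationState(0.0, self.y1_0, self.y2_0)


@dataclass
class Trajectory:
    """Latent population path recorded on the daily grid.

    ``death_time`` is the day at which the death rule first fired (the
    state at that day is the last one recorded); ``None`` for runs
    censored at the horizon.
    """

    t: np.ndarray
    y1: np.ndarray
    y2: np.ndarray
    death_time: int | None
    horizon: int

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=np.int64)
        self.y1 = np.asarray(self.y1, dtype=np.int64)
        self.y2 = np.asarray(self.y2, dtype=np.int64)
        if not (len(self.t) == len(self.y1) == len(self.y2)):
            raise ValueError("t, y1, y2 must have equal length")
        if len(self.t) and np.any(np.diff(self.t) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def terminated_by_death(self) -> bool:
        return self.death_time is not None

    @property
    def n_days(self) -> int:
        return len(self.t)

    def mutant_fraction(self) -> np.ndarray:
        tot = self.y1 + self.y2
        with np.errstate(invalid="ignore"):
            return np.where(tot > 0, self.y2 / np.maximum(tot, 1), np.nan)

    def observable_days(self) -> np.ndarray:
        """Indices of days a measurement may be taken at.

        The death-day state itself is excluded: once the lethal threshold
        has fired the cell is gone and cannot be sampled.
        """
        if self.terminated_by_death:
            return np.arange(self.n_days - 1)
        return np.arange(self.n_days)


def propensities(state: PopulationState, theta: ThetaParams) -> np.ndarray:
    """Per-day rates (a1..a5) of the five reactions at the given state.

    Returns ``(c1*Y1, 1000*c3*Y1/(Y1+Y2), c3*Y1, 1000*c3*Y2/(Y1+Y2),
    c3*Y2)``; all zeros for an empty population.
    """
    y1, y2 = state.y1, state.y2
    if y1 < 0 or y2 < 0:
        raise ValueError("invalid state: negative counts")
    tot = y1 + y2
    if tot == 0:
        return np.zeros(5)
    a = np.array(
        [
            theta.c1 * y1,
            CAPACITY * theta.c3 * y1 / tot,
            theta.c3 * y1,
            CAPACITY * theta.c3 * y2 / tot,
            theta.c3 * y2,
        ]
    )
    if not np.all(np.isfinite(a)):
        raise ValueError("invalid state: non-finite propensities")
    return a


def check_death(state: PopulationState, tau: float) -> bool:
    """Death rule: mutant fraction strictly exceeds tau (ties survive).

    An empty population is dead by convention (the fraction is undefined).
    """
    tot = state.y1 + state.y2
    if tot == 0:
        return True
    return state.y2 > tau * tot


def _resolve_seed(rng: np.random.Generator | int | None) -> int:
    """Derive a 31-bit kernel seed from a Generator, an int, or None."""
    if rng is None:
        rng = np.random.default_rng()
    if isinstance(rng, (int, np.integer)):
        return int(rng) & 0x7FFFFFFF
    return int(rng.integers(0, 2**31))


def _run_kernel(
    kernel,
    theta: ThetaParams,
    init: PopulationState,
    horizon: int,
    rng: np.random.Generator | int | None,
) -> Trajectory:
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    seed = _resolve_seed(rng)
    buf1 = np.empty(horizon + 1, dtype=np.int64)
    buf2 = np.empty(horizon + 1, dtype=np.int64)
    n, death = kernel(
        theta.c1, theta.c3, theta.tau, init.y1, init.y2, horizon, seed, buf1, buf2
    )
    return Trajectory(
        t=np.arange(n),
        y1=buf1[:n].copy(),
        y2=buf2[:n].copy(),
        death_time=None if death < 0 else int(death),
        horizon=horizon,
    )


def simulate_ssa(
    theta: ThetaParams,
    init: PopulationState | None = None,
    horizon: int = 36_500,
    rng: np.random.Generator | int | None = None,
) -> Trajectory:
    """Exact Gillespie simulation recorded on the daily grid.

    Waiting times are exponential with rate equal to the total propensity
    and the reaction channel is chosen proportionally to its propensity.
    Death is checked once per recorded day.
    """
    if init is None:
        init = PopulationState(0.0, 400, 600)
    return _run_kernel(ssa_kernel, theta, init, horizon, rng)


def simulate_daily(
    theta: ThetaParams,
    init: PopulationState | None = None,
    horizon: int = 36_500,
    rng: np.random.Generator | int | None = None,
) -> Trajectory:
    """Daily Poisson-leap approximation of the five-reaction process.

    Per 1-day step the number of firings of each reaction is Poisson with
    mean propensity x 1 day; removals are clamped to availability in
    reaction-index order so counts never go negative.
    """
    if init is None:
        init = PopulationState(0.0, 400, 600)
    return _run_kernel(daily_kernel, theta, init, horizon, rng)


def simulate(
    theta: ThetaParams,
    settings: SimulationSettings,
    rng: np.random.Generator | int | None = None,
) -> Trajectory:
    """Run the engine named in ``settings`` (``daily`` or ``ssa``)."""
    fn = simulate_daily if settings.engine == "daily" else simulate_ssa
    return fn(theta, settings.init, settings.horizon, rng)


def sample_prior(
    prior: PriorSpec, n: int, rng: np.random.Generator
) -> list[ThetaParams]:
    """n independent draws from the uniform prior box."""
    arr = prior.sample_array(n, rng)
    return [ThetaParams(*row) for row in arr]
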