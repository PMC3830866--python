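"""Numba kernels for the latent five-reaction birth-death-mutation process.

Both kernels record the population state on the integer-day grid and test
the lethal-threshold death rule once per recorded day (not per event), so
the exact event-driven simulator and the daily Poisson-leap approximation
terminate under identical rules and are directly comparable.

Reactions on (Y1, Y2) = (healthy, mutant) copy numbers, rates per day:

    R1  mutation            Y1 -> Y1-1, Y2+1   a1 = c1*Y1
    R2  synthesis           Y1 -> Y1+1         a2 = 1000*c3*Y1/(Y1+Y2)
    R3  degradation         Y1 -> Y1-1         a3 = c3*Y1
    R4  mutant synthesis    Y2 -> Y2+1         a4 = 1000*c3*Y2/(Y1+Y2)
    R5  mutant degradation  Y2 -> Y2-1         a5 = c3*Y2

A cell dies when its mutant fraction Y2/(Y1+Y2) strictly exceeds tau; an
empty population (Y1+Y2 = 0) is treated as dead (the fraction is undefined
and the cell has no mtDNA left).
"""

import numpy as np
from numba import njit

__all__ = ["daily_kernel", "ssa_kernel", "ssa_event_kernel"]


@njit(cache=True)
def _is_dead(y1, y2, tau):
    tot = y1 + y2
    if tot == 0:
        return True
    return y2 > tau * tot


@njit(cache=True)
def daily_kernel(c1, c3, tau, y1, y2, horizon, seed, out_y1, out_y2):
    """Poisson tau-leap with 1-day steps and per-reaction clamping.

    Records the state at days 0..end into out_y1/out_y2 and returns
    (n_recorded, death_day) with death_day = -1 when the run is censored
    at the horizon.  Proposed removals exceeding the available copies are
    capped at availability, applied in reaction-index order R1..R5.
    """
    np.random.seed(seed)
    n = 0
    t = 0
    while True:
        out_y1[n] = y1
        out_y2[n] = y2
        n += 1
        if _is_dead(y1, y2, tau):
            return n, t
        if t >= horizon:
            return n, -1
        tot = y1 + y2
        n1 = np.random.poisson(c1 * y1)
        n2 = np.random.poisson(1000.0 * c3 * y1 / tot)
        n3 = np.random.poisson(c3 * y1)
        n4 = np.random.poisson(1000.0 * c3 * y2 / tot)
        n5 = np.random.poisson(c3 * y2)
        if n1 > y1:
            n1 = y1
        y1 -= n1
        y2 += n1
        y1 += n2
        if n3 > y1:
            n3 = y1
        y1 -= n3
        y2 += n4
        if n5 > y2:
            n5 = y2
        y2 -= n5
        t += 1


@njit(cache=True)
def ssa_kernel(c1, c3, tau, y1, y2, horizon, seed, out_y1, out_y2):
    """Exact Gillespie simulation, recorded on the daily grid.

    Exponential waiting times with rate = total propensity; the reaction is
    chosen with probability proportional to its propensity.  Death is
    checked at each recorded day.  Returns (n_recorded, death_day).
    """
    np.random.seed(seed)
    n = 0
    day = 0
    t = 0.0
    a1 = a2 = a3 = a4 = a5 = 0.0
    while True:
        tot = y1 + y2
        if tot == 0:
            a0 = 0.0
        else:
            a1 = c1 * y1
            a2 = 1000.0 * c3 * y1 / tot
            a3 = c3 * y1
            a4 = 1000.0 * c3 * y2 / tot
            a5 = c3 * y2
            a0 = a1 + a2 + a3 + a4 + a5
        if a0 <= 0.0:
            # frozen state: emit remaining daily records
            while day <= horizon:
                out_y1[n] = y1
                out_y2[n] = y2
                n += 1
                if _is_dead(y1, y2, tau):
                    return n, day
                day += 1
            return n, -1
        t_next = t + np.random.exponential(1.0 / a0)
        # record every day boundary crossed before the next event
        while day <= t_next and day <= horizon:
            out_y1[n] = y1
            out_y2[n] = y2
            n += 1
            if _is_dead(y1, y2, tau):
                return n, day
            day += 1
        if day > horizon:
            return n, -1
        t = t_next
        u = np.random.random() * a0
        if u < a1:
            y1 -= 1
            y2 += 1
        elif u < a1 + a2:
            y1 += 1
        elif u < a1 + a2 + a3:
            y1 -= 1
        elif u < a1 + a2 + a3 + a4:
            y2 += 1
        else:
            y2 -= 1


@njit(cache=True)
def ssa_event_kernel(c1, c3, tau, y1, y2, max_events, seed, dy1, dy2):
    """Exact SSA recording per-event state changes (for invariant checks).

    Fills dy1/dy2 with the stoichiometry of each fired event and returns
    the number of events fired (stops at max_events or when the total
    propensity is zero).  No daily grid, no death rule: pure dynamics.
    """
    np.random.seed(seed)
    k = 0
    while k < max_events:
        tot = y1 + y2
        if tot == 0:
            return k
        a1 = c1 * y1
        a2 = 1000.0 * c3 * y1 / tot
        a3 = c3 * y1
        a4 = 1000.0 * c3 * y2 / tot
        a5 = c3 * y2
        a0 = a1 + a2 + a3 + a4 + a5
        if a0 <= 0.0:
            return k
        u = np.random.random() * a0
        if u < a1:
            d1, d2 = -1, 1
        elif u < a1 + a2:
            d1, d2 = 1, 0
        elif u < a1 + a2 + a3:
            d1, d2 = -1, 0
        elif u < a1 + a2 + a3 + a4:
            d1, d2 = 0, 1
        else:
            d1, d2 = 0, -1
        y1 += d1
        y2 += d2
        dy1[k] = d1
        dy2[k] = d2
        k += 1
    return k
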