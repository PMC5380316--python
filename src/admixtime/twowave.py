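"""Two-wave admixture theory: pulse equivalence and historical bounds.

Under a two-wave history (A/B merge at t1 with A-fraction q; A replaces a
fraction mu at t2 < t1) the minor-source (B) tract lengths are exponential
with rate r = t1 - (1-q)(t1 - mu*t2) = q*t1 + (1-q)*mu*t2, and the B ancestry
fraction is M = (1-q)(1-mu).  A one-pulse fit to such data recovers neither
t1 nor t2 but the pulse-equivalent time T with r = (1-M)T, i.e.

    T (q + mu - q*mu) = t1 - (1-q)(t1 - mu*t2).

Inverting for t1 given (T, t2, q, mu) turns an inferred single-event time
into a constraint on two-wave histories; extremizing over plausible
parameter boxes yields bounds on the early admixture time.  Since t1 is
affine in each argument, extrema sit at box corners; the grid scan here is
a cheap cross-check of that corner argument.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product

import numpy as np

from .models import TwoWaveModel

__all__ = [
    "b_tract_rate", "b_fraction", "pulse_equivalent_time", "solve_early_time",
    "BoundSpec", "EarlyTimeBounds", "early_time_bounds",
    "weighted_average_time", "back_project_ancestry",
    "southern_ancestry_bounds",
]


def b_tract_rate(model: TwoWaveModel) -> float:
    """Exponential rate (per Morgan) of minor-source (B) tract lengths."""
    return model.t1 - (1.0 - model.q) * (model.t1 - model.mu * model.t2)


def b_fraction(q: float, mu: float) -> float:
    """Final B-ancestry fraction M = (1-q)(1-mu)."""
    if not (0 <= q <= 1 and 0 <= mu <= 1):
        raise ValueError("q and mu must lie in [0, 1]")
    return (1.0 - q) * (1.0 - mu)


def pulse_equivalent_time(model: TwoWaveModel) -> float:
    """The single-event time T that a pulse fit recovers from two-wave data."""
    denom = model.q + model.mu - model.q * model.mu
    if denom == 0:
        raise ValueError("q + mu = 0: pulse-equivalent time undefined")
    return b_tract_rate(model) / denom


def solve_early_time(T: float, t2: float, q: float, mu: float) -> float:
    """Early admixture time t1 from the pulse-equivalence relation.

    t1 = [T(q + mu - q*mu) - (1-q)*mu*t2] / q.  Warns if the solution
    violates the t1 > t2 ordering.
    """
    if q == 0:
        raise ValueError("q = 0: early time undefined")
    t1 = (T * (q + mu - q * mu) - (1.0 - q) * mu * t2) / q
    if t1 <= t2:
        warnings.warn(
            f"solved t1 = {t1:.2f} <= t2 = {t2}: inconsistent event ordering",
            stacklevel=2)
    return t1


@dataclass
class BoundSpec:
    """Intervals [lo, hi] for the pulse time T, q, mu, and the recent time t2."""

    T: tuple[float, float]
    q: tuple[float, float]
    mu: tuple[float, float]
    t2: tuple[float, float]

    def __post_init__(self) -> None:
        for name in ("T", "q", "mu", "t2"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name}: lo > hi")
            if lo < 0:
                raise ValueError(f"{name}: negative bound")
        for name in ("q", "mu"):
            if getattr(self, name)[1] > 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.q[0] <= 0:
            raise ValueError("q lower bound must be positive")


@dataclass
class EarlyTimeBounds:
    t1_min: float
    t1_max: float
    argmin: dict[str, float]
    argmax: dict[str, float]


def early_time_bounds(spec: BoundSpec, time_step: float = 1.0,
                      prop_step: float = 0.01) -> EarlyTimeBounds:
    """Extremes of the early admixture time over the parameter box.

    Scans the Cartesian grid (default steps: 1 generation for T and t2, 0.01
    for q and mu), keeping only solutions with t1 > t2, and cross-checks
    against the analytic corner scan (t1 is affine in each argument).
    """

    def axis(lo_hi, step):
        lo, hi = lo_hi
        n = max(int(round((hi - lo) / step)), 0)
        return np.unique(np.append(lo + step * np.arange(n + 1), hi).clip(lo, hi))

    Ts = axis(spec.T, time_step)
    qs = axis(spec.q, prop_step)
    mus = axis(spec.mu, prop_step)
    t2s = axis(spec.t2, time_step)

    best_min = (np.inf, None)
    best_max = (-np.inf, None)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for T, q, mu, t2 in product(Ts, qs, mus, t2s):
            t1 = solve_early_time(float(T), float(t2), float(q), float(mu))
            if t1 <= t2:
                continue
            if t1 < best_min[0]:
                best_min = (t1, {"T": T, "q": q, "mu": mu, "t2": t2})
            if t1 > best_max[0]:
                best_max = (t1, {"T": T, "q": q, "mu": mu, "t2": t2})
        # corner cross-check (t1 affine in each argument => extrema at corners)
        for T, q, mu, t2 in product(spec.T, spec.q, spec.mu, spec.t2):
            t1 = solve_early_time(T, t2, q, mu)
            if t1 <= t2:
                continue
            if t1 < best_min[0]:
                best_min = (t1, {"T": T, "q": q, "mu": mu, "t2": t2})
            if t1 > best_max[0]:
                best_max = (t1, {"T": T, "q": q, "mu": mu, "t2": t2})
    if best_min[1] is None:
        raise ValueError("empty feasible set: every solution has t1 <= t2")
    return EarlyTimeBounds(
        t1_min=float(best_min[0]), t1_max=float(best_max[0]),
        argmin={k: float(v) for k, v in best_min[1].items()},
        argmax={k: float(v) for k, v in best_max[1].items()})


def weighted_average_time(t1: float, t2: float, q: float, mu: float) -> float:
    """Proportion-weighted average (q*t1 + mu*t2)/(q + mu), a simple
    approximation to the pulse-equivalent time."""
    if q + mu <= 0:
        raise ValueError("q + mu must be positive")
    return (q * t1 + mu * t2) / (q + mu)


def back_project_ancestry(S_present: float, mu: float) -> float:
    """Ancestry fraction at the early event from its present-day value.

    A later replacement of a fraction mu dilutes early ancestry by (1 - mu),
    so f_early = S_present / (1 - mu).
    """
    if not (0.0 <= S_present <= 1.0 - mu):
        raise ValueError(
            f"S_present = {S_present} exceeds 1 - mu = {1 - mu}: infeasible")
    return S_present / (1.0 - mu)


def southern_ancestry_bounds(total_eu_bounds: tuple[float, float],
                             west_east_bounds: tuple[float, float],
                             ) -> tuple[float, float]:
    """Present-day bounds on the dominant (Southern) EU ancestry component.

    The Southern component is the total EU ancestry minus the Western/Eastern
    contribution, so its extremes pair the low total with the high minor
    component and vice versa.
    """
    eu_lo, eu_hi = total_eu_bounds
    we_lo, we_hi = west_east_bounds
    return eu_lo - we_hi, eu_hi - we_lo
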