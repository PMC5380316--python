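"""Admixture dating from ancestry proportions and tract lengths.

The core estimator fits the pulse-admixture parameters (q, t) by maximum
likelihood over a grid, using the per-chromosome ancestry-proportion
distribution (haploid or diploid).  Also provided: the one-line tract-length
dating relation t = 1/(q * mean minor-tract length), the square-root-of-length
weighted SD summary used for variance matching, a generic
calibration-by-simulation loop, and individual-level bootstrap intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .density import DiploidPulseDensity, PulseDensity
from .maps import GeneticMap
from .sim import AncestryCallTable
from .tracks import AncestryTrack, haploid_fractions

__all__ = [
    "ProportionDataset", "PulseFit", "PulseDatingMLE",
    "proportion_loglik", "fit_pulse", "mean_tract_time",
    "weighted_sd_statistic", "calibrate_by_simulation", "bootstrap_ci",
]


@dataclass
class ProportionDataset:
    """Per-individual, per-chromosome ancestry fractions.

    ``fractions`` is (n_individuals, n_chromosomes); ``lengths_morgans`` the
    matching chromosome lengths.  ``diploid`` says whether rows are diploid
    averages y = (x1+x2)/2 or haploid fractions x.
    """

    fractions: np.ndarray
    lengths_morgans: np.ndarray
    diploid: bool = True
    chrom_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.fractions = np.atleast_2d(np.asarray(self.fractions, dtype=float))
        self.lengths_morgans = np.asarray(self.lengths_morgans, dtype=float)
        if self.fractions.shape[1] != self.lengths_morgans.size:
            raise ValueError("fractions/lengths chromosome count mismatch")
        if np.any((self.fractions < 0) | (self.fractions > 1)):
            raise ValueError("ancestry fractions must lie in [0, 1]")
        if np.any(self.lengths_morgans <= 0):
            raise ValueError("chromosome lengths must be positive")

    @property
    def n_individuals(self) -> int:
        return self.fractions.shape[0]

    def subset(self, idx: np.ndarray) -> "ProportionDataset":
        return ProportionDataset(self.fractions[idx], self.lengths_morgans,
                                 self.diploid, self.chrom_ids)

    # -- constructors ---------------------------------------------------------

    @classmethod
    def from_tracks(cls, tracks: list[AncestryTrack], gmap: GeneticMap,
                    label: str) -> "ProportionDataset":
        fr = haploid_fractions(tracks, label)
        chroms = list(tracks[0].chrom_ends)
        lengths = np.array([gmap.length_morgans(c) for c in chroms])
        return cls(fr, lengths, diploid=False, chrom_ids=chroms)

    @classmethod
    def from_diploid_pairs(cls, pairs: list[tuple[AncestryTrack, AncestryTrack]],
                           gmap: GeneticMap, label: str) -> "ProportionDataset":
        a = haploid_fractions([p[0] for p in pairs], label)
        b = haploid_fractions([p[1] for p in pairs], label)
        chroms = list(pairs[0][0].chrom_ends)
        lengths = np.array([gmap.length_morgans(c) for c in chroms])
        return cls((a + b) / 2.0, lengths, diploid=True, chrom_ids=chroms)

    @classmethod
    def from_call_table(cls, calls: AncestryCallTable, label: str,
                        diploid: bool = True) -> "ProportionDataset":
        """Per-SNP call fractions; haplotype rows paired in order if diploid."""
        fr = calls.snp_fractions(label)
        chroms = [c for c in calls.gmap.chromosomes if c in calls.calls]
        lengths = np.array([calls.gmap.length_morgans(c) for c in chroms])
        if diploid:
            if fr.shape[0] % 2:
                raise ValueError("odd haplotype count cannot form diploids")
            fr = (fr[0::2] + fr[1::2]) / 2.0
        return cls(fr, lengths, diploid=diploid, chrom_ids=chroms)


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def _chrom_loglik(obs: np.ndarray, q: float, t: float, L: float,
                  diploid: bool, eps: float, n_grid: int,
                  alpha_variant: str) -> float:
    """Sum of log densities for one chromosome's observations."""
    ll = 0.0
    if diploid:
        # looser normalization guard here: extreme grid corners during the
        # search can carry ~1e-4 quadrature error without affecting the argmax
        d = DiploidPulseDensity(q, t, L, n_grid=n_grid,
                                alpha_variant=alpha_variant, norm_tol=1e-3)
        masses = ((0.0, d.mass_at_0), (0.5, d.mass_at_half),
                  (1.0, d.mass_at_1))
        at_mass = np.zeros(obs.shape, dtype=bool)
        for loc, m in masses:
            hit = np.abs(obs - loc) < eps
            if hit.any():
                with np.errstate(divide="ignore"):
                    ll += hit.sum() * float(np.log(m)) if m > 0 else -np.inf
            at_mass |= hit
        rest = obs[~at_mass]
        if rest.size:
            with np.errstate(divide="ignore"):
                ll += float(np.log(d.pdf(rest)).sum())
        return ll
    d = PulseDensity(q, t, L, alpha_variant=alpha_variant)
    at0 = np.abs(obs) < eps
    at1 = np.abs(obs - 1.0) < eps
    with np.errstate(divide="ignore"):
        if at0.any():
            ll += at0.sum() * float(np.log(d.mass_at_0)) if d.mass_at_0 > 0 \
                else -np.inf
        if at1.any():
            ll += at1.sum() * float(np.log(d.mass_at_1)) if d.mass_at_1 > 0 \
                else -np.inf
        rest = obs[~(at0 | at1)]
        if rest.size:
            ll += float(d.log_pdf(rest).sum())
    return ll


def proportion_loglik(data: ProportionDataset, q: float, t: float,
                      eps: float = 1e-6, n_grid: int = 2001,
                      alpha_variant: str = "sqrt") -> float:
    """Log-likelihood of the dataset under the pulse model (q, t).

    Chromosomes are independent within and between individuals.  An
    observation within ``eps`` of an atom ({0, 1} haploid; {0, 1/2, 1}
    diploid) contributes that point-mass probability instead of a density.
    """
    if data.n_individuals == 0:
        raise ValueError("empty dataset")
    total = 0.0
    for j, L in enumerate(data.lengths_morgans):
        total += _chrom_loglik(data.fractions[:, j], q, t, float(L),
                               data.diploid, eps, n_grid, alpha_variant)
    return total


@dataclass
class PulseFit:
    """Grid-search MLE result for the pulse model."""

    q_hat: float
    t_hat: float
    loglik: float
    q_grid: np.ndarray
    t_grid: np.ndarray
    loglik_grid: np.ndarray  # (len(q_grid), len(t_grid))
    bootstrap_ci_t: tuple[float, float] | None = None


def fit_pulse(data: ProportionDataset,
              q_grid: Sequence[float] | None = None,
              t_grid: Sequence[float] | None = None,
              eps: float = 1e-6, n_grid: int = 2001,
              alpha_variant: str = "sqrt") -> PulseFit:
    """Maximize the ancestry-proportion likelihood over a (q, t) grid.

    Defaults: q on [0.05, 0.95] in steps of 0.01, t integer on [2, 100].
    Ties are broken toward smaller t, then smaller q.
    """
    if q_grid is None:
        q_grid = np.round(np.arange(0.05, 0.9501, 0.01), 4)
    if t_grid is None:
        t_grid = np.arange(2, 101)
    q_grid = np.asarray(list(q_grid), dtype=float)
    t_grid = np.asarray(list(t_grid), dtype=float)
    if q_grid.size == 0 or t_grid.size == 0:
        raise ValueError("empty search grid")

    fr = data.fractions
    if np.all(fr == fr.flat[0]) and fr.flat[0] in (0.0, 1.0):
        raise ValueError("all observations are identical 0 or 1: "
                         "admixture time non-identifiable")

    ll = np.full((q_grid.size, t_grid.size), -np.inf)
    for iq, q in enumerate(q_grid):
        for it, t in enumerate(t_grid):
            ll[iq, it] = proportion_loglik(data, float(q), float(t), eps,
                                           n_grid, alpha_variant)
    if not np.isfinite(ll).any():
        raise ValueError("log-likelihood is -inf on the whole grid: "
                         "degenerate fit")
    # tie-break toward smaller t then smaller q: scan t-major
    flat = ll.T.ravel()  # index = it * n_q + iq
    best = int(np.argmax(flat))
    it, iq = divmod(best, q_grid.size)
    return PulseFit(q_hat=float(q_grid[iq]), t_hat=float(t_grid[it]),
                    loglik=float(ll[iq, it]), q_grid=q_grid, t_grid=t_grid,
                    loglik_grid=ll)


class PulseDatingMLE(BaseEstimator):
    """Grid-search maximum-likelihood dating of a pulse admixture event.

    Parameters
    ----------
    q_grid, t_grid
        Search grids; ``None`` uses the package defaults (q in [0.05, 0.95]
        step 0.01; t integer in [2, 100]).
    fix_q
        ``"mean"`` fixes q at the sample mean ancestry (the usual choice when
        only t is of interest); a float fixes it at that value; ``None``
        searches the 2-D grid.
    eps
        Half-width within which an observation is attributed to an atom.

    Attributes (after ``fit``)
    --------------------------
    q_, t_ : point estimates; loglik_ : maximized log-likelihood;
    fit_ : the underlying :class:`PulseFit` with the evaluated grid.
    """

    def __init__(self, q_grid=None, t_grid=None, fix_q=None, eps: float = 1e-6,
                 n_grid: int = 2001, alpha_variant: str = "sqrt"):
        self.q_grid = q_grid
        self.t_grid = t_grid
        self.fix_q = fix_q
        self.eps = eps
        self.n_grid = n_grid
        self.alpha_variant = alpha_variant

    def fit(self, X: ProportionDataset, y=None) -> "PulseDatingMLE":
        if not isinstance(X, ProportionDataset):
            raise TypeError("X must be a ProportionDataset")
        q_grid = self.q_grid
        if self.fix_q == "mean":
            q_grid = [float(np.clip(X.fractions.mean(), 1e-3, 1 - 1e-3))]
        elif self.fix_q is not None:
            q_grid = [float(self.fix_q)]
        self.fit_ = fit_pulse(X, q_grid, self.t_grid, self.eps, self.n_grid,
                              self.alpha_variant)
        self.q_ = self.fit_.q_hat
        self.t_ = self.fit_.t_hat
        self.loglik_ = self.fit_.loglik
        return self


# ---------------------------------------------------------------------------
# tract-length dating and summary statistics
# ---------------------------------------------------------------------------

def mean_tract_time(mean_b_length_morgans: float, q: float) -> float:
    """Admixture time from the mean minor-source tract length.

    Under pulse admixture the mean length (Morgans) of tracts from the
    second source is 1/(q t), so t = 1/(q * mean length).
    """
    if mean_b_length_morgans <= 0 or q <= 0:
        raise ValueError("mean tract length and q must be positive")
    return 1.0 / (q * mean_b_length_morgans)


def weighted_sd_statistic(data: ProportionDataset) -> float:
    """Average per-chromosome SD of ancestry proportions across individuals,
    weighted by the square root of chromosome length in cM."""
    if data.n_individuals < 2:
        raise ValueError("need at least two individuals for an SD")
    sds = data.fractions.std(axis=0, ddof=1)
    w = np.sqrt(100.0 * data.lengths_morgans)
    return float((w * sds).sum() / w.sum())


# ---------------------------------------------------------------------------
# calibration by simulation
# ---------------------------------------------------------------------------

@dataclass
class CalibrationResult:
    t_star: float
    t_grid: np.ndarray
    stat_curve: np.ndarray  # mean simulated statistic per grid point
    replicates: int


def calibrate_by_simulation(observed_stat: float,
                            simulate_and_summarize: Callable[[float, int], float],
                            t_grid: Sequence[float], replicates: int,
                            seed: int) -> CalibrationResult:
    """Find the admixture time whose simulated statistic matches the data.

    ``simulate_and_summarize(t, seed)`` must return the summary statistic of
    one simulated cohort.  The mean statistic is computed per grid time; if
    the curve is monotone the match is linearly interpolated between grid
    points, otherwise the closest grid point is returned.
    """
    t_grid = np.asarray(list(t_grid), dtype=float)
    if np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    children = np.random.SeedSequence(seed).spawn(t_grid.size)
    curve = np.empty(t_grid.size)
    for i, t in enumerate(t_grid):
        reps = [simulate_and_summarize(float(t),
                                       int(s.generate_state(1)[0] % (2 ** 31)))
                for s in children[i].spawn(replicates)]
        curve[i] = float(np.mean(reps))
    if np.allclose(curve, curve[0]):
        raise ValueError("statistic curve is constant in t: non-identifiable")
    lo, hi = curve.min(), curve.max()
    if not (lo <= observed_stat <= hi):
        raise ValueError(
            f"observed statistic {observed_stat} outside simulated range "
            f"[{lo}, {hi}]: extrapolation failure")
    diffs = np.diff(curve)
    monotone = np.all(diffs > 0) or np.all(diffs < 0)
    if monotone:
        if diffs[0] < 0:  # make increasing for interp
            t_star = float(np.interp(observed_stat, curve[::-1], t_grid[::-1]))
        else:
            t_star = float(np.interp(observed_stat, curve, t_grid))
    else:
        t_star = float(t_grid[int(np.argmin(np.abs(curve - observed_stat)))])
    return CalibrationResult(t_star=t_star, t_grid=t_grid, stat_curve=curve,
                             replicates=replicates)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def bootstrap_ci(estimator: Callable[[ProportionDataset], float],
                 data: ProportionDataset, B: int = 1000, seed: int = 0,
                 alpha: float = 0.05) -> tuple[float, float]:
    """Percentile bootstrap CI, resampling individuals with replacement.

    Failed replicates are skipped; more than 5% failures aborts.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    n = data.n_individuals
    vals = []
    failures = 0
    for _ in range(B):
        idx = rng.integers(n, size=n)
        try:
            vals.append(float(estimator(data.subset(idx))))
        except Exception:
            failures += 1
    if failures > 0.05 * B:
        raise RuntimeError(
            f"{failures}/{B} bootstrap replicates failed (> 5%)")
    if failures:
        warnings.warn(f"{failures} bootstrap replicates skipped", stacklevel=2)
    vals = np.asarray(vals)
    lo = float(np.percentile(vals, 100 * alpha / 2))
    hi = float(np.percentile(vals, 100 * (1 - alpha / 2)))
    return lo, hi
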