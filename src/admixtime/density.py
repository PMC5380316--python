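"""The chromosome-wide ancestry-proportion distribution under pulse admixture.

For a two-source pulse t generations ago with source-A fraction q, ancestry
along a chromosome of length L Morgans is a stationary two-state Markov
process (A-segment rate (1-q)t, B-segment rate qt per Morgan).  The fraction
x of the chromosome in state A then follows the classic occupation-time
distribution (Stam/Pedler form): point masses

    P(x = 0) = (1-q) e^{-qh},     P(x = 1) = q e^{-(1-q)h},   h = tL,

plus a continuous part

    f_c(x) = q(1-q) h e^{-h[(1-q)x + q(1-x)]}
             { [qx + (1-q)(1-x)] I_1(2 h a)/a + 2 I_0(2 h a) },

with a = sqrt(q(1-q)x(1-x)) and I_0, I_1 modified Bessel functions of the
first kind.  The mean is q and the variance is 2q(1-q)(e^{-h}+h-1)/h^2.

Published statements of this density sometimes typeset the Bessel argument
without the radical; the plain-product variant does not normalize (it is
available here behind ``alpha_variant="plain"`` for the validation test, and
must not be used for inference).

Evaluation uses exponentially scaled Bessel functions and log-space
accumulation so that large h (long chromosomes x old admixture) does not
overflow; overflow would otherwise occur near h ~ 700.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve
from scipy.special import ive

__all__ = [
    "PulseDensity", "DiploidPulseDensity",
    "ancestry_density", "ancestry_moments", "diploid_density",
]

_ALPHA_VARIANTS = ("sqrt", "plain")


def _validate(q: float, t: float, L: float) -> float:
    if not (0.0 <= q <= 1.0):
        raise ValueError(f"q must lie in [0, 1], got {q}")
    h = t * L
    if h <= 0:
        raise ValueError(f"h = t*L must be positive, got {h}")
    return h


def ancestry_moments(q: float, t: float, L: float) -> tuple[float, float]:
    """Mean and variance of the haploid ancestry proportion.

    mean = q; variance = 2q(1-q)(e^{-h} + h - 1)/h^2 with h = tL.  The h->0
    limit q(1-q) (a single-segment chromosome) is evaluated stably.
    """
    h = _validate(q, t, L)
    if h < 1e-6:
        shape = 0.5 - h / 6.0 + h * h / 24.0
    else:
        shape = (np.expm1(-h) + h) / (h * h)
    return q, 2.0 * q * (1.0 - q) * shape


@dataclass
class PulseDensity:
    """The haploid ancestry-proportion distribution for one chromosome."""

    q: float
    t: float
    L: float
    alpha_variant: str = "sqrt"
    _h: float = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.alpha_variant not in _ALPHA_VARIANTS:
            raise ValueError(f"unknown alpha_variant {self.alpha_variant!r}")
        self._h = _validate(self.q, self.t, self.L)

    @property
    def h(self) -> float:
        return self._h

    @property
    def mass_at_0(self) -> float:
        """Probability the whole chromosome is B (no A ancestry)."""
        return (1.0 - self.q) * np.exp(-self.q * self._h)

    @property
    def mass_at_1(self) -> float:
        """Probability the whole chromosome is A."""
        return self.q * np.exp(-(1.0 - self.q) * self._h)

    def log_pdf(self, x) -> np.ndarray:
        """Log of the continuous part, elementwise; -inf where it vanishes."""
        x = np.asarray(x, dtype=float)
        if np.any((x < 0) | (x > 1)):
            raise ValueError("x must lie in [0, 1]")
        q, h = self.q, self._h
        if q in (0.0, 1.0):
            return np.full(x.shape, -np.inf)
        prod = q * (1.0 - q) * x * (1.0 - x)
        a = np.sqrt(prod) if self.alpha_variant == "sqrt" else prod
        z = 2.0 * h * a
        # I_n(z) = ive(n, z) * e^z; keep e^z in the exponent
        with np.errstate(divide="ignore", invalid="ignore"):
            i1_term = np.where(a > 1e-12, ive(1, z) / np.where(a > 0, a, 1.0), h)
        bracket = (q * x + (1.0 - q) * (1.0 - x)) * i1_term + 2.0 * ive(0, z)
        log_pref = np.log(q * (1.0 - q) * h)
        exponent = -h * ((1.0 - q) * x + q * (1.0 - x)) + z
        with np.errstate(divide="ignore"):
            return log_pref + exponent + np.log(bracket)

    def pdf(self, x) -> np.ndarray:
        return np.exp(self.log_pdf(x))

    def moments(self) -> tuple[float, float]:
        return ancestry_moments(self.q, self.t, self.L)

    # -- sampling -------------------------------------------------------------

    def _grid(self, n: int = 2001) -> tuple[np.ndarray, np.ndarray]:
        x = np.linspace(0.0, 1.0, n)
        return x, self.pdf(x)

    def sample(self, n: int, rng: np.random.Generator,
               n_grid: int = 4001) -> np.ndarray:
        """Draw haploid proportions: point masses plus inverse-CDF continuous."""
        m0, m1 = self.mass_at_0, self.mass_at_1
        u = rng.random(n)
        out = np.empty(n)
        at0 = u < m0
        at1 = (u >= m0) & (u < m0 + m1)
        cont = ~(at0 | at1)
        out[at0] = 0.0
        out[at1] = 1.0
        k = int(cont.sum())
        if k:
            x, f = self._grid(n_grid)
            cdf = np.concatenate([[0.0], np.cumsum((f[1:] + f[:-1]) / 2.0
                                                   * np.diff(x))])
            cdf /= cdf[-1]
            out[cont] = np.interp(rng.random(k), cdf, x)
        return out


@dataclass
class DiploidPulseDensity:
    """Distribution of y = (x1 + x2)/2 for independent homologous chromosomes.

    Homologous chromosomes have independent histories, so the diploid
    proportion is the convolution of two haploid copies.  Delta x delta terms
    give point masses at y in {0, 1/2, 1}; delta x continuous terms give
    boundary-attached continuous components; the continuous x continuous term
    is evaluated by FFT convolution on a fixed grid.
    """

    q: float
    t: float
    L: float
    n_grid: int = 4001
    alpha_variant: str = "sqrt"
    norm_tol: float = 1e-5

    def __post_init__(self) -> None:
        if self.n_grid % 2 == 0:
            self.n_grid += 1  # need a grid point exactly at y = 1/2
        hap = PulseDensity(self.q, self.t, self.L, self.alpha_variant)
        self._hap = hap
        m0, m1 = hap.mass_at_0, hap.mass_at_1
        self.mass_at_0 = m0 * m0
        self.mass_at_1 = m1 * m1
        self.mass_at_half = 2.0 * m0 * m1

        n_hap = (self.n_grid + 1) // 2  # haploid grid; y-grid has 2*n_hap - 1
        x = np.linspace(0.0, 1.0, n_hap)
        dx = x[1] - x[0]
        f = hap.pdf(x)
        g = f.copy()
        g[0] *= 0.5
        g[-1] *= 0.5  # trapezoid end-weights for the convolution quadrature
        conv = fftconvolve(g, g) * dx          # density of s = x1 + x2 on [0, 2]
        y = np.arange(2 * n_hap - 1) * dx / 2.0
        pdf = 2.0 * conv                       # y = s/2
        # delta x continuous cross terms (factor 2 orderings, factor 2 Jacobian);
        # each is supported on half the range, so the pdf jumps at y = 1/2 —
        # the grid point there takes the mean of the one-sided limits so the
        # trapezoid rule stays second order across the jump
        mid = n_hap - 1  # index of y = 1/2
        left = 2.0 * y <= 1.0
        add = 4.0 * m0 * hap.pdf(2.0 * y[left])
        add[-1] *= 0.5
        pdf[left] += add
        right = 2.0 * y >= 1.0
        add = 4.0 * m1 * hap.pdf(2.0 * y[right] - 1.0)
        add[0] *= 0.5
        pdf[right] += add
        self._y = y
        self._pdf = np.maximum(pdf, 0.0)

        total = (self.mass_at_0 + self.mass_at_1 + self.mass_at_half
                 + np.trapezoid(self._pdf, self._y))
        self.total_mass = float(total)
        if abs(total - 1.0) > self.norm_tol:
            raise ValueError(
                f"diploid convolution grid too coarse: total mass {total:.8f} "
                f"misses 1 by more than {self.norm_tol}; increase n_grid")

    def pdf(self, y) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        if np.any((y < 0) | (y > 1)):
            raise ValueError("y must lie in [0, 1]")
        return np.interp(y, self._y, self._pdf)

    def variance(self) -> float:
        mean = (self.mass_at_1 + 0.5 * self.mass_at_half
                + np.trapezoid(self._y * self._pdf, self._y))
        m2 = (self.mass_at_1 + 0.25 * self.mass_at_half
              + np.trapezoid(self._y ** 2 * self._pdf, self._y))
        return float(m2 - mean ** 2)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        x1 = self._hap.sample(n, rng)
        x2 = self._hap.sample(n, rng)
        return (x1 + x2) / 2.0


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def ancestry_density(x, q: float, t: float, L: float,
                     alpha_variant: str = "sqrt"):
    """(mass_at_0, mass_at_1, continuous density at x) for the haploid law."""
    d = PulseDensity(q, t, L, alpha_variant)
    return d.mass_at_0, d.mass_at_1, d.pdf(x)


def diploid_density(y, q: float, t: float, L: float, n_grid: int = 4001,
                    alpha_variant: str = "sqrt"):
    """(point masses at {0, 1/2, 1}, continuous density at y) for diploids."""
    d = DiploidPulseDensity(q, t, L, n_grid=n_grid, alpha_variant=alpha_variant)
    masses = {0.0: d.mass_at_0, 0.5: d.mass_at_half, 1.0: d.mass_at_1}
    return masses, d.pdf(y)
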