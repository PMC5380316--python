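"""IBD ancestry-matrix deconvolution.

Long IBD segments shared within a founder population mostly coalesce at the
founder bottleneck, so their ancestry reflects the gene pool at that time.
Each shared segment involves three independent chromosomes — the shared
haplotype plus one other per individual — so the 3x3 matrix of cM-weighted
diploid-ancestry states (hom-EU, het, hom-ME) over IBD segments has a
characteristic structure: truly IBD, correctly labelled material follows
A_IBD(f_EU, p_EU) whose (hom-EU, hom-ME) corners are exactly zero, while
falsely detected or mislabelled material follows the independent-haplotype
matrix A_rand(p_EU).  The observed matrix is the mixture

    A_obs = lambda * A_IBD + (1 - lambda) * A_rand,

so the corner occupancy measures the noise fraction 1 - lambda directly, and
the de-noised matrix yields f_EU (the EU fraction at the bottleneck) by an
L1 fit.  The post-bottleneck EU replacement then follows from
p_EU = mu_EU + (1 - mu_EU) f_EU.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .sim import IBD_STATES

__all__ = [
    "trim_segment", "trim_segments", "diploid_state",
    "ancestry_matrix_from_states", "observed_ancestry_matrix",
    "rand_matrix", "ibd_matrix", "estimate_noise",
    "estimate_bottleneck_ancestry", "post_bottleneck_fraction",
    "IBDAncestryDeconvolution",
]

_HOM_EU, _HET, _HOM_ME = 0, 1, 2


# ---------------------------------------------------------------------------
# segments
# ---------------------------------------------------------------------------

@dataclass
class IBDSegment:
    id1: str
    id2: str
    chrom: str
    start_cm: float
    end_cm: float

    @property
    def length_cm(self) -> float:
        return self.end_cm - self.start_cm


def trim_segment(seg: IBDSegment, trim_cm: float = 0.25) -> IBDSegment:
    """Trim ``trim_cm`` from each end (boundary misidentification guard)."""
    if seg.length_cm <= 2 * trim_cm:
        raise ValueError(
            f"segment of length {seg.length_cm:.3f} cM shorter than twice "
            f"the trim {trim_cm} cM")
    return IBDSegment(seg.id1, seg.id2, seg.chrom,
                      seg.start_cm + trim_cm, seg.end_cm - trim_cm)


def trim_segments(segments: pd.DataFrame, trim_cm: float = 0.25,
                  ) -> tuple[pd.DataFrame, int]:
    """Trim a segment table (columns start_cm, end_cm); drop short segments.

    Returns the trimmed table and the number of dropped segments.
    """
    keep = (segments["end_cm"] - segments["start_cm"]) > 2 * trim_cm
    out = segments.loc[keep].copy()
    out["start_cm"] = out["start_cm"] + trim_cm
    out["end_cm"] = out["end_cm"] - trim_cm
    return out, int((~keep).sum())


def diploid_state(label1: str, label2: str) -> str:
    """Diploid ancestry state from two haplotype labels in {EU, ME}."""
    for lab in (label1, label2):
        if lab not in ("EU", "ME"):
            raise ValueError(f"unknown ancestry label {lab!r}")
    n_eu = (label1 == "EU") + (label2 == "EU")
    return IBD_STATES[2 - n_eu]


# ---------------------------------------------------------------------------
# matrices
# ---------------------------------------------------------------------------

def _normalize_symmetrize(A: np.ndarray) -> np.ndarray:
    A = (A + A.T) / 2.0  # pair order is arbitrary
    total = A.sum()
    if total <= 0:
        raise ValueError("no segment material accumulated")
    return A / total


def ancestry_matrix_from_states(lengths_cm: np.ndarray, state1: np.ndarray,
                                state2: np.ndarray) -> np.ndarray:
    """A_obs from per-segment diploid states, cM-weighted and symmetrized."""
    A = np.zeros((3, 3))
    np.add.at(A, (np.asarray(state1, dtype=int), np.asarray(state2, dtype=int)),
              np.asarray(lengths_cm, dtype=float))
    return _normalize_symmetrize(A)


def observed_ancestry_matrix(segments: pd.DataFrame,
                             diploid_states: dict[str, dict[str, np.ndarray]],
                             positions_cm: dict[str, np.ndarray],
                             trim_cm: float = 0.25) -> tuple[np.ndarray, int]:
    """A_obs from segments plus per-SNP diploid ancestry states.

    ``segments`` needs columns id1, id2, chrom, start_cm, end_cm.
    ``diploid_states[individual][chrom]`` is the per-SNP state code array
    (0 hom-EU, 1 het, 2 hom-ME) aligned with ``positions_cm[chrom]``.  Each
    SNP inside the trimmed span contributes its local cM spacing as weight.
    Segments without ancestry coverage are excluded and counted.
    """
    trimmed, _ = trim_segments(segments, trim_cm)
    A = np.zeros((3, 3))
    excluded = 0
    spacing = {}
    for chrom, pos in positions_cm.items():
        if pos.size < 2:
            spacing[chrom] = np.ones(pos.size)
            continue
        d = np.diff(pos)
        w = np.empty(pos.size)
        w[0] = d[0] / 2.0
        w[-1] = d[-1] / 2.0
        if pos.size > 2:
            w[1:-1] = (d[:-1] + d[1:]) / 2.0
        spacing[chrom] = w
    for row in trimmed.itertuples(index=False):
        pos = positions_cm.get(row.chrom)
        if pos is None:
            excluded += 1
            continue
        i0 = int(np.searchsorted(pos, row.start_cm, side="left"))
        i1 = int(np.searchsorted(pos, row.end_cm, side="right"))
        if i1 <= i0 or row.id1 not in diploid_states or \
                row.id2 not in diploid_states:
            excluded += 1
            continue
        s1 = diploid_states[row.id1][row.chrom][i0:i1]
        s2 = diploid_states[row.id2][row.chrom][i0:i1]
        np.add.at(A, (s1.astype(int), s2.astype(int)),
                  spacing[row.chrom][i0:i1])
    return _normalize_symmetrize(A), excluded


def rand_matrix(p_eu: float) -> np.ndarray:
    """Expected ancestry matrix for independent haplotypes (noise regime)."""
    if not (0.0 <= p_eu <= 1.0):
        raise ValueError("p_eu must lie in [0, 1]")
    p, u = p_eu, 1.0 - p_eu
    g = np.array([p * p, 2 * p * u, u * u])  # diploid state probabilities
    return np.outer(g, g)


def ibd_matrix(f_eu: float, p_eu: float) -> np.ndarray:
    """Expected ancestry matrix for true IBD material.

    The shared haplotype is EU with probability f_eu; each individual's other
    haplotype is EU with probability p_eu.  The (hom-EU, hom-ME) corners are
    structurally zero.
    """
    for name, v in (("f_eu", f_eu), ("p_eu", p_eu)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1]")
    f, p = f_eu, p_eu
    u = 1.0 - p
    return np.array([
        [f * p * p,      f * p * u,                          0.0],
        [f * p * u,      f * u * u + (1 - f) * p * p,        (1 - f) * p * u],
        [0.0,            (1 - f) * p * u,                    (1 - f) * u * u],
    ])


# ---------------------------------------------------------------------------
# estimation
# ---------------------------------------------------------------------------

def estimate_noise(A_obs: np.ndarray, p_eu: float) -> tuple[float, bool]:
    """Noise-complement lambda from the (hom-EU, hom-ME) corner occupancy.

    True IBD material cannot occupy the corner, so
    lambda = 1 - corner(A_obs)/corner(A_rand), using the symmetrized corner.
    Returns (lambda clamped to [0, 1], clamped flag).
    """
    if not (0.0 < p_eu < 1.0):
        raise ValueError("corner of A_rand vanishes for p_eu in {0, 1}")
    corner_obs = (A_obs[_HOM_EU, _HOM_ME] + A_obs[_HOM_ME, _HOM_EU]) / 2.0
    corner_rand = rand_matrix(p_eu)[_HOM_EU, _HOM_ME]
    lam = 1.0 - corner_obs / corner_rand
    clamped = not (0.0 <= lam <= 1.0)
    return float(np.clip(lam, 0.0, 1.0)), clamped


def estimate_bottleneck_ancestry(A_obs: np.ndarray, lam: float, p_eu: float,
                                 f_grid: np.ndarray | None = None,
                                 cell_weights: np.ndarray | None = None,
                                 ) -> tuple[float, dict]:
    """EU ancestry fraction at the bottleneck by L1 fit of the de-noised matrix.

    The empirical A_IBD = (A_obs - (1-lambda) A_rand)/lambda (negative
    entries clamped to zero, flagged) is matched to the theoretical
    ibd_matrix(f, p_eu) over ``f_grid`` (default step 0.001) by the sum of
    absolute entry differences, optionally cell-weighted.
    """
    if lam <= 0.0:
        raise ValueError("lambda = 0: bottleneck ancestry non-identifiable")
    if f_grid is None:
        f_grid = np.round(np.arange(0.0, 1.0005, 0.001), 6)
    emp = (A_obs - (1.0 - lam) * rand_matrix(p_eu)) / lam
    clamped_mass = float(-emp[emp < 0].sum())
    emp = np.maximum(emp, 0.0)
    diag = {"clamped_mass": clamped_mass, "unstable": clamped_mass > 0.02}
    if diag["unstable"]:
        warnings.warn(
            f"clamped negative mass {clamped_mass:.3f} exceeds 2%: "
            "the deconvolution is unstable", stacklevel=2)
    w = np.ones((3, 3)) if cell_weights is None else np.asarray(cell_weights)
    dists = [float((w * np.abs(emp - ibd_matrix(float(f), p_eu))).sum())
             for f in f_grid]
    best = int(np.argmin(dists))
    diag["l1_distance"] = dists[best]
    return float(f_grid[best]), diag


def post_bottleneck_fraction(p_eu: float, f_eu: float) -> float:
    """Post-bottleneck EU replacement mu from p = mu + (1 - mu) f."""
    if f_eu >= 1.0:
        raise ValueError("f_eu = 1: replacement fraction undefined")
    mu = (p_eu - f_eu) / (1.0 - f_eu)
    if mu < 0:
        warnings.warn(
            f"f_eu = {f_eu} exceeds p_eu = {p_eu}: negative replacement "
            "(model violation)", stacklevel=2)
    return mu


class IBDAncestryDeconvolution(BaseEstimator):
    """Estimate (lambda, f_EU, mu_EU) from an IBD segment-ancestry table.

    Parameters
    ----------
    p_eu
        Genome-wide EU ancestry fraction (an input from upstream LAI; never
        re-estimated here).
    trim_cm
        Trimmed from each segment end before weighting (default 0.25 cM).
    length_range_cm
        Optional (lo, hi) stratum filter on the untrimmed segment length;
        ``None`` keeps all segments.

    ``fit`` accepts a DataFrame with columns length_cm, state1, state2
    (per-segment diploid state codes).  Attributes: ``A_obs_``, ``lambda_``,
    ``f_eu_``, ``mu_eu_``, ``diagnostics_``.
    """

    def __init__(self, p_eu: float = 0.53, trim_cm: float = 0.25,
                 length_range_cm: tuple[float, float] | None = None,
                 f_grid=None):
        self.p_eu = p_eu
        self.trim_cm = trim_cm
        self.length_range_cm = length_range_cm
        self.f_grid = f_grid

    def fit(self, X: pd.DataFrame, y=None) -> "IBDAncestryDeconvolution":
        df = X
        if self.length_range_cm is not None:
            lo, hi = self.length_range_cm
            df = df[(df["length_cm"] >= lo) & (df["length_cm"] <= hi)]
        lengths = df["length_cm"].to_numpy() - 2 * self.trim_cm
        keep = lengths > 0
        self.n_dropped_ = int((~keep).sum())
        self.A_obs_ = ancestry_matrix_from_states(
            lengths[keep], df["state1"].to_numpy()[keep],
            df["state2"].to_numpy()[keep])
        self.lambda_, lam_clamped = estimate_noise(self.A_obs_, self.p_eu)
        self.f_eu_, diag = estimate_bottleneck_ancestry(
            self.A_obs_, self.lambda_, self.p_eu, self.f_grid)
        self.mu_eu_ = post_bottleneck_fraction(self.p_eu, self.f_eu_)
        diag["lambda_clamped"] = lam_clamped
        self.diagnostics_ = diag
        return self

    def ancestry_quality_diagnostic(self, X: pd.DataFrame,
                                    quality_col: str) -> float:
        """Correlation between a segment's ME-ancestry share and a quality
        covariate (reported, not acted on)."""
        me_share = (X["state1"].to_numpy() + X["state2"].to_numpy()) / 4.0
        return float(np.corrcoef(me_share, X[quality_col].to_numpy())[0, 1])
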