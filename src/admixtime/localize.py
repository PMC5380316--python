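"""Naive-Bayes geographic localization of ancestry-masked chromosomes.

After local ancestry deconvolution, each haploid chromosome's segments of a
target continental ancestry are compared against regional allele-frequency
panels: the log-likelihood of the masked-in alleles is a sum of per-SNP
log frequencies (valid after LD thinning), and the inferred source is the
region maximizing it.  Cohort-level classified-chromosome proportions are a
summary statistic, NOT ancestry proportions; actual ancestry proportions are
recovered separately by matching the observed classified proportions to
simulated admixed cohorts over a grid (``match_mixture_proportions``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from sklearn.base import BaseEstimator

__all__ = [
    "ld_thin", "region_frequencies", "classify_masked_chromosome",
    "cohort_classification_proportions", "match_mixture_proportions",
    "ChromosomeClassification", "NaiveBayesAncestryLocalizer",
]


def ld_thin(haplotypes: np.ndarray, positions_cm: np.ndarray,
            r2_max: float = 0.2, window_cm: float = 1.0,
            window_snps: int = 250) -> tuple[np.ndarray, int]:
    """Greedy left-to-right LD thinning.

    A SNP is dropped if its squared correlation with any retained SNP within
    the window exceeds ``r2_max``.  The window is the larger of ``window_cm``
    and the span of the last ``window_snps`` retained SNPs.  Monomorphic SNPs
    are dropped and counted.  Deterministic given input order.

    Returns (retained indices, number of monomorphic SNPs dropped).
    """
    X = np.asarray(haplotypes, dtype=float)
    positions_cm = np.asarray(positions_cm, dtype=float)
    n_hap, n_snp = X.shape
    sd = X.std(axis=0)
    mono = sd == 0
    Z = np.zeros_like(X)
    ok = ~mono
    Z[:, ok] = (X[:, ok] - X[:, ok].mean(axis=0)) / sd[ok]

    # window = last `window_snps` retained SNPs, or all retained within
    # `window_cm`, whichever reaches further back
    retained: list[int] = []
    ret_pos: list[float] = []
    for j in range(n_snp):
        if mono[j]:
            continue
        if retained:
            k_cm = int(np.searchsorted(ret_pos, positions_cm[j] - window_cm))
            k0 = min(len(retained) - window_snps, k_cm)
            cand = retained[max(k0, 0):]
            r = Z[:, cand].T @ Z[:, j] / n_hap
            if np.any(r * r > r2_max):
                continue
        retained.append(j)
        ret_pos.append(float(positions_cm[j]))
    return np.asarray(retained, dtype=int), int(mono.sum())


def region_frequencies(panels: dict[str, np.ndarray],
                       retained_idx: np.ndarray | None = None,
                       pseudocount: float = 0.5) -> dict[str, np.ndarray]:
    """Smoothed alternate-allele frequencies per region on the retained SNPs.

    freq = (alt count + pseudocount) / (n_haplotypes + 2 * pseudocount),
    which keeps frequencies away from 0 and 1 whenever pseudocount > 0.
    """
    out = {}
    for region, haps in panels.items():
        haps = np.asarray(haps)
        if haps.shape[0] < 1:
            raise ValueError(f"region {region!r} has no haplotypes")
        if retained_idx is not None:
            haps = haps[:, retained_idx]
        n = haps.shape[0]
        out[region] = (haps.sum(axis=0) + pseudocount) / (n + 2 * pseudocount)
    return out


@dataclass
class ChromosomeClassification:
    hap_id: str
    chrom: str
    loglik: dict[str, float]
    region: str | None
    n_snps_used: int
    tie: bool = False


def classify_masked_chromosome(alleles: np.ndarray, mask: np.ndarray,
                               freqs: dict[str, np.ndarray],
                               region_order: Sequence[str] | None = None,
                               hap_id: str = "", chrom: str = "",
                               ) -> ChromosomeClassification:
    """Classify the masked-in part of one haploid chromosome.

    ``alleles`` are 0/1 calls on the retained SNP set of this chromosome;
    ``mask`` marks which of those SNPs carry the target continental ancestry.
    Per region, the log-likelihood is the sum over masked-in SNPs of
    log(freq) for alternate alleles and log(1 - freq) for reference alleles.
    Ties are broken by the fixed region order and flagged.
    """
    alleles = np.asarray(alleles)
    mask = np.asarray(mask, dtype=bool)
    if region_order is None:
        region_order = list(freqs)
    a = alleles[mask].astype(float)
    n_used = int(mask.sum())
    if n_used == 0:
        return ChromosomeClassification(hap_id, chrom,
                                        {r: np.nan for r in region_order},
                                        None, 0)
    ll = {}
    for region in region_order:
        f = np.asarray(freqs[region])[mask]
        ll[region] = float((a * np.log(f) + (1 - a) * np.log(1 - f)).sum())
    vals = np.array([ll[r] for r in region_order])
    best = int(np.argmax(vals))
    tie = bool(np.sum(vals == vals[best]) > 1)
    return ChromosomeClassification(hap_id, chrom, ll,
                                    region_order[best], n_used, tie)


def cohort_classification_proportions(
        classifications: list[ChromosomeClassification],
        region_order: Sequence[str] | None = None) -> dict[str, float]:
    """Fraction of classifiable haploid chromosomes assigned to each region."""
    usable = [c for c in classifications if c.region is not None]
    if not usable:
        raise ValueError("no classifiable chromosome")
    if region_order is None:
        region_order = list(usable[0].loglik)
    counts = {r: 0 for r in region_order}
    for c in usable:
        counts[c.region] += 1
    n = len(usable)
    return {r: counts[r] / n for r in region_order}


@dataclass
class MixtureMatch:
    proportions: dict[str, float]
    distance: float
    grid_distances: list[tuple[dict[str, float], float]]
    extrapolation: bool


def match_mixture_proportions(
        observed: dict[str, float],
        mixture_family: Callable[[dict[str, float], int], dict[str, float]],
        search_grid: Sequence[dict[str, float]],
        seed: int = 0, replicates: int = 1) -> MixtureMatch:
    """Grid-search the ancestry proportions whose simulated classified-
    chromosome proportions best match the observed vector (squared distance).

    ``mixture_family(proportions, seed)`` runs the full pipeline (simulate ->
    degrade calls -> classify) and returns a classified-proportion vector.
    Supports staged scans: the grid is whatever the caller enumerates.
    """
    search_grid = list(search_grid)
    if not search_grid:
        raise ValueError("empty search grid")
    keys = list(observed)
    obs = np.array([observed[k] for k in keys])
    children = np.random.SeedSequence(seed).spawn(len(search_grid))
    results = []
    sim_vectors = []
    for props, child in zip(search_grid, children):
        reps = []
        for s in child.spawn(replicates):
            vec = mixture_family(props, int(s.generate_state(1)[0] % (2 ** 31)))
            reps.append([vec.get(k, 0.0) for k in keys])
        mean_vec = np.mean(reps, axis=0)
        sim_vectors.append(mean_vec)
        results.append((props, float(((mean_vec - obs) ** 2).sum())))
    sims = np.asarray(sim_vectors)
    extrap = bool(np.any(obs < sims.min(axis=0) - 1e-12) or
                  np.any(obs > sims.max(axis=0) + 1e-12))
    best = min(results, key=lambda pr: pr[1])
    return MixtureMatch(proportions=dict(best[0]), distance=best[1],
                        grid_distances=results, extrapolation=extrap)


class NaiveBayesAncestryLocalizer(BaseEstimator):
    """Per-chromosome naive-Bayes source-region classifier.

    ``fit`` takes regional reference panels (dict region -> (n_hap, n_snps)
    0/1 haplotypes) with SNP positions, thins SNPs for linkage equilibrium,
    optionally balances panel sizes by down-sampling, and stores smoothed
    regional allele frequencies.  ``predict`` classifies haploid chromosomes
    given an ancestry mask on the same SNP set.

    Attributes (after ``fit``): ``retained_idx_``, ``freqs_``, ``regions_``,
    ``n_monomorphic_``.
    """

    def __init__(self, r2_max: float = 0.2, window_cm: float = 1.0,
                 window_snps: int = 250, pseudocount: float = 0.5,
                 balance: bool = True, seed: int = 0):
        self.r2_max = r2_max
        self.window_cm = window_cm
        self.window_snps = window_snps
        self.pseudocount = pseudocount
        self.balance = balance
        self.seed = seed

    def fit(self, panels: dict[str, np.ndarray],
            positions_cm: np.ndarray) -> "NaiveBayesAncestryLocalizer":
        rng = np.random.default_rng(self.seed)
        panels = {r: np.asarray(h) for r, h in panels.items()}
        if self.balance:
            n_min = min(h.shape[0] for h in panels.values())
            panels = {r: h[rng.choice(h.shape[0], n_min, replace=False)]
                      if h.shape[0] > n_min else h
                      for r, h in panels.items()}
        pooled = np.concatenate(list(panels.values()), axis=0)
        self.retained_idx_, self.n_monomorphic_ = ld_thin(
            pooled, positions_cm, self.r2_max, self.window_cm,
            self.window_snps)
        self.freqs_ = region_frequencies(panels, self.retained_idx_,
                                         self.pseudocount)
        self.regions_ = list(panels)
        return self

    def predict(self, haplotypes: np.ndarray,
                masks: np.ndarray | None = None,
                hap_ids: Sequence[str] | None = None,
                chrom: str = "") -> list[ChromosomeClassification]:
        """Classify each haploid chromosome row (alleles on the full SNP set).

        ``masks`` (same shape) marks target-ancestry SNPs; ``None`` uses all.
        """
        haplotypes = np.atleast_2d(np.asarray(haplotypes))
        if masks is None:
            masks = np.ones_like(haplotypes, dtype=bool)
        masks = np.atleast_2d(np.asarray(masks, dtype=bool))
        out = []
        for i in range(haplotypes.shape[0]):
            out.append(classify_masked_chromosome(
                haplotypes[i, self.retained_idx_],
                masks[i, self.retained_idx_],
                self.freqs_, self.regions_,
                hap_id=hap_ids[i] if hap_ids else str(i), chrom=chrom))
        return out

    def predict_proportions(self, haplotypes: np.ndarray,
                            masks: np.ndarray | None = None) -> dict[str, float]:
        return cohort_classification_proportions(
            self.predict(haplotypes, masks), self.regions_)
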