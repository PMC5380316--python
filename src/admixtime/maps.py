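"""Genetic maps in centimorgan coordinates.

All internal coordinates are cM, 0-based, with half-open segment intervals
[start, end).  Conversions to Morgans divide by 100, matching the convention
that a pulse admixture G generations ago produces ancestry tract lengths that
are exponential with rate G/100 per cM (i.e. rate G per Morgan).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Sex-averaged autosomal genetic lengths (cM), published-style values.
DEFAULT_AUTOSOME_CM: dict[str, float] = {
    "1": 286.3, "2": 268.6, "3": 223.4, "4": 214.6, "5": 204.1,
    "6": 192.0, "7": 187.2, "8": 168.0, "9": 166.4, "10": 181.1,
    "11": 158.2, "12": 174.7, "13": 125.9, "14": 120.2, "15": 141.9,
    "16": 134.0, "17": 128.5, "18": 117.9, "19": 107.9, "20": 108.3,
    "21": 62.8, "22": 74.1,
}


@dataclass
class GeneticMap:
    """Per-chromosome genetic lengths and (optionally) SNP positions.

    Parameters
    ----------
    lengths_cm
        Mapping of chromosome id to genetic length in cM.
    positions_cm
        Optional mapping of chromosome id to a strictly increasing array of
        SNP positions in cM.
    positions_bp
        Optional physical positions (1-based bp, PLINK convention), aligned
        with ``positions_cm``.
    snp_ids
        Optional SNP identifiers aligned with ``positions_cm``.
    """

    lengths_cm: dict[str, float]
    positions_cm: dict[str, np.ndarray] = field(default_factory=dict)
    positions_bp: dict[str, np.ndarray] = field(default_factory=dict)
    snp_ids: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, L in self.lengths_cm.items():
            if L <= 0:
                raise ValueError(f"chromosome {chrom}: non-positive length {L}")
        for chrom, pos in self.positions_cm.items():
            pos = np.asarray(pos, dtype=float)
            self.positions_cm[chrom] = pos
            if pos.size and np.any(np.diff(pos) <= 0):
                bad = int(np.flatnonzero(np.diff(pos) <= 0)[0]) + 1
                raise ValueError(
                    f"chromosome {chrom}: positions not strictly increasing "
                    f"at index {bad}"
                )
            if pos.size and (pos[0] < 0 or pos[-1] > self.lengths_cm[chrom]):
                raise ValueError(
                    f"chromosome {chrom}: SNP positions outside [0, L]"
                )

    @classmethod
    def default(cls) -> "GeneticMap":
        """The 22 autosomes with the shipped default lengths, no SNPs."""
        return cls(lengths_cm=dict(DEFAULT_AUTOSOME_CM))

    @classmethod
    def uniform(cls, lengths_cm: dict[str, float], snps_per_cm: float = 1.0,
                offset: float = 0.0) -> "GeneticMap":
        """A map with evenly spaced SNPs, handy for simulation."""
        positions = {}
        for chrom, L in lengths_cm.items():
            n = max(int(round(L * snps_per_cm)), 1)
            positions[chrom] = np.linspace(offset, L - offset, n) if n > 1 \
                else np.array([L / 2.0])
        return cls(lengths_cm=dict(lengths_cm), positions_cm=positions)

    @property
    def chromosomes(self) -> list[str]:
        return list(self.lengths_cm)

    def length_morgans(self, chrom: str) -> float:
        return self.lengths_cm[chrom] / 100.0

    @property
    def lengths_morgans(self) -> np.ndarray:
        return np.array([L / 100.0 for L in self.lengths_cm.values()])

    @property
    def total_cm(self) -> float:
        return float(sum(self.lengths_cm.values()))

    def n_snps(self, chrom: str | None = None) -> int:
        if chrom is not None:
            return int(self.positions_cm[chrom].size)
        return int(sum(p.size for p in self.positions_cm.values()))

    def interpolate_cm(self, chrom: str, bp: np.ndarray) -> np.ndarray:
        """Linear bp -> cM interpolation from the SNP grid of `chrom`."""
        if chrom not in self.positions_bp or not len(self.positions_bp[chrom]):
            raise ValueError(f"chromosome {chrom} has no bp positions")
        return np.interp(np.asarray(bp, dtype=float),
                         np.asarray(self.positions_bp[chrom], dtype=float),
                         self.positions_cm[chrom])
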