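"""Ancestry tracks: per-haplotype mosaics of ancestry segments.

A track stores, for each chromosome, the ordered segment end positions (cM)
and integer label codes indexing into a shared label set.  Segments are
half-open [start, end) and tile the chromosome exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .maps import GeneticMap

_TILING_TOL = 1e-9


@dataclass
class AncestryTrack:
    """One haploid genome as an ordered ancestry mosaic."""

    hap_id: str
    label_set: tuple[str, ...]
    # chrom -> cumulative segment end positions (last entry == chrom length)
    chrom_ends: dict[str, np.ndarray]
    # chrom -> per-segment label codes (same length as chrom_ends)
    chrom_labels: dict[str, np.ndarray]

    def validate(self, gmap: GeneticMap) -> None:
        for chrom, ends in self.chrom_ends.items():
            L = gmap.lengths_cm[chrom]
            if abs(float(ends[-1]) - L) > _TILING_TOL:
                raise ValueError(
                    f"{self.hap_id}/{chrom}: segments end at {ends[-1]}, "
                    f"chromosome length is {L}"
                )
            if np.any(np.diff(np.concatenate([[0.0], ends])) <= 0):
                raise ValueError(f"{self.hap_id}/{chrom}: non-positive segment")

    def segments(self) -> Iterator[tuple[str, float, float, str]]:
        """Yield (chrom, start_cM, end_cM, label) in order."""
        for chrom, ends in self.chrom_ends.items():
            start = 0.0
            for end, code in zip(ends, self.chrom_labels[chrom]):
                yield chrom, start, float(end), self.label_set[int(code)]
                start = float(end)

    # -- ancestry proportions -------------------------------------------------

    def chrom_fraction(self, label: str) -> dict[str, float]:
        """Fraction of each chromosome's length carrying `label`."""
        code = self.label_set.index(label)
        out = {}
        for chrom, ends in self.chrom_ends.items():
            lengths = np.diff(np.concatenate([[0.0], ends]))
            out[chrom] = float(
                lengths[self.chrom_labels[chrom] == code].sum() / ends[-1]
            )
        return out

    def fraction(self, label: str) -> float:
        """Genome-wide fraction of total length carrying `label`."""
        code = self.label_set.index(label)
        tot = num = 0.0
        for chrom, ends in self.chrom_ends.items():
            lengths = np.diff(np.concatenate([[0.0], ends]))
            num += float(lengths[self.chrom_labels[chrom] == code].sum())
            tot += float(ends[-1])
        return num / tot

    # -- per-SNP view ---------------------------------------------------------

    def labels_at(self, chrom: str, positions_cm: np.ndarray) -> np.ndarray:
        """Label code at each query position (segments are [start, end))."""
        ends = self.chrom_ends[chrom]
        idx = np.searchsorted(ends, positions_cm, side="right")
        idx = np.minimum(idx, len(ends) - 1)  # position == chrom end
        return self.chrom_labels[chrom][idx]

    # -- run lengths ----------------------------------------------------------

    def run_lengths(self, label: str, with_censoring: bool = False):
        """Lengths (cM) of maximal runs of `label`, merging adjacent pieces.

        Runs touching a chromosome end are included (truncated by the end).
        With ``with_censoring=True`` also returns a boolean array marking
        runs that ended with an ancestry switch (runs cut by the chromosome
        end are right-censored; for exponential tract lengths a run starting
        at the origin is a fresh draw by memorylessness).
        """
        code = self.label_set.index(label)
        runs: list[float] = []
        complete: list[bool] = []
        for chrom, ends in self.chrom_ends.items():
            lengths = np.diff(np.concatenate([[0.0], ends]))
            is_lab = self.chrom_labels[chrom] == code
            acc = 0.0
            for seg_len, hit in zip(lengths, is_lab):
                if hit:
                    acc += float(seg_len)
                elif acc > 0:
                    runs.append(acc)
                    complete.append(True)  # ended by a switch
                    acc = 0.0
            if acc > 0:  # run cut by the chromosome end
                runs.append(acc)
                complete.append(False)
        if with_censoring:
            return np.array(runs), np.array(complete, dtype=bool)
        return np.array(runs)


def merge_adjacent(ends: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge consecutive segments sharing a label code."""
    if len(labels) <= 1:
        return ends, labels
    keep = np.concatenate([labels[1:] != labels[:-1], [True]])
    return ends[keep], labels[keep]


def mean_run_length(tracks: list[AncestryTrack], label: str,
                    method: str = "censored_mle") -> float:
    """Mean maximal-run length (cM) of `label` across a track collection.

    ``censored_mle`` treats runs cut by a chromosome end as right-censored
    exponential observations (estimate = total run length / number of
    complete runs), removing the edge-truncation bias of the naive mean.
    ``naive`` averages all observed run lengths as-is.
    """
    res = [t.run_lengths(label, with_censoring=True) for t in tracks]
    runs = np.concatenate([r[0] for r in res])
    complete = np.concatenate([r[1] for r in res])
    if method == "naive":
        return float(runs.mean())
    if method != "censored_mle":
        raise ValueError(f"unknown method {method!r}")
    n_complete = int(complete.sum())
    if n_complete == 0:
        raise ValueError("no complete runs: cannot estimate mean length")
    return float(runs.sum() / n_complete)


def haploid_fractions(tracks: list[AncestryTrack], label: str) -> np.ndarray:
    """(n_tracks, n_chrom) matrix of per-chromosome fractions of `label`."""
    chroms = list(tracks[0].chrom_ends)
    out = np.empty((len(tracks), len(chroms)))
    for i, t in enumerate(tracks):
        fr = t.chrom_fraction(label)
        out[i] = [fr[c] for c in chroms]
    return out
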