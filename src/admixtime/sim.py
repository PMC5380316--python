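"""Synthetic-data generators for the admixture-inference pipeline.

Everything the downstream estimators consume can be generated here with
known ground truth: admixed ancestry mosaics (single pulse or two waves),
painted haplotypes from regional reference panels, forward Wright--Fisher
ancestry evolution, local-ancestry call noise, Balding--Nichols reference
panels, and IBD cohorts with a planted ancestry structure.

Lengths are in cM throughout; a pulse G generations ago yields tract lengths
that are exponential with rate G/100 per cM.  Mosaic pieces receive i.i.d.
source labels, so maximal same-label runs are themselves exponential (rate
q*t per Morgan for the minor source when the major source has weight q).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .maps import GeneticMap
from .models import PulseModel, TwoWaveModel
from .tracks import AncestryTrack, merge_adjacent


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeMatrix:
    """Phased 0/1 haplotypes aligned to the SNP grid of a GeneticMap."""

    gmap: GeneticMap
    data: dict[str, np.ndarray]  # chrom -> (n_hap, n_snps) uint8
    hap_ids: list[str]

    @property
    def n_haplotypes(self) -> int:
        return len(self.hap_ids)

    def stacked(self) -> np.ndarray:
        """(n_hap, total_snps) concatenation over chromosomes, in map order."""
        return np.concatenate(
            [self.data[c] for c in self.gmap.chromosomes if c in self.data],
            axis=1,
        )


@dataclass
class AncestryCallTable:
    """Per-SNP, per-haplotype ancestry label codes (an LAI-style table)."""

    gmap: GeneticMap
    label_set: tuple[str, ...]
    calls: dict[str, np.ndarray]  # chrom -> (n_hap, n_snps) int8
    hap_ids: list[str]

    def accuracy_vs(self, other: "AncestryCallTable") -> float:
        num = tot = 0
        for chrom, mine in self.calls.items():
            num += int((mine == other.calls[chrom]).sum())
            tot += mine.size
        return num / tot

    def snp_fractions(self, label: str) -> np.ndarray:
        """(n_hap, n_chrom) per-chromosome fraction of SNPs called `label`."""
        code = self.label_set.index(label)
        cols = [(self.calls[c] == code).mean(axis=1)
                for c in self.gmap.chromosomes if c in self.calls]
        return np.stack(cols, axis=1)

    def mean_run_length_cm(self, chrom_weights: bool = True) -> float:
        """Mean length (cM) of maximal same-label SNP runs across haplotypes."""
        runs: list[float] = []
        for chrom, calls in self.calls.items():
            pos = self.gmap.positions_cm[chrom]
            for row in calls:
                change = np.flatnonzero(row[1:] != row[:-1])
                bounds = np.concatenate([[0], change + 1, [len(row)]])
                for a, b in zip(bounds[:-1], bounds[1:]):
                    runs.append(float(pos[b - 1] - pos[a]))
        return float(np.mean(runs))


def truth_call_table(tracks: list[AncestryTrack], gmap: GeneticMap) -> AncestryCallTable:
    """Per-SNP true labels of a track collection on the map's SNP grid."""
    label_set = tracks[0].label_set
    calls = {}
    for chrom in gmap.chromosomes:
        pos = gmap.positions_cm.get(chrom)
        if pos is None or pos.size == 0:
            continue
        calls[chrom] = np.stack(
            [t.labels_at(chrom, pos).astype(np.int8) for t in tracks]
        )
    return AncestryCallTable(gmap=gmap, label_set=label_set, calls=calls,
                             hap_ids=[t.hap_id for t in tracks])


# ---------------------------------------------------------------------------
# pulse mosaics
# ---------------------------------------------------------------------------

def _mosaic_chromosome(L_cm: float, rate_per_cm: float, weights: np.ndarray,
                       rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Sequential exponential mosaic; the last piece is truncated at L."""
    mean_len = 1.0 / rate_per_cm
    ends: list[np.ndarray] = []
    total = 0.0
    while total < L_cm:
        n = max(int((L_cm - total) / mean_len * 1.5) + 8, 8)
        chunk = rng.exponential(mean_len, size=n)
        ends.append(chunk)
        total += float(chunk.sum())
    lens = np.concatenate(ends)
    cum = np.cumsum(lens)
    k = int(np.searchsorted(cum, L_cm)) + 1
    cum = cum[:k]
    cum[-1] = L_cm  # truncate the final piece
    labels = rng.choice(len(weights), size=k, p=weights).astype(np.int8)
    return cum, labels


def simulate_pulse_tracks(gmap: GeneticMap,
                          model: PulseModel | dict[str, float],
                          n_haploid: int,
                          seed: int | np.random.Generator,
                          t: float | None = None) -> list[AncestryTrack]:
    """Simulate haploid ancestry mosaics under a single admixture pulse.

    Each chromosome is a sequential mosaic: piece lengths are exponential
    with rate G/100 per cM (G = admixture time, generations) and each piece's
    source label is drawn independently with the source weights.  The first
    post-admixture generation, during which sources do not yet mix, is
    neglected.
    """
    if isinstance(model, dict):
        if t is None:
            raise ValueError("pass t when giving raw proportions")
        model = PulseModel(proportions=model, t=t)
    rng = np.random.default_rng(seed)
    weights = np.array(list(model.proportions.values()), dtype=float)
    labels = tuple(model.proportions)
    rate = model.t / 100.0  # per cM

    pure = int(np.argmax(weights)) if weights.max() >= 1.0 else None
    tracks = []
    for i in range(n_haploid):
        chrom_ends, chrom_labels = {}, {}
        for chrom, L in gmap.lengths_cm.items():
            if pure is not None:  # degenerate mixture: one segment
                ends = np.array([L])
                labs = np.array([pure], dtype=np.int8)
            else:
                ends, labs = _mosaic_chromosome(L, rate, weights, rng)
            chrom_ends[chrom] = ends
            chrom_labels[chrom] = labs
        tracks.append(AncestryTrack(hap_id=f"hap{i}", label_set=labels,
                                    chrom_ends=chrom_ends,
                                    chrom_labels=chrom_labels))
    return tracks


def pair_diploid(tracks: list[AncestryTrack],
                 seed: int | np.random.Generator) -> list[tuple[AncestryTrack, AncestryTrack]]:
    """Randomly pair haploid tracks into diploid individuals (perfect matching)."""
    if len(tracks) % 2:
        raise ValueError(f"cannot pair an odd number of tracks ({len(tracks)})")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(tracks))
    return [(tracks[order[2 * i]], tracks[order[2 * i + 1]])
            for i in range(len(tracks) // 2)]


def paint_haplotypes(tracks: list[AncestryTrack],
                     panels: dict[str, HaplotypeMatrix],
                     gmap: GeneticMap,
                     seed: int | np.random.Generator) -> HaplotypeMatrix:
    """Paint mosaic tracks with alleles from regional reference panels.

    For each mosaic piece a panel chromosome of the piece's source is chosen
    uniformly and donates its alleles over the piece's SNP span.
    """
    rng = np.random.default_rng(seed)
    for t in tracks:
        for lab in t.label_set:
            if lab not in panels:
                raise ValueError(f"no reference panel for label {lab!r}")
    for lab, panel in panels.items():
        for chrom in gmap.positions_cm:
            if panel.data[chrom].shape[1] != gmap.positions_cm[chrom].size:
                raise ValueError(
                    f"panel {lab!r}/{chrom}: SNP count mismatch with map")

    out = {chrom: np.zeros((len(tracks), pos.size), dtype=np.uint8)
           for chrom, pos in gmap.positions_cm.items()}
    for ti, track in enumerate(tracks):
        for chrom, pos in gmap.positions_cm.items():
            ends = track.chrom_ends[chrom]
            labs = track.chrom_labels[chrom]
            chrom_end = float(ends[-1])
            start = 0.0
            for end, code in zip(ends, labs):
                i0 = int(np.searchsorted(pos, start, side="left"))
                # a SNP exactly at the chromosome end belongs to the final
                # (half-open) segment
                i1 = pos.size if end >= chrom_end \
                    else int(np.searchsorted(pos, end, side="left"))
                if i1 > i0:
                    panel = panels[track.label_set[int(code)]]
                    donor = int(rng.integers(panel.data[chrom].shape[0]))
                    out[chrom][ti, i0:i1] = panel.data[chrom][donor, i0:i1]
                start = float(end)
    return HaplotypeMatrix(gmap=gmap, data=out,
                           hap_ids=[t.hap_id for t in tracks])


# ---------------------------------------------------------------------------
# forward Wright--Fisher ancestry evolution
# ---------------------------------------------------------------------------

def _splice(ends: np.ndarray, labels: np.ndarray, a: float, b: float
            ) -> tuple[np.ndarray, np.ndarray]:
    """Segments of a parent chromosome restricted to [a, b)."""
    i0 = int(np.searchsorted(ends, a, side="right"))
    i1 = int(np.searchsorted(ends, b, side="left"))
    piece_ends = np.concatenate([ends[i0:i1], [b]])
    piece_labels = labels[i0:i1 + 1]
    return piece_ends, piece_labels


def simulate_wf_markov(N: int, q: float, L: float, t: int,
                       seed: int | np.random.Generator,
                       chrom: str = "1",
                       labels: tuple[str, str] = ("A", "B"),
                       init: list[tuple[np.ndarray, np.ndarray]] | None = None,
                       ) -> list[AncestryTrack]:
    """Forward Wright--Fisher ancestry simulation for one chromosome.

    The 2N chromosomes of each generation are built by following a Markovian
    path along the 2N chromosomes of the previous generation: crossover
    breakpoints arrive as a Poisson process with rate 1 per Morgan, and at
    each breakpoint the copying switches to a uniformly chosen parent
    chromosome.  Generation 0 chromosomes are single-source, labelled A with
    probability q.  Only breakpoints and labels are tracked (no genotypes).

    Parameters
    ----------
    N : haploid population size is 2N chromosomes (N diploids).
    q : initial fraction of A-labelled chromosomes (in expectation).
    L : chromosome length in Morgans.
    t : number of generations to evolve (>= 1).
    """
    if N < 1 or t < 1:
        raise ValueError("require N >= 1 and t >= 1")
    rng = np.random.default_rng(seed)
    L_cm = 100.0 * L
    n_chrom = 2 * N

    if init is None:
        codes = (rng.random(n_chrom) >= q).astype(np.int8)  # 0 = A, 1 = B
        gen = [(np.array([L_cm]), np.array([c], dtype=np.int8)) for c in codes]
    else:
        gen = init

    for _ in range(t):
        nxt = []
        n_bp = rng.poisson(L, size=n_chrom)
        for k in n_bp:
            if k == 0:
                parent = int(rng.integers(n_chrom))
                nxt.append(gen[parent])
                continue
            bps = np.sort(rng.uniform(0.0, L_cm, size=int(k)))
            bounds = np.concatenate([[0.0], bps, [L_cm]])
            parents = rng.integers(n_chrom, size=int(k) + 1)
            ends_parts, lab_parts = [], []
            for a, b, p in zip(bounds[:-1], bounds[1:], parents):
                pe, pl = _splice(*gen[int(p)], float(a), float(b))
                ends_parts.append(pe)
                lab_parts.append(pl)
            ends = np.concatenate(ends_parts)
            labs = np.concatenate(lab_parts)
            nxt.append(merge_adjacent(ends, labs))
        gen = nxt

    return [AncestryTrack(hap_id=f"hap{i}", label_set=labels,
                          chrom_ends={chrom: e.copy()},
                          chrom_labels={chrom: l.copy()})
            for i, (e, l) in enumerate(gen)]


def simulate_two_wave(N: int, model: TwoWaveModel, L: float,
                      seed: int | np.random.Generator,
                      chrom: str = "1") -> list[AncestryTrack]:
    """Two-wave history: A/B merge at t1, A replaces a fraction mu at t2.

    Runs the Wright--Fisher ancestry dynamics from the founding event; at
    generation t2 before present a fraction mu of chromosomes (rounded to the
    nearest count) is replaced by pure-A chromosomes, and the dynamics then
    continue to the present.
    """
    rng = np.random.default_rng(seed)
    t1, t2 = int(round(model.t1)), int(round(model.t2))
    n_chrom = 2 * N
    n_replace = int(round(model.mu * n_chrom))
    if model.mu > 0 and n_replace < 1:
        warnings.warn(
            f"mu*2N = {model.mu * n_chrom:.2f} < 1: the recent wave is "
            "unrepresentable at this population size", stacklevel=2)

    # evolve from the founding event down to the replacement event
    early = simulate_wf_markov(N, model.q, L, t1 - t2, rng, chrom=chrom,
                               labels=model.labels)
    gen = [(tr.chrom_ends[chrom], tr.chrom_labels[chrom]) for tr in early]
    L_cm = 100.0 * L
    if n_replace >= 1:
        replaced = rng.choice(n_chrom, size=n_replace, replace=False)
        for idx in replaced:
            gen[int(idx)] = (np.array([L_cm]), np.array([0], dtype=np.int8))
    return simulate_wf_markov(N, model.q, L, t2, rng, chrom=chrom,
                              labels=model.labels, init=gen)


# ---------------------------------------------------------------------------
# LAI-call noise emulation
# ---------------------------------------------------------------------------

def degrade_ancestry_calls(tracks: list[AncestryTrack], gmap: GeneticMap,
                           target_accuracy: float,
                           seed: int | np.random.Generator,
                           error_block_mean_snps: float = 40.0,
                           target_inflation: float | None = None,
                           inflation_tol: float = 0.5,
                           accuracy_tol: float = 0.02,
                           ) -> tuple[AncestryCallTable, dict]:
    """Corrupt true per-SNP ancestry labels with a block-error process.

    Error regions arrive as contiguous blocks (alternating geometric run
    lengths along the SNP index, error-block mean ``error_block_mean_snps``)
    and each error block is assigned a single random label drawn from the
    cohort's truth label frequencies -- emulating a local-ancestry caller
    misassigning a whole window to one source.  Because the block label can
    coincide with the local truth, the stationary block fraction is tuned as
    e = (1 - accuracy) / (1 - sum_l w_l^2), which reproduces the target
    per-SNP accuracy.  Long constant blocks both lower accuracy and inflate
    the apparent mean same-label segment length, as observed for LAI between
    closely related source populations.

    Returns the degraded call table and a stats dict with the realized
    accuracy and the run-length inflation factor (call-table mean same-label
    run length over the truth's).  Raises if the realized accuracy misses
    the target by more than ``accuracy_tol``, or if ``target_inflation`` is
    requested and missed by more than ``inflation_tol``.
    """
    if not (0.5 <= target_accuracy <= 1.0):
        raise ValueError("target_accuracy must lie in [0.5, 1]")
    rng = np.random.default_rng(seed)
    truth = truth_call_table(tracks, gmap)
    n_labels = len(truth.label_set)

    if target_accuracy == 1.0:
        calls = {c: v.copy() for c, v in truth.calls.items()}
        stats = {"accuracy": 1.0, "inflation": 1.0, "target": 1.0}
        return AncestryCallTable(gmap, truth.label_set, calls, truth.hap_ids), stats

    # truth label frequencies drive both block labels and the attainable range
    counts = np.zeros(n_labels)
    for v in truth.calls.values():
        counts += np.bincount(v.ravel(), minlength=n_labels)
    w = counts / counts.sum()
    collision = float((w ** 2).sum())  # P(random block label matches truth)
    e_frac = (1.0 - target_accuracy) / (1.0 - collision)
    if target_accuracy < collision - 0.02:
        raise ValueError(
            f"accuracy {target_accuracy} unattainable: random labelling "
            f"already achieves {collision:.3f}")
    e_frac = min(e_frac, 1.0)

    m = float(error_block_mean_snps)
    p_ec = 1.0 / m                                   # leave an error block
    p_ce = 1.0 if e_frac >= 1.0 else e_frac / (m * (1.0 - e_frac))
    if p_ce > 1.0:
        raise ValueError(
            f"block fraction {e_frac:.2f} unattainable with mean block "
            f"{m} SNPs; increase error_block_mean_snps")

    def _error_blocks(n_snp: int) -> list[tuple[int, int]]:
        """Half-open [start, end) index ranges of error blocks."""
        blocks = []
        pos = 0
        s = bool(rng.random() < e_frac)  # stationary start
        while pos < n_snp:
            run = int(rng.geometric(p_ec if s else p_ce))
            end = min(pos + run, n_snp)
            if s:
                blocks.append((pos, end))
            pos = end
            s = not s
        return blocks

    calls = {}
    for chrom, true_calls in truth.calls.items():
        n_hap, n_snp = true_calls.shape
        out = true_calls.copy()
        for h in range(n_hap):
            for a, b in _error_blocks(n_snp):
                out[h, a:b] = rng.choice(n_labels, p=w)
        calls[chrom] = out

    table = AncestryCallTable(gmap, truth.label_set, calls, truth.hap_ids)
    realized = table.accuracy_vs(truth)
    inflation = table.mean_run_length_cm() / truth.mean_run_length_cm()
    stats = {"accuracy": realized, "inflation": inflation,
             "target": target_accuracy, "block_fraction": e_frac}
    if abs(realized - target_accuracy) > accuracy_tol:
        raise RuntimeError(
            f"realized accuracy {realized:.3f} misses target "
            f"{target_accuracy:.3f} by more than {accuracy_tol}; "
            f"stats: {stats}")
    if target_inflation is not None and \
            abs(inflation - target_inflation) > inflation_tol:
        raise RuntimeError(
            f"realized run-length inflation {inflation:.2f} misses target "
            f"{target_inflation:.2f}; adjust error_block_mean_snps")
    return table, stats


# ---------------------------------------------------------------------------
# Balding--Nichols reference panels
# ---------------------------------------------------------------------------

def synth_reference_panels(gmap: GeneticMap, n_per_region: int,
                           divergence: dict[str, float],
                           seed: int | np.random.Generator,
                           ) -> tuple[dict[str, HaplotypeMatrix], dict[str, np.ndarray]]:
    """Regional haplotype panels with Balding--Nichols allele-frequency drift.

    Ancestral frequencies are uniform on [0.05, 0.95]; each region's
    frequencies are Beta-distributed around the ancestral value with drift
    parameter F (``divergence[region]``), and haplotypes are drawn
    site-independently (linkage equilibrium within panels).  For two regions
    drifting independently with parameter F each, the expected pairwise
    Hudson F_ST between them is F.

    Returns (panels, true_frequencies) where ``true_frequencies`` maps region
    to the concatenated per-SNP frequency array (map chromosome order).
    """
    for region, F in divergence.items():
        if not (0.0 < F < 1.0):
            raise ValueError(f"drift for {region!r} must lie in (0, 1), got {F}")
    rng = np.random.default_rng(seed)
    n_snps = gmap.n_snps()
    anc = rng.uniform(0.05, 0.95, size=n_snps)

    freqs: dict[str, np.ndarray] = {}
    panels: dict[str, HaplotypeMatrix] = {}
    sizes = [gmap.positions_cm[c].size for c in gmap.chromosomes
             if c in gmap.positions_cm]
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    chroms = [c for c in gmap.chromosomes if c in gmap.positions_cm]

    for region, F in divergence.items():
        a = anc * (1.0 - F) / F
        b = (1.0 - anc) * (1.0 - F) / F
        p = rng.beta(a, b)
        freqs[region] = p
        haps = (rng.random((n_per_region, n_snps)) < p).astype(np.uint8)
        data = {c: haps[:, offsets[i]:offsets[i + 1]]
                for i, c in enumerate(chroms)}
        panels[region] = HaplotypeMatrix(
            gmap=gmap, data=data,
            hap_ids=[f"{region}_{i}" for i in range(n_per_region)])
    return panels, freqs


def hudson_fst(p1: np.ndarray, p2: np.ndarray, n1: int, n2: int) -> float:
    """Hudson's F_ST estimator (ratio of averages) from sample frequencies."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return float(num.sum() / den.sum())


# ---------------------------------------------------------------------------
# synthetic IBD cohorts
# ---------------------------------------------------------------------------

#: diploid ancestry states, in matrix order
IBD_STATES = ("hom-EU", "het", "hom-ME")


def _diploid_state_code(eu1: np.ndarray, eu2: np.ndarray) -> np.ndarray:
    """0 = hom-EU, 1 = het, 2 = hom-ME from two EU-indicator haplotypes."""
    return 2 - (eu1.astype(int) + eu2.astype(int))


def synth_ibd_cohort(n_segments: int, f_eu: float, p_eu: float, lam: float,
                     seed: int | np.random.Generator,
                     length_range_cm: tuple[float, float] = (3.0, 7.0)):
    """Synthetic IBD segments with a planted three-chromosome ancestry model.

    For a fraction ``lam`` of segment material the segment is truly IBD with
    correct ancestry labels: the shared haplotype is European with
    probability ``f_eu`` and each individual's other haplotype is European
    with probability ``p_eu``.  For the remaining fraction 1-lam all four
    haplotype labels are independent Bernoulli(p_eu) (the random regime).
    Segment ancestry is constant along the segment (segments of 3--7 cM are
    much shorter than typical ancestry tracts).

    Returns (DataFrame with columns length_cm, state1, state2, is_true;
    ground-truth dict).
    """
    import pandas as pd

    for name, v in (("f_eu", f_eu), ("p_eu", p_eu), ("lam", lam)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    lo, hi = length_range_cm
    if not (0 < lo <= hi):
        raise ValueError("empty or invalid length distribution")
    rng = np.random.default_rng(seed)

    lengths = rng.uniform(lo, hi, size=n_segments)
    is_true = rng.random(n_segments) < lam

    shared = rng.random(n_segments) < f_eu        # shared haplotype is EU
    other1 = rng.random(n_segments) < p_eu
    other2 = rng.random(n_segments) < p_eu
    s1_true = _diploid_state_code(shared, other1)
    s2_true = _diploid_state_code(shared, other2)

    h = rng.random((4, n_segments)) < p_eu        # random regime, 4 indep haps
    s1_rand = _diploid_state_code(h[0], h[1])
    s2_rand = _diploid_state_code(h[2], h[3])

    df = pd.DataFrame({
        "length_cm": lengths,
        "state1": np.where(is_true, s1_true, s1_rand),
        "state2": np.where(is_true, s2_true, s2_rand),
        "is_true": is_true,
    })
    truth = {"lambda": lam, "f_eu": f_eu, "p_eu": p_eu}
    return df, truth
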