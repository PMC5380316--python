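"""Readers and writers for the pipeline's plain-text formats.

Dialects: PLINK ``.map`` genetic maps (chrom, id, cM, bp; 1-based bp),
BED-like ancestry-track TSVs, RFMix-Viterbi-like per-SNP call tables,
GERMLINE ``.match`` IBD lists, phased VCF or TSV haplotype matrices, and a
YAML run configuration.  Internally everything is cM, 0-based, half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .maps import GeneticMap
from .sim import AncestryCallTable, HaplotypeMatrix
from .tracks import AncestryTrack

__all__ = [
    "read_genetic_map", "write_genetic_map",
    "read_haplotypes", "write_haplotypes_tsv", "write_vcf",
    "read_ancestry_calls", "write_ancestry_calls",
    "read_tracks", "write_tracks",
    "read_ibd_match", "write_ibd_match",
    "RunConfig",
]


# ---------------------------------------------------------------------------
# genetic map (PLINK .map dialect)
# ---------------------------------------------------------------------------

def read_genetic_map(path: str | Path) -> GeneticMap:
    """Read a PLINK-style .map file (chrom, snp id, cM, bp).

    Positions must be strictly increasing within each chromosome; offending
    lines are reported.  The chromosome length is the last SNP's cM position.
    """
    df = pd.read_csv(path, sep=r"\s+", header=None,
                     names=["chrom", "snp", "cm", "bp"], dtype={"chrom": str})
    if df["cm"].isna().any():
        raise ValueError(f"{path}: missing cM column values")
    lengths, pos_cm, pos_bp, ids = {}, {}, {}, {}
    for chrom, grp in df.groupby("chrom", sort=False):
        cm = grp["cm"].to_numpy(dtype=float)
        bad = np.flatnonzero(np.diff(cm) <= 0)
        if bad.size:
            line = int(grp.index[bad[0] + 1]) + 1
            raise ValueError(
                f"{path}: non-increasing cM position on line {line} "
                f"(chromosome {chrom})")
        lengths[chrom] = float(cm[-1]) if cm[-1] > 0 else float(cm[-1] + 1e-9)
        pos_cm[chrom] = cm
        pos_bp[chrom] = grp["bp"].to_numpy(dtype=float)
        ids[chrom] = grp["snp"].to_numpy(dtype=object)
    return GeneticMap(lengths_cm=lengths, positions_cm=pos_cm,
                      positions_bp=pos_bp, snp_ids=ids)


def write_genetic_map(gmap: GeneticMap, path: str | Path) -> None:
    rows = []
    for chrom in gmap.chromosomes:
        pos = gmap.positions_cm.get(chrom)
        if pos is None:
            continue
        bp = gmap.positions_bp.get(chrom,
                                   np.arange(1, pos.size + 1) * 1000)
        snp = gmap.snp_ids.get(
            chrom, np.array([f"{chrom}:{i}" for i in range(pos.size)]))
        for s, c, b in zip(snp, pos, bp):
            rows.append(f"{chrom}\t{s}\t{c:.6f}\t{int(b)}")
    Path(path).write_text("\n".join(rows) + "\n")


# ---------------------------------------------------------------------------
# haplotypes
# ---------------------------------------------------------------------------

def _hap_from_records(records, gmap: GeneticMap, sample_names) -> HaplotypeMatrix:
    data = {}
    for chrom in gmap.chromosomes:
        if chrom in records and records[chrom]:
            data[chrom] = np.array(records[chrom], dtype=np.uint8).T
    hap_ids = [f"{s}_{h}" for s in sample_names for h in (0, 1)]
    return HaplotypeMatrix(gmap=gmap, data=data, hap_ids=hap_ids)


def read_haplotypes(path: str | Path, gmap: GeneticMap,
                    fmt: str | None = None) -> tuple[HaplotypeMatrix, dict]:
    """Read phased haplotypes from a VCF (``|``-phased GT) or TSV matrix.

    Only biallelic phased records aligned to the map by (chrom, bp) are
    kept; skipped record counts are returned alongside the matrix.
    """
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.suffix in (".vcf", ".gz") else "tsv"
    if fmt == "tsv":
        return _read_haplotypes_tsv(path, gmap)
    return _read_haplotypes_vcf(path, gmap)


def _read_haplotypes_tsv(path: Path, gmap: GeneticMap) -> tuple[HaplotypeMatrix, dict]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    hap_cols = [c for c in df.columns if c not in ("chrom", "pos_cm", "bp")]
    data = {}
    for chrom, grp in df.groupby("chrom", sort=False):
        want = gmap.positions_cm.get(chrom)
        if want is None:
            continue
        if grp.shape[0] != want.size:
            raise ValueError(f"{path}: chromosome {chrom} SNP count mismatch")
        data[chrom] = grp[hap_cols].to_numpy(dtype=np.uint8).T
    if not data:
        raise ValueError(f"{path}: no sites overlap the map")
    hm = HaplotypeMatrix(gmap=gmap, data=data, hap_ids=list(hap_cols))
    return hm, {"skipped_unphased": 0, "skipped_multiallelic": 0}


def _read_haplotypes_vcf(path: Path, gmap: GeneticMap) -> tuple[HaplotypeMatrix, dict]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    bp_index = {chrom: {int(b): i for i, b in enumerate(gmap.positions_bp[chrom])}
                for chrom in gmap.positions_bp}
    records: dict[str, list] = {c: [None] * gmap.positions_cm[c].size
                                for c in gmap.positions_cm}
    skipped = {"skipped_unphased": 0, "skipped_multiallelic": 0,
               "skipped_off_map": 0}
    for var in vcf:
        chrom = var.CHROM.removeprefix("chr")
        if len(var.ALT) != 1:
            skipped["skipped_multiallelic"] += 1
            continue
        idx = bp_index.get(chrom, {}).get(var.POS)
        if idx is None:
            skipped["skipped_off_map"] += 1
            continue
        gts = var.genotype.array()
        if np.any(gts[:, 2] == 0):  # phase flag per cyvcf2
            skipped["skipped_unphased"] += 1
            continue
        records[chrom][idx] = gts[:, :2].reshape(-1)
    data = {}
    for chrom, rows in records.items():
        got = [r for r in rows if r is not None]
        if len(got) != len(rows):
            missing = len(rows) - len(got)
            if len(got) == 0:
                continue
            raise ValueError(
                f"{path}: chromosome {chrom} missing {missing} map sites")
        data[chrom] = np.array(got, dtype=np.uint8).T
    if not data:
        raise ValueError(f"{path}: no overlapping sites with the map")
    hap_ids = [f"{s}_{h}" for s in samples for h in (0, 1)]
    return HaplotypeMatrix(gmap=gmap, data=data, hap_ids=hap_ids), skipped


def write_haplotypes_tsv(hm: HaplotypeMatrix, path: str | Path) -> None:
    frames = []
    for chrom in hm.gmap.chromosomes:
        if chrom not in hm.data:
            continue
        df = pd.DataFrame(hm.data[chrom].T, columns=hm.hap_ids)
        df.insert(0, "pos_cm", hm.gmap.positions_cm[chrom])
        df.insert(0, "chrom", chrom)
        frames.append(df)
    pd.concat(frames).to_csv(path, sep="\t", index=False)


def write_vcf(hm: HaplotypeMatrix, path: str | Path) -> None:
    """Write a minimal phased VCF (GT only, synthetic A/G alleles)."""
    if hm.n_haplotypes % 2:
        raise ValueError("need an even haplotype count to form VCF samples")
    samples = [hm.hap_ids[2 * i].rsplit("_", 1)[0]
               for i in range(hm.n_haplotypes // 2)]
    lines = ["##fileformat=VCFv4.2",
             '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
             "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
             + "\t".join(samples)]
    for chrom in hm.gmap.chromosomes:
        if chrom not in hm.data:
            continue
        pos_bp = hm.gmap.positions_bp.get(
            chrom, np.arange(1, hm.gmap.positions_cm[chrom].size + 1) * 1000)
        H = hm.data[chrom]
        for j, bp in enumerate(pos_bp):
            gts = "\t".join(f"{H[2*i, j]}|{H[2*i+1, j]}"
                            for i in range(len(samples)))
            lines.append(f"{chrom}\t{int(bp)}\t{chrom}:{j}\tA\tG\t.\tPASS\t.\tGT\t{gts}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# ancestry tracks and call tables
# ---------------------------------------------------------------------------

def write_tracks(tracks: list[AncestryTrack], path: str | Path) -> None:
    """BED-like TSV: chrom, start_cM, end_cM, haplotype_id, label."""
    rows = ["chrom\tstart_cm\tend_cm\thap_id\tlabel"]
    for t in tracks:
        for chrom, start, end, label in t.segments():
            rows.append(f"{chrom}\t{start:.9f}\t{end:.9f}\t{t.hap_id}\t{label}")
    Path(path).write_text("\n".join(rows) + "\n")


def read_tracks(path: str | Path) -> list[AncestryTrack]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    label_set = tuple(dict.fromkeys(df["label"]))
    tracks = []
    for hap_id, grp in df.groupby("hap_id", sort=False):
        ends, labels = {}, {}
        for chrom, g in grp.groupby("chrom", sort=False):
            g = g.sort_values("start_cm")
            ends[chrom] = g["end_cm"].to_numpy(dtype=float)
            labels[chrom] = np.array([label_set.index(l) for l in g["label"]],
                                     dtype=np.int8)
        tracks.append(AncestryTrack(hap_id=str(hap_id), label_set=label_set,
                                    chrom_ends=ends, chrom_labels=labels))
    return tracks


def write_ancestry_calls(table: AncestryCallTable, path: str | Path) -> None:
    """RFMix-Viterbi-like TSV: one row per SNP, one column per haplotype,
    integer label codes; the label set is recorded in a header comment."""
    with open(path, "w") as fh:
        fh.write("#labels=" + ",".join(table.label_set) + "\n")
        fh.write("chrom\tpos_cm\t" + "\t".join(table.hap_ids) + "\n")
        for chrom in table.gmap.chromosomes:
            if chrom not in table.calls:
                continue
            pos = table.gmap.positions_cm[chrom]
            calls = table.calls[chrom]
            for j, p in enumerate(pos):
                fh.write(f"{chrom}\t{p:.6f}\t"
                         + "\t".join(str(int(c)) for c in calls[:, j]) + "\n")


def read_ancestry_calls(path: str | Path, gmap: GeneticMap) -> AncestryCallTable:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#labels="):
            raise ValueError(f"{path}: missing #labels= header")
        label_set = tuple(header.removeprefix("#labels=").split(","))
        df = pd.read_csv(fh, sep="\t", dtype={"chrom": str})
    hap_ids = [c for c in df.columns if c not in ("chrom", "pos_cm")]
    n_labels = len(label_set)
    calls = {}
    for chrom, grp in df.groupby("chrom", sort=False):
        vals = grp[hap_ids].to_numpy(dtype=np.int8).T
        if vals.size and (vals.min() < 0 or vals.max() >= n_labels):
            raise ValueError(f"{path}: unknown label code on chromosome {chrom}")
        calls[chrom] = vals
    return AncestryCallTable(gmap=gmap, label_set=label_set, calls=calls,
                             hap_ids=hap_ids)


# ---------------------------------------------------------------------------
# GERMLINE .match IBD lists
# ---------------------------------------------------------------------------

_MATCH_COLS = ["fam1", "id1", "fam2", "id2", "chrom", "bp_start", "bp_end",
               "snp_start", "snp_end", "n_snps", "length", "unit",
               "n_mismatch", "hom1", "hom2"]


def read_ibd_match(path: str | Path, gmap: GeneticMap | None = None,
                   mismatch_tol: float = 0.10) -> pd.DataFrame:
    """Read a GERMLINE .match-layout IBD list.

    If a map with bp positions is given, each segment's genetic length is
    recomputed by linear interpolation and segments whose stated length
    disagrees by more than ``mismatch_tol`` (relative) are flagged in the
    ``length_flag`` column.  Adds start_cm/end_cm columns when possible.
    """
    df = pd.read_csv(path, sep=r"\s+", header=None, names=_MATCH_COLS,
                     dtype={"chrom": str, "fam1": str, "id1": str,
                            "fam2": str, "id2": str})
    if gmap is not None and gmap.positions_bp:
        start_cm = np.empty(len(df))
        end_cm = np.empty(len(df))
        for i, row in enumerate(df.itertuples(index=False)):
            chrom = str(row.chrom)
            if chrom not in gmap.positions_bp:
                raise ValueError(f"{path}: segment on unknown chromosome {chrom}")
            start_cm[i] = gmap.interpolate_cm(chrom, np.array([row.bp_start]))[0]
            end_cm[i] = gmap.interpolate_cm(chrom, np.array([row.bp_end]))[0]
        df["start_cm"] = start_cm
        df["end_cm"] = end_cm
        recomputed = end_cm - start_cm
        stated = df["length"].to_numpy(dtype=float)
        is_cm = df["unit"].astype(str).str.lower().eq("cm")
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = np.abs(recomputed - stated) / np.where(stated > 0, stated, np.nan)
        df["length_flag"] = is_cm & (rel > mismatch_tol)
    return df


def write_ibd_match(df: pd.DataFrame, path: str | Path) -> None:
    df[_MATCH_COLS].to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Root seed plus per-stage parameter blocks; YAML round-trippable."""

    seed: int = 0
    out_dir: str = "admixtime_out"
    simulate: dict = field(default_factory=lambda: {
        "n_haploid": 100, "t": 30, "proportions": {"EU": 0.5, "ME": 0.5},
        "chromosomes": 4})
    degrade: dict = field(default_factory=lambda: {
        "target_accuracy": 0.95, "error_block_mean_snps": 30})
    dating: dict = field(default_factory=lambda: {
        "t_min": 2, "t_max": 80, "fix_q": "mean"})
    ibd: dict = field(default_factory=lambda: {
        "n_segments": 20000, "p_eu": 0.53, "f_eu": 0.42, "lambda": 0.65,
        "trim_cm": 0.25})
    bounds: dict = field(default_factory=lambda: {
        "T": [24, 37], "q": [0.34, 0.61], "mu": [0.15, 0.23], "t2": [10, 20]})

    def derived_seed(self, stage: str) -> int:
        """Deterministic per-stage seed below 2**31."""
        import zlib

        tag = zlib.crc32(stage.encode())
        h = np.random.SeedSequence([self.seed, tag])
        return int(h.generate_state(1)[0] % (2 ** 31))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))
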