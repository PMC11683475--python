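"""Readers and writers for the plain-text formats the pipeline consumes.

Coordinate conventions are fixed here and nowhere else: BED and bedGraph are
0-based half-open; VCF positions are 1-based and converted to 0-based points
only by downstream interval lookups. Genotypes are stored as alt-allele
dosages in {0, 1, 2} with ``nan`` for missing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import ceil
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, IntervalSet

__all__ = [
    "VariantRecord",
    "GenotypeMatrix",
    "SignalTrack",
    "GeneModel",
    "read_vcf",
    "write_vcf",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "read_gene_models",
    "write_gene_models",
    "validate_intervals",
]

MISSING = np.nan


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic SNP with 1-based position."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    vid: str | None = None

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"VCF position must be >= 1, got {self.pos}")

    @property
    def point(self) -> int:
        """0-based point coordinate for interval membership tests."""
        return self.pos - 1

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


@dataclass
class GenotypeMatrix:
    """Samples x variants dosage matrix plus variant metadata.

    dosages[i, j] = number of alt alleles carried by sample i at variant j,
    nan when the genotype is missing (uncalled or masked by the DP filter).
    """

    dosages: np.ndarray  # (n_samples, n_variants) float
    samples: list[str]
    variants: list[VariantRecord]
    populations: np.ndarray | None = None  # per-sample labels
    haplotypes: np.ndarray | None = None  # (2*n_samples, n_variants) 0/1, if phased

    def __post_init__(self):
        n, m = self.dosages.shape
        if len(self.samples) != n:
            raise ValueError("sample count does not match dosage rows")
        if len(self.variants) != m:
            raise ValueError("variant count does not match dosage columns")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def chroms(self) -> np.ndarray:
        return np.array([v.chrom for v in self.variants], dtype=object)

    @property
    def positions(self) -> np.ndarray:
        return np.array([v.pos for v in self.variants], dtype=np.int64)

    def allele_frequencies(self) -> np.ndarray:
        """Per-variant alt-allele frequency over non-missing calls."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.dosages, axis=0) / 2.0

    def take_variants(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        hap = None
        if self.haplotypes is not None:
            hap = self.haplotypes[:, index]
        return GenotypeMatrix(
            self.dosages[:, index],
            self.samples,
            [self.variants[j] for j in np.flatnonzero(index) if index.dtype == bool]
            if index.dtype == bool
            else [self.variants[j] for j in index],
            populations=self.populations,
            haplotypes=hap,
        )


@dataclass
class SignalTrack:
    """Fixed-bin non-negative signal, one vector per chromosome (origin 0)."""

    values: dict[str, np.ndarray]
    bin_size: int

    def __post_init__(self):
        if self.bin_size < 1:
            raise ValueError("bin_size must be >= 1")

    @property
    def chroms(self) -> list[str]:
        return sorted(self.values)

    def n_bins(self, chrom: str) -> int:
        return len(self.values[chrom])

    def concatenated(self) -> np.ndarray:
        return np.concatenate([self.values[c] for c in self.chroms])


@dataclass(frozen=True)
class GeneModel:
    """Gene with strand-resolved TSS/TES (both 1-based)."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tes: int
    length: int

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        if self.tss == self.tes:
            raise ValueError(f"zero-length gene {self.gene_id}")
        if self.length <= 0:
            raise ValueError(f"non-positive length for {self.gene_id}")

    @property
    def body(self) -> GenomicInterval:
        lo, hi = sorted((self.tss, self.tes))
        return GenomicInterval(self.chrom, lo - 1, hi, name=self.gene_id,
                               strand=self.strand)


# ---------------------------------------------------------------------------
# VCF

def read_vcf(path: str | Path, min_dp: int = 0) -> GenotypeMatrix:
    """Read a diploid VCF into a GenotypeMatrix.

    Indels and multi-allelic records are dropped; genotypes with per-sample
    DP below `min_dp` are set missing when a DP FORMAT field is present.
    Phased records additionally populate ``haplotypes``.
    """
    from cyvcf2 import VCF

    if min_dp < 0:
        raise ValueError("min_dp must be >= 0")
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    variants: list[VariantRecord] = []
    rows: list[np.ndarray] = []
    hap_rows: list[np.ndarray] = []
    all_phased = True
    for rec in vcf:
        if len(rec.ALT) != 1:
            continue  # multi-allelic: dropped, not decomposed
        ref, alt = rec.REF, rec.ALT[0]
        if len(ref) != 1 or len(alt) != 1:
            continue  # indel
        gts = np.array(rec.genotypes, dtype=object)
        ploidies = {len(g) - 1 for g in rec.genotypes}
        if ploidies != {2}:
            raise ValueError(
                f"unsupported ploidy at {rec.CHROM}:{rec.POS}: only diploid GT supported"
            )
        g = np.array([[a1, a2] for a1, a2, _ in rec.genotypes], dtype=float)
        g[g < 0] = np.nan
        dosage = g.sum(axis=1)
        if min_dp > 0:
            dp = rec.format("DP")
            if dp is not None:
                shallow = (dp.astype(float).ravel() < min_dp)
                dosage[shallow] = np.nan
                g[shallow, :] = np.nan
        phased_flags = [bool(t[2]) for t in rec.genotypes]
        if not all(phased_flags):
            all_phased = False
        variants.append(VariantRecord(rec.CHROM, rec.POS, ref, alt,
                                      vid=rec.ID or f"{rec.CHROM}:{rec.POS}"))
        rows.append(dosage)
        hap_rows.append(g.reshape(-1))
    dosages = (np.array(rows, dtype=float).T if rows
               else np.empty((len(samples), 0)))
    haplotypes = None
    if all_phased and hap_rows and not np.isnan(np.array(hap_rows)).any():
        haplotypes = np.array(hap_rows, dtype=np.int8).T
    return GenotypeMatrix(dosages, samples, variants, haplotypes=haplotypes)


def write_vcf(path: str | Path, gm: GenotypeMatrix, phased: bool | None = None) -> None:
    """Write a GenotypeMatrix as a minimal VCF 4.2 text file."""
    if phased is None:
        phased = gm.haplotypes is not None
    sep = "|" if phased else "/"
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.samples) + "\n")
        for j, v in enumerate(gm.variants):
            if phased and gm.haplotypes is not None:
                a1 = gm.haplotypes[0::2, j]
                a2 = gm.haplotypes[1::2, j]
                gts = [f"{x}{sep}{y}" for x, y in zip(a1, a2)]
            else:
                gts = []
                for d in gm.dosages[:, j]:
                    if np.isnan(d):
                        gts.append(f".{sep}.")
                    else:
                        d = int(d)
                        gts.append(("0", "0") if d == 0 else ("0", "1") if d == 1 else ("1", "1"))
                        gts[-1] = sep.join(gts[-1])
            fh.write(f"{v.chrom}\t{v.pos}\t{v.vid or '.'}\t{v.ref}\t{v.alt}"
                     f"\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n")


# ---------------------------------------------------------------------------
# BED / bedGraph

def read_bed(path: str | Path) -> IntervalSet:
    """Read BED3/BED6 into a sorted IntervalSet (0-based half-open)."""
    ivs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end <= start ({start}, {end})")
            name = parts[3] if len(parts) > 3 else None
            score = float(parts[4]) if len(parts) > 4 and parts[4] != "." else None
            strand = parts[5] if len(parts) > 5 and parts[5] != "." else None
            ivs.append(GenomicInterval(chrom, start, end, name, score, strand))
    return IntervalSet(ivs)


def write_bed(path: str | Path, intervals: IntervalSet | Sequence[GenomicInterval]) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None or iv.strand is not None:
                cols.append(iv.name if iv.name is not None else ".")
            if iv.score is not None or iv.strand is not None:
                cols.append(format(iv.score, "g") if iv.score is not None else ".")
            if iv.strand is not None:
                cols.append(iv.strand)
            fh.write("\t".join(cols) + "\n")


def read_bedgraph(path: str | Path, bin_size: int,
                  chrom_sizes: dict[str, int]) -> SignalTrack:
    """Project bedGraph records onto a fixed bin grid.

    Each bin gets the coverage-weighted mean of the records overlapping it,
    with uncovered base pairs contributing zero — i.e. bin value =
    sum(value * overlap_bp) / bin_size.
    """
    values = {c: np.zeros(ceil(L / bin_size)) for c, L in chrom_sizes.items()}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            chrom, s, e, v = line.split("\t")[:4]
            s, e, v = int(s), int(e), float(v)
            if chrom not in chrom_sizes:
                raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom}")
            if e > chrom_sizes[chrom]:
                raise ValueError(f"{path}:{lineno}: interval exceeds chromosome length")
            if e <= s:
                raise ValueError(f"{path}:{lineno}: end <= start")
            first, last = s // bin_size, (e - 1) // bin_size
            vec = values[chrom]
            for b in range(first, last + 1):
                lo = max(s, b * bin_size)
                hi = min(e, (b + 1) * bin_size)
                vec[b] += v * (hi - lo) / bin_size
    return SignalTrack(values, bin_size)


def write_bedgraph(path: str | Path, track: SignalTrack) -> None:
    with open(path, "w") as fh:
        for chrom in track.chroms:
            vec = track.values[chrom]
            for b, v in enumerate(vec):
                if v != 0:
                    fh.write(f"{chrom}\t{b * track.bin_size}\t{(b + 1) * track.bin_size}"
                             f"\t{v:g}\n")


# ---------------------------------------------------------------------------
# Gene models and tables

_GENE_COLUMNS = ("gene_id", "chrom", "strand", "start", "end")


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read a TSV gene table (gene_id, chrom, strand, start, end[, length]).

    start/end are 1-based inclusive gene-body bounds; TSS is start on "+"
    and end on "-"; length defaults to the genomic span.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _GENE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"gene table missing column(s): {', '.join(missing)}")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"duplicate gene_id {dup!r}")
    genes = []
    for row in df.itertuples(index=False):
        start, end = int(row.start), int(row.end)
        tss, tes = (start, end) if row.strand == "+" else (end, start)
        length = int(getattr(row, "length", end - start + 1) or end - start + 1)
        genes.append(GeneModel(str(row.gene_id), str(row.chrom), str(row.strand),
                               tss, tes, length))
    return genes


def write_gene_models(path: str | Path, genes: Sequence[GeneModel]) -> None:
    rows = []
    for g in genes:
        start, end = sorted((g.tss, g.tes))
        rows.append((g.gene_id, g.chrom, g.strand, start, end, g.length))
    pd.DataFrame(rows, columns=list(_GENE_COLUMNS) + ["length"]).to_csv(
        path, sep="\t", index=False)


def validate_intervals(ivset: IntervalSet) -> None:
    """Assert the sorted 0-based half-open contract downstream code assumes."""
    prev: GenomicInterval | None = None
    for iv in ivset:
        if iv.start < 0 or iv.end <= iv.start:
            raise ValueError(f"invalid interval {iv}")
        if prev is not None and prev.chrom == iv.chrom and iv.start < prev.start:
            raise ValueError("intervals not sorted")
        prev = iv
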