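"""Readers, writers and core containers for the formats the pipeline touches.

All genomic intervals are stored internally as 0-based half-open (BED
convention); everything user-facing — VCF positions, haplotype interval
reports — is 1-based inclusive (CanFam3.1-style coordinates such as
``CFA5:32389061-33633274``). :class:`Interval` carries the conversion so that
it is done in exactly one place and is lossless.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam


class DataValidationError(ValueError):
    """Raised when an input file or container violates a format invariant."""


# ---------------------------------------------------------------------------
# Genotype container
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Samples x SNPs alternate-allele dosage matrix with a 1-based SNP map.

    Parameters
    ----------
    sample_ids : list of str
        Unique sample identifiers (rows).
    snp_ids : list of str
        SNP identifiers (columns).
    chromosomes : array of str
        Chromosome label per SNP.
    positions : array of int
        1-based physical position per SNP; strictly increasing within each
        chromosome.
    ref, alt : arrays of str
        Allele labels; dosage counts copies of ``alt``.
    dosages : (n_samples, n_snps) float array
        Entries in {0, 1, 2}; missing genotypes are NaN and are never
        silently imputed.
    """

    sample_ids: list[str]
    snp_ids: list[str]
    chromosomes: np.ndarray
    positions: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.chromosomes = np.asarray(self.chromosomes, dtype=object)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        n, p = self.dosages.shape
        if len(self.sample_ids) != n:
            raise DataValidationError(
                f"{len(self.sample_ids)} sample ids for {n} dosage rows"
            )
        if len(set(self.sample_ids)) != n:
            raise DataValidationError("duplicated sample IDs")
        for arr, name in [
            (self.snp_ids, "snp_ids"),
            (self.chromosomes, "chromosomes"),
            (self.positions, "positions"),
            (self.ref, "ref"),
            (self.alt, "alt"),
        ]:
            if len(arr) != p:
                raise DataValidationError(f"{name} length {len(arr)} != {p} SNPs")
        ok = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not ok.all():
            bad = np.argwhere(~ok)[0]
            raise DataValidationError(
                f"dosage out of {{0,1,2,NaN}} at sample {self.sample_ids[bad[0]]}, "
                f"snp {self.snp_ids[bad[1]]}"
            )
        # positions strictly increasing within chromosome (file order)
        for chrom in pd.unique(self.chromosomes):
            pos = self.positions[self.chromosomes == chrom]
            if len(pos) > 1 and not (np.diff(pos) > 0).all():
                raise DataValidationError(
                    f"positions not strictly increasing on {chrom}"
                )

    # -- accessors ------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def snp_index(self, snp_id: str) -> int:
        try:
            return self.snp_ids.index(snp_id)
        except ValueError:
            raise KeyError(f"SNP {snp_id!r} not in matrix") from None

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"sample {sample_id!r} not in matrix") from None

    def subset_samples(self, keep: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in keep],
            snp_ids=list(self.snp_ids),
            chromosomes=self.chromosomes,
            positions=self.positions,
            ref=self.ref,
            alt=self.alt,
            dosages=self.dosages[keep],
        )

    def snp_map(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": self.snp_ids,
                "chromosome": self.chromosomes,
                "position": self.positions,
                "ref": self.ref,
                "alt": self.alt,
            }
        )


# ---------------------------------------------------------------------------
# Intervals
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Interval:
    """A genomic interval stored 0-based half-open."""

    chromosome: str
    start: int  # 0-based, inclusive
    end: int    # 0-based, exclusive
    label: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise DataValidationError(
                f"empty/negative interval {self.chromosome}:{self.start}-{self.end}"
            )

    @classmethod
    def from_1based(cls, chromosome: str, start: int, end: int, label: str = "") -> "Interval":
        """Build from 1-based inclusive coordinates (paper/VCF style)."""
        return cls(chromosome, start - 1, end, label)

    def to_1based(self) -> tuple[str, int, int]:
        """Return (chromosome, start, end) 1-based inclusive; lossless."""
        return self.chromosome, self.start + 1, self.end

    @property
    def length_bp(self) -> int:
        return self.end - self.start

    @property
    def length_kb(self) -> int:
        """Length in kb, truncated (631,612 bp -> 631 kb)."""
        return self.length_bp // 1000

    @property
    def length_mb(self) -> float:
        """Length in Mb, rounded to one decimal (1,244,214 bp -> 1.2 Mb)."""
        return round(self.length_bp / 1e6, 1)

    def contains_position(self, chromosome: str, position_1based: int) -> bool:
        return (
            chromosome == self.chromosome
            and self.start <= position_1based - 1 < self.end
        )


class IntervalSet:
    """An ordered collection of intervals with merge/intersect operations."""

    def __init__(self, intervals: Iterable[Interval] = ()):
        self.intervals: list[Interval] = sorted(
            intervals, key=lambda iv: (str(iv.chromosome), iv.start, iv.end)
        )

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def __eq__(self, other) -> bool:
        return isinstance(other, IntervalSet) and self.intervals == other.intervals

    @property
    def is_empty(self) -> bool:
        return not self.intervals

    def total_bp(self) -> int:
        return sum(iv.length_bp for iv in self.intervals)

    def merge(self) -> "IntervalSet":
        """Union of overlapping/adjacent intervals, per chromosome."""
        merged: list[Interval] = []
        for iv in self.intervals:
            if (
                merged
                and merged[-1].chromosome == iv.chromosome
                and iv.start <= merged[-1].end
            ):
                last = merged.pop()
                merged.append(
                    Interval(last.chromosome, last.start, max(last.end, iv.end), last.label)
                )
            else:
                merged.append(iv)
        return IntervalSet(merged)

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        return intersect_intervals(self, other)

    def contains_position(self, chromosome: str, position_1based: int) -> bool:
        return any(iv.contains_position(chromosome, position_1based) for iv in self.intervals)


def intersect_intervals(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Exact intersection of two interval sets (same genome labels assumed)."""
    out: list[Interval] = []
    for iva in a:
        for ivb in b:
            if iva.chromosome != ivb.chromosome:
                continue
            start = max(iva.start, ivb.start)
            end = min(iva.end, ivb.end)
            if start < end:
                label = iva.label or ivb.label
                out.append(Interval(iva.chromosome, start, end, label))
    return IntervalSet(out).merge()


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | Path, label: str = "") -> IntervalSet:
    """Read a BED3/BED6 file (0-based half-open) into an IntervalSet.

    The BED ``name`` column, when present, is kept unless an explicit
    ``label`` (e.g. the assay source: H3K4me1, ATAC) overrides it.
    """
    ivs: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise DataValidationError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = label or (parts[3] if len(parts) > 3 else "")
            ivs.append(Interval(chrom, start, end, name))
    return IntervalSet(ivs)


def write_bed(intervals: IntervalSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            if iv.label:
                fh.write(f"{iv.chromosome}\t{iv.start}\t{iv.end}\t{iv.label}\n")
            else:
                fh.write(f"{iv.chromosome}\t{iv.start}\t{iv.end}\n")


# ---------------------------------------------------------------------------
# Genotypes: VCF and dosage-matrix formats
# ---------------------------------------------------------------------------

def _dosage_from_gt(gt: tuple) -> float:
    alleles = [a for a in gt if a is not None]
    if not alleles:
        return np.nan
    if len(alleles) < 2:  # half-missing treated as missing
        return np.nan
    return float(sum(1 for a in alleles if a != 0))


def read_vcf_genotypes(path: str | Path) -> GenotypeMatrix:
    """Read a (possibly gzipped) VCF 4.2 into a :class:`GenotypeMatrix`.

    Multi-allelic records are rejected here; decompose first (the WGS
    prioritization layer does this per alternate allele).
    """
    path = str(path)
    with pysam.VariantFile(path) as vcf:
        samples = list(vcf.header.samples)
        if len(set(samples)) != len(samples):
            raise DataValidationError("duplicated sample IDs in VCF header")
        chroms, poss, refs, alts, ids, rows = [], [], [], [], [], []
        for i, rec in enumerate(vcf.fetch() if vcf.index is not None else vcf):
            if rec.alts is None or len(rec.alts) != 1:
                raise DataValidationError(
                    f"{path}: record {rec.chrom}:{rec.pos} is not biallelic"
                )
            chroms.append(rec.chrom)
            poss.append(rec.pos)
            refs.append(rec.ref)
            alts.append(rec.alts[0])
            ids.append(rec.id or f"{rec.chrom}:{rec.pos}")
            rows.append(
                [_dosage_from_gt(rec.samples[s].get("GT", (None,))) for s in samples]
            )
    dos = np.array(rows, dtype=float).T if rows else np.empty((len(samples), 0))
    return GenotypeMatrix(samples, ids, chroms, poss, refs, alts, dos)


_VCF_GT = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf_genotypes(gm: GenotypeMatrix, path: str | Path,
                        contig_lengths: dict[str, int] | None = None) -> None:
    """Write unphased genotypes as VCF 4.2 via pysam."""
    header = pysam.VariantHeader()
    header.add_meta("FORMAT", items=[("ID", "GT"), ("Number", "1"),
                                     ("Type", "String"), ("Description", "Genotype")])
    lengths = contig_lengths or {}
    for chrom in pd.unique(gm.chromosomes):
        default_len = int(gm.positions[gm.chromosomes == chrom].max()) + 1000
        header.contigs.add(str(chrom), length=lengths.get(chrom, default_len))
    for s in gm.sample_ids:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for j in range(gm.n_snps):
            rec = out.new_record(
                contig=str(gm.chromosomes[j]),
                start=int(gm.positions[j]) - 1,
                stop=int(gm.positions[j]) - 1 + len(gm.ref[j]),
                alleles=(str(gm.ref[j]), str(gm.alt[j])),
                id=str(gm.snp_ids[j]),
            )
            for i, s in enumerate(gm.sample_ids):
                d = gm.dosages[i, j]
                if np.isnan(d):
                    rec.samples[s]["GT"] = (None, None)
                else:
                    rec.samples[s]["GT"] = (0, 1) if d == 1 else ((1, 1) if d == 2 else (0, 0))
            out.write(rec)


def read_dosage_matrix(path: str | Path) -> GenotypeMatrix:
    """Read the transposed tab-separated dosage format (SNP rows).

    Columns: snp_id, chromosome, position, ref, alt, then one column per
    sample with dosages in {0,1,2} or NA.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    required = ["snp_id", "chromosome", "position", "ref", "alt"]
    for col in required:
        if col not in df.columns:
            raise DataValidationError(f"{path}: missing column {col!r}")
    samples = [c for c in df.columns if c not in required]
    dos = df[samples].to_numpy(dtype=float).T
    return GenotypeMatrix(
        sample_ids=samples,
        snp_ids=df["snp_id"].astype(str).tolist(),
        chromosomes=df["chromosome"].to_numpy(),
        positions=df["position"].to_numpy(),
        ref=df["ref"].to_numpy(),
        alt=df["alt"].to_numpy(),
        dosages=dos,
    )


def write_dosage_matrix(gm: GenotypeMatrix, path: str | Path) -> None:
    df = pd.concat(
        [gm.snp_map(), pd.DataFrame(gm.dosages.T, columns=gm.sample_ids)], axis=1
    )
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_genotypes(path: str | Path, fmt: str = "auto") -> GenotypeMatrix:
    """Dispatch to the VCF or dosage-matrix reader.

    ``fmt`` is one of ``vcf``, ``dosage`` or ``auto`` (by extension).
    """
    path = Path(path)
    if fmt == "auto":
        fmt = "vcf" if ".vcf" in path.suffixes or path.suffix in (".vcf", ".gz", ".bcf") else "dosage"
    if fmt == "vcf":
        return read_vcf_genotypes(path)
    if fmt == "dosage":
        return read_dosage_matrix(path)
    raise ValueError(f"unknown genotype format {fmt!r}")


# ---------------------------------------------------------------------------
# Phenotype / covariate tables
# ---------------------------------------------------------------------------

def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read a tab-separated phenotype/covariate table.

    Requires ``sample_id`` and ``phenotype`` (0=control, 1=case) columns;
    extra columns (age, region, tumor_site, ...) pass through.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    for col in ("sample_id", "phenotype"):
        if col not in df.columns:
            raise DataValidationError(f"{path}: missing column {col!r}")
    if df["sample_id"].duplicated().any():
        raise DataValidationError(f"{path}: duplicated sample IDs")
    if not df["phenotype"].isin([0, 1]).all():
        raise DataValidationError(f"{path}: phenotype must be 0/1")
    return df


def write_phenotypes(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# MEME minimal motif format
# ---------------------------------------------------------------------------

def read_meme_motifs(path: str | Path) -> list[dict]:
    """Parse MEME minimal format into dicts with id, matrix, background.

    Returned matrix is (w, 4) position probability over A,C,G,T. The
    background line is optional; uniform is assumed when absent.
    """
    motifs: list[dict] = []
    background = np.full(4, 0.25)
    with open(path) as fh:
        lines = [ln.strip() for ln in fh]
    i = 0
    while i < len(lines):
        line = lines[i]
        if line.startswith("Background letter frequencies"):
            freqs = lines[i + 1].split()
            background = np.array([float(freqs[k]) for k in (1, 3, 5, 7)])
            i += 2
            continue
        if line.startswith("MOTIF"):
            parts = line.split()
            motif_id = parts[1]
            i += 1
            while i < len(lines) and not lines[i].startswith("letter-probability"):
                i += 1
            if i == len(lines):
                raise DataValidationError(f"{path}: MOTIF {motif_id} has no matrix")
            rows = []
            i += 1
            while i < len(lines) and lines[i] and (
                lines[i][0].isdigit() or lines[i][0] == "."
            ):
                rows.append([float(x) for x in lines[i].split()])
                i += 1
            motifs.append(
                {
                    "id": motif_id,
                    "matrix": np.array(rows, dtype=float),
                    "background": background.copy(),
                }
            )
            continue
        i += 1
    return motifs


def write_meme_motifs(motifs: list[dict], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        bg = motifs[0].get("background", np.full(4, 0.25)) if motifs else np.full(4, 0.25)
        fh.write("Background letter frequencies\n")
        fh.write(f"A {bg[0]:.5f} C {bg[1]:.5f} G {bg[2]:.5f} T {bg[3]:.5f}\n\n")
        for m in motifs:
            mat = np.asarray(m["matrix"], dtype=float)
            fh.write(f"MOTIF {m['id']}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {mat.shape[0]} "
                f"nsites= 20 E= 0\n"
            )
            for row in mat:
                fh.write(" ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")
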