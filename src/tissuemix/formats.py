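"""Readers and writers for the external representations the pipeline touches.

Four formats are handled: two-column k-mer multiplicity histograms (as
written by common k-mer counters), VCF variant tables with per-allele read
depths, "sync" pileup count tables (tab-separated, one colon-delimited
A:T:C:G:N:del field per sample), and per-scaffold coverage / chromosome
assignment TSVs. All coordinates are 1-based inclusive, following the
VCF/sync convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pysam

logger = logging.getLogger(__name__)

GENOTYPE_HET = "heterozygous"
GENOTYPE_HOM_ALT = "homozygous_alt"

CHROM_AUTOSOME = "autosome"
CHROM_X = "X"
CHROM_UNKNOWN = "unknown"

#: strict lower bound on retained variant quality, mirroring `QUAL > 20`
QUALITY_THRESHOLD = 20.0

PathLike = Union[str, Path]

__all__ = [
    "KmerHistogram",
    "AlleleDepthRecord",
    "PileupSite",
    "read_kmer_histogram",
    "write_kmer_histogram",
    "read_allele_depths",
    "read_assignment_table",
    "write_assignment_table",
    "read_sync",
    "write_sync",
    "read_coverage_table",
    "write_coverage_table",
]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class KmerHistogram:
    """A k-mer multiplicity spectrum: multiplicity -> count of distinct k-mers.

    Multiplicities must be strictly increasing positive integers; at least
    two entries are required and the counts may not all be zero.
    """

    multiplicities: tuple[int, ...]
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.multiplicities) != len(self.counts):
            raise ValueError("multiplicities and counts differ in length")
        if len(self.multiplicities) < 2:
            raise ValueError("histogram needs at least 2 entries")
        if self.multiplicities[0] < 1:
            raise ValueError("multiplicities must be positive")
        if any(b <= a for a, b in zip(self.multiplicities, self.multiplicities[1:])):
            raise ValueError("multiplicities must be strictly increasing")
        if any(c < 0 for c in self.counts):
            raise ValueError("counts must be non-negative")
        if not any(self.counts):
            raise ValueError("counts are all zero")

    @classmethod
    def from_entries(cls, entries: Iterable[tuple[int, int]]) -> "KmerHistogram":
        pairs = list(entries)
        return cls(
            multiplicities=tuple(int(m) for m, _ in pairs),
            counts=tuple(int(c) for _, c in pairs),
        )

    @property
    def entries(self) -> list[tuple[int, int]]:
        return list(zip(self.multiplicities, self.counts))

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        return (
            np.asarray(self.multiplicities, dtype=np.int64),
            np.asarray(self.counts, dtype=np.float64),
        )


@dataclass(frozen=True)
class AlleleDepthRecord:
    """One biallelic SNP with per-allele read depths.

    ``genotype_class`` is "heterozygous" or "homozygous_alt"; heterozygous
    records must have positive depth on both alleles. ``chrom_class`` is
    "autosome", "X" or "unknown" for scaffolds without an assignment.
    """

    scaffold: str
    position: int
    genotype_class: str
    depth_ref: int
    depth_alt: int
    quality: float
    chrom_class: str = CHROM_UNKNOWN

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.genotype_class not in (GENOTYPE_HET, GENOTYPE_HOM_ALT):
            raise ValueError(f"bad genotype_class {self.genotype_class!r}")
        if self.depth_ref < 0 or self.depth_alt < 0:
            raise ValueError("depths must be non-negative")
        if self.genotype_class == GENOTYPE_HET and (
            self.depth_ref == 0 or self.depth_alt == 0
        ):
            raise ValueError("heterozygous records need positive depth on both alleles")
        if self.chrom_class not in (CHROM_AUTOSOME, CHROM_X, CHROM_UNKNOWN):
            raise ValueError(f"bad chrom_class {self.chrom_class!r}")


@dataclass(frozen=True)
class PileupSite:
    """Per-site base counts in sync order: A, T, C, G, N, deletion."""

    scaffold: str
    position: int
    counts: tuple[int, int, int, int, int, int]

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if len(self.counts) != 6:
            raise ValueError("counts must have exactly 6 entries (A,T,C,G,N,del)")
        if any(c < 0 for c in self.counts):
            raise ValueError("counts must be non-negative")


# ---------------------------------------------------------------------------
# k-mer histograms


def read_kmer_histogram(path: PathLike) -> KmerHistogram:
    """Parse a two-column (multiplicity, count) histogram file."""
    entries: list[tuple[int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 2:
                raise FormatError(
                    f"{path}:{lineno}: expected 2 columns, found {len(parts)}"
                )
            try:
                entries.append((int(parts[0]), int(parts[1])))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer field: {exc}") from exc
    if not entries:
        raise FormatError(f"{path}: empty histogram file")
    try:
        return KmerHistogram.from_entries(entries)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_kmer_histogram(hist: KmerHistogram, path: PathLike) -> None:
    with open(path, "w") as fh:
        for m, c in hist.entries:
            fh.write(f"{m}\t{c}\n")


# ---------------------------------------------------------------------------
# VCF allele depths


def read_assignment_table(path: PathLike) -> dict[str, str]:
    """Read a scaffold -> {autosome, X} assignment TSV.

    Lines whose class is "unassigned" (and comment/header lines) are
    skipped; downstream those scaffolds are treated as "unknown".
    """
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            scaffold, cls = parts[0], parts[1].strip()
            if lineno == 1 and cls.lower() in ("class", "chrom_class"):
                continue
            low = cls.lower()
            if low in ("autosome", "a", "autosomal"):
                mapping[scaffold] = CHROM_AUTOSOME
            elif low == "x":
                mapping[scaffold] = CHROM_X
            elif low in ("unassigned", "unknown", "na"):
                continue
            else:
                raise FormatError(f"{path}:{lineno}: unknown class {cls!r}")
    return mapping


def _depths_from_sample(sample) -> Optional[tuple[int, int]]:
    """Ref/alt depths: dedicated RO/AO observation counts first, AD second."""
    ro = sample.get("RO")
    ao = sample.get("AO")
    if ro is not None and ao is not None:
        ro_v = ro[0] if isinstance(ro, tuple) else ro
        ao_v = ao[0] if isinstance(ao, tuple) else ao
        if ro_v is not None and ao_v is not None:
            return int(ro_v), int(ao_v)
    ad = sample.get("AD")
    if ad is not None and len(ad) >= 2 and ad[0] is not None and ad[1] is not None:
        return int(ad[0]), int(ad[1])
    return None


def read_allele_depths(
    vcf_path: PathLike,
    assignment: Union[Mapping[str, str], PathLike, None] = None,
    sample: Optional[str] = None,
) -> list[AlleleDepthRecord]:
    """Load quality-filtered biallelic SNPs with per-allele depths from a VCF.

    Only biallelic SNP records with QUAL > 20 are retained. Multiallelic
    sites, indels, missing or half genotypes and homozygous-reference calls
    are dropped; records lacking usable depth fields are skipped with a
    logged count. ``assignment`` maps scaffolds to "autosome"/"X" (a
    mapping or a TSV path); unassigned scaffolds get chrom_class
    "unknown".
    """
    if assignment is None:
        assign_map: Mapping[str, str] = {}
    elif isinstance(assignment, (str, Path)):
        assign_map = read_assignment_table(assignment)
    else:
        assign_map = assignment

    records: list[AlleleDepthRecord] = []
    n_missing_depth = 0
    n_dropped = 0  # multiallelic / indel / missing genotype / hom-ref
    with pysam.VariantFile(str(vcf_path)) as vcf:
        if sample is None:
            sample = next(iter(vcf.header.samples))
        for rec in vcf:
            if rec.qual is None or rec.qual <= QUALITY_THRESHOLD:
                continue
            alts = rec.alts
            if alts is None or len(alts) != 1:
                n_dropped += 1
                continue
            if len(rec.ref) != 1 or len(alts[0]) != 1 or alts[0] not in "ACGT":
                n_dropped += 1
                continue
            smp = rec.samples[sample]
            gt = smp.get("GT")
            if gt is None or len(gt) != 2 or None in gt:
                n_dropped += 1
                continue
            alleles = set(gt)
            if alleles == {0, 1}:
                genotype_class = GENOTYPE_HET
            elif alleles == {1}:
                genotype_class = GENOTYPE_HOM_ALT
            else:
                n_dropped += 1
                continue
            depths = _depths_from_sample(smp)
            if depths is None:
                n_missing_depth += 1
                continue
            depth_ref, depth_alt = depths
            if genotype_class == GENOTYPE_HET and (depth_ref == 0 or depth_alt == 0):
                n_missing_depth += 1
                continue
            records.append(
                AlleleDepthRecord(
                    scaffold=rec.chrom,
                    position=rec.pos,
                    genotype_class=genotype_class,
                    depth_ref=depth_ref,
                    depth_alt=depth_alt,
                    quality=float(rec.qual),
                    chrom_class=assign_map.get(rec.chrom, CHROM_UNKNOWN),
                )
            )
    if n_missing_depth:
        logger.info("%d records skipped for unusable depth fields", n_missing_depth)
    if n_dropped:
        logger.info(
            "%d records dropped (multiallelic/indel/missing genotype/hom-ref)",
            n_dropped,
        )
    return records


# ---------------------------------------------------------------------------
# sync pileups


def read_sync(path: PathLike, sample: int = 0) -> list[PileupSite]:
    """Read one sample column of a sync pileup table.

    Columns are scaffold, 1-based position, reference base, then one
    ``A:T:C:G:N:del`` count field per sample; ``sample`` selects the
    0-based sample column.
    """
    sites: list[PileupSite] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 4 + sample:
                raise FormatError(
                    f"{path}:{lineno}: expected >= {4 + sample} columns, "
                    f"found {len(parts)}"
                )
            field = parts[3 + sample]
            bits = field.split(":")
            if len(bits) != 6:
                raise FormatError(
                    f"{path}:{lineno}: count field {field!r} has {len(bits)} parts, "
                    "expected 6 (A:T:C:G:N:del)"
                )
            try:
                counts = tuple(int(b) for b in bits)
                position = int(parts[1])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer field: {exc}") from exc
            sites.append(PileupSite(scaffold=parts[0], position=position, counts=counts))
    return sites


def write_sync(
    sites: Sequence[PileupSite], path: PathLike, ref_bases: Optional[Sequence[str]] = None
) -> None:
    with open(path, "w") as fh:
        for i, site in enumerate(sites):
            ref = ref_bases[i] if ref_bases is not None else "N"
            field = ":".join(str(c) for c in site.counts)
            fh.write(f"{site.scaffold}\t{site.position}\t{ref}\t{field}\n")


# ---------------------------------------------------------------------------
# per-scaffold coverage tables


def read_coverage_table(path: PathLike):
    """Read a per-scaffold coverage TSV with columns scaffold, length, coverage."""
    import pandas as pd

    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        names=["scaffold", "length", "coverage"],
        dtype={"scaffold": str, "length": np.int64, "coverage": np.float64},
    )
    if df.empty:
        raise FormatError(f"{path}: empty coverage table")
    if (df["coverage"] < 0).any() or (df["length"] <= 0).any():
        raise FormatError(f"{path}: negative coverage or non-positive length")
    return df


def write_coverage_table(df, path: PathLike) -> None:
    df.to_csv(path, sep="\t", header=False, index=False, columns=["scaffold", "length", "coverage"])


def write_assignment_table(assignments, path: PathLike) -> None:
    """Write scaffold/class pairs consumable by :func:`read_assignment_table`.

    Accepts a mapping scaffold -> class or an iterable of objects with
    ``scaffold`` and ``chrom_class`` attributes.
    """
    with open(path, "w") as fh:
        if isinstance(assignments, Mapping):
            for scaffold, cls in assignments.items():
                fh.write(f"{scaffold}\t{cls}\n")
        else:
            for a in assignments:
                fh.write(f"{a.scaffold}\t{a.chrom_class}\n")
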