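"""Variant records, VCF round-tripping and site-level filtering.

The upstream aligner/caller is out of scope: this module consumes VCF v4.x
produced elsewhere (or by :mod:`mcoascan.simulate`), decomposes multi-allelic
records into biallelic ones, and applies the site filters used in the MCOA
exclusion analysis: PHRED site quality above 20 and total read depth between
50 and 100,000 (varfilter-style, i.e. the site-level INFO/DP, not per-sample
depth).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pysam

from .intervals import GenomicInterval


class VcfError(ValueError):
    """Malformed VCF input."""


# ---------------------------------------------------------------------------
# genotype calls
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenotypeCall:
    """Unphased diploid genotype over {0=ref, 1=alt}; ``alleles is None`` = missing."""

    alleles: tuple[int, int] | None

    def __post_init__(self) -> None:
        if self.alleles is not None:
            a, b = self.alleles
            if a not in (0, 1) or b not in (0, 1):
                raise ValueError(f"alleles must be 0/1, got {self.alleles}")
            # store unordered
            if a > b:
                object.__setattr__(self, "alleles", (b, a))

    @property
    def is_missing(self) -> bool:
        return self.alleles is None

    @property
    def dosage(self) -> int | None:
        """Number of alt-allele copies, or None if missing."""
        if self.alleles is None:
            return None
        return sum(self.alleles)

    @property
    def is_het(self) -> bool:
        return self.dosage == 1

    def is_hom(self, allele: int) -> bool:
        return self.alleles == (allele, allele)

    @classmethod
    def missing(cls) -> "GenotypeCall":
        return cls(None)

    @classmethod
    def from_dosage(cls, dosage: int) -> "GenotypeCall":
        return cls({0: (0, 0), 1: (0, 1), 2: (1, 1)}[dosage])

    def to_vcf(self) -> str:
        if self.alleles is None:
            return "./."
        return f"{self.alleles[0]}/{self.alleles[1]}"


HOM_REF = GenotypeCall((0, 0))
HET = GenotypeCall((0, 1))
HOM_ALT = GenotypeCall((1, 1))


class VariantClass(str, Enum):
    SNP = "SNP"
    INDEL = "INDEL"


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic variant with site quality, depth and per-sample calls.

    ``genotypes`` maps sample id -> :class:`GenotypeCall`; insertion order is
    the VCF sample-column order and is preserved by readers and writers.
    """

    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    site_quality: float | None = None
    total_depth: int | None = None
    genotypes: dict[str, GenotypeCall] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"ref and alt alleles identical at {self.chrom}:{self.pos}")
        for allele in (self.ref_allele, self.alt_allele):
            if not allele or any(b not in "ACGTN" for b in allele.upper()):
                raise ValueError(f"invalid allele {allele!r} at {self.chrom}:{self.pos}")

    @property
    def variant_class(self) -> VariantClass:
        if len(self.ref_allele) == 1 and len(self.alt_allele) == 1:
            return VariantClass.SNP
        return VariantClass.INDEL

    @property
    def samples(self) -> tuple[str, ...]:
        return tuple(self.genotypes)

    def genotype(self, sample: str) -> GenotypeCall:
        return self.genotypes[sample]


# ---------------------------------------------------------------------------
# VCF I/O (pysam-backed)
# ---------------------------------------------------------------------------

def _decompose(rec: "pysam.VariantRecord") -> list[VariantRecord]:
    """Split a (possibly multi-allelic) pysam record into biallelic records.

    For alt allele k, sample alleles equal to k map to 1 and every other
    non-missing allele maps to 0; missing stays missing.
    """
    out: list[VariantRecord] = []
    alts = rec.alts or ()
    for k, alt in enumerate(alts, start=1):
        genotypes: dict[str, GenotypeCall] = {}
        for name, sample in rec.samples.items():
            gt = sample.get("GT")
            if gt is None or any(a is None for a in gt):
                genotypes[name] = GenotypeCall.missing()
            else:
                genotypes[name] = GenotypeCall(tuple(1 if a == k else 0 for a in gt))
        dp = rec.info.get("DP")
        out.append(
            VariantRecord(
                chrom=rec.chrom,
                pos=rec.pos,
                ref_allele=rec.ref,
                alt_allele=alt,
                site_quality=rec.qual,
                total_depth=int(dp) if dp is not None else None,
                genotypes=genotypes,
            )
        )
    return out


def read_vcf(path: str | Path, region: GenomicInterval | None = None) -> list[VariantRecord]:
    """Read a VCF into biallelic :class:`VariantRecord` objects.

    Multi-allelic sites are decomposed into one record per alt allele sharing
    chrom/pos; records outside ``region`` are dropped.  Sample order follows
    the VCF header.
    """
    try:
        vf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise VcfError(f"cannot parse VCF {path}: {exc}") from exc
    with vf:
        if not list(vf.header.samples):
            raise VcfError(f"VCF {path} has no sample columns")
        records: list[VariantRecord] = []
        for rec in vf:
            if region is not None and not region.contains(rec.pos, rec.chrom):
                continue
            records.extend(_decompose(rec))
    return records


def write_vcf(
    path: str | Path,
    variants: Sequence[VariantRecord],
    samples: Sequence[str],
    contig_lengths: dict[str, int] | None = None,
) -> None:
    """Write biallelic records as uncompressed VCF v4.2 (QUAL, INFO/DP, GT)."""
    header = pysam.VariantHeader()
    header.add_meta("INFO", items=[("ID", "DP"), ("Number", "1"), ("Type", "Integer"),
                                   ("Description", "Total read depth at the site")])
    header.add_meta("FORMAT", items=[("ID", "GT"), ("Number", "1"), ("Type", "String"),
                                     ("Description", "Genotype")])
    chroms = {v.chrom for v in variants}
    for chrom in sorted(chroms):
        length = (contig_lengths or {}).get(chrom, 2**29)
        header.contigs.add(chrom, length=length)
    for s in samples:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in sorted(variants, key=lambda r: (r.chrom, r.pos, r.alt_allele)):
            rec = out.new_record(
                contig=v.chrom,
                start=v.pos - 1,
                alleles=(v.ref_allele, v.alt_allele),
            )
            rec.qual = v.site_quality
            if v.total_depth is not None:
                rec.info["DP"] = v.total_depth
            for s in samples:
                call = v.genotypes.get(s, GenotypeCall.missing())
                rec.samples[s]["GT"] = call.alleles
            out.write(rec)


# ---------------------------------------------------------------------------
# site filters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FilterConfig:
    """Site-level quality/depth thresholds.

    ``quality_strict=True`` implements "qualities above 20" as a strict
    inequality; set False for >=.  ``indel_min_quality`` optionally relaxes
    (or tightens) the quality cut for indels only, mirroring the lower indel
    threshold used upstream; None means same threshold as SNPs.
    """

    min_site_quality: float = 20.0
    min_depth: int = 50
    max_depth: int = 100_000
    quality_strict: bool = True
    indel_min_quality: float | None = None

    def __post_init__(self) -> None:
        if self.min_depth > self.max_depth:
            raise ValueError("min_depth exceeds max_depth")
        if min(self.min_site_quality, self.min_depth) < 0:
            raise ValueError("thresholds must be >= 0")


@dataclass(frozen=True)
class RejectedVariant:
    variant: VariantRecord
    reasons: tuple[str, ...]


@dataclass(frozen=True)
class FilterResult:
    kept: list[VariantRecord]
    rejected: list[RejectedVariant]


def apply_site_filters(
    variants: Iterable[VariantRecord], config: FilterConfig = FilterConfig()
) -> FilterResult:
    """Partition variants into kept / rejected-with-reasons.

    A variant is kept iff its site quality passes the quality comparison and
    min_depth <= total_depth <= max_depth.  Missing quality or depth fails
    the corresponding check (tagged ``quality_missing`` / ``depth_missing``).
    """
    kept: list[VariantRecord] = []
    rejected: list[RejectedVariant] = []
    for v in variants:
        reasons: list[str] = []
        qmin = config.min_site_quality
        if v.variant_class is VariantClass.INDEL and config.indel_min_quality is not None:
            qmin = config.indel_min_quality
        if v.site_quality is None:
            reasons.append("quality_missing")
        elif config.quality_strict:
            if not v.site_quality > qmin:
                reasons.append("quality")
        elif not v.site_quality >= qmin:
            reasons.append("quality")
        if v.total_depth is None:
            reasons.append("depth_missing")
        elif v.total_depth < config.min_depth:
            reasons.append("depth_low")
        elif v.total_depth > config.max_depth:
            reasons.append("depth_high")
        if reasons:
            rejected.append(RejectedVariant(v, tuple(reasons)))
        else:
            kept.append(v)
    return FilterResult(kept=kept, rejected=rejected)


def write_rejection_report(path: str | Path, result: FilterResult) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\treasons\n")
        for r in result.rejected:
            v = r.variant
            fh.write(f"{v.chrom}\t{v.pos}\t{v.ref_allele}\t{v.alt_allele}\t"
                     f"{','.join(r.reasons)}\n")


__all__ = [
    "GenotypeCall", "VariantRecord", "VariantClass", "FilterConfig",
    "FilterResult", "RejectedVariant", "VcfError",
    "read_vcf", "write_vcf", "apply_site_filters", "write_rejection_report",
    "HOM_REF", "HET", "HOM_ALT",
]
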