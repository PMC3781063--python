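"""Conservation and molecular-consequence annotation.

Conservation is element membership against a constraint-element track (the
29-eutherian-mammal elements in the original analysis); consequence calling
uses a minimal gene model (exons, strand, CDS span) plus a reference slice,
translating the affected codon with the standard genetic code.  Only SNP
consequences are called; coding indels are tagged ``coding_indel_unclassified``.

Intervals are 1-based inclusive throughout; BED conversion happens in the
track reader/writer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO
from Bio.SeqUtils import seq3

from .intervals import GenomicInterval, IntervalError
from .variant_io import VariantRecord, VariantClass, HOM_ALT


class AnnotationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# conservation track
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConservationTrack:
    """Sorted, non-overlapping constraint elements (build via normalize_track)."""

    elements: tuple[GenomicInterval, ...]

    def covers(self, chrom: str, pos: int) -> bool:
        # elements are few (tens); linear scan is fine and oracle-simple
        return any(e.contains(pos, chrom) for e in self.elements)

    def covered_bp(self) -> int:
        return sum(e.length() for e in self.elements)


def normalize_track(elements: Iterable[GenomicInterval]) -> ConservationTrack:
    """Merge overlapping/adjacent elements per chromosome and sort."""
    merged: list[GenomicInterval] = []
    for e in sorted(elements):
        if merged and e.chrom == merged[-1].chrom and e.start <= merged[-1].end + 1:
            if e.end > merged[-1].end:
                merged[-1] = GenomicInterval(e.chrom, merged[-1].start, e.end)
        else:
            merged.append(e)
    return ConservationTrack(tuple(merged))


def read_bed_track(path: str | Path) -> ConservationTrack:
    elements = []
    with open(path) as fh:
        for n, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                elements.append(
                    GenomicInterval.from_bed_fields(fields[0], int(fields[1]), int(fields[2]))
                )
            except (IndexError, ValueError, IntervalError) as exc:
                raise AnnotationError(f"bad BED line {n} in {path}: {exc}") from exc
    return normalize_track(elements)


def write_bed_track(path: str | Path, track: ConservationTrack) -> None:
    with open(path, "w") as fh:
        for e in track.elements:
            chrom, start, end = e.to_bed_fields()
            fh.write(f"{chrom}\t{start}\t{end}\n")


# ---------------------------------------------------------------------------
# gene model + reference slice
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    """Minimal single-transcript gene model.

    ``exons`` are genomic-sorted 1-based inclusive intervals; ``cds_start`` /
    ``cds_end`` bound the CDS in genomic coordinates (cds_start <= cds_end
    regardless of strand).  CDS length must be a multiple of 3.
    """

    gene_id: str
    strand: str  # "+" or "-"
    exons: tuple[GenomicInterval, ...]
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise AnnotationError(f"strand must be + or -, got {self.strand!r}")
        for a, b in zip(self.exons, self.exons[1:]):
            if a.chrom != b.chrom or a.end >= b.start:
                raise AnnotationError("exons must be sorted and non-overlapping")
        if not any(e.contains(self.cds_start) for e in self.exons) or not any(
            e.contains(self.cds_end) for e in self.exons
        ):
            raise AnnotationError("CDS bounds must lie within exons")
        if len(self.cds_positions()) % 3 != 0:
            raise AnnotationError("CDS length must be divisible by 3")

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.exons[0].start, self.exons[-1].end)

    def cds_positions(self) -> list[int]:
        """Genomic positions of coding bases, ascending."""
        out: list[int] = []
        for e in self.exons:
            lo = max(e.start, self.cds_start)
            hi = min(e.end, self.cds_end)
            if lo <= hi:
                out.extend(range(lo, hi + 1))
        return out

    def in_exon(self, pos: int) -> bool:
        return any(e.contains(pos) for e in self.exons)

    def cds_index(self, pos: int) -> int | None:
        """1-based transcript CDS coordinate of a genomic position, or None."""
        positions = self.cds_positions()
        if self.strand == "-":
            positions = positions[::-1]
        try:
            return positions.index(pos) + 1
        except ValueError:
            return None

    # --- TSV boundary ---------------------------------------------------
    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#gene_id\t{self.gene_id}\n")
            fh.write(f"#strand\t{self.strand}\n")
            fh.write(f"#cds\t{self.cds_start}\t{self.cds_end}\n")
            fh.write("chrom\tstart\tend\n")
            for e in self.exons:
                fh.write(f"{e.chrom}\t{e.start}\t{e.end}\n")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "GeneModel":
        gene_id = strand = None
        cds: tuple[int, int] | None = None
        exons: list[GenomicInterval] = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#gene_id"):
                    gene_id = line.split("\t")[1]
                elif line.startswith("#strand"):
                    strand = line.split("\t")[1]
                elif line.startswith("#cds"):
                    _, a, b = line.split("\t")
                    cds = (int(a), int(b))
                elif line and not line.startswith(("#", "chrom")):
                    chrom, start, end = line.split("\t")
                    exons.append(GenomicInterval(chrom, int(start), int(end)))
        if gene_id is None or strand is None or cds is None or not exons:
            raise AnnotationError(f"incomplete gene model file {path}")
        return cls(gene_id, strand, tuple(exons), cds[0], cds[1])


@dataclass(frozen=True)
class ReferenceSlice:
    """Reference sequence over an interval (plus-strand), 1-based lookup."""

    chrom: str
    start: int  # genomic position of seq[0]
    seq: str

    @property
    def end(self) -> int:
        return self.start + len(self.seq) - 1

    def base(self, pos: int) -> str:
        if not self.start <= pos <= self.end:
            raise AnnotationError(f"position {pos} outside reference slice "
                                  f"{self.chrom}:{self.start}-{self.end}")
        return self.seq[pos - self.start]

    def write_fasta(self, path: str | Path) -> None:
        rec = SeqRecord(Seq(self.seq), id=self.chrom,
                        description=f"offset={self.start}")
        SeqIO.write([rec], str(path), "fasta")

    @classmethod
    def read_fasta(cls, path: str | Path) -> "ReferenceSlice":
        rec = next(SeqIO.parse(str(path), "fasta"))
        offset = 1
        for token in rec.description.split():
            if token.startswith("offset="):
                offset = int(token.split("=", 1)[1])
        return cls(rec.id, offset, str(rec.seq).upper())


# ---------------------------------------------------------------------------
# consequence calling
# ---------------------------------------------------------------------------

class ConsequenceCategory(str, Enum):
    INTERGENIC = "intergenic"
    INTRONIC = "intronic"
    UTR = "utr"
    SYNONYMOUS = "synonymous"
    MISSENSE = "missense"
    NONSENSE = "nonsense"


_CODING = {ConsequenceCategory.SYNONYMOUS, ConsequenceCategory.MISSENSE,
           ConsequenceCategory.NONSENSE}


@dataclass(frozen=True)
class Consequence:
    category: ConsequenceCategory
    protein_change: str | None = None  # e.g. "Arg625Cys"
    codon_change: str | None = None    # e.g. "CGC>TGC"

    def __post_init__(self) -> None:
        if (self.protein_change is not None) != (self.category in _CODING):
            raise AnnotationError(
                "protein_change must be present iff the consequence is coding"
            )

    def render(self) -> str:
        """Table cell rendering: coding changes by name, the rest 'none'."""
        return self.protein_change if self.protein_change else "none"


def call_consequence(
    variant: VariantRecord, gene: GeneModel, reference: ReferenceSlice
) -> Consequence:
    """Consequence of a SNP against a minimal gene model.

    Outside the gene span -> intergenic; in an intron -> intronic; in an exon
    outside the CDS -> utr; in the CDS the affected codon is translated
    before/after substitution (reverse-complementing on the minus strand) and
    the change is reported as ThreeLetterRef + residue + ThreeLetterAlt with
    residue numbering from the CDS start codon.
    """
    if variant.variant_class is not VariantClass.SNP:
        raise AnnotationError("consequence calling supports SNPs only")
    if variant.chrom != gene.chrom or not gene.span.contains(variant.pos):
        return Consequence(ConsequenceCategory.INTERGENIC)
    if reference.base(variant.pos) != variant.ref_allele:
        raise AnnotationError(
            f"reference mismatch at {variant.chrom}:{variant.pos}: VCF says "
            f"{variant.ref_allele}, reference slice has {reference.base(variant.pos)}"
        )
    if not gene.in_exon(variant.pos):
        return Consequence(ConsequenceCategory.INTRONIC)
    cds_idx = gene.cds_index(variant.pos)
    if cds_idx is None:
        return Consequence(ConsequenceCategory.UTR)

    residue = (cds_idx - 1) // 3 + 1
    offset_in_codon = (cds_idx - 1) % 3  # 0-based within codon, transcript order

    positions = gene.cds_positions()
    if gene.strand == "-":
        positions = positions[::-1]
    codon_genomic = positions[(residue - 1) * 3 : residue * 3]

    def transcript_base(pos: int, substitute: bool) -> str:
        base = variant.alt_allele if (substitute and pos == variant.pos) else reference.base(pos)
        return str(Seq(base).reverse_complement()) if gene.strand == "-" else base

    ref_codon = "".join(transcript_base(p, False) for p in codon_genomic)
    alt_codon = "".join(transcript_base(p, True) for p in codon_genomic)
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())

    if alt_aa == ref_aa:
        category = ConsequenceCategory.SYNONYMOUS
    elif alt_aa == "*":
        category = ConsequenceCategory.NONSENSE
    else:
        category = ConsequenceCategory.MISSENSE

    def three(aa: str) -> str:
        return "Ter" if aa == "*" else seq3(aa)

    return Consequence(
        category=category,
        protein_change=f"{three(ref_aa)}{residue}{three(alt_aa)}",
        codon_change=f"{ref_codon}>{alt_codon}",
    )


# ---------------------------------------------------------------------------
# annotated variants, reference-only classification, reports
# ---------------------------------------------------------------------------

VALID_TAGS = frozenset({
    "reference_only_difference", "concordant", "coding_indel_unclassified",
})


@dataclass
class AnnotatedVariant:
    variant: VariantRecord
    conserved: bool = False
    consequence: Consequence | None = None
    tags: set[str] = field(default_factory=set)

    def add_tag(self, tag: str) -> None:
        if tag not in VALID_TAGS:
            raise AnnotationError(f"unknown tag {tag!r}")
        self.tags.add(tag)


def annotate_conservation(
    variants: Sequence[VariantRecord], track: ConservationTrack
) -> list[AnnotatedVariant]:
    """Mark each variant conserved iff its position lies inside an element."""
    return [
        AnnotatedVariant(v, conserved=track.covers(v.chrom, v.pos)) for v in variants
    ]


def classify_reference_only(
    variants: Sequence[VariantRecord],
) -> tuple[list[AnnotatedVariant], int]:
    """Tag variants where every non-missing genotype is homozygous-alt.

    These sites differ from the reference genome only — the sequenced panel is
    monomorphic — so they carry no case/control information and are excluded
    from candidacy.  Returns (annotated list, tagged count).
    """
    out: list[AnnotatedVariant] = []
    count = 0
    for v in variants:
        calls = [c for c in v.genotypes.values() if not c.is_missing]
        av = AnnotatedVariant(v)
        if calls and all(c == HOM_ALT for c in calls):
            av.add_tag("reference_only_difference")
            count += 1
        out.append(av)
    return out, count


def write_candidate_table(path: str | Path, annotated: Sequence[AnnotatedVariant]) -> None:
    """Candidate report shaped like the published candidate table."""
    with open(path, "w") as fh:
        fh.write("Position\tReference allele\tMutant allele\tConserved\tCoding\t"
                 "Predicted consequence\n")
        for av in annotated:
            v = av.variant
            coding = av.consequence is not None and av.consequence.category in _CODING
            fh.write(
                f"{v.chrom}:{v.pos}\t{v.ref_allele}\t{v.alt_allele}\t"
                f"{'yes' if av.conserved else 'no'}\t{'yes' if coding else 'no'}\t"
                f"{av.consequence.render() if av.consequence else 'none'}\n"
            )


__all__ = [
    "ConservationTrack", "GeneModel", "ReferenceSlice", "Consequence",
    "ConsequenceCategory", "AnnotatedVariant", "AnnotationError",
    "normalize_track", "read_bed_track", "write_bed_track",
    "annotate_conservation", "call_consequence", "classify_reference_only",
    "write_candidate_table",
]
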