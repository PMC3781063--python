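"""Incomplete-dominance genotype concordance filtering.

MCOA segregates as an incompletely dominant trait: affected (MCOA) horses are
homozygous for the disease allele, Cyst-phenotype horses are heterozygous and
unaffected horses are homozygous for the opposite allele.  The exclusion step
keeps only variants whose per-sample genotypes exactly match that pattern —
no statistics, just exact pattern matching over the sequenced panel.

Two per-variant flags are produced:

* *candidate* — the full case/intermediate/control pattern holds for some
  orientation of the alleles (either allele may be the disease allele);
* *IBD-compatible* — weaker: all cases are homozygous for one shared allele
  and the intermediate carries at least one copy of it.  Variants violating
  this contradict a shared ancestral case haplotype and are the markers used
  to narrow the IBD interval (controls are not consulted, because controls
  were deliberately chosen to carry near-disease haplotypes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Literal, Sequence

from .variant_io import GenotypeCall, VariantRecord


class ManifestError(ValueError):
    """Sample manifest inconsistent with the genotyped samples."""


class Phenotype(str, Enum):
    CASE = "case"          # MCOA phenotype (homozygous affected)
    INTERMEDIATE = "intermediate"  # Cyst phenotype (heterozygous)
    CONTROL = "control"    # unaffected


@dataclass(frozen=True)
class SampleInfo:
    phenotype: Phenotype
    breed: str


@dataclass(frozen=True)
class SampleManifest:
    entries: dict[str, SampleInfo]

    def samples_with(self, phenotype: Phenotype) -> tuple[str, ...]:
        return tuple(s for s, info in self.entries.items() if info.phenotype == phenotype)

    @property
    def cases(self) -> tuple[str, ...]:
        return self.samples_with(Phenotype.CASE)

    @property
    def intermediates(self) -> tuple[str, ...]:
        return self.samples_with(Phenotype.INTERMEDIATE)

    @property
    def controls(self) -> tuple[str, ...]:
        return self.samples_with(Phenotype.CONTROL)

    def breed(self, sample: str) -> str:
        return self.entries[sample].breed

    def validate_for_filtering(self) -> None:
        if not self.cases or not self.controls:
            raise ManifestError("concordance filtering needs >= 1 case and >= 1 control")

    # --- TSV boundary ---------------------------------------------------
    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("sample_id\tphenotype\tbreed\n")
            for sample, info in self.entries.items():
                fh.write(f"{sample}\t{info.phenotype.value}\t{info.breed}\n")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "SampleManifest":
        entries: dict[str, SampleInfo] = {}
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[:3] != ["sample_id", "phenotype", "breed"]:
                raise ManifestError(f"unexpected manifest header in {path}: {header}")
            for line in fh:
                if not line.strip():
                    continue
                sample, phenotype, breed = line.rstrip("\n").split("\t")[:3]
                if sample in entries:
                    raise ManifestError(f"duplicate sample id {sample!r} in {path}")
                entries[sample] = SampleInfo(Phenotype(phenotype), breed)
        return cls(entries)


@dataclass(frozen=True)
class ConcordancePolicy:
    """How missing genotypes are treated and whether the Cyst horse must be het.

    ``fail_variant`` (default) demands a positively confirmed genotype for
    every required sample; ``ignore_sample`` drops missing samples from the
    pattern check.
    """

    missing_genotype_handling: Literal["fail_variant", "ignore_sample"] = "fail_variant"
    require_intermediate_het: bool = True


@dataclass(frozen=True)
class Violation:
    sample: str
    observed: str
    required: str


@dataclass(frozen=True)
class ExcludedVariant:
    variant: VariantRecord
    violations: tuple[Violation, ...]


@dataclass(frozen=True)
class ConcordanceResult:
    candidates: list[VariantRecord]
    excluded: list[ExcludedVariant]


def _orientation_violations(
    variant: VariantRecord,
    manifest: SampleManifest,
    policy: ConcordancePolicy,
    disease_allele: int,
) -> list[Violation]:
    """Violations under the hypothesis that ``disease_allele`` is causal."""
    other = 1 - disease_allele
    required: list[tuple[str, str, GenotypeCall | None]] = []
    for s in manifest.cases:
        required.append((s, f"hom({'alt' if disease_allele else 'ref'})",
                         GenotypeCall((disease_allele, disease_allele))))
    if policy.require_intermediate_het:
        for s in manifest.intermediates:
            required.append((s, "het", GenotypeCall((0, 1))))
    for s in manifest.controls:
        required.append((s, f"hom({'alt' if other else 'ref'})",
                         GenotypeCall((other, other))))

    violations: list[Violation] = []
    for sample, req_label, req_call in required:
        call = variant.genotypes.get(sample)
        if call is None or call.is_missing:
            if policy.missing_genotype_handling == "fail_variant":
                violations.append(Violation(sample, "missing", req_label))
            continue
        if call != req_call:
            violations.append(Violation(sample, call.to_vcf(), req_label))
    return violations


def concordance_filter(
    variants: Iterable[VariantRecord],
    manifest: SampleManifest,
    policy: ConcordancePolicy = ConcordancePolicy(),
) -> ConcordanceResult:
    """Partition variants into pattern-concordant candidates and excluded rest.

    A variant is a candidate iff for some allele orientation every case is
    homozygous for the disease allele, every intermediate is heterozygous and
    every control is homozygous for the other allele.  For excluded variants
    the violation list of the closer-matching orientation is reported.
    """
    manifest.validate_for_filtering()
    variants = list(variants)
    genotyped = {s for v in variants for s in v.genotypes}
    unmatched = genotyped - set(manifest.entries)
    if unmatched:
        raise ManifestError(f"samples missing from manifest: {sorted(unmatched)}")

    candidates: list[VariantRecord] = []
    excluded: list[ExcludedVariant] = []
    for v in variants:
        per_orientation = [
            _orientation_violations(v, manifest, policy, allele) for allele in (0, 1)
        ]
        best = min(per_orientation, key=len)
        if not best:
            candidates.append(v)
        else:
            excluded.append(ExcludedVariant(v, tuple(best)))
    return ConcordanceResult(candidates=candidates, excluded=excluded)


def is_ibd_compatible(variant: VariantRecord, manifest: SampleManifest) -> bool:
    """True unless the genotypes contradict a shared homozygous case haplotype.

    Compatible iff there is an allele for which every non-missing case is
    homozygous and every non-missing intermediate carries >= 1 copy.  Missing
    genotypes cannot contradict anything and are ignored; a variant with no
    informative case genotype is vacuously compatible.
    """
    case_calls = [variant.genotypes.get(s) for s in manifest.cases]
    case_calls = [c for c in case_calls if c is not None and not c.is_missing]
    int_calls = [variant.genotypes.get(s) for s in manifest.intermediates]
    int_calls = [c for c in int_calls if c is not None and not c.is_missing]
    for allele in (0, 1):
        if all(c.is_hom(allele) for c in case_calls) and all(
            allele in c.alleles for c in int_calls
        ):
            return True
    return False


@dataclass(frozen=True)
class SegregationFlags:
    """Per-variant flags consumed downstream (candidate reports, narrowing)."""

    candidate: bool
    ibd_discordant: bool
    violations: tuple[Violation, ...] = field(default_factory=tuple)


def flag_variants(
    variants: Sequence[VariantRecord],
    manifest: SampleManifest,
    policy: ConcordancePolicy = ConcordancePolicy(),
) -> dict[int, SegregationFlags]:
    """Map variant position -> flags (candidate + IBD-discordance)."""
    result = concordance_filter(variants, manifest, policy)
    candidate_pos = {v.pos for v in result.candidates}
    violations = {e.variant.pos: e.violations for e in result.excluded}
    return {
        v.pos: SegregationFlags(
            candidate=v.pos in candidate_pos,
            ibd_discordant=not is_ibd_compatible(v, manifest),
            violations=violations.get(v.pos, ()),
        )
        for v in variants
    }


def expected_background_pass_rate(
    p: float, n_case: int, n_intermediate: int, n_control: int
) -> float:
    """Probability that an HWE-independent site passes the concordance filter.

    With allele frequency p (q = 1-p), a site passes iff (cases hom one
    allele) x (intermediates het) x (controls hom the other allele), summed
    over the two allele orientations:

        (2pq)^n_int * [ p^(2 n_case) q^(2 n_control) + q^(2 n_case) p^(2 n_control) ]

    Used as the closed-form check that the filter's false-positive rate on
    background sites behaves as expected.
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"allele frequency must be in (0, 1), got {p}")
    if min(n_case, n_intermediate, n_control) < 0:
        raise ValueError("panel counts must be >= 0")
    q = 1.0 - p
    het = (2.0 * p * q) ** n_intermediate
    return het * (
        p ** (2 * n_case) * q ** (2 * n_control)
        + q ** (2 * n_case) * p ** (2 * n_control)
    )


def write_exclusion_audit(path: str | Path, result: ConcordanceResult) -> None:
    """TSV audit: one row per violating sample of each excluded variant."""
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tsample\tobserved\trequired\n")
        for e in result.excluded:
            v = e.variant
            for viol in e.violations:
                fh.write(f"{v.chrom}\t{v.pos}\t{v.ref_allele}\t{v.alt_allele}\t"
                         f"{viol.sample}\t{viol.observed}\t{viol.required}\n")


__all__ = [
    "Phenotype", "SampleInfo", "SampleManifest", "ManifestError",
    "ConcordancePolicy", "Violation", "ExcludedVariant", "ConcordanceResult",
    "SegregationFlags", "concordance_filter", "is_ibd_compatible",
    "flag_variants", "expected_background_pass_rate", "write_exclusion_audit",
]
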