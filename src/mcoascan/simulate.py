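"""Synthetic inputs with planted ground truth.

Generates everything the exclusion pipeline consumes — panel VCF, sample
manifest, constraint-element track, toy gene model + reference slice, per-base
depth tables and a validation-cohort genotype table — together with a truth
ledger stating what was planted, so every downstream stage can be tested
without any sequence download.

The emulated study: a ten-horse panel (five MCOA cases from three breeds, one
Cyst-phenotype intermediate, four controls), a ~208 kb interval on horse
chromosome 6 carrying hundreds of background variants, a causal SNP pair in
complete LD 760 bp apart (only the lower, coding one inside a constraint
element), haplotype-discordance clusters in each flank-exclusion zone, and a
large two-locus genotyped cohort.

Genotype model.  Cases are homozygous for a shared disease haplotype across
the core interval (taken as the reference background plus the two causal
alleles — echoing the original study's deliberate selection of controls with
near-disease haplotypes); the intermediate carries one copy of it; control
genotypes are drawn independently per sample and per site under
Hardy-Weinberg at ``background_allele_freq``.  Sites are independent of each
other (no background LD).  Flank clusters break the sharing the way the
published narrowing did: at the 5' end the Rocky Mountain cases carry a
different haplotype; at the 3' end the Cyst horse does not carry the disease
haplotype.  Background or indel sites whose random genotypes would spuriously
complete the full disease pattern are redrawn, so the planted causal pair is
exactly the set of expected candidates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .annotation import ConservationTrack, GeneModel, ReferenceSlice, normalize_track
from .datasets import CODING_SNP_POS, INTRONIC_SNP_POS, MCOA_REGION
from .intervals import GenomicInterval
from .segregation import Phenotype, SampleInfo, SampleManifest
from .variant_io import HET, HOM_ALT, HOM_REF, GenotypeCall, VariantRecord


class ConfigError(ValueError):
    """A generator configuration violates one of its invariants."""


_BASES = np.array(list("ACGT"))
_STOP_CODONS = {"TAA", "TAG", "TGA"}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# Toy gene geometry, as offsets from the coding causal SNP position c.
# Minus strand (the last exon lies at the lowest coordinates, so the intronic
# SNP 760 bp *downstream* in transcript terms sits at a higher genomic
# coordinate).  CDS = 650 codons; the causal SNP lands at codon 625, position
# 1 (transcript CGC -> TGC, Arg625Cys for a genomic G>A).
_EXON_OFFSETS = ((-504, 196), (896, 1970), (2096, 2796))
_CDS_OFFSETS = (-77, 2696)
_GENE_PAD = 504  # bp of gene span below c


@dataclass(frozen=True)
class PanelConfig:
    region: GenomicInterval = MCOA_REGION
    n_case: int = 5
    n_intermediate: int = 1
    n_control: int = 4
    n_background_snps: int = 547   # 609 SNPs = background + reference-only + causal pair
    n_reference_only: int = 60
    n_indels: int = 129
    conserved_fraction: float = 0.038
    causal_pair_offsets: tuple[int, int] | None = (CODING_SNP_POS, INTRONIC_SNP_POS)
    flank_exclusion_5prime: int = 7_900
    flank_exclusion_3prime: int = 6_500
    background_allele_freq: float = 0.3
    n_flank_discordant_per_side: int = 6
    seed: int = 1

    def validate(self) -> None:
        counts = {
            "n_case": self.n_case, "n_intermediate": self.n_intermediate,
            "n_control": self.n_control, "n_background_snps": self.n_background_snps,
            "n_reference_only": self.n_reference_only, "n_indels": self.n_indels,
            "flank_exclusion_5prime": self.flank_exclusion_5prime,
            "flank_exclusion_3prime": self.flank_exclusion_3prime,
        }
        for name, value in counts.items():
            if value < 0:
                raise ConfigError(f"{name} must be >= 0, got {value}")
        if not 0.0 <= self.conserved_fraction <= 1.0:
            raise ConfigError("conserved_fraction must be in [0, 1]")
        if not 0.0 < self.background_allele_freq < 1.0:
            raise ConfigError("background_allele_freq must be in (0, 1)")
        flanks = self.flank_exclusion_5prime + self.flank_exclusion_3prime
        if self.region.length() < flanks + 1:
            raise ConfigError(
                "region length must be >= flank exclusions + 1 "
                f"({self.region.length()} < {flanks + 1})"
            )
        if self.causal_pair_offsets is not None:
            lo, hi = sorted(self.causal_pair_offsets)
            core_start = self.region.start + self.flank_exclusion_5prime
            core_end = self.region.end - self.flank_exclusion_3prime
            if not (core_start < lo and hi < core_end):
                raise ConfigError(
                    f"causal pair ({lo}, {hi}) must lie strictly inside the "
                    f"post-flank interval {core_start}-{core_end}"
                )
            if lo - _GENE_PAD < self.region.start or lo + _EXON_OFFSETS[-1][1] > self.region.end:
                raise ConfigError("region too small to host the gene model around the causal SNP")


@dataclass(frozen=True)
class CohortConfig:
    n_total: int = 936
    n_carriers_het: int = 24
    n_carriers_hom: int = 4
    n_discordant: int = 0  # carriers of the locus-1 allele who lack the locus-2 allele
    seed: int = 1

    def validate(self) -> None:
        for name in ("n_total", "n_carriers_het", "n_carriers_hom", "n_discordant"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.n_carriers_het + self.n_carriers_hom + self.n_discordant > self.n_total:
            raise ConfigError("carrier + discordant counts exceed n_total")


@dataclass(frozen=True)
class PlantedCNV:
    interval: GenomicInterval
    copy_ratio: float
    samples: tuple[str, ...]


@dataclass(frozen=True)
class TruthSet:
    """Ground-truth ledger consumed by recovery tests."""

    causal_positions: tuple[int, ...] = ()
    expected_candidates: tuple[int, ...] = ()
    flank_discordant_positions: tuple[int, ...] = ()
    planted_reference_only_positions: tuple[int, ...] = ()
    planted_cnvs: tuple[PlantedCNV, ...] = ()
    expected_narrowed_interval: GenomicInterval | None = None

    def __post_init__(self) -> None:
        if not set(self.causal_positions) <= set(self.expected_candidates):
            raise ConfigError("causal positions must be expected candidates")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "causal_positions": list(self.causal_positions),
            "expected_candidates": list(self.expected_candidates),
            "flank_discordant_positions": list(self.flank_discordant_positions),
            "planted_reference_only_positions": list(self.planted_reference_only_positions),
            "planted_cnvs": [
                {"chrom": c.interval.chrom, "start": c.interval.start,
                 "end": c.interval.end, "copy_ratio": c.copy_ratio,
                 "samples": list(c.samples)}
                for c in self.planted_cnvs
            ],
            "expected_narrowed_interval": (
                None if self.expected_narrowed_interval is None else {
                    "chrom": self.expected_narrowed_interval.chrom,
                    "start": self.expected_narrowed_interval.start,
                    "end": self.expected_narrowed_interval.end,
                }
            ),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthSet":
        with open(path) as fh:
            payload = json.load(fh)
        narrowed = payload.get("expected_narrowed_interval")
        return cls(
            causal_positions=tuple(payload["causal_positions"]),
            expected_candidates=tuple(payload["expected_candidates"]),
            flank_discordant_positions=tuple(payload["flank_discordant_positions"]),
            planted_reference_only_positions=tuple(
                payload["planted_reference_only_positions"]
            ),
            planted_cnvs=tuple(
                PlantedCNV(GenomicInterval(c["chrom"], c["start"], c["end"]),
                           c["copy_ratio"], tuple(c["samples"]))
                for c in payload["planted_cnvs"]
            ),
            expected_narrowed_interval=(
                None if narrowed is None else
                GenomicInterval(narrowed["chrom"], narrowed["start"], narrowed["end"])
            ),
        )


@dataclass(frozen=True)
class PanelSimulation:
    variants: list[VariantRecord]
    manifest: SampleManifest
    conservation: ConservationTrack
    gene_model: GeneModel
    reference: ReferenceSlice
    truth: TruthSet


# ---------------------------------------------------------------------------
# panel simulation
# ---------------------------------------------------------------------------

_CASE_BREEDS = ("American Miniature", "Icelandic Horse", "Icelandic Horse",
                "Rocky Mountain Horse", "Rocky Mountain Horse")
_CONTROL_BREEDS = ("American Miniature", "American Miniature",
                   "Rocky Mountain Horse", "Rocky Mountain Horse")


def default_manifest(config: PanelConfig) -> SampleManifest:
    """Sequenced-panel manifest; the 5/1/4 default mirrors the study panel."""
    entries: dict[str, SampleInfo] = {}
    i = 0
    for k in range(config.n_case):
        i += 1
        entries[f"Horse{i}"] = SampleInfo(Phenotype.CASE, _CASE_BREEDS[k % len(_CASE_BREEDS)])
    for _ in range(config.n_intermediate):
        i += 1
        entries[f"Horse{i}"] = SampleInfo(Phenotype.INTERMEDIATE, "American Miniature")
    for k in range(config.n_control):
        i += 1
        entries[f"Horse{i}"] = SampleInfo(
            Phenotype.CONTROL, _CONTROL_BREEDS[k % len(_CONTROL_BREEDS)]
        )
    return SampleManifest(entries)


def _build_gene_and_reference(
    config: PanelConfig, rng: np.random.Generator
) -> tuple[GeneModel, ReferenceSlice, np.ndarray]:
    region = config.region
    if config.causal_pair_offsets is not None:
        c = min(config.causal_pair_offsets)
    else:
        # no planted pair: park the gene at the default relative position
        c = region.start + max(_GENE_PAD + 1, region.length() // 8)
    seq = rng.choice(_BASES, size=region.length())

    exons = tuple(
        GenomicInterval(region.chrom, c + lo, c + hi) for lo, hi in _EXON_OFFSETS
    )
    gene = GeneModel("PMEL", "-", exons, c + _CDS_OFFSETS[0], c + _CDS_OFFSETS[1])

    n_codons = len(gene.cds_positions()) // 3
    causal_residue = 625
    codons: list[str] = []
    for i in range(1, n_codons + 1):
        if i == causal_residue:
            codons.append("CGC")
        elif i == n_codons:
            codons.append("TAA")
        else:
            while True:
                codon = "".join(rng.choice(_BASES, size=3))
                if codon not in _STOP_CODONS:
                    break
            codons.append(codon)
    transcript = "".join(codons)

    positions = gene.cds_positions()[::-1]  # transcript order on the minus strand
    for k, pos in enumerate(positions):
        seq[pos - region.start] = transcript[k].translate(_COMPLEMENT)
    if config.causal_pair_offsets is not None:
        hi = max(config.causal_pair_offsets)
        seq[hi - region.start] = "A"  # the intronic SNP is the published A>T

    reference = ReferenceSlice(region.chrom, region.start, "".join(seq))
    return gene, reference, seq


def _build_conservation(
    config: PanelConfig, rng: np.random.Generator
) -> ConservationTrack:
    region = config.region
    elements: list[GenomicInterval] = []
    covered = 0
    target = int(config.conserved_fraction * region.length())
    if config.causal_pair_offsets is not None:
        lo, hi = sorted(config.causal_pair_offsets)
        anchor = GenomicInterval(
            region.chrom, max(region.start, lo - 100), min(region.end, lo + 200)
        )
        if anchor.end >= hi:  # must not swallow the intronic SNP
            anchor = GenomicInterval(region.chrom, anchor.start, hi - 1)
        elements.append(anchor)
        covered += anchor.length()
        forbidden = hi
    else:
        forbidden = None
    while covered < target:
        size = int(rng.integers(100, 500))
        start = int(rng.integers(region.start, region.end - size + 1))
        element = GenomicInterval(region.chrom, start, start + size - 1)
        if forbidden is not None and element.contains(forbidden):
            continue
        elements.append(element)
        covered += element.length()
    return normalize_track(elements)


def _draw_control_call(rng: np.random.Generator, p: float) -> GenotypeCall:
    return GenotypeCall(tuple(sorted(int(x) for x in rng.random(2) < p)))


def _background_genotypes(
    manifest: SampleManifest, rng: np.random.Generator, p: float
) -> dict[str, GenotypeCall]:
    """Shared-haplotype model: cases hom-ref, intermediate carries one ref copy."""
    calls: dict[str, GenotypeCall] = {}
    for s in manifest.entries:
        phenotype = manifest.entries[s].phenotype
        if phenotype is Phenotype.CASE:
            calls[s] = HOM_REF
        elif phenotype is Phenotype.INTERMEDIATE:
            calls[s] = HET if rng.random() < p else HOM_REF
        else:
            calls[s] = _draw_control_call(rng, p)
    return calls


def _spurious_pattern(calls: dict[str, GenotypeCall], manifest: SampleManifest) -> bool:
    """Would these genotypes pass the full disease pattern by accident?"""
    for allele in (0, 1):
        other = 1 - allele
        if (
            all(calls[s].is_hom(allele) for s in manifest.cases)
            and all(calls[s].is_het for s in manifest.intermediates)
            and all(calls[s].is_hom(other) for s in manifest.controls)
        ):
            return True
    return False


def _site_quality_depth(
    rng: np.random.Generator, indel: bool
) -> tuple[float, int]:
    quality = float(rng.uniform(21.0, 60.0) if indel else rng.uniform(30.0, 900.0))
    depth = int(np.clip(rng.poisson(1_000), 50, 100_000))
    return round(quality, 1), depth


def simulate_panel(config: PanelConfig = PanelConfig()) -> PanelSimulation:
    """Generate the sequenced-panel inputs with planted ground truth.

    Deterministic given ``config.seed``; see the module docstring for the
    genotype model.  Returns variants sorted by position.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    region = config.region
    manifest = default_manifest(config)
    gene, reference, seq = _build_gene_and_reference(config, rng)
    conservation = _build_conservation(config, rng)
    p = config.background_allele_freq

    causal = tuple(sorted(config.causal_pair_offsets)) if config.causal_pair_offsets else ()

    # flank discordance clusters come out of the background-SNP budget
    n5 = config.n_flank_discordant_per_side if config.flank_exclusion_5prime > 0 else 0
    n3 = config.n_flank_discordant_per_side if config.flank_exclusion_3prime > 0 else 0
    n5 = min(n5, config.flank_exclusion_5prime)
    n3 = min(n3, config.flank_exclusion_3prime)
    n_core_bg = config.n_background_snps - n5 - n3
    if n_core_bg < 0:
        raise ConfigError("n_background_snps too small for the flank clusters")

    cluster5: list[int] = []
    if n5:
        inner = region.start + config.flank_exclusion_5prime - 1
        cluster5 = [inner]
        if n5 > 1:
            pool = np.arange(region.start, inner)
            cluster5 += sorted(
                int(x) for x in rng.choice(pool, size=n5 - 1, replace=False)
            )
    cluster3: list[int] = []
    if n3:
        inner = region.end - config.flank_exclusion_3prime + 1
        cluster3 = [inner]
        if n3 > 1:
            pool = np.arange(inner + 1, region.end + 1)
            cluster3 += sorted(
                int(x) for x in rng.choice(pool, size=n3 - 1, replace=False)
            )

    taken = set(causal) | set(cluster5) | set(cluster3)
    pool = np.array([pos for pos in range(region.start, region.end + 1)
                     if pos not in taken])
    n_other = n_core_bg + config.n_reference_only + config.n_indels
    drawn = rng.choice(pool, size=n_other, replace=False)
    bg_positions = [int(x) for x in drawn[:n_core_bg]]
    ref_only_positions = sorted(int(x) for x in drawn[n_core_bg:n_core_bg + config.n_reference_only])
    used = taken | {int(x) for x in drawn}
    indel_positions = [
        int(x) for x in drawn[n_core_bg + config.n_reference_only:]
        # indel REF strings span pos..pos+len; keep them inside the region
        if int(x) <= region.end - 4
    ]
    # (rare) positions too close to the region end are re-homed just inside
    while len(indel_positions) < config.n_indels:
        cand = int(rng.integers(region.start, region.end - 4))
        if cand not in used:
            used.add(cand)
            indel_positions.append(cand)

    def ref_base(pos: int) -> str:
        return str(seq[pos - region.start])

    def alt_base(pos: int) -> str:
        choices = [b for b in "ACGT" if b != ref_base(pos)]
        return str(rng.choice(choices))

    variants: list[VariantRecord] = []

    def add(pos: int, ref: str, alt: str, calls: dict[str, GenotypeCall],
            indel: bool = False) -> None:
        quality, depth = _site_quality_depth(rng, indel)
        variants.append(VariantRecord(region.chrom, pos, ref, alt, quality, depth,
                                      dict(calls)))

    # causal pair: cases hom-alt, intermediate het, controls hom-ref
    causal_calls = {}
    for s, info in manifest.entries.items():
        causal_calls[s] = {Phenotype.CASE: HOM_ALT, Phenotype.INTERMEDIATE: HET,
                           Phenotype.CONTROL: HOM_REF}[info.phenotype]
    if causal:
        lo, hi = causal
        add(lo, ref_base(lo), "A" if ref_base(lo) == "G" else alt_base(lo), causal_calls)
        add(hi, "A", "T", causal_calls)

    # 5' cluster: Rocky Mountain cases carry a different haplotype
    rm_cases = [s for s in manifest.cases
                if manifest.breed(s) == "Rocky Mountain Horse"]
    if not rm_cases or len(rm_cases) == len(manifest.cases):
        rm_cases = list(manifest.cases[-1:])  # fallback: deviate the last case
    for pos in cluster5:
        calls = {s: HOM_REF for s in manifest.entries}
        for s in rm_cases:
            calls[s] = HOM_ALT if len(rm_cases) < len(manifest.cases) else HET
        add(pos, ref_base(pos), alt_base(pos), calls)

    # 3' cluster: the Cyst horse does not carry the disease haplotype
    for pos in cluster3:
        calls = {s: HOM_REF for s in manifest.entries}
        for s in manifest.intermediates:
            calls[s] = HOM_ALT
        if not manifest.intermediates and manifest.cases:
            calls[manifest.cases[-1]] = HET  # degenerate panels: break case sharing
        add(pos, ref_base(pos), alt_base(pos), calls)

    # reference-only differences: the whole panel is homozygous non-reference
    for pos in ref_only_positions:
        add(pos, ref_base(pos), alt_base(pos), {s: HOM_ALT for s in manifest.entries})

    # background SNPs and indels under the shared-haplotype model
    guard = manifest.cases and manifest.controls

    def draw_guarded() -> dict[str, GenotypeCall]:
        for _ in range(100):
            calls = _background_genotypes(manifest, rng, p)
            if not (guard and _spurious_pattern(calls, manifest)):
                return calls
        raise RuntimeError("could not draw non-spurious genotypes")  # pragma: no cover

    for pos in bg_positions:
        add(pos, ref_base(pos), alt_base(pos), draw_guarded())

    for pos in indel_positions:
        if rng.random() < 0.5:  # deletion
            length = int(rng.integers(1, 4))
            ref = "".join(ref_base(pos + k) for k in range(length + 1))
            alt = ref[0]
        else:  # insertion
            ref = ref_base(pos)
            alt = ref + "".join(rng.choice(_BASES, size=int(rng.integers(1, 4))))
        add(pos, ref, alt, draw_guarded(), indel=True)

    variants.sort(key=lambda v: v.pos)

    narrowed = GenomicInterval(
        region.chrom,
        region.start + (config.flank_exclusion_5prime if n5 else 0),
        region.end - (config.flank_exclusion_3prime if n3 else 0),
    )
    truth = TruthSet(
        causal_positions=causal,
        expected_candidates=causal,
        flank_discordant_positions=tuple(sorted(cluster5 + cluster3)),
        planted_reference_only_positions=tuple(ref_only_positions),
        expected_narrowed_interval=narrowed,
    )
    return PanelSimulation(variants, manifest, conservation, gene, reference, truth)


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

def simulate_cohort(config: CohortConfig = CohortConfig()):
    """Two-locus cohort genotype table (pandas DataFrame) plus truth.

    Carriers hold identical dosage at both loci (complete LD) unless
    ``n_discordant`` > 0; heterozygous carriers are labelled Silver and
    homozygous ones chestnut (the coat labels are cosmetic).  Row order is
    shuffled deterministically.
    """
    import pandas as pd

    config.validate()
    rng = np.random.default_rng(config.seed)
    rows: list[tuple[int, int, str]] = []
    rows += [(1, 1, "Silver")] * config.n_carriers_het
    rows += [(2, 2, "Chestnut")] * config.n_carriers_hom
    rows += [(1, 0, "Other")] * config.n_discordant
    rows += [(0, 0, "Other")] * (config.n_total - len(rows))
    order = rng.permutation(len(rows))
    table = pd.DataFrame(
        {
            "horse_id": [f"H{k + 1:04d}" for k in range(len(rows))],
            "locus1_dosage": [rows[i][0] for i in order],
            "locus2_dosage": [rows[i][1] for i in order],
            "coat_label": [rows[i][2] for i in order],
        }
    )
    truth = {
        "n_carriers": config.n_carriers_het + config.n_carriers_hom + config.n_discordant,
        "n_noncarriers": config.n_total - config.n_carriers_het
        - config.n_carriers_hom - config.n_discordant,
        "complete_ld_expected": config.n_discordant == 0,
    }
    return table, truth


# ---------------------------------------------------------------------------
# depth simulation
# ---------------------------------------------------------------------------

def simulate_depth_tracks(
    region: GenomicInterval,
    mean_depths: dict[str, float],
    planted_cnvs: Sequence[PlantedCNV] = (),
    noise_sd: float = 0.0,
    gaps: Sequence[GenomicInterval] = (),
    seed: int = 1,
):
    """Per-base integer depth per sample; deterministic given ``seed``.

    Expected depth is the sample mean, scaled by the copy ratio inside a
    planted CNV for affected samples; Gaussian noise with ``noise_sd`` is
    added and values are rounded and floored at zero.  ``gaps`` become
    zero-depth stretches in every sample (reference-gap emulation).
    """
    from .coverage import DepthTrack

    for sample, mean in mean_depths.items():
        if mean <= 0:
            raise ConfigError(f"mean depth for {sample} must be > 0")
    for cnv in planted_cnvs:
        if not region.contains_interval(cnv.interval):
            raise ConfigError(f"planted CNV {cnv.interval} outside region {region}")
    rng = np.random.default_rng(seed)
    n = region.length()
    tracks = []
    for sample, mean in mean_depths.items():
        expected = np.full(n, float(mean))
        for cnv in planted_cnvs:
            if sample in cnv.samples:
                lo = cnv.interval.start - region.start
                hi = cnv.interval.end - region.start + 1
                expected[lo:hi] = mean * cnv.copy_ratio
        if noise_sd > 0:
            expected = expected + rng.normal(0.0, noise_sd, size=n)
        depth = np.clip(np.rint(expected), 0, None).astype(int)
        for gap in gaps:
            lo = max(gap.start, region.start) - region.start
            hi = min(gap.end, region.end) - region.start + 1
            depth[lo:hi] = 0
        tracks.append(DepthTrack(sample, region, depth))
    return tracks


__all__ = [
    "PanelConfig", "CohortConfig", "PlantedCNV", "TruthSet", "PanelSimulation",
    "ConfigError", "simulate_panel", "simulate_cohort", "simulate_depth_tracks",
    "default_manifest",
]
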