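"""End-to-end orchestration of the exclusion analysis.

Stage order mirrors the study narrative: read variants -> site filters ->
conservation annotation -> reference-only classification -> concordance
filter -> consequence annotation of the survivors -> IBD narrowing ->
cohort LD validation -> relative coverage scan.  One structured log line per
stage records input/output counts, which *is* the count narrative of the
analysis (e.g. "609 SNPs ... only two remained").
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any

from . import annotation as ann
from . import coverage as cov
from . import ld as ldmod
from .intervals import GenomicInterval
from .narrowing import narrow_interval, write_narrowing_report
from .segregation import (
    ConcordancePolicy,
    SampleManifest,
    concordance_filter,
    is_ibd_compatible,
    write_exclusion_audit,
)
from .simulate import (
    CohortConfig,
    PanelConfig,
    PanelSimulation,
    PlantedCNV,
    simulate_cohort,
    simulate_depth_tracks,
    simulate_panel,
)
from .variant_io import (
    FilterConfig,
    VariantClass,
    apply_site_filters,
    read_vcf,
    write_rejection_report,
    write_vcf,
)

log = logging.getLogger("mcoascan")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Paths and thresholds for a pipeline run (flat key=value config file)."""

    vcf: Path
    manifest: Path
    conservation_bed: Path
    gene_model: Path
    reference_fasta: Path
    depth_tsv: Path
    cohort_tsv: Path
    output_dir: Path
    region_chrom: str = "chr6"
    region_start: int = 73_640_494
    region_end: int = 73_848_154
    min_site_quality: float = 20.0
    min_depth: int = 50
    max_depth: int = 100_000
    quality_strict: bool = True
    missing_genotype_handling: str = "fail_variant"
    scan_window_bp: int = 500
    scan_min_abs_log2: float = 0.58
    seed: int = 1

    @property
    def region(self) -> GenomicInterval:
        return GenomicInterval(self.region_chrom, self.region_start, self.region_end)

    def filter_config(self) -> FilterConfig:
        return FilterConfig(
            min_site_quality=self.min_site_quality,
            min_depth=self.min_depth,
            max_depth=self.max_depth,
            quality_strict=self.quality_strict,
        )

    def policy(self) -> ConcordancePolicy:
        return ConcordancePolicy(missing_genotype_handling=self.missing_genotype_handling)

    def validate(self) -> None:
        for name in ("vcf", "manifest", "conservation_bed", "gene_model",
                     "reference_fasta", "depth_tsv", "cohort_tsv"):
            path = getattr(self, name)
            if not Path(path).exists():
                raise FileNotFoundError(f"{name} input does not exist: {path}")
        Path(self.output_dir).mkdir(parents=True, exist_ok=True)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Parse a flat ``key = value`` config file ('#' starts a comment)."""
        values: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                key, _, value = line.partition("=")
                values[key.strip()] = value.strip()
        kwargs: dict[str, Any] = {}
        for f in fields(cls):
            if f.name not in values:
                continue
            raw = values.pop(f.name)
            if f.type in ("Path", Path):
                kwargs[f.name] = Path(raw)
            elif f.type in ("int", int):
                kwargs[f.name] = int(raw)
            elif f.type in ("float", float):
                kwargs[f.name] = float(raw)
            elif f.type in ("bool", bool):
                kwargs[f.name] = raw.lower() in ("1", "true", "yes")
            else:
                kwargs[f.name] = raw
        if values:
            raise ValueError(f"unknown config keys: {sorted(values)}")
        return cls(**kwargs)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for f in fields(self):
                fh.write(f"{f.name} = {getattr(self, f.name)}\n")


@dataclass
class CandidateReport:
    status: str
    counts: dict[str, int]
    narrowed: dict[str, Any]
    candidates: list[dict[str, Any]]
    ld: dict[str, Any]
    cnv_calls: list[dict[str, Any]]
    stages: list[str] = field(default_factory=list)

    def to_dict(self) -> dict[str, Any]:
        return {
            "status": self.status,
            "counts": self.counts,
            "narrowed": self.narrowed,
            "candidates": self.candidates,
            "ld": self.ld,
            "cnv_calls": self.cnv_calls,
            "stages": self.stages,
        }


def _write_report(outdir: Path, payload: dict[str, Any]) -> None:
    with open(outdir / "report.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_pipeline(config: RunConfig) -> CandidateReport:
    """Execute all stages and write report.json plus per-stage artifacts.

    Deterministic for fixed inputs.  On a stage failure, a report with a
    failure marker is flushed before the error propagates.
    """
    config.validate()
    outdir = Path(config.output_dir)
    region = config.region
    counts: dict[str, int] = {}
    stages: list[str] = []
    stage = "setup"
    try:
        stage = "read"
        stages.append(stage)
        variants = read_vcf(config.vcf, region)
        counts["raw"] = len(variants)
        counts["raw_snps"] = sum(
            v.variant_class is VariantClass.SNP for v in variants
        )
        counts["raw_indels"] = counts["raw"] - counts["raw_snps"]
        log.info("read: %d variants (%d SNPs, %d indels)", counts["raw"],
                 counts["raw_snps"], counts["raw_indels"])

        stage = "filter"
        stages.append(stage)
        filtered = apply_site_filters(variants, config.filter_config())
        write_rejection_report(outdir / "rejected_sites.tsv", filtered)
        kept = filtered.kept
        counts["post_filter"] = len(kept)
        counts["filter_rejected"] = len(filtered.rejected)
        log.info("filter: kept %d, rejected %d", len(kept), len(filtered.rejected))

        stage = "annotate_conservation"
        stages.append(stage)
        track = ann.read_bed_track(config.conservation_bed)
        conserved_pos = {v.pos for v in kept if track.covers(v.chrom, v.pos)}
        counts["conserved"] = len(conserved_pos)
        counts["conserved_snps"] = sum(
            v.pos in conserved_pos and v.variant_class is VariantClass.SNP for v in kept
        )
        log.info("conservation: %d sites in constraint elements", counts["conserved"])

        stage = "classify_reference_only"
        stages.append(stage)
        classified, n_ref_only = ann.classify_reference_only(kept)
        counts["reference_only"] = n_ref_only
        informative = [
            av.variant for av in classified
            if "reference_only_difference" not in av.tags
        ]
        counts["candidate_input"] = len(informative)
        log.info("reference-only: %d sites excluded from candidacy", n_ref_only)

        stage = "concordance"
        stages.append(stage)
        manifest = SampleManifest.read_tsv(config.manifest)
        result = concordance_filter(informative, manifest, config.policy())
        write_exclusion_audit(outdir / "exclusion_audit.tsv", result)
        counts["concordant"] = len(result.candidates)
        log.info("concordance: only %d variants remained", len(result.candidates))

        stage = "annotate_consequence"
        stages.append(stage)
        gene = ann.GeneModel.read_tsv(config.gene_model)
        reference = ann.ReferenceSlice.read_fasta(config.reference_fasta)
        annotated = []
        for v in result.candidates:
            av = ann.AnnotatedVariant(v, conserved=v.pos in conserved_pos)
            av.add_tag("concordant")
            if v.variant_class is VariantClass.SNP:
                av.consequence = ann.call_consequence(v, gene, reference)
            elif gene.span.contains(v.pos) and gene.cds_index(v.pos) is not None:
                av.add_tag("coding_indel_unclassified")
            annotated.append(av)
        ann.write_candidate_table(outdir / "candidates.tsv", annotated)

        stage = "narrow"
        stages.append(stage)
        candidate_pos = [v.pos for v in result.candidates]
        discordant_pos = [
            v.pos for v in kept if not is_ibd_compatible(v, manifest)
        ]
        narrowing = narrow_interval(region, candidate_pos, discordant_pos)
        write_narrowing_report(outdir / "narrowing.json", narrowing)
        log.info("narrowing: excluded %d + %d bp, %d bp remain",
                 narrowing.excluded_5prime_bp, narrowing.excluded_3prime_bp,
                 narrowing.narrowed.length())

        stage = "ld"
        stages.append(stage)
        cohort = ldmod.read_cohort_tsv(config.cohort_tsv)
        ld_report = ldmod.analyse_cohort(cohort)
        ldmod.write_ld_report(outdir / "ld.json", ld_report)
        log.info("ld: r^2=%.4f D'=%.4f over %d individuals",
                 ld_report["r_squared"], ld_report["D_prime"],
                 ld_report["n_individuals"])

        stage = "coverage_scan"
        stages.append(stage)
        tracks = cov.read_depth_tsv(config.depth_tsv)
        by_sample = {t.sample_id: t for t in tracks}
        case_tracks = [by_sample[s] for s in manifest.cases if s in by_sample]
        control_tracks = [by_sample[s] for s in manifest.controls if s in by_sample]
        calls = cov.relative_coverage_scan(
            case_tracks, control_tracks,
            window_bp=config.scan_window_bp,
            min_abs_log2=config.scan_min_abs_log2,
        )
        cov.write_cnv_report(outdir / "cnv_calls.bed", outdir / "cnv_calls.json", calls)
        counts["cnv_calls"] = len(calls)
        log.info("coverage scan: %d calls", len(calls))
    except Exception as exc:
        _write_report(outdir, {"status": "failed", "stage": stage, "error": str(exc),
                               "counts": counts, "stages": stages})
        raise PipelineError(stage, exc) from exc

    report = CandidateReport(
        status="ok" if result.candidates else "no candidates",
        counts=counts,
        narrowed={
            "chrom": narrowing.narrowed.chrom,
            "start": narrowing.narrowed.start,
            "end": narrowing.narrowed.end,
            "length_bp": narrowing.narrowed.length(),
            "excluded_5prime_bp": narrowing.excluded_5prime_bp,
            "excluded_3prime_bp": narrowing.excluded_3prime_bp,
        },
        candidates=[
            {
                "position": f"{av.variant.chrom}:{av.variant.pos}",
                "ref": av.variant.ref_allele,
                "alt": av.variant.alt_allele,
                "conserved": av.conserved,
                "coding": bool(av.consequence and av.consequence.protein_change),
                "consequence": av.consequence.render() if av.consequence else "none",
            }
            for av in annotated
        ],
        ld=ld_report,
        cnv_calls=[
            {"chrom": c.window.chrom, "start": c.window.start, "end": c.window.end,
             "log2_ratio": c.log2_ratio, "direction": c.direction}
            for c in calls
        ],
        stages=stages,
    )
    _write_report(outdir, report.to_dict())
    return report


# ---------------------------------------------------------------------------
# simulated-input convenience (used by the CLI and the acceptance script)
# ---------------------------------------------------------------------------

def write_panel_inputs(sim: PanelSimulation, outdir: str | Path) -> dict[str, Path]:
    """Write every panel artifact of a simulation to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "panel.vcf",
        "manifest": outdir / "manifest.tsv",
        "conservation_bed": outdir / "constraint_elements.bed",
        "gene_model": outdir / "gene_model.tsv",
        "reference_fasta": outdir / "reference.fa",
        "truth": outdir / "truth.json",
    }
    samples = list(sim.manifest.entries)
    write_vcf(paths["vcf"], sim.variants, samples,
              contig_lengths={sim.reference.chrom: sim.reference.end + 10_000})
    sim.manifest.write_tsv(paths["manifest"])
    ann.write_bed_track(paths["conservation_bed"], sim.conservation)
    sim.gene_model.write_tsv(paths["gene_model"])
    sim.reference.write_fasta(paths["reference_fasta"])
    sim.truth.to_json(paths["truth"])
    return paths


def simulate_run(
    outdir: str | Path,
    panel_config: PanelConfig = PanelConfig(),
    cohort_config: CohortConfig = CohortConfig(),
    mean_depth: float = 100.0,
    depth_noise_sd: float = 0.0,
    planted_cnvs: tuple[PlantedCNV, ...] = (),
) -> RunConfig:
    """Generate a full simulated input set and the matching RunConfig."""
    outdir = Path(outdir)
    sim = simulate_panel(panel_config)
    paths = write_panel_inputs(sim, outdir)

    cohort, _ = simulate_cohort(cohort_config)
    cohort_path = outdir / "cohort.tsv"
    cohort.to_csv(cohort_path, sep="\t", index=False)

    tracks = simulate_depth_tracks(
        panel_config.region,
        {s: mean_depth for s in sim.manifest.entries},
        planted_cnvs=planted_cnvs,
        noise_sd=depth_noise_sd,
        seed=panel_config.seed + 1,
    )
    depth_path = outdir / "depth.tsv"
    cov.write_depth_tsv(depth_path, tracks)

    config = RunConfig(
        vcf=paths["vcf"],
        manifest=paths["manifest"],
        conservation_bed=paths["conservation_bed"],
        gene_model=paths["gene_model"],
        reference_fasta=paths["reference_fasta"],
        depth_tsv=depth_path,
        cohort_tsv=cohort_path,
        output_dir=outdir / "results",
        region_chrom=panel_config.region.chrom,
        region_start=panel_config.region.start,
        region_end=panel_config.region.end,
        seed=panel_config.seed,
    )
    config.to_file(outdir / "run.cfg")
    return config


__all__ = [
    "RunConfig", "CandidateReport", "PipelineError",
    "run_pipeline", "write_panel_inputs", "simulate_run",
]
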