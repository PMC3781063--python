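# Methods

## The analysis being modelled

MCOA syndrome segregates with incomplete dominance: homozygotes for the
disease allele show the full ocular phenotype, heterozygotes the milder Cyst
phenotype.  That inheritance mode makes the mapping logic *exact* rather
than statistical — across a sequenced panel of five cases, one Cyst horse
and four controls, a causal variant must show cases homozygous for one
allele, the Cyst horse heterozygous, and controls homozygous for the other
allele, at every single animal.  The pipeline therefore contains no
association test and computes no p-values; its core operation is exhaustive
per-sample pattern matching, surrounded by the standard trimmings of a
resequencing study: site-quality/depth filters, conservation and
consequence annotation, IBD-interval narrowing, a cohort LD check on the
surviving pair, and a read-depth scan for structural differences.

## Stage-by-stage notes

### Site filters (`variant_io`)

* Quality: "above 20" is implemented as a strict `>` (`quality_strict=True`);
  a config switch allows `>=` since the phrasing is ambiguous in common
  usage.  Depth bounds (default 50 and 100,000) act on site-level total
  depth (INFO/DP), matching varfilter semantics, not per-sample depth.
* An optional per-class `indel_min_quality` override exists because indel
  calling conventionally uses a laxer threshold; the default applies the
  same cut to both classes since no separate value is established.
* Multi-allelic records are decomposed on read into one biallelic record
  per alt allele; sample alleles equal to that alt map to 1, all other
  non-missing alleles to 0.
* Coordinates are 1-based inclusive internally; BED conversion happens only
  at file boundaries.

### Annotation (`annotation`)

* Conservation is point membership of the variant position in a normalized
  (sorted, merged, both-ends-inclusive) constraint-element track.
* Consequences are called for SNPs only, by translating the affected codon
  before and after substitution with the standard genetic code,
  reverse-complementing on minus-strand genes.  Residue numbering starts at
  the CDS start codon.  Coding indels are tagged
  `coding_indel_unclassified` rather than interpreted.
* The toy *PMEL* model is minus-strand: its last exon lies at a *lower*
  genomic coordinate than the intron carrying the second candidate SNP,
  which is the only geometry in which a coding SNP in the last exon can
  have an intronic neighbour 760 bp higher.  Consequently the causal coding
  change is genomic G>A = transcript C>T (CGC→TGC, Arg625Cys).  Published
  allele labels for this locus are transcript-oriented; this package always
  reports genomic plus-strand alleles and keeps strand explicit.
* `reference_only` classification tags sites where every non-missing
  genotype is homozygous-alt: the "variant" distinguishes the reference
  genome from the panel, not cases from controls, so such sites are
  excluded from candidacy (60 planted by default).

### Concordance filter (`segregation`)

* Matching is orientation-agnostic: either allele may be the disease
  allele.  The filter reports, for each excluded variant, the violating
  samples of the closer-matching orientation.
* Missing genotypes default to `fail_variant` (a candidate must be
  positively confirmed in every required sample); `ignore_sample` is
  available for sparser data.
* `expected_background_pass_rate(p, n_case, n_int, n_ctl)` gives the
  closed-form probability that an iid Hardy–Weinberg site slips through:
  `(2pq)^n_int (p^{2n_case} q^{2n_ctl} + q^{2n_case} p^{2n_ctl})`.
  It is verified in tests against brute-force enumeration over all genotype
  configurations and against vectorized simulation at 10⁵ sites.

### IBD narrowing (`ibd_narrowing`)

* A second, weaker per-variant flag drives narrowing: a variant is
  *IBD-compatible* if some allele has all cases homozygous for it and the
  intermediate carrying at least one copy.  Controls are deliberately not
  consulted: in the emulated design controls were chosen to carry
  near-disease haplotypes, so control genotypes say nothing about where the
  shared case haplotype ends.
* The candidate span anchors the scan: the 5′ cut is one base past the
  innermost incompatible marker below the lowest candidate (3′ symmetric).
  The excluded segment *includes* the contradicting marker, making
  exclusions well-defined to the base pair; this convention is the
  package's own choice.  Incompatible markers between candidates cannot
  trim (the span is positively established) and are reported as
  `interior_discordants` for audit.  If no candidates exist, markers are
  assigned to the nearer edge; boundaries that cross raise
  "no IBD core remains".
* The default generator splits the 14.4 kb of exclusions as 7.9 kb at 5′
  (Rocky Mountain cases on a different haplotype) + 6.5 kb at 3′ (the Cyst
  horse off the disease haplotype); only the total is established, the
  split is a package choice.

### Cohort LD (`ld_cohort`)

* Haplotype frequencies for unphased two-locus dosage data are estimated by
  EM: all genotype classes except the double heterozygote are
  phase-determined; the double-het class is split between coupling and
  repulsion by its expected proportion each iteration.  Initialization is
  at linkage equilibrium (products of observed allele frequencies),
  tolerance 1e-10 on the largest frequency change, max 1000 iterations —
  conventional values.  The log-likelihood is non-decreasing across
  iterations (tested), and the estimate attains an exhaustive
  grid-search-oracle likelihood within 1e-6 on random tables.
* D = p_AB − p_A p_B, D′ = |D|/D_max with the usual frequency-dependent
  bound, r² = D²/(p_A q_A p_B q_B).  Monomorphic loci yield a flagged
  degenerate result with all statistics 0 instead of an exception, so batch
  runs do not abort.
* `complete_ld_check` is the direct cohort-level statement: every
  individual carries identical dosage at both loci.  With both loci
  polymorphic this implies r² = 1.

### Coverage scan (`coverage_scan`)

* Each track is normalized by its own mean, making the scan invariant to
  absolute yield; the statistic per non-overlapping window (default 500 bp)
  is log2 of the case-vs-control ratio of mean normalized depth, and
  windows with |log2| ≥ 0.58 (≈1.5-fold, sized to catch a single-copy
  change while tolerating noise) are reported, merged when adjacent with
  the same direction.  Window size and threshold are package choices; no
  values are established for the original per-base assessment.
* Bases with zero depth in every sample emulate unalignable reference gaps
  and are masked; windows more than half masked are skipped.
* Mean normalization slightly attenuates the expected log2 when the event
  is a large fraction of the interval; at realistic proportions (a few kb
  in ~200 kb) a heterozygous deletion scores ≈ −1.0 and a 1.5× duplication
  ≈ +0.585.

## The synthetic-data generator

Defaults emulate the study conditions: a 207,661 bp interval
(chr6:73,640,494–73,848,154); a 5/1/4 panel across American Miniature,
Icelandic and Rocky Mountain breeds; 609 SNPs (547 background + 60
reference-only + the causal pair) and 129 indels; a conserved-track
coverage fraction of 0.038 (≈23 of 609 SNPs in elements, in expectation); a
causal pair 760 bp apart with only the lower, coding SNP inside an element;
flank-discordance clusters of six markers per side whose innermost markers
sit exactly at the planted 7,900/6,500 bp boundaries; and a 936-horse
cohort with 24 + 4 carriers in complete LD (the het/hom split of the 28
carriers is a generator parameter, as the true split is not established).
Background allele frequency defaults to 0.3, a typical intermediate SNP
frequency; site qualities and depths are drawn comfortably inside the
filter thresholds, since filter behaviour is exercised by dedicated unit
tests rather than by the default scenario.

Genotype model: cases are homozygous for a shared disease haplotype across
the core interval — represented as the reference background plus the two
causal alt alleles — and the intermediate carries one copy of it; controls
are iid Hardy–Weinberg.  Sites are mutually independent (no background LD),
which is all the concordance filter can see.  This case/intermediate
structure is what makes interval narrowing well-posed: if every sample were
iid at every site, essentially all sites would contradict haplotype sharing
and the planted flank boundaries would be unrecoverable.  Background or
indel sites whose random control/intermediate draws would spuriously
complete the full disease pattern (probability ≈ p⁹ per site) are redrawn,
so the planted pair is exactly the expected candidate set for every seed.

All randomness flows from a single integer seed per generator call;
identical configs and seeds produce byte-identical files (tested).

What the generator does *not* model — and what passing tests therefore do
not show about real data: read-level errors and mapping artifacts, genotype
calling uncertainty (no missing calls by default), background LD and breed
structure within sites, GC-dependent coverage, and amplicon tiling.  Depth
is generated at desk scale (default mean 100×, not the ~11,000–16,000× of
the original panel); no downstream logic depends on absolute depth except
the min/max thresholds, which scale accordingly.  The two reference-genome
gaps (100 and 640 bp) can be emulated as zero-depth stretches but are off
by default.

## Problem sizes and determinism in the checks

The test suite regenerates all fixtures programmatically: full-scale panels
(738 variants, 10 samples) across ≥25 seeds for truth recovery, 10⁵-site
vectorized matrices for the pass-rate law, exhaustive enumeration (3¹⁰
configurations) for the closed form, and 100 kb depth intervals for CNV
recovery.  The acceptance script runs one full pipeline at default scale
plus the published-table aggregations; everything completes in well under
a minute on one CPU.  Hypothesis-based property tests are derandomized.

## Known limitations

* The narrowing convention (marker-inclusive exclusion, candidate-anchored
  scan) is one of several defensible readings; alternatives shift
  boundaries by one marker spacing.
* Conserved-SNP counts are binomial around their expectation (SD ≈ 5 at
  default scale), so individual seeds vary around ≈23–26.
* The EM estimator returns a *flagged* zero for monomorphic loci rather
  than attempting boundary-case inference.
* Consequence calling handles single-nucleotide substitutions in a single
  transcript model; splice-site effects, multi-transcript genes and indel
  consequences are out of scope.
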