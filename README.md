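# mcoascan

Variant-exclusion mapping of the equine **MCOA/Silver** locus, packaged as a
tested, reusable pipeline.

Equine Multiple Congenital Ocular Anomalies (MCOA) syndrome is an
incompletely dominant eye disorder: horses homozygous for the disease allele
show the full MCOA phenotype, heterozygotes the milder "Cyst" phenotype.
The causal gene was pinned down by deep-sequencing a previously mapped
~208 kb identity-by-descent (IBD) interval on horse chromosome 6
(chr6:73,640,494–73,848,154) in ten animals — five MCOA cases from three
breeds, one Cyst-phenotype horse, four unaffected controls — and then
*excluding* every polymorphism that could not be causal.  Two SNPs in *PMEL*
survive: an intronic SNP and, 760 bp away, a coding missense change
(Arg625Cys) inside a mammalian constraint element.

`mcoascan` re-implements every computational stage of that exclusion
analysis and exercises it on synthetic data with planted ground truth, so
the whole cascade is testable without any sequence download:

1. **Site filtering** (`variant_io`) — PHRED site quality > 20, total depth
   within [50, 100 000] (varfilter-style).
2. **Annotation** (`annotation`) — constraint-element membership and
   molecular consequence from a minimal gene model (codon translation,
   strand-aware); classification of *reference-only* sites where the whole
   panel is homozygous non-reference.
3. **Concordance filtering** (`segregation`) — the core exclusion step: keep
   a variant only if, for some allele orientation, every case is homozygous
   for the disease allele, the Cyst horse heterozygous, and every control
   homozygous for the opposite allele.  For an iid Hardy–Weinberg site this
   happens with probability
   `(2pq)^n_int · [p^(2n_case) q^(2n_ctl) + q^(2n_case) p^(2n_ctl)]`
   (≈ 3.8 × 10⁻⁶ for the 5/1/4 panel at p = 0.5).
4. **IBD narrowing** (`ibd_narrowing`) — trim each flank to one base past
   the innermost marker whose genotypes contradict the shared case
   haplotype (14.4 kb excluded, 193.3 kb remaining in the emulated study).
5. **Cohort LD validation** (`ld_cohort`) — EM haplotype-frequency
   estimation for unphased two-locus genotypes (double heterozygotes split
   by expected phase), then D, D′ = |D|/D_max and r² = D²/(p_A q_A p_B q_B).
   A cohort in complete LD gives D′ = r² = 1.
6. **Relative coverage scan** (`coverage_scan`) — windowed case-vs-control
   log2 ratio of mean-normalized per-base depth, for large insertions,
   deletions and copy-number differences.
7. **Synthetic data** (`synthetic_data`) — seeded generators for the panel
   VCF, manifest, constraint BED, gene model + reference FASTA, per-base
   depth TSVs and the 936-horse two-locus cohort, each with a JSON truth
   ledger.

## Worked example

```bash
mcoascan simulate-run --outdir demo --seed 1
mcoascan -v run demo/run.cfg
```

prints one log line per stage and then:

```
{"counts": {"candidate_input": 678, "cnv_calls": 0, "concordant": 2, "conserved": 30,
"conserved_snps": 26, "filter_rejected": 0, "post_filter": 738, "raw": 738,
"raw_indels": 129, "raw_snps": 609, "reference_only": 60}, "status": "ok"}
```

Reading: of 738 variants (609 SNPs + 129 indels, the emulated inventory),
none fail the quality/depth filters, 60 SNPs are reference-only differences
carrying no case/control information, and after exact inheritance-pattern
matching **only two candidates remain** — the planted pair.
`demo/results/candidates.tsv` shows them:

```
Position	Reference allele	Mutant allele	Conserved	Coding	Predicted consequence
chr6:73665304	G	A	yes	yes	Arg625Cys
chr6:73666064	A	T	no	no	none
```

`demo/results/narrowing.json` records 7,900 + 6,500 = 14,400 bp of flank
exclusions leaving a 193,261 bp (≈193.3 kb) IBD core, and
`demo/results/ld.json` shows the simulated 936-horse cohort in complete LD
(r² = D′ = 1; 28 carriers, 908 non-carriers).  Alleles are reported on the
genomic plus strand; the gene model is minus-strand, so the genomic G>A is
the transcript C>T that converts codon 625 CGC (Arg) to TGC (Cys).

Every stage is also available as its own subcommand
(`filter`, `annotate`, `segregate`, `narrow`, `ld`, `scan-coverage`,
`simulate-panel`, `simulate-cohort`, `simulate-depth`, `report`).

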