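import numpy as np
import pytest
from Bio.Seq import Seq
from hypothesis import given, settings
from hypothesis import strategies as st

from mcoascan.annotation import (
    AnnotationError,
    GeneModel,
    ReferenceSlice,
    annotate_conservation,
    call_consequence,
    classify_reference_only,
    normalize_track,
    read_bed_track,
    write_bed_track,
)
from mcoascan.intervals import GenomicInterval
from mcoascan.variant_io import HET, HOM_ALT, VariantRecord


def iv(start, end, chrom="chr1"):
    return GenomicInterval(chrom, start, end)


# ---------------------------------------------------------------------------
# conservation track
# ---------------------------------------------------------------------------

class TestNormalizeTrack:
    def test_overlapping_elements_merge(self):
        track = normalize_track([iv(10, 20), iv(15, 30)])
        assert track.elements == (iv(10, 30),)

    def test_adjacent_elements_merge(self):
        track = normalize_track([iv(10, 20), iv(21, 30)])
        assert track.elements == (iv(10, 30),)

    def test_disjoint_elements_sorted_unchanged(self):
        track = normalize_track([iv(50, 60), iv(10, 20)])
        assert track.elements == (iv(10, 20), iv(50, 60))

    @settings(derandomize=True, max_examples=100)
    @given(
        st.lists(
            st.tuples(st.integers(1, 200), st.integers(0, 30)),
            min_size=0, max_size=15,
        )
    )
    def test_covered_bp_matches_per_base_union_oracle(self, raw):
        elements = [iv(start, start + span) for start, span in raw]
        track = normalize_track(elements)
        oracle = set()
        for e in elements:
            oracle.update(range(e.start, e.end + 1))
        assert track.covered_bp() == len(oracle)
        for pos in range(1, 240):
            assert track.covers("chr1", pos) == (pos in oracle)


def test_bed_round_trip(tmp_path):
    track = normalize_track([iv(10, 20, "chr6"), iv(50, 60, "chr6")])
    path = tmp_path / "track.bed"
    write_bed_track(path, track)
    assert path.read_text() == "chr6\t9\t20\nchr6\t49\t60\n"
    assert read_bed_track(path).elements == track.elements


class TestAnnotateConservation:
    def test_element_membership_with_inclusive_boundaries(self):
        track = normalize_track([iv(100, 200, "chr6")])
        variants = [
            VariantRecord("chr6", pos, "A", "T", 30, 60, {"s": HET})
            for pos in (99, 100, 150, 200, 201)
        ]
        annotated = annotate_conservation(variants, track)
        assert [av.conserved for av in annotated] == [False, True, True, True, False]

    def test_empty_track_marks_nothing(self):
        track = normalize_track([])
        variants = [VariantRecord("chr6", 5, "A", "T", 30, 60, {"s": HET})]
        assert not annotate_conservation(variants, track)[0].conserved

    def test_causal_pair_split_on_panel_track(self, default_sim):
        # the planted element covers the coding SNP but not the intronic one
        lo, hi = default_sim.truth.causal_positions
        assert default_sim.conservation.covers("chr6", lo)
        assert not default_sim.conservation.covers("chr6", hi)


# ---------------------------------------------------------------------------
# consequence calling vs an independent translate-then-diff oracle
# ---------------------------------------------------------------------------

def spliced_cds(gene, seq_str, start=1):
    cds = "".join(seq_str[p - start] for p in gene.cds_positions())
    if gene.strand == "-":
        cds = str(Seq(cds).reverse_complement())
    return cds


def oracle_consequence(gene, seq_str, pos, alt, start=1):
    """Independent oracle: translate the whole CDS before/after substitution."""
    before = spliced_cds(gene, seq_str, start)
    mutated = list(seq_str)
    mutated[pos - start] = alt
    after = spliced_cds(gene, "".join(mutated), start)
    prot_before = str(Seq(before).translate())
    prot_after = str(Seq(after).translate())
    diffs = [i for i, (a, b) in enumerate(zip(prot_before, prot_after)) if a != b]
    if not diffs:
        return "synonymous", None
    (i,) = diffs
    if prot_after[i] == "*":
        return "nonsense", i + 1
    return "missense", i + 1


@pytest.mark.parametrize("strand", ["+", "-"])
def test_every_cds_substitution_agrees_with_translation_oracle(strand):
    rng = np.random.default_rng(11)
    seq = "".join(rng.choice(list("ACGT"), size=60))
    exons = (iv(11, 25, "chrT"), iv(36, 50, "chrT"))
    # CDS bases: 14..25 in exon 1 (12) + 36..47 in exon 2 (12) = 8 codons
    gene = GeneModel("toy", strand, exons, 14, 47)
    ref = ReferenceSlice("chrT", 1, seq)
    for pos in gene.cds_positions():
        for alt in "ACGT":
            if alt == seq[pos - 1]:
                continue
            v = VariantRecord("chrT", pos, seq[pos - 1], alt, 30, 60, {"s": HET})
            got = call_consequence(v, gene, ref)
            category, residue = oracle_consequence(gene, seq, pos, alt)
            assert got.category.value == category
            if residue is not None:
                assert got.protein_change is not None
                digits = "".join(c for c in got.protein_change if c.isdigit())
                assert int(digits) == residue


def test_gene_regions_classified():
    rng = np.random.default_rng(3)
    seq = "".join(rng.choice(list("ACGT"), size=60))
    exons = (iv(11, 25, "chrT"), iv(36, 50, "chrT"))
    gene = GeneModel("toy", "+", exons, 14, 47)
    ref = ReferenceSlice("chrT", 1, seq)

    def consequence_at(pos):
        alt = "A" if seq[pos - 1] != "A" else "C"
        v = VariantRecord("chrT", pos, seq[pos - 1], alt, 30, 60, {"s": HET})
        return call_consequence(v, gene, ref)

    assert consequence_at(5).category.value == "intergenic"
    assert consequence_at(30).category.value == "intronic"
    assert consequence_at(12).category.value == "utr"  # exonic, before CDS
    assert consequence_at(30).render() == "none"


def test_known_codon_change_arg_to_cys():
    # codon CGC with C>T at its first position on the + strand: Arg -> Cys
    seq = "AAACGCGGGTAA"  # codons: AAA CGC GGG TAA
    gene = GeneModel("mini", "+", (iv(1, 12, "chrT"),), 1, 12)
    ref = ReferenceSlice("chrT", 1, seq)
    v = VariantRecord("chrT", 4, "C", "T", 30, 60, {"s": HET})
    got = call_consequence(v, gene, ref)
    assert got.category.value == "missense"
    assert got.protein_change == "Arg2Cys"
    assert got.codon_change == "CGC>TGC"


def test_strand_symmetry_on_mirrored_gene():
    """A - strand gene equals its reverse complement annotated on +."""
    rng = np.random.default_rng(13)
    n = 60
    seq = "".join(rng.choice(list("ACGT"), size=n))
    exons = (iv(11, 25, "chrT"), iv(36, 50, "chrT"))
    gene_minus = GeneModel("toy", "-", exons, 14, 47)
    ref_minus = ReferenceSlice("chrT", 1, seq)

    mirrored_seq = str(Seq(seq).reverse_complement())
    mirror = lambda pos: n - pos + 1
    mirrored_exons = tuple(
        iv(mirror(e.end), mirror(e.start), "chrT") for e in reversed(exons)
    )
    gene_plus = GeneModel("toy", "+", mirrored_exons, mirror(47), mirror(14))
    ref_plus = ReferenceSlice("chrT", 1, mirrored_seq)

    for pos in gene_minus.cds_positions():
        base = seq[pos - 1]
        for alt in "ACGT":
            if alt == base:
                continue
            v = VariantRecord("chrT", pos, base, alt, 30, 60, {"s": HET})
            got = call_consequence(v, gene_minus, ref_minus)
            comp = str(Seq(alt).complement())
            mpos = mirror(pos)
            mv = VariantRecord("chrT", mpos, mirrored_seq[mpos - 1], comp, 30, 60,
                               {"s": HET})
            expected = call_consequence(mv, gene_plus, ref_plus)
            assert (got.category, got.protein_change, got.codon_change) == (
                expected.category, expected.protein_change, expected.codon_change)


def test_indel_and_ref_mismatch_are_errors():
    seq = "AAACGCGGGTAA"
    gene = GeneModel("mini", "+", (iv(1, 12, "chrT"),), 1, 12)
    ref = ReferenceSlice("chrT", 1, seq)
    with pytest.raises(AnnotationError):
        call_consequence(
            VariantRecord("chrT", 4, "CG", "C", 30, 60, {"s": HET}), gene, ref)
    with pytest.raises(AnnotationError):
        call_consequence(
            VariantRecord("chrT", 4, "G", "T", 30, 60, {"s": HET}), gene, ref)


# ---------------------------------------------------------------------------
# reference-only classification
# ---------------------------------------------------------------------------

class TestReferenceOnly:
    def test_all_hom_alt_is_tagged(self):
        v = VariantRecord("chr6", 10, "A", "T", 30, 60,
                          {f"s{i}": HOM_ALT for i in range(10)})
        annotated, count = classify_reference_only([v])
        assert count == 1
        assert "reference_only_difference" in annotated[0].tags

    def test_one_het_prevents_tagging(self):
        calls = {f"s{i}": HOM_ALT for i in range(9)}
        calls["s9"] = HET
        v = VariantRecord("chr6", 10, "A", "T", 30, 60, calls)
        _, count = classify_reference_only([v])
        assert count == 0

    def test_planted_reference_only_count_recovered(self, default_sim, default_config):
        _, count = classify_reference_only(default_sim.variants)
        assert count == default_config.n_reference_only == 60
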