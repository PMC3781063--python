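import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mcoascan.segregation import (
    ConcordancePolicy,
    ManifestError,
    Phenotype,
    SampleInfo,
    SampleManifest,
    concordance_filter,
    expected_background_pass_rate,
    is_ibd_compatible,
)
from mcoascan.variant_io import HET, HOM_ALT, HOM_REF, GenotypeCall, VariantRecord


def manifest(n_case=5, n_intermediate=1, n_control=4):
    entries = {}
    for i in range(n_case):
        entries[f"case{i}"] = SampleInfo(Phenotype.CASE, "b")
    for i in range(n_intermediate):
        entries[f"int{i}"] = SampleInfo(Phenotype.INTERMEDIATE, "b")
    for i in range(n_control):
        entries[f"ctl{i}"] = SampleInfo(Phenotype.CONTROL, "b")
    return SampleManifest(entries)


def variant(calls, pos=100):
    return VariantRecord("chr6", pos, "A", "T", 30, 60, calls)


def perfect_calls(mani, disease_allele=1):
    other = 1 - disease_allele
    calls = {}
    for s in mani.cases:
        calls[s] = GenotypeCall((disease_allele, disease_allele))
    for s in mani.intermediates:
        calls[s] = HET
    for s in mani.controls:
        calls[s] = GenotypeCall((other, other))
    return calls


# ---------------------------------------------------------------------------
# concordance filter behaviour
# ---------------------------------------------------------------------------

class TestConcordanceFilter:
    def test_worked_example_two_sites_survive(self):
        """5 cases hom-alt / 1 Cyst het / 4 controls hom-ref at two sites,
        violating backgrounds everywhere else -> exactly the two sites remain."""
        mani = manifest()
        good1 = variant(perfect_calls(mani), pos=73_665_304)
        good2 = variant(perfect_calls(mani), pos=73_666_064)
        bad = []
        for k in range(20):
            calls = perfect_calls(mani)
            sample = list(calls)[k % len(calls)]
            calls[sample] = HET if not calls[sample].is_het else HOM_REF
            bad.append(variant(calls, pos=1000 + k))
        result = concordance_filter([good1, good2, *bad], mani)
        assert sorted(v.pos for v in result.candidates) == [73_665_304, 73_666_064]
        assert len(result.excluded) == 20

    def test_violation_names_the_offending_sample(self):
        mani = manifest()
        calls = perfect_calls(mani)
        calls["ctl2"] = HET
        result = concordance_filter([variant(calls)], mani)
        assert not result.candidates
        assert [v.sample for v in result.excluded[0].violations] == ["ctl2"]

    def test_orientation_agnostic(self):
        """Cases hom-REF / controls hom-ALT also matches (either allele may
        be the disease allele)."""
        mani = manifest()
        result = concordance_filter([variant(perfect_calls(mani, disease_allele=0))],
                                    mani)
        assert len(result.candidates) == 1

    def test_missing_genotype_policies(self):
        mani = manifest()
        calls = perfect_calls(mani)
        calls["case0"] = GenotypeCall.missing()
        v = variant(calls)
        strict = concordance_filter([v], mani)
        assert not strict.candidates
        lenient = concordance_filter(
            [v], mani, ConcordancePolicy(missing_genotype_handling="ignore_sample"))
        assert lenient.candidates

    def test_unknown_sample_raises(self):
        mani = manifest(1, 0, 1)
        v = variant({"case0": HOM_ALT, "ctl0": HOM_REF, "ghost": HET})
        with pytest.raises(ManifestError, match="ghost"):
            concordance_filter([v], mani)

    def test_needs_cases_and_controls(self):
        with pytest.raises(ManifestError):
            concordance_filter([], manifest(0, 1, 4))


def naive_concordant(calls, mani):
    """Independent oracle: explicit loop over both allele orientations."""
    for disease in (0, 1):
        ok = True
        for s in mani.cases:
            ok &= calls[s].alleles == (disease, disease)
        for s in mani.intermediates:
            ok &= calls[s].alleles == (0, 1)
        for s in mani.controls:
            ok &= calls[s].alleles == (1 - disease, 1 - disease)
        if ok:
            return True
    return False


@settings(derandomize=True, max_examples=200)
@given(st.integers(0, 2**32 - 1))
def test_filter_equals_naive_oracle_on_random_genotypes(seed):
    rng = np.random.default_rng(seed)
    mani = manifest(int(rng.integers(1, 4)), int(rng.integers(0, 3)),
                    int(rng.integers(1, 4)))
    samples = list(mani.entries)
    variants = []
    for pos in range(1, 40):
        calls = {
            s: GenotypeCall.from_dosage(int(rng.integers(0, 3))) for s in samples
        }
        variants.append(variant(calls, pos=pos))
    result = concordance_filter(variants, mani)
    expected = {v.pos for v in variants if naive_concordant(v.genotypes, mani)}
    assert {v.pos for v in result.candidates} == expected


# ---------------------------------------------------------------------------
# closed-form background pass rate
# ---------------------------------------------------------------------------

def brute_force_pass_rate(p, n_case, n_intermediate, n_control):
    """Enumerate every genotype configuration of the panel with HWE weights."""
    q = 1 - p
    probs = {0: q * q, 1: 2 * p * q, 2: p * p}
    mani = manifest(n_case, n_intermediate, n_control)
    samples = list(mani.entries)
    total = 0.0
    for combo in itertools.product((0, 1, 2), repeat=len(samples)):
        calls = {s: GenotypeCall.from_dosage(d) for s, d in zip(samples, combo)}
        if naive_concordant(calls, mani):
            weight = 1.0
            for d in combo:
                weight *= probs[d]
            total += weight
    return total


class TestExpectedBackgroundPassRate:
    @pytest.mark.parametrize("p,panel", [
        (0.5, (5, 1, 4)),
        (0.5, (1, 0, 1)),
        (0.3, (2, 1, 2)),
        (0.8, (3, 2, 1)),
    ])
    def test_matches_brute_force_enumeration(self, p, panel):
        expected = brute_force_pass_rate(p, *panel)
        assert expected_background_pass_rate(p, *panel) == pytest.approx(
            expected, rel=1e-12)

    def test_study_panel_value_at_half(self):
        # 0.5^18: 10 hom factors, one het factor, doubled for orientation
        assert expected_background_pass_rate(0.5, 5, 1, 4) == pytest.approx(
            0.5 ** 18, rel=1e-12)
        assert expected_background_pass_rate(0.5, 5, 1, 4) == pytest.approx(
            3.8147e-6, rel=1e-4)

    def test_two_sample_panel(self):
        assert expected_background_pass_rate(0.5, 1, 0, 1) == pytest.approx(0.125)

    @settings(derandomize=True, max_examples=100)
    @given(p=st.floats(0.01, 0.99), n_case=st.integers(1, 6),
           n_int=st.integers(0, 3), n_ctl=st.integers(1, 6))
    def test_symmetry_in_allele_frequency(self, p, n_case, n_int, n_ctl):
        assert expected_background_pass_rate(p, n_case, n_int, n_ctl) == pytest.approx(
            expected_background_pass_rate(1 - p, n_case, n_int, n_ctl), rel=1e-9)

    def test_boundary_frequencies_rejected(self):
        for bad in (0.0, 1.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                expected_background_pass_rate(bad, 5, 1, 4)


def test_empirical_pass_rate_matches_closed_form():
    """Fraction of iid HWE sites passing tracks the closed form within 3 SE."""
    rng = np.random.default_rng(2024)
    p = 0.5
    n_sites = 100_000
    panel = (2, 1, 2)
    mani = manifest(*panel)
    samples = list(mani.entries)
    dosages = (rng.random((n_sites, len(samples))) < p).astype(int) + (
        rng.random((n_sites, len(samples))) < p
    ).astype(int)
    # vectorized pattern check in both orientations
    case_idx = [samples.index(s) for s in mani.cases]
    int_idx = [samples.index(s) for s in mani.intermediates]
    ctl_idx = [samples.index(s) for s in mani.controls]
    passes = np.zeros(n_sites, dtype=bool)
    for disease_dosage in (0, 2):
        ok = np.all(dosages[:, case_idx] == disease_dosage, axis=1)
        ok &= np.all(dosages[:, int_idx] == 1, axis=1)
        ok &= np.all(dosages[:, ctl_idx] == 2 - disease_dosage, axis=1)
        passes |= ok
    rate = expected_background_pass_rate(p, *panel)
    se = np.sqrt(rate * (1 - rate) / n_sites)
    assert abs(passes.mean() - rate) <= 3 * se

    # spot-check the vectorized pass flags against the filter itself
    hits = np.flatnonzero(passes)[:5]
    for row in hits:
        calls = {s: GenotypeCall.from_dosage(int(d))
                 for s, d in zip(samples, dosages[row])}
        assert concordance_filter([variant(calls)], mani).candidates


# ---------------------------------------------------------------------------
# IBD compatibility flag
# ---------------------------------------------------------------------------

class TestIbdCompatibility:
    def test_shared_homozygous_cases_with_carrier_intermediate(self):
        mani = manifest()
        calls = {s: HOM_REF for s in mani.entries}
        assert is_ibd_compatible(variant(calls), mani)
        calls = dict(calls)
        for s in mani.intermediates:
            calls[s] = HET
        assert is_ibd_compatible(variant(calls), mani)

    def test_split_cases_are_discordant(self):
        mani = manifest()
        calls = {s: HOM_REF for s in mani.entries}
        calls["case4"] = HOM_ALT
        assert not is_ibd_compatible(variant(calls), mani)

    def test_intermediate_without_disease_allele_is_discordant(self):
        mani = manifest()
        calls = {s: HOM_REF for s in mani.entries}
        for s in mani.intermediates:
            calls[s] = HOM_ALT
        assert not is_ibd_compatible(variant(calls), mani)

    def test_het_case_is_discordant(self):
        mani = manifest()
        calls = {s: HOM_REF for s in mani.entries}
        calls["case0"] = HET
        assert not is_ibd_compatible(variant(calls), mani)

    def test_missing_genotypes_cannot_contradict(self):
        mani = manifest()
        calls = {s: GenotypeCall.missing() for s in mani.entries}
        assert is_ibd_compatible(variant(calls), mani)


def test_manifest_tsv_round_trip(tmp_path):
    mani = manifest()
    path = tmp_path / "manifest.tsv"
    mani.write_tsv(path)
    assert SampleManifest.read_tsv(path) == mani
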