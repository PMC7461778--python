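"""Scanner behaviour: window enumeration, the reference veto, worked
rejection cases, gRNA arithmetic, and equivalence with the brute-force oracle."""

import random

import pytest

from snppam import (
    AlleleContext,
    CasRegistry,
    PamMatch,
    PamMotif,
    RegistryError,
    ScanOptions,
    VariantRecord,
    brute_force_oracle,
    candidate_windows,
    reference_blocked,
    revcomp,
    scan_variant,
    suggest_grna,
)
from conftest import random_indel, random_substitution


class TestCandidateWindows:
    @pytest.mark.parametrize(
        "seq_len,affected,motif_len,expected",
        [
            (5, (2, 3), 4, [(0, 4), (1, 5)]),
            (3, (1, 2), 3, [(0, 3)]),
            (2, (0, 1), 8, []),
            (10, (4, 6), 2, [(3, 5), (4, 6), (5, 7)]),
        ],
    )
    def test_enumeration(self, seq_len, affected, motif_len, expected):
        assert candidate_windows(seq_len, affected, motif_len) == expected

    def test_all_windows_overlap_and_fit(self):
        for win in candidate_windows(30, (12, 14), 6):
            s, e = win
            assert 0 <= s and e <= 30 and e - s == 6
            assert e > 12 and s < 14


class TestReferenceVeto:
    def test_multi_pam_cas_blocked_by_sibling_motif(self, registry):
        # TTCN on the reference vetoes any enAsCas12a candidate at the locus
        assert reference_blocked(registry.get("enAsCas12a"), "TTCTA", (2, 3))

    def test_off_target_motif_blocks(self, registry):
        # NAG is never a candidate but vetoes SpCas9 on the reference side
        assert reference_blocked(registry.get("SpCas9"), "TAG", (1, 2))

    def test_clean_reference_not_blocked(self, registry):
        assert not reference_blocked(registry.get("SaCas9"), "AAAAAA", (2, 3))


class TestWorkedRejections:
    """The two canonical accept/reject cases for the allele-exclusivity rule."""

    def test_enas_tttt_vetoed_but_tttn_accepted(self, options):
        rec = VariantRecord(id="w1", upstream="TT", ref_allele="C",
                            alt_alleles=("T",), downstream="TA")
        matches = scan_variant(rec, options)
        names = {m.cas_name for m in matches}
        assert "enAsCas12a" not in names  # reference TTCTA carries TTCN
        tttn = [m for m in matches if m.cas_name == "AsCas12a/LbCas12a"]
        assert any(m.motif.pattern == "TTTN" and m.strand == "+" and m.window == (0, 4)
                   for m in tttn)

    def test_spcas9_vetoed_by_reference_nag(self, options):
        rec = VariantRecord(id="w2", upstream="T", ref_allele="A",
                            alt_alleles=("G",), downstream="G")
        assert not any(m.cas_name == "SpCas9" for m in scan_variant(rec, options))

    def test_spcas9_accepted_on_clean_reference(self, options):
        rec = VariantRecord(id="w3", upstream="AA", ref_allele="T",
                            alt_alleles=("G",), downstream="GA")
        hits = [m for m in scan_variant(rec, options) if m.cas_name == "SpCas9"]
        assert [(m.motif.pattern, m.strand, m.window) for m in hits] == [("NGG", "+", (1, 4))]


class TestGrnaSuggestion:
    def _match(self, cas_name, strand, window, registry):
        return PamMatch(record_id="g", alt_used="A", cas_name=cas_name,
                        motif=registry.get(cas_name).primary_motifs[0],
                        strand=strand, window=window, variant_window_seq="",
                        reference_window_seq="", grna="", grna_complete=False)

    def test_class_ii_spacer_5prime_of_pam(self, registry):
        var_seq = "".join("ACGT"[i % 4] for i in range(30))
        ctx = AlleleContext(ref_seq=var_seq, var_seq=var_seq, affected=(25, 26), alt_used="A")
        m = self._match("SpCas9", "+", (24, 27), registry)
        grna, complete = suggest_grna(m, ctx, registry.get("SpCas9"))
        assert grna == var_seq[4:24] and complete

    def test_class_v_spacer_3prime_of_pam(self, registry):
        var_seq = "".join("ACGT"[i % 4] for i in range(30))
        ctx = AlleleContext(ref_seq=var_seq, var_seq=var_seq, affected=(1, 2), alt_used="A")
        m = self._match("FnCas12a", "+", (0, 3), registry)
        grna, complete = suggest_grna(m, ctx, registry.get("FnCas12a"))
        assert grna == var_seq[3:26] and complete and len(grna) == 23

    def test_short_flank_truncates(self, registry):
        var_seq = "ACGTACGTAC"
        ctx = AlleleContext(ref_seq=var_seq, var_seq=var_seq, affected=(3, 4), alt_used="A")
        m = self._match("SpCas9", "+", (2, 5), registry)
        grna, complete = suggest_grna(m, ctx, registry.get("SpCas9"))
        assert grna == "AC" and not complete

    def test_minus_strand_spacer_is_on_pam_strand(self, registry):
        var_seq = "".join("ACGT"[i % 4] for i in range(30))
        ctx = AlleleContext(ref_seq=var_seq, var_seq=var_seq, affected=(5, 6), alt_used="A")
        m = self._match("SpCas9", "-", (3, 6), registry)
        grna, complete = suggest_grna(m, ctx, registry.get("SpCas9"))
        rc = revcomp(var_seq)
        assert grna == rc[len(var_seq) - 26 : len(var_seq) - 6] and complete

    def test_incomplete_matches_can_be_excluded(self, registry):
        rec = VariantRecord(id="w", upstream="AA", ref_allele="T",
                            alt_alleles=("G",), downstream="GA")
        strict = scan_variant(
            rec, ScanOptions(registry=registry, include_incomplete_grna=False)
        )
        assert all(m.grna_complete for m in strict)


class TestOracleEquivalence:
    def test_substitutions_match_oracle(self, registry, options):
        rng = random.Random(1234)
        for i in range(150):
            rec = random_substitution(rng, record_id=f"s{i}")
            got = {m.key() for m in scan_variant(rec, options)}
            want = {m.key() for m in brute_force_oracle(rec, registry)}
            assert got == want, rec

    def test_indels_match_oracle(self, registry, options):
        rng = random.Random(99)
        for i in range(60):
            rec = random_indel(rng, record_id=f"i{i}")
            got = {m.key() for m in scan_variant(rec, options)}
            want = {m.key() for m in brute_force_oracle(rec, registry)}
            assert got == want, rec


def _flip(record: VariantRecord) -> VariantRecord:
    return VariantRecord(
        id=record.id,
        upstream=revcomp(record.downstream),
        ref_allele=revcomp(record.ref_allele),
        alt_alleles=tuple(revcomp(a) for a in record.alt_alleles),
        downstream=revcomp(record.upstream),
    )


class TestScanProperties:
    def test_strand_symmetry(self, options):
        rng = random.Random(7)
        for i in range(60):
            rec = random_substitution(rng, record_id=f"y{i}")
            fwd = sorted((m.cas_name, m.motif.pattern, m.strand)
                         for m in scan_variant(rec, options))
            rev = sorted((m.cas_name, m.motif.pattern, "+-"[m.strand == "+"])
                         for m in scan_variant(_flip(rec), options))
            assert fwd == rev

    def test_registry_monotonicity(self, registry):
        rng = random.Random(21)
        rec = random_substitution(rng, record_id="mono")
        full = scan_variant(rec, ScanOptions(registry=registry))
        reduced = scan_variant(rec, ScanOptions(registry=registry.without("SpCas9")))
        assert [m.key() for m in reduced] == [m.key() for m in full
                                              if m.cas_name != "SpCas9"]

    def test_multiallelic_decomposition(self, options):
        rec = VariantRecord(id="ma", upstream="AATTCG", ref_allele="T",
                            alt_alleles=("G", "A"), downstream="GACCAT")
        joint = {m.key() for m in scan_variant(rec, options)}
        parts = set()
        for alt in rec.alt_alleles:
            single = VariantRecord(id="ma", upstream=rec.upstream,
                                   ref_allele=rec.ref_allele,
                                   alt_alleles=(alt,), downstream=rec.downstream)
            parts |= {m.key() for m in scan_variant(single, options)}
        assert joint == parts

    def test_deterministic_ordering(self, options):
        rng = random.Random(3)
        rec = random_substitution(rng, record_id="ord")
        first = [m.key() for m in scan_variant(rec, options)]
        second = [m.key() for m in scan_variant(rec, options)]
        assert first == second
        # plus-strand hits precede minus-strand hits within each enzyme block
        by_cas = {}
        for m in scan_variant(rec, options):
            by_cas.setdefault((m.alt_used, m.cas_name), []).append(m.strand)
        for strands in by_cas.values():
            assert strands == sorted(strands, key=lambda s: s != "+")

    def test_plus_only_scan(self, registry):
        rng = random.Random(17)
        rec = random_substitution(rng, record_id="po")
        plus_only = scan_variant(
            rec, ScanOptions(registry=registry, scan_minus_strand=False)
        )
        assert all(m.strand == "+" for m in plus_only)

    def test_empty_registry_rejected(self):
        with pytest.raises(RegistryError):
            ScanOptions(registry=CasRegistry(()))

    def test_match_invariants(self, options):
        rng = random.Random(5)
        for i in range(40):
            rec = random_substitution(rng, record_id=f"inv{i}")
            for m in scan_variant(rec, options):
                s, e = m.window
                assert e > s and m.motif.length == e - s
                if m.grna_complete:
                    cas = options.registry.get(m.cas_name)
                    assert len(m.grna) == cas.spacer_length
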