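"""Brute-force re-derivation of the scan by literal substring search.

This module recomputes everything the scanner does through a deliberately
different route: every motif is fully expanded into its concrete sequences
(:func:`snppam.sequence.expand_motif`) and windows are accepted by set
membership rather than positional IUPAC matching; both strands are built
explicitly. It exists as an independent oracle for tests and for the
fixture generator's self-verification — it is never the production path.
"""

from __future__ import annotations

from .registry import CasEnzyme, CasRegistry, PamOrientation
from .scanner import MINUS, PLUS, PamMatch
from .sequence import Interval, VariantRecord, expand_motif, revcomp


def _affected_intervals(up_len: int, ref: str, alt: str, var_len: int, ref_len: int):
    # recomputed inline so the oracle does not lean on build_alleles
    if ref and alt:
        return (up_len, up_len + 1), (up_len, up_len + 1)
    if alt:  # insertion
        return (up_len, up_len + 1), (max(0, up_len - 1), min(ref_len, up_len + 1))
    # deletion
    return (max(0, up_len - 1), min(var_len, up_len + 1)), (up_len, up_len + 1)


def _overlapping_occurrences(seq: str, words: frozenset[str], span: Interval):
    """All (start, end) where a word from *words* occurs in *seq* with the
    window overlapping *span*."""
    if not words:
        return
    wlen = len(next(iter(words)))
    a, b = span
    for s in range(max(0, a - wlen + 1), min(b, len(seq) - wlen + 1)):
        if seq[s : s + wlen] in words:
            yield (s, s + wlen)


def _ref_is_blocked(cas: CasEnzyme, ref_o: str, ref_aff_o: Interval) -> bool:
    for motif in cas.primary_motifs + cas.off_target_motifs:
        for _ in _overlapping_occurrences(ref_o, expand_motif(motif), ref_aff_o):
            return True
    return False


def brute_force_oracle(
    record: VariantRecord,
    registry: CasRegistry,
    scan_minus_strand: bool = True,
) -> list[PamMatch]:
    """Recompute the full match list for *record* by exhaustive enumeration."""
    strands = (PLUS, MINUS) if scan_minus_strand else (PLUS,)
    matches: list[PamMatch] = []
    for alt in record.alt_alleles:
        up, ref, down = record.upstream, record.ref_allele, record.downstream
        var_seq = up + alt + down
        ref_seq = up + ref + down
        aff, ref_aff = _affected_intervals(
            len(up), ref, alt, len(var_seq), len(ref_seq)
        )
        for cas in registry:
            for strand in strands:
                if strand == PLUS:
                    var_o, ref_o = var_seq, ref_seq
                    aff_o, ref_aff_o = aff, ref_aff
                else:
                    var_o, ref_o = revcomp(var_seq), revcomp(ref_seq)
                    aff_o = (len(var_seq) - aff[1], len(var_seq) - aff[0])
                    ref_aff_o = (len(ref_seq) - ref_aff[1], len(ref_seq) - ref_aff[0])
                if _ref_is_blocked(cas, ref_o, ref_aff_o):
                    continue
                for motif in cas.primary_motifs:
                    words = expand_motif(motif)
                    for s, e in _overlapping_occurrences(var_o, words, aff_o):
                        n = cas.spacer_length
                        if cas.pam_orientation is PamOrientation.downstream_of_protospacer:
                            grna, complete = var_o[max(0, s - n) : s], s >= n
                        else:
                            grna, complete = var_o[e : e + n], e + n <= len(var_o)
                        if strand == PLUS:
                            window = (s, e)
                        else:
                            window = (len(var_seq) - e, len(var_seq) - s)
                        matches.append(
                            PamMatch(
                                record_id=record.id,
                                alt_used=alt,
                                cas_name=cas.name,
                                motif=motif,
                                strand=strand,
                                window=window,
                                variant_window_seq=var_o[s:e],
                                reference_window_seq="",
                                grna=grna,
                                grna_complete=complete,
                                cas_class=cas.cas_class.value,
                                cas_origin=cas.origin.value,
                                approx_size_bp=cas.approx_size_bp,
                            )
                        )
    return matches
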