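"""The core scan: variant-allele-exclusive PAM detection.

For each alternate allele, both strands are examined. A (Cas, motif, window)
triple is accepted when the motif matches the variant-allele window overlapping
the variant locus AND no motif of that Cas — primary or off-target — matches
the reference allele at any window overlapping the homologous locus on the same
strand. The second condition is what guarantees allele specificity: a
reference-side PAM of the same enzyme at the locus would let the nuclease
engage the wild-type allele too.

The reference veto is deliberately local (windows overlapping the variant
locus, same strand): a reference PAM far from the locus addresses a different
protospacer and does not compromise specificity at the variant site. This is
the single most consequential interpretation in the package and reproduces
both canonical rejection cases (TTCN on the reference vetoes an enAsCas12a
TTTT candidate at the locus; NAG on the reference vetoes an SpCas9 NGG
candidate).

Minus-strand scanning reverse-complements the sequences and applies the
forward motifs; reported windows are mapped back to plus-strand variant-allele
coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .errors import RegistryError
from .registry import CasEnzyme, CasRegistry, PamOrientation
from .sequence import (
    AlleleContext,
    Interval,
    PamMotif,
    VariantRecord,
    build_alleles,
    iupac_match,
    mirror_interval,
    revcomp,
)

PLUS = "+"
MINUS = "-"


@dataclass(frozen=True)
class PamMatch:
    """One accepted (Cas, motif, strand, window) hit with its gRNA suggestion.

    ``window`` is half-open in plus-strand var_seq coordinates regardless of
    strand; ``variant_window_seq``/``reference_window_seq`` are read in motif
    orientation (i.e. already reverse-complemented for minus-strand hits).
    ``grna`` is the suggested spacer, 5'->3' on the protospacer strand;
    ``grna_complete`` is False when the flank was too short for the full
    spacer and the returned spacer is truncated.
    """

    record_id: str
    alt_used: str
    cas_name: str
    motif: PamMotif
    strand: str
    window: Interval
    variant_window_seq: str
    reference_window_seq: str
    grna: str
    grna_complete: bool
    cas_class: str = ""
    cas_origin: str = ""
    approx_size_bp: Optional[int] = None

    def key(self) -> tuple:
        """Identity for order-insensitive comparison (oracle equivalence)."""
        return (
            self.record_id,
            self.alt_used,
            self.cas_name,
            self.motif.pattern,
            self.strand,
            self.window,
            self.variant_window_seq,
            self.grna,
            self.grna_complete,
        )


@dataclass(frozen=True)
class ScanOptions:
    registry: CasRegistry
    scan_minus_strand: bool = True
    include_incomplete_grna: bool = True

    def __post_init__(self) -> None:
        if len(self.registry) == 0:
            raise RegistryError("scan requires a non-empty Cas registry")


def candidate_windows(seq_len: int, affected: Interval, motif_len: int) -> list[Interval]:
    """All in-bounds motif-length windows overlapping the affected interval,
    ascending by start."""
    a, b = affected
    lo = max(0, a - motif_len + 1)
    hi = min(b, seq_len - motif_len + 1)
    return [(s, s + motif_len) for s in range(lo, hi)]


def reference_blocked(cas: CasEnzyme, ref_seq: str, ref_affected: Interval) -> bool:
    """True iff any motif of *cas* (primary or off-target) matches *ref_seq*
    at a window overlapping *ref_affected* on the strand under scan (the
    caller passes strand-oriented sequence and coordinates)."""
    for motif in cas.rejection_motifs:
        for s, e in candidate_windows(len(ref_seq), ref_affected, motif.length):
            if iupac_match(motif, ref_seq[s:e]):
                return True
    return False


def _oriented_spacer(seq: str, window: Interval, cas: CasEnzyme) -> tuple[str, bool]:
    """Spacer in the strand-oriented frame: 5' of the PAM for downstream-PAM
    (class II) enzymes, 3' of the PAM for upstream-PAM (class V) enzymes."""
    s, e = window
    n = cas.spacer_length
    if cas.pam_orientation is PamOrientation.downstream_of_protospacer:
        return seq[max(0, s - n) : s], s >= n
    return seq[e : e + n], e + n <= len(seq)


def suggest_grna(match: PamMatch, context: AlleleContext, cas: CasEnzyme) -> tuple[str, bool]:
    """Recompute the spacer suggestion for *match* against its context."""
    if match.strand == PLUS:
        seq, window = context.var_seq, match.window
    else:
        seq = revcomp(context.var_seq)
        window = mirror_interval(match.window, len(context.var_seq))
    return _oriented_spacer(seq, window, cas)


def _ref_homolog_window(
    window_plus: Interval, ctx: AlleleContext, strand: str
) -> str:
    """Reference-allele sequence at the coordinates homologous to a
    variant-allele window (evidence for reporting; clipped at bounds)."""
    s, _ = window_plus
    mlen = window_plus[1] - window_plus[0]
    lu_plus_alt = len(ctx.var_seq) - len(ctx.ref_seq)  # len(alt) - len(ref)
    rs = s if s <= ctx.affected[0] else s - lu_plus_alt
    rs = max(0, rs)
    seq = ctx.ref_seq[rs : rs + mlen]
    return revcomp(seq) if strand == MINUS else seq


def scan_variant(record: VariantRecord, options: ScanOptions) -> list[PamMatch]:
    """Scan one variant record against every enzyme in the registry.

    Output order is deterministic: alt alleles in record order, enzymes in
    registry order, plus strand before minus, then ascending plus-frame
    window start (motif list order breaking ties).
    """
    strands = (PLUS, MINUS) if options.scan_minus_strand else (PLUS,)
    matches: list[PamMatch] = []
    for alt in record.alt_alleles:
        ctx = build_alleles(record, alt)
        var_len, ref_len = len(ctx.var_seq), len(ctx.ref_seq)
        for cas in options.registry:
            for strand in strands:
                if strand == PLUS:
                    var_o, aff_o = ctx.var_seq, ctx.affected
                    ref_o, ref_aff_o = ctx.ref_seq, ctx.ref_affected
                else:
                    var_o = revcomp(ctx.var_seq)
                    aff_o = mirror_interval(ctx.affected, var_len)
                    ref_o = revcomp(ctx.ref_seq)
                    ref_aff_o = mirror_interval(ctx.ref_affected, ref_len)
                if reference_blocked(cas, ref_o, ref_aff_o):
                    continue
                hits: list[tuple[int, int, PamMatch]] = []
                for mi, motif in enumerate(cas.primary_motifs):
                    for win in candidate_windows(len(var_o), aff_o, motif.length):
                        s, e = win
                        if not iupac_match(motif, var_o[s:e]):
                            continue
                        grna, complete = _oriented_spacer(var_o, win, cas)
                        if not complete and not options.include_incomplete_grna:
                            continue
                        window_plus = (
                            win if strand == PLUS else mirror_interval(win, var_len)
                        )
                        hits.append(
                            (
                                window_plus[0],
                                mi,
                                PamMatch(
                                    record_id=record.id,
                                    alt_used=alt,
                                    cas_name=cas.name,
                                    motif=motif,
                                    strand=strand,
                                    window=window_plus,
                                    variant_window_seq=var_o[s:e],
                                    reference_window_seq=_ref_homolog_window(
                                        window_plus, ctx, strand
                                    ),
                                    grna=grna,
                                    grna_complete=complete,
                                    cas_class=cas.cas_class.value,
                                    cas_origin=cas.origin.value,
                                    approx_size_bp=cas.approx_size_bp,
                                ),
                            )
                        )
                hits.sort(key=lambda t: (t[0], t[1]))
                matches.extend(m for _, _, m in hits)
    return matches


def scan(
    record: VariantRecord,
    registry: Optional[CasRegistry] = None,
    scan_minus_strand: bool = True,
    include_incomplete_grna: bool = True,
) -> list[PamMatch]:
    """Convenience wrapper around :func:`scan_variant` with the built-in registry."""
    from .registry import builtin_registry

    return scan_variant(
        record,
        ScanOptions(
            registry=registry or builtin_registry(),
            scan_minus_strand=scan_minus_strand,
            include_incomplete_grna=include_incomplete_grna,
        ),
    )
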