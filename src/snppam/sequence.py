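"""DNA-string primitives for allele-specific PAM scanning.

Conventions used throughout the package:

* All sequences are plus-strand, 5'->3', uppercase A/C/G/T (flanks and
  alleles); PAM motifs additionally use the 15 IUPAC degeneracy codes.
* All coordinates are 0-based, half-open intervals. The variant-allele
  sequence (``var_seq``) is the canonical reporting frame.
* Ambiguity codes in flanks are rejected rather than treated as wildcards:
  an N in a flank makes allele specificity undecidable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from itertools import product
from typing import Literal

from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import reverse_complement as _bio_revcomp

from .errors import ValidationError

#: The IUPAC nucleotide alphabet accepted in PAM motifs.
IUPAC_CODES = "ACGTRYWSKMBDHVN"

#: Per-code sets of concrete bases, e.g. ``R -> {A, G}``.
IUPAC_SETS: dict[str, frozenset[str]] = {
    code: frozenset(ambiguous_dna_values[code]) for code in IUPAC_CODES
}

Interval = tuple[int, int]


def validate_sequence(s: str) -> str:
    """Uppercase *s* and require it to contain only A/C/G/T.

    The empty string is allowed (indel alleles). Raises
    :class:`ValidationError` naming the first offending position otherwise.
    """
    s = s.upper()
    for i, ch in enumerate(s):
        if ch not in "ACGT":
            raise ValidationError(
                f"invalid base {ch!r} at position {i} (only A/C/G/T allowed)"
            )
    return s


def validate_motif_string(pattern: str) -> str:
    """Uppercase *pattern* and require valid IUPAC codes; non-empty."""
    pattern = pattern.upper()
    if not pattern:
        raise ValidationError("motif pattern must be non-empty")
    for i, ch in enumerate(pattern):
        if ch not in IUPAC_SETS:
            raise ValidationError(
                f"invalid IUPAC code {ch!r} at position {i} in motif {pattern!r}"
            )
    return pattern


def revcomp(s: str) -> str:
    """Reverse complement, honouring IUPAC degeneracy codes (R<->Y, W<->W, ...)."""
    s = s.upper()
    for i, ch in enumerate(s):
        if ch not in IUPAC_SETS:
            raise ValidationError(f"invalid nucleotide code {ch!r} at position {i}")
    return _bio_revcomp(s)


@dataclass(frozen=True)
class PamMotif:
    """A PAM pattern over the IUPAC alphabet, e.g. ``NNGRRT`` or ``TTCN``."""

    pattern: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "pattern", validate_motif_string(self.pattern))

    def __len__(self) -> int:
        return len(self.pattern)

    @property
    def length(self) -> int:
        return len(self.pattern)

    def __str__(self) -> str:
        return self.pattern


def iupac_match(motif: PamMotif | str, window: str) -> bool:
    """True iff every base of *window* lies in the IUPAC set of the
    corresponding motif position. *window* must be concrete A/C/G/T of the
    motif's length."""
    pattern = motif.pattern if isinstance(motif, PamMotif) else motif
    if len(window) != len(pattern):
        raise ValidationError(
            f"window length {len(window)} != motif length {len(pattern)}"
        )
    return all(base in IUPAC_SETS[code] for code, base in zip(pattern, window))


@lru_cache(maxsize=None)
def _expand(pattern: str) -> frozenset[str]:
    return frozenset(
        "".join(bases) for bases in product(*(sorted(IUPAC_SETS[c]) for c in pattern))
    )


def expand_motif(motif: PamMotif | str) -> frozenset[str]:
    """Fully enumerate the concrete sequences matching *motif*.

    The result size is the product of per-position code cardinalities
    (e.g. NNGRRT -> 4*4*1*2*2*1 = 64). Used as the independent matching
    route in the brute-force oracle and in the fixture generator.
    """
    pattern = motif.pattern if isinstance(motif, PamMotif) else validate_motif_string(motif)
    return _expand(pattern)


VariantType = Literal["substitution", "insertion", "deletion"]


@dataclass(frozen=True)
class VariantRecord:
    """One single-base variant: substitution, insertion or deletion.

    ``upstream``/``downstream`` are the plus-strand flanks immediately 5'/3'
    of the variant locus. ``ref_allele`` and each alt allele are length 0 or 1;
    an empty ref with a one-base alt is an insertion, the converse a deletion.
    """

    id: str
    upstream: str
    ref_allele: str
    alt_alleles: tuple[str, ...]
    downstream: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "upstream", validate_sequence(self.upstream))
        object.__setattr__(self, "downstream", validate_sequence(self.downstream))
        object.__setattr__(self, "ref_allele", validate_sequence(self.ref_allele))
        if len(self.ref_allele) > 1:
            raise ValidationError(
                f"record {self.id!r}: ref allele must be 0 or 1 bases, got {self.ref_allele!r}"
            )
        alts = tuple(validate_sequence(a) for a in self.alt_alleles)
        if not alts:
            raise ValidationError(f"record {self.id!r}: at least one alt allele required")
        for alt in alts:
            if len(alt) > 1:
                raise ValidationError(
                    f"record {self.id!r}: alt allele must be 0 or 1 bases, got {alt!r}"
                )
            if alt == self.ref_allele:
                raise ValidationError(
                    f"record {self.id!r}: alt allele equals ref allele {alt!r}"
                )
            if not alt and not self.ref_allele:
                raise ValidationError(
                    f"record {self.id!r}: ref and alt cannot both be empty"
                )
        object.__setattr__(self, "alt_alleles", alts)

    def variant_type(self, alt: str) -> VariantType:
        if self.ref_allele and alt:
            return "substitution"
        if alt:
            return "insertion"
        return "deletion"


@dataclass(frozen=True)
class AlleleContext:
    """Materialized reference and variant allele sequences for one alt.

    ``affected`` is the half-open interval of ``var_seq`` positions a
    candidate PAM window must touch: the substituted or inserted base, or —
    for a deletion, which can only create a PAM by juxtaposition — the two
    bases flanking the deletion junction.
    """

    ref_seq: str
    var_seq: str
    affected: Interval
    alt_used: str
    ref_affected: Interval = field(default=(0, 0))

    @property
    def is_length_preserving(self) -> bool:
        return len(self.ref_seq) == len(self.var_seq)


def build_alleles(record: VariantRecord, alt: str) -> AlleleContext:
    """Materialize ref/var sequences and the affected intervals for one alt."""
    if alt not in record.alt_alleles:
        raise ValidationError(
            f"alt {alt!r} is not an allele of record {record.id!r}"
        )
    up, ref, down = record.upstream, record.ref_allele, record.downstream
    ref_seq = up + ref + down
    var_seq = up + alt + down
    lu = len(up)
    vt = record.variant_type(alt)
    if vt == "substitution":
        affected = (lu, lu + 1)
        ref_affected = (lu, lu + 1)
    elif vt == "insertion":
        affected = (lu, lu + 1)
        # zero-length junction on the reference side, widened one base each way
        ref_affected = (max(0, lu - 1), min(len(ref_seq), lu + 1))
    else:  # deletion: the junction in var_seq, the deleted base in ref_seq
        affected = (max(0, lu - 1), min(len(var_seq), lu + 1))
        ref_affected = (lu, lu + 1)
    return AlleleContext(
        ref_seq=ref_seq,
        var_seq=var_seq,
        affected=affected,
        alt_used=alt,
        ref_affected=ref_affected,
    )


def mirror_interval(interval: Interval, seq_len: int) -> Interval:
    """Map a plus-strand interval to reverse-complement-frame coordinates."""
    a, b = interval
    return (seq_len - b, seq_len - a)
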