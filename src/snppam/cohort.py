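"""Cohort-level targetability statistics.

Summarizes a collection of variant records: how many have at least one
variant-exclusive PAM, per-enzyme coverage, how many depend entirely on
engineered (synthetic) PAM-relaxed variants, and the directed substitution
spectrum of the untargetable remainder (untargetable substitutions are
expected to concentrate in C>T and G>A, since most PAMs are G-rich and the
T-rich ones are rigid).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ValidationError
from .registry import CasOrigin, CasRegistry
from .scanner import ScanOptions, scan_variant
from .sequence import VariantRecord

#: The 12 directed single-base substitution types.
SUBSTITUTION_TYPES = tuple(
    f"{r}>{a}" for r in "ACGT" for a in "ACGT" if r != a
)


def classify_substitution(record: VariantRecord, alt: str) -> str | None:
    """Directed substitution type ("C>T", "G>A", ...) on the plus strand as
    given; strands are not collapsed (C>T and G>A stay distinct). Returns
    None for indel alleles (not applicable)."""
    if record.variant_type(alt) != "substitution":
        return None
    return f"{record.ref_allele}>{alt}"


@dataclass(frozen=True)
class CohortSummary:
    n_total: int
    n_matched: int
    fraction_matched: float
    per_cas_coverage: dict[str, int]
    n_exclusive_synthetic: int
    n_exclusive_by_cas: dict[str, int]
    unmatched_substitution_profile: dict[str, int]
    matched_ids: tuple[str, ...] = field(default=(), repr=False)

    def as_rows(self) -> list[tuple[str, str]]:
        """Flatten to (statistic, value) rows for TSV output."""
        rows = [
            ("n_total", str(self.n_total)),
            ("n_matched", str(self.n_matched)),
            ("fraction_matched", f"{self.fraction_matched:.6f}"),
            ("n_exclusive_synthetic", str(self.n_exclusive_synthetic)),
        ]
        rows += [
            (f"coverage[{k}]", str(v)) for k, v in self.per_cas_coverage.items()
        ]
        rows += [
            (f"exclusive[{k}]", str(v)) for k, v in self.n_exclusive_by_cas.items()
        ]
        rows += [
            (f"unmatched_substitutions[{k}]", str(v))
            for k, v in self.unmatched_substitution_profile.items()
            if v
        ]
        return rows


def summarize(
    records: list[VariantRecord],
    registry: CasRegistry,
    scan_minus_strand: bool = True,
) -> CohortSummary:
    """Scan every record and aggregate targetability statistics.

    A record counts as matched when any of its alt alleles yields at least
    one variant-exclusive PAM. An unmatched multi-allelic record contributes
    a single entry to the substitution profile (its first substitution alt),
    so the profile never exceeds the unmatched count; records whose alleles
    are all indels are excluded from the profile.
    """
    if not records:
        raise ValidationError("cohort must contain at least one record")
    options = ScanOptions(registry=registry, scan_minus_strand=scan_minus_strand)
    synthetic_names = {e.name for e in registry if e.origin is CasOrigin.synthetic}

    per_cas = {e.name: 0 for e in registry}
    exclusive_by_cas = {e.name: 0 for e in registry}
    profile = {t: 0 for t in SUBSTITUTION_TYPES}
    n_matched = 0
    n_exclusive_synthetic = 0
    matched_ids: list[str] = []

    for record in records:
        matches = scan_variant(record, options)
        cas_hit = {m.cas_name for m in matches}
        if cas_hit:
            n_matched += 1
            matched_ids.append(record.id)
            for name in cas_hit:
                per_cas[name] += 1
            if len(cas_hit) == 1:
                exclusive_by_cas[next(iter(cas_hit))] += 1
            if cas_hit <= synthetic_names:
                n_exclusive_synthetic += 1
        else:
            for alt in record.alt_alleles:
                sub_type = classify_substitution(record, alt)
                if sub_type is not None:
                    profile[sub_type] += 1
                    break

    return CohortSummary(
        n_total=len(records),
        n_matched=n_matched,
        fraction_matched=n_matched / len(records),
        per_cas_coverage=per_cas,
        n_exclusive_synthetic=n_exclusive_synthetic,
        n_exclusive_by_cas=exclusive_by_cas,
        unmatched_substitution_profile=profile,
        matched_ids=tuple(matched_ids),
    )
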