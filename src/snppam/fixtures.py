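"""Seeded synthetic variant generator with known ground truth.

Produces substitution records in which a chosen PAM is planted so that it
exists exclusively on the variant allele (verified against the brute-force
oracle before the record is emitted), guaranteed-negative records with no
variant-exclusive PAM for any enzyme in a registry, and whole cohorts with a
planted matched fraction. Flank composition is uniform over A/C/G/T by
default; a GC-fraction knob supports composition stress tests, since
untargetability is tied to base composition.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Optional

from .errors import GenerationError
from .oracle import brute_force_oracle
from .registry import CasEnzyme, CasRegistry
from .scanner import PLUS
from .sequence import IUPAC_SETS, PamMotif, VariantRecord, expand_motif

_MAX_FLANK_RESAMPLES = 200
_MAX_NEGATIVE_ATTEMPTS = 10_000


@dataclass(frozen=True)
class PlantedTruth:
    record_id: str
    expected_matched: bool
    planted_cas: Optional[str] = None
    planted_motif: Optional[str] = None
    planted_window_offset: Optional[int] = None


def _random_flank(rng: random.Random, n: int, gc: float = 0.5) -> str:
    weights = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choices("ACGT", weights=weights, k=n))


def plant_positive(
    cas: CasEnzyme,
    motif: PamMotif,
    flank_len: int,
    seed: int,
    record_id: Optional[str] = None,
    gc: float = 0.5,
) -> tuple[VariantRecord, PlantedTruth]:
    """Build a substitution record whose alt allele completes a concrete
    instance of *motif* on the plus strand while the reference allele carries
    no PAM of *cas* overlapping the locus.

    The planted hit is verified via the brute-force oracle before the record
    is returned; deterministic given (cas, motif, seed).
    """
    if flank_len < motif.length + cas.spacer_length:
        raise GenerationError(
            f"flank_len {flank_len} < motif {motif.length} + spacer {cas.spacer_length}"
        )
    rng = random.Random(seed)
    rid = record_id or f"pos-{cas.name}-{motif.pattern}-{seed}"
    single = CasRegistry((cas,))
    # The variant base must sit at an informative motif position: at a fully
    # degenerate (N) position every reference base still completes the PAM on
    # the reference allele, so the hit could never be allele-exclusive.
    informative = [i for i, c in enumerate(motif.pattern) if len(IUPAC_SETS[c]) < 4]
    if not informative:
        raise GenerationError(
            f"motif {motif.pattern!r} is fully degenerate; no allele-exclusive "
            "PAM can be planted"
        )
    words = sorted(expand_motif(motif))
    for _ in range(_MAX_FLANK_RESAMPLES):
        # resample word, in-PAM position and flanks together: some
        # (word, position) combinations admit no non-blocking context
        word = rng.choice(words)
        j = rng.choice(informative)  # variant base position within the PAM
        alt = word[j]
        planted_start = flank_len - j  # window start in var_seq coordinates
        up = _random_flank(rng, flank_len, gc)
        down = _random_flank(rng, flank_len, gc)
        up = up[: flank_len - j] + word[:j]
        down = word[j + 1 :] + down[motif.length - 1 - j :]
        refs = [b for b in "ACGT" if b != alt]
        rng.shuffle(refs)
        for ref in refs:
            record = VariantRecord(
                id=rid, upstream=up, ref_allele=ref, alt_alleles=(alt,), downstream=down
            )
            planted_hit = any(
                m.cas_name == cas.name
                and m.motif.pattern == motif.pattern
                and m.strand == PLUS
                and m.window == (planted_start, planted_start + motif.length)
                for m in brute_force_oracle(record, single)
            )
            if planted_hit:
                truth = PlantedTruth(
                    record_id=rid,
                    expected_matched=True,
                    planted_cas=cas.name,
                    planted_motif=motif.pattern,
                    planted_window_offset=planted_start,
                )
                return record, truth
    raise GenerationError(
        f"could not plant {cas.name}/{motif.pattern}: every reference base was "
        f"blocked after {_MAX_FLANK_RESAMPLES} flank resamples"
    )


def plant_negative(
    flank_len: int,
    registry: CasRegistry,
    seed: int,
    record_id: Optional[str] = None,
    gc: float = 0.5,
) -> tuple[VariantRecord, PlantedTruth]:
    """Rejection-sample a substitution record with no variant-exclusive PAM
    for any enzyme in *registry* (oracle-verified); deterministic given seed."""
    if flank_len < 8:
        raise GenerationError(f"flank_len must be >= 8, got {flank_len}")
    rng = random.Random(seed)
    rid = record_id or f"neg-{seed}"
    for _ in range(_MAX_NEGATIVE_ATTEMPTS):
        up = _random_flank(rng, flank_len, gc)
        down = _random_flank(rng, flank_len, gc)
        ref = rng.choice("ACGT")
        alt = rng.choice([b for b in "ACGT" if b != ref])
        record = VariantRecord(
            id=rid, upstream=up, ref_allele=ref, alt_alleles=(alt,), downstream=down
        )
        if not brute_force_oracle(record, registry):
            return record, PlantedTruth(record_id=rid, expected_matched=False)
    raise GenerationError(
        f"no negative record found in {_MAX_NEGATIVE_ATTEMPTS} attempts"
    )


def make_cohort(
    n_positive_per_cas: int,
    n_negative: int,
    seed: int,
    registry: Optional[CasRegistry] = None,
    flank_len: int = 35,
) -> tuple[list[VariantRecord], list[PlantedTruth]]:
    """A shuffled cohort: *n_positive_per_cas* planted positives per enzyme
    (motif sampled among the enzyme's primary motifs) plus *n_negative*
    guaranteed negatives. Deterministic given the seed."""
    if n_positive_per_cas < 0 or n_negative < 0:
        raise GenerationError("cohort sizes must be non-negative")
    if n_positive_per_cas == 0 and n_negative == 0:
        raise GenerationError("cohort cannot be empty")
    if registry is None:
        from .registry import builtin_registry

        registry = builtin_registry()
    rng = random.Random(seed)
    pairs: list[tuple[VariantRecord, PlantedTruth]] = []
    for cas in registry:
        for i in range(n_positive_per_cas):
            motif = rng.choice(cas.primary_motifs)
            flen = max(flank_len, motif.length + cas.spacer_length)
            pairs.append(
                plant_positive(
                    cas,
                    motif,
                    flen,
                    seed=rng.randrange(2**31),
                    record_id=f"pos-{cas.name}-{i}",
                )
            )
    for i in range(n_negative):
        pairs.append(
            plant_negative(
                flank_len, registry, seed=rng.randrange(2**31), record_id=f"neg-{i}"
            )
        )
    rng.shuffle(pairs)
    records = [r for r, _ in pairs]
    truths = [t for _, t in pairs]
    return records, truths
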