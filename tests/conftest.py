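import random

import pytest

from snppam import ScanOptions, VariantRecord, builtin_registry


@pytest.fixture(scope="session")
def registry():
    return builtin_registry()


@pytest.fixture(scope="session")
def options(registry):
    return ScanOptions(registry=registry)


def random_substitution(rng: random.Random, flank_lo: int = 10, flank_hi: int = 30,
                        record_id: str = "r") -> VariantRecord:
    up = "".join(rng.choices("ACGT", k=rng.randint(flank_lo, flank_hi)))
    down = "".join(rng.choices("ACGT", k=rng.randint(flank_lo, flank_hi)))
    ref = rng.choice("ACGT")
    alt = rng.choice([b for b in "ACGT" if b != ref])
    return VariantRecord(id=record_id, upstream=up, ref_allele=ref,
                         alt_alleles=(alt,), downstream=down)


def random_indel(rng: random.Random, flank_lo: int = 10, flank_hi: int = 30,
                 record_id: str = "r") -> VariantRecord:
    up = "".join(rng.choices("ACGT", k=rng.randint(flank_lo, flank_hi)))
    down = "".join(rng.choices("ACGT", k=rng.randint(flank_lo, flank_hi)))
    if rng.random() < 0.5:  # insertion
        ref, alt = "", rng.choice("ACGT")
    else:  # deletion
        ref, alt = rng.choice("ACGT"), ""
    return VariantRecord(id=record_id, upstream=up, ref_allele=ref,
                         alt_alleles=(alt,), downstream=down)
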