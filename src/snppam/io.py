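"""Readers and writers: TSV batch files, VCF+FASTA ingestion, result tables.

Batch dialect: tab-delimited UTF-8 with a required header line
``id  upstream  ref  alt  downstream``; multi-allelic sites put a
comma-separated list in ``alt``; an empty ``ref``/``alt`` denotes an
insertion/deletion allele.

VCF ingestion normalizes the anchor-base indel convention (REF "CT" / ALT "C")
to the internal 0/1-length allele representation (ref "T", alt "") and
extracts flanks of the requested length from an indexed reference FASTA.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Union

import pandas as pd
import pysam

from .errors import BatchFormatError, ValidationError
from .scanner import PamMatch
from .sequence import PamMotif, VariantRecord

logger = logging.getLogger(__name__)

BATCH_COLUMNS = ["id", "upstream", "ref", "alt", "downstream"]

RESULT_COLUMNS = [
    "record_id",
    "alt",
    "cas",
    "motif",
    "strand",
    "pam_start",
    "pam_end",
    "pam_seq_variant",
    "pam_seq_reference",
    "grna",
    "grna_complete",
    "cas_class",
    "cas_origin",
    "approx_size_bp",
]

PathLike = Union[str, Path]


def parse_batch(path: PathLike) -> list[VariantRecord]:
    """Read a 5-column TSV batch file into variant records."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in BATCH_COLUMNS if c not in df.columns]
    if missing:
        raise BatchFormatError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        try:
            records.append(
                VariantRecord(
                    id=row.id,
                    upstream=row.upstream,
                    ref_allele=row.ref,
                    alt_alleles=tuple(a.strip() for a in row.alt.split(",")),
                    downstream=row.downstream,
                )
            )
        except ValidationError as exc:
            raise BatchFormatError(f"{path}: line {i}: {exc}") from exc
    return records


def write_batch(records: Iterable[VariantRecord], path: PathLike) -> None:
    """Serialize records back to the batch TSV dialect (lossless round-trip)."""
    rows = [
        {
            "id": r.id,
            "upstream": r.upstream,
            "ref": r.ref_allele,
            "alt": ",".join(r.alt_alleles),
            "downstream": r.downstream,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=BATCH_COLUMNS).to_csv(path, sep="\t", index=False)


def parse_vcf(vcf_path: PathLike, fasta_path: PathLike, flank: int = 30) -> list[VariantRecord]:
    """Read SNVs and single-base indels from a VCF, pulling flanks from an
    indexed FASTA. Multi-base substitutions and records with non-ACGT flanks
    are skipped with a logged warning; an unknown contig raises KeyError.
    """
    fasta = pysam.FastaFile(str(fasta_path))
    out: list[VariantRecord] = []
    with pysam.VariantFile(str(vcf_path)) as vcf:
        for rec in vcf:
            if rec.chrom not in fasta.references:
                raise KeyError(f"contig {rec.chrom!r} not present in {fasta_path}")
            clen = fasta.get_reference_length(rec.chrom)
            rid = rec.id or f"{rec.chrom}:{rec.pos}"
            # group normalized alts that share flanks and internal ref
            grouped: dict[tuple[str, str, str], list[str]] = {}
            for alt in rec.alts or ():
                norm = _normalize_vcf_allele(rec, alt, fasta, clen, flank)
                if norm is None:
                    continue
                up, ref_i, alt_i, down = norm
                grouped.setdefault((up, ref_i, down), []).append(alt_i)
            for n, ((up, ref_i, down), alts) in enumerate(grouped.items()):
                name = rid if len(grouped) == 1 else f"{rid}.{n}"
                try:
                    out.append(
                        VariantRecord(
                            id=name,
                            upstream=up,
                            ref_allele=ref_i,
                            alt_alleles=tuple(alts),
                            downstream=down,
                        )
                    )
                except ValidationError as exc:
                    logger.warning("skipping %s: %s", rid, exc)
    return out


def _normalize_vcf_allele(rec, alt: str, fasta, clen: int, flank: int):
    """Map one VCF REF/ALT pair to (upstream, ref, alt, downstream) in the
    internal 0/1-length allele convention, or None if unsupported."""
    ref, alt = rec.ref.upper(), alt.upper()
    chrom, p0 = rec.chrom, rec.pos - 1  # 0-based position of REF start
    if len(ref) == 1 and len(alt) == 1:  # SNV
        locus, ref_i, alt_i = p0, ref, alt
        down_start = p0 + 1
    elif len(ref) == 2 and len(alt) == 1 and ref[0] == alt:  # 1-base deletion
        locus, ref_i, alt_i = p0 + 1, ref[1], ""
        down_start = p0 + 2
    elif len(ref) == 1 and len(alt) == 2 and alt[0] == ref:  # 1-base insertion
        locus, ref_i, alt_i = p0 + 1, "", alt[1]
        down_start = p0 + 1
    else:
        logger.warning(
            "skipping %s:%s %s>%s: only SNVs and single-base indels supported",
            chrom, rec.pos, ref, alt,
        )
        return None
    up = fasta.fetch(chrom, max(0, locus - flank), locus).upper()
    down = fasta.fetch(chrom, down_start, min(clen, down_start + flank)).upper()
    if any(b not in "ACGT" for b in up + down):
        logger.warning(
            "skipping %s:%s: flank contains non-ACGT bases", chrom, rec.pos
        )
        return None
    return up, ref_i, alt_i, down


def _match_rows(matches: Iterable[PamMatch]) -> list[dict]:
    return [
        {
            "record_id": m.record_id,
            "alt": m.alt_used,
            "cas": m.cas_name,
            "motif": m.motif.pattern,
            "strand": m.strand,
            "pam_start": m.window[0],
            "pam_end": m.window[1],
            "pam_seq_variant": m.variant_window_seq,
            "pam_seq_reference": m.reference_window_seq,
            "grna": m.grna,
            "grna_complete": m.grna_complete,
            "cas_class": m.cas_class,
            "cas_origin": m.cas_origin,
            "approx_size_bp": m.approx_size_bp,
        }
        for m in matches
    ]


def matches_to_frame(matches: Iterable[PamMatch]) -> pd.DataFrame:
    df = pd.DataFrame(_match_rows(matches), columns=RESULT_COLUMNS)
    # keep missing enzyme sizes from floating the whole column
    df["approx_size_bp"] = df["approx_size_bp"].astype("Int64")
    return df


def write_results(
    matches: list[PamMatch], format: str, destination: PathLike
) -> None:
    """Write matches as TSV or JSON with a stable column order; an empty
    match list produces a header-only TSV / empty JSON array."""
    if format == "tsv":
        matches_to_frame(matches).to_csv(destination, sep="\t", index=False)
    elif format == "json":
        with open(destination, "w", encoding="utf-8") as fh:
            json.dump(_match_rows(matches), fh, indent=1)
    else:
        raise ValueError(f"unknown output format {format!r} (expected tsv or json)")


def matches_from_json(path: PathLike) -> list[PamMatch]:
    """Reconstruct matches from the JSON output (round-trip support)."""
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    return [
        PamMatch(
            record_id=d["record_id"],
            alt_used=d["alt"],
            cas_name=d["cas"],
            motif=PamMotif(d["motif"]),
            strand=d["strand"],
            window=(d["pam_start"], d["pam_end"]),
            variant_window_seq=d["pam_seq_variant"],
            reference_window_seq=d["pam_seq_reference"],
            grna=d["grna"],
            grna_complete=bool(d["grna_complete"]),
            cas_class=d["cas_class"],
            cas_origin=d["cas_origin"],
            approx_size_bp=d["approx_size_bp"],
        )
        for d in payload
    ]
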