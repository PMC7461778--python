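# Methods

## The problem and the procedure

CRISPR-Cas nucleases tolerate single mismatches between the gRNA spacer and
the target DNA, so a spacer placed over a heterozygous single-nucleotide
variant usually cuts both alleles. PAM recognition, by contrast, is strict:
without a compatible protospacer-adjacent motif immediately next to the
protospacer, the nuclease does not engage. When the variant nucleotide itself
*creates* a PAM, that PAM exists only on the variant allele, and a Cas enzyme
using it cleaves the variant allele exclusively. This package finds such
variant-created PAMs.

For each variant record (upstream flank, reference allele, alternate alleles,
downstream flank) and each alternate allele, the scan:

1. materializes the reference sequence `upstream + ref + downstream` and the
   variant sequence `upstream + alt + downstream`;
2. on each strand (the minus strand is scanned by reverse-complementing both
   sequences and applying the forward motifs), enumerates every motif-length
   window that overlaps the variant-affected interval;
3. accepts a (Cas, motif, strand, window) candidate iff the motif matches the
   variant-allele window **and** no motif of that Cas — primary or off-target
   — matches the reference allele at any window overlapping the homologous
   locus on the same strand;
4. attaches a spacer suggestion: for class II enzymes (PAM 3' of the
   protospacer) the `spacer_length` bases immediately 5' of the PAM on the
   PAM-containing strand; for class V (PAM 5' of the protospacer) the bases
   immediately 3' of it. A spacer truncated by a short flank is reported with
   `grna_complete=False` rather than dropped.

Every alternate allele of a multi-allelic record is handled independently,
and all accepted candidates are reported.

### The reference veto — the consequential interpretation

Step 3's veto is deliberately *local and strand-matched*: only reference
windows overlapping the variant locus, on the strand being scanned, can kill
a candidate. A reference PAM far from the locus addresses a different
protospacer and does not compromise allele specificity at the variant site.
This interpretation reproduces both canonical cases: a `TT⟨C→T⟩TA` variant
creates a TTTT PAM for enAsCas12a but the reference carries TTCN — another
enAsCas12a PAM — at the same offset, so enAsCas12a is rejected while
AsCas12a/LbCas12a (TTTN, whose only motif the reference lacks) is accepted;
and a `T⟨A→G⟩G` variant creates NGG for SpCas9 but the reference reads TAG,
matching SpCas9's off-target NAG, so SpCas9 is rejected. Off-target motifs
(only NAG for SpCas9 in the built-in table) participate exclusively in the
veto, never in candidate generation.

## Coordinates and indel conventions

All coordinates are 0-based, half-open, on the plus strand of the
variant-allele sequence (minus-strand hits are mapped back into this frame).
The variant-affected interval a candidate window must touch is:

* substitution — the substituted base, `[len(up), len(up)+1)`;
* insertion — the inserted base (same interval in the variant frame); on the
  reference side the zero-length junction is widened one base each way;
* deletion — the two bases flanking the junction in the variant frame,
  `[len(up)-1, len(up)+1)` clipped to bounds (a deletion can create a PAM
  only by juxtaposition); on the reference side, the deleted base.

VCF input uses the anchor-base convention (`REF CT / ALT C`); the reader
normalizes it to the internal 0/1-length allele representation (ref `T`,
alt ``) and pulls flanks from an indexed FASTA. Flanks are case-normalized;
ambiguity codes in flanks are rejected (an N makes allele specificity
undecidable) — the VCF reader skips such records with a warning rather than
aborting a whole batch.

## The enzyme registry

The built-in table holds 23 entries spanning 26 distinct primary PAM
patterns; AsCas12a and LbCas12a share one entry because they recognise the
same TTTN PAM. Class II entries read the PAM downstream (3') of the
protospacer, class V upstream (5'). Spacer lengths are the canonical family
defaults — 20 nt for class II (Cas9 family), 23 nt for class V (Cas12a
family) — and are overridable per enzyme via the plain-text config format.
All PAMs listed for multi-PAM enzymes (e.g. the NGGN of the SpCas9-NRRH/NRTH/
NRCH variants) are treated as candidate-generating primary motifs; only NAG
is off-target-only. `approx_size_bp` is carried as pure metadata for delivery-
vector considerations and never enters the logic. User-defined enzymes are
appended as synthetic entries with value semantics (the original registry is
never mutated).

## The brute-force oracle

`snppam.oracle.brute_force_oracle` recomputes the entire scan by a different
route: every motif is expanded into its full set of concrete sequences
(feasible because all built-in motifs are ≤ 8 bases) and windows are accepted
by literal set membership on explicitly constructed strands. It shares no
matching code with the scanner and is used in tests and inside the fixture
generator's self-verification, never in production paths.

## The synthetic fixture generator

`plant_positive` embeds a concrete instance of a chosen motif so that the
variant base completes it, with the variant placed at an *informative* motif
position (at a fully degenerate N position the reference would always carry
the same PAM, so no allele-exclusive hit is possible), then rejection-samples
the reference base and flanks until the oracle confirms the planted hit is
allele-exclusive. `plant_negative` rejection-samples substitution records
until the oracle returns no match for any registry enzyme (attempt cap
10,000 — constructive joint avoidance of 26 degenerate motifs would be
error-prone). Flank composition is uniform over A/C/G/T by default with a
GC-fraction knob, since untargetability is tied to base composition. All
generation is deterministic given the seed.

What the fixtures do *not* emulate: real flanks are not uniform random DNA
(human pathogenic variants sit in genic, often GC-skewed context), variant
type frequencies are not uniform (CpG-driven C>T/G>A transitions dominate
real cohorts), and no linkage or clinical annotation is modelled. Passing
the planted-truth tests therefore demonstrates correctness of the scanning
and accounting machinery, not population-level targetability rates.

## Cohort statistics

`summarize` counts a record as matched when any alternate allele yields at
least one accepted candidate; it reports per-enzyme coverage (records with
≥1 hit for that enzyme), records matched by exactly one enzyme
(`n_exclusive_by_cas`), records whose matching enzymes are all engineered
variants (`n_exclusive_synthetic` — the two exclusivity notions differ and
both are reported), and the directed substitution spectrum (12 types, no
strand collapsing: C>T and G>A stay distinct) of unmatched records. An
unmatched multi-allelic record contributes once to the spectrum (its first
substitution allele); indel-only records are excluded from it.

## Problem sizes and numerical choices

The test suite and `scripts/acceptance.py` use: 500 substitution + 100 indel
records (flanks 10–30 nt) for scanner/oracle equivalence; 200 records for
strand symmetry; a planted cohort of 2 positives per enzyme + 20 negatives
(66 records) for truth recovery and the allele-exclusivity audit; and a
12,000-record uniform-context cohort (1,000 per directed substitution type,
30 nt flanks) for the untargetability spectrum. On that uniform cohort
roughly 95% of substitutions are targetable and the untargetable remainder
is strongly concentrated in C>T and G>A (the transitions that remove a G
from a PAM-bearing strand without creating one) — the spectrum test asserts
only this qualitative concentration, as the quantity depends on flank
composition.

There is no floating-point numerics in the scan: all decisions are exact
string/set operations, output ordering is fully deterministic (alt allele,
registry order, plus strand before minus, ascending window start, motif list
order), and no randomness exists outside the fixture generator.

## Known limitations

* Database-scale statistics over the published human pathogenic SNP set
  (dbSNP build 153) are not regenerated here — ingestion is supported via the
  generic TSV/VCF readers, but no downloader or scraper is bundled.
* Only single-base variants (substitution, insertion, deletion) are in scope;
  multi-base VCF records are skipped with a warning.
* No on-target efficiency scoring, genome-wide off-target search, PAM
  binding-affinity modelling, or haplotype-aware dual-gRNA design.
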