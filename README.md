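# snppam

Allele-specific CRISPR targeting via variant-created PAM sites.

## The problem

CRISPR-Cas nucleases tolerate single gRNA:DNA mismatches, so a guide placed
over a heterozygous point mutation usually cuts the pathogenic *and* the
wild-type allele. PAM recognition is strict, though: no compatible
protospacer-adjacent motif next to the target, no cleavage. When the variant
nucleotide itself creates a PAM, that PAM exists **only on the variant
allele**, and a Cas enzyme that uses it cleaves the variant allele
exclusively — the basis for allele-specific editing in heterozygous patients
with dominant-negative or gain-of-function mutations.

`snppam` is for researchers designing such experiments. Given a variant
(upstream flank, ref/alt alleles, downstream flank — entered manually, as a
TSV batch, or as VCF + reference FASTA), it scans both strands against a
built-in registry of 23 Cas enzymes spanning 26 distinct PAM patterns
(IUPAC-degenerate motifs such as NGG, NNGRRT, TTTN, TYCV) and reports every
enzyme whose PAM is created by the variant.

## The rule at the core

For alternate allele *a* of a variant with flanks *u*, *d*, let
`var = u·a·d` and `ref = u·r·d`. A candidate (Cas *C*, motif *m*, strand *s*,
window *w*) is accepted iff

* *w* overlaps the variant-affected position(s), and `var[w]` matches *m* on
  strand *s*, and
* **no** motif of *C* — primary or off-target — matches `ref` at any window
  overlapping the homologous locus on strand *s*.

The second clause is the allele-exclusivity veto. It is what rejects
enAsCas12a for a `TT⟨C→T⟩TA` variant (the new TTTT PAM is shadowed by the
reference's TTCN, another enAsCas12a PAM) and SpCas9 for a `T⟨A→G⟩G` variant
(the reference TAG matches NAG, SpCas9's off-target PAM). Accepted matches
come with a spacer suggestion: 20 nt immediately 5' of the PAM for class II
enzymes (PAM downstream of the protospacer), 23 nt immediately 3' of it for
class V (PAM upstream). Single-base insertions and deletions are supported,
as are user-defined PAMs.

## Worked example

A C→A substitution with 25-nt flanks:

```bash
snppam scan --id rsDEMO \
  --up ACCTGAAGCTGGTGGCGTTGTCAGT --ref C --alt A \
  --down CTGTGATCGAGGACTGGTTCAATGC
```

prints (gRNA columns truncated here for width):

```
record_id  alt  cas          motif    strand  pam_start  pam_end  pam_seq_variant  pam_seq_reference  grna                  grna_complete
rsDEMO     A    SpCas9-NRCH  NRCH     +       24         28       TACT             TCCT               GAAGCTGGTGGCGTTGTCAG  True
rsDEMO     A    KKH SaCas9   NNNRRT   -       25         31       CACAGT           CACAGG             GCATTGAACCAGTCCTCGAT  True
rsDEMO     A    CjCas9       NNNVRYM  -       24         31       CACAGTA          CACAGGA            GCATTGAACCAGTCCTCGAT  True
```

Read it as: the A allele creates a TACT window at positions 24–28 of the
variant sequence that satisfies SpCas9-NRCH's NRCH PAM, while the reference
reads TCCT there and carries no NRCH/NGGN PAM over the locus — so SpCas9-NRCH
cuts the variant allele only, using the 20-nt spacer shown. Two further
enzymes find PAMs on the minus strand (their windows reported in plus-strand
coordinates, their spacers on the PAM-containing strand). Any enzyme whose
PAM also appears on the reference at the locus is silently rejected.

Other entry points: `snppam batch variants.tsv`, `snppam vcf calls.vcf
--fasta ref.fa --flank 30`, `snppam registry` (prints the enzyme table),
`snppam cohort variants.tsv` (targetability statistics: fraction of variants
with ≥1 variant-exclusive PAM, per-enzyme coverage, records rescued only by
engineered enzymes, substitution spectrum of the untargetable remainder).
Everything is equally available as a library (`snppam.scan_variant`,
`snppam.summarize`, ...), including a seeded generator of ground-truth
fixtures (`snppam.make_cohort`) and a brute-force oracle
(`snppam.brute_force_oracle`) that re-derives any scan by exhaustive motif
expansion.

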