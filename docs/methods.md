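# Methods

## Coordinate conventions

Internally every genomic interval is 0-based half-open; 1-based inclusive
coordinates appear only at I/O boundaries that demand them (the
samtools-depth position column). Printed exon tables of the
start–end/c.start–c.end style are read as half-open genomic pairs
(length = end − start). For the built-in nine-exon *POLR1C* model this is
the one reading under which every exon's genomic length equals its coding
length (totalling 1275 nt), so it is adopted as a documented
coordinate-dialect choice rather than shifting either endpoint. Coding
coordinates are CDS-relative (c.) only; UTRs are not modelled.
Negative-strand transcripts are supported in the data model (coding order
runs antiparallel to genomic order) and are exercised by synthetic
fixtures.

## Read-depth CNV screen

The screen targets the single-gene candidate-CNV question: does one
sample's exon coverage depart from a control cohort's in a copy-number-like
way?

1. **Per-exon means.** For each sample and exon, the arithmetic mean of
   per-base coverage over the exon, excluding missing base calls. A
   position absent from the depth table is missing, not zero; an explicit
   0 is a covered base with zero reads. An exon with fewer than
   `min_covered_fraction` (default 0.8) of its bases covered is not
   callable for that sample.
2. **Library-size scaling.** Each sample's exon means are divided by their
   mean over the target exons, giving relative coverage with mean 1.
3. **Control-median normalization.** The test sample's relative coverage is
   divided, exon by exon, by the median over controls only. Fewer than
   three controls still computes but flags every call low-confidence; a
   zero control median makes the exon no-call.
4. **Median-ratio recalibration** (`ScreenConfig.recentre`, default on).
   Because step 2's denominator is the screened target itself, a real
   event contaminates the carrier's scale factor: a deletion of 2 of 9
   exons deterministically inflates all of that sample's ratios by 9/8,
   biasing the deleted-exon ratio from 0.50 to ≈ 0.56. Since this
   miscalibration multiplies every exon ratio by the same constant,
   dividing the sample's ratio vector by its own median removes it exactly
   whenever fewer than half the exons are non-diploid — the same
   self-calibration genome-wide read-depth callers use. With recalibration
   the recovered ratio for a two-exon heterozygous deletion at 100× is
   0.50 ± ~0.02 across seeds.
5. **State calling and merging.** Ratios map to states by bands:
   hom_del ≤ 0.15, het_del in [0.35, 0.65], dup ≥ 1.35, otherwise diploid
   (values in the gaps are conservatively left diploid). The bands sit
   several Poisson standard deviations apart at ~100× over ≥ 70-bp exons
   and are fully configurable. Consecutive exons sharing a non-diploid
   state merge into one segment whose ratio is the member mean; segment
   length is reported so multi-exon candidates rank above single-exon
   ones.

The cohort screen tests each sample in turn against all others
(leave-one-out) unless a fixed control set is supplied. The screen is also
exposed as a model/result pair (`CnvScreen(...).fit()` returning a
`CnvScreenResult` with `summary()`, the ratio matrix and a bar-plot
helper), which is the natural shape for the one estimation-like component
of the package.

## HGVS consequence engine

Exonic variants are applied to the CDS by direct string editing (with
reference-base verification where the descriptor states reference bases),
and wild-type and mutant sequences are translated with the standard
genetic code to the first stop. The first differing residue anchors the
protein description:

- **Frameshift** iff the nucleotide length change is not a multiple of 3;
  the frame offset is reported as (length change) mod 3, so a 2-nt
  deletion is a +1 frame offset (−2 ≡ +1 mod 3), matching how such
  deletions are conventionally described.
- **fs\*N** counts the new-frame stop with the first changed residue as
  position 1; the stop's protein coordinate is therefore
  first_affected + N − 1, and the truncated product has stop − 1 residues
  before the stop. Both numbers are reported because published accounts
  sometimes quote the stop position itself as the truncated-protein
  length; the engine anchors on the stop position.
- A frameshift whose first affected codon is itself a stop is emitted as a
  nonsense change (p.Xxx#Ter); an in-frame indel gets the documented
  extension kind `inframe_indel`; a mutant frame that reaches the end of
  the supplied sequence without a stop is `no_stop_found` — no 3′UTR
  readthrough is guessed.
- Splice classification is positional: an intronic substitution at an
  internal exon's 3′ coding end with positive offset is a donor variant,
  at a non-initial exon's 5′ start with negative offset an acceptor;
  canonical iff |offset| ≤ 2. RNA-level outcome prediction (exon skipping,
  intron retention) is out of scope.

Biopython supplies translation and FASTA I/O; the parser and consequence
arithmetic are this package's own, checked in the test suite against an
independent hand-coded codon-table oracle over hundreds of random CDSs and
indels.

## ACMG/AMP combination and triage

Evidence codes carry guideline default strengths with structural support
for overrides (an upgraded code counts at its overridden strength; a
second very-strong code counts toward the strong tally). The combiner
encodes the published five-tier combining clauses verbatim; simultaneous
satisfaction of a pathogenic-side and benign-side clause yields uncertain
significance with a conflict warning. The benign-side clauses are
implemented for completeness although a TCS workup mostly exercises the
pathogenic side. Triage excludes a variant when its allele frequency
(maximum of the supplied worldwide and admixed-American values — the
conservative reading of an either/or filter) exceeds 0.01%, when the
inheritance mode does not match the gene, or when fewer than two of the
patient's manifestations match the gene's phenotype spectrum; that count
is interpreted as patient manifestations matching the gene, one of two
readings of the filter. Double-count guards flag PVS1+PM4 and PVS1+PP3
with a LOF rationale; they warn and never remove evidence.

## Pedigrees and cohort summaries

Segregation checking evaluates, per individual, the autosomal-dominant
co-occurrence rules: affected non-carriers and unaffected carriers break
consistency (phenocopy and incomplete-penetrance violations); an affected
carrier with no carrier among tested parents raises an informational
de-novo-or-untested flag. The PP1 quantity is a bare count of
parent-to-child links where both are affected carriers; mapping counts to
evidence strength is configuration (≥ 3 transmissions defaults to
supporting). A three-generation chain of five affected carriers yields
four informative transmissions.

Feature frequencies truncate to whole percents (9/11 → 81%), while
diagnostic yield and gene shares round half-up to one decimal
(10/11 → 90.9%); the two display conventions deliberately coexist, each
bound to its reporting context. Unknown cells stay in the denominator and
never count as present (hence 6/11 hearing loss with two unknowns). In the
fixed eleven-patient cohort fixture, the downslanted-palpebral-fissure row
tallies 9 of 11 present although the accompanying prose frequency
elsewhere corresponds to 8 of 11; the fixture preserves the table and the
discrepancy is noted here rather than silently harmonized. The patient
carrying only the candidate *POLR1C* CNV counts as unsolved.

## Synthetic data

The coverage simulator draws per-base depth as
Poisson(mean_depth · s_i · b_e · c/2) with per-sample factors
s_i ~ lognormal(0, 0.1), shared per-exon capture biases
b_e ~ lognormal(0, 0.2), and exon-aligned copy events c ∈ {0, 1, 2, 3}.
Defaults (14 controls + test samples, 100× mean) reproduce the operating
point of a capture-based exome at ~100× screened against 11 external plus
3 internal controls. Poisson-with-multiplicative-bias was chosen over a
negative binomial for transparency; optional gamma mixing supplies
overdispersion, and an optional missing fraction drops positions to
exercise the NA-exclusion rule. What the simulator does not emulate:
GC-tracking bias within exons, mapping artifacts, capture edge effects and
batch structure — so passing recovery tests demonstrate the statistical
machinery, not robustness to every real-exome artifact. Sub-exonic events
are out of scope (candidate events of interest are exon-spanning).

Random CDSs are ATG + non-stop codons + stop, satisfying the complete-CDS
invariants by construction. Random pedigrees transmit a founder variant
with probability 1/2 per offspring, married-in spouses are non-carriers,
and affected status equals carrier status with configurable penetrance.
All generators are deterministic given their seed.

## Problem sizes and numerical choices

The acceptance computation simulates 15 samples over the 1275 coding bases
of the nine-exon model (~19k Poisson draws) and screens leave-one-out;
property suites use hundreds of random CDSs/pedigrees and a 64-subset
exhaustive check of the evidence combiner — sizes at which the oracles are
exact and the whole suite runs in seconds. Ratios are reported to 4
decimals; percent conventions are as above; ties at band edges belong to
the named band (inclusive bounds on the het-del band, inclusive thresholds
for hom-del and dup).

## Known limitations

No statistical CNV genotyping (no likelihoods or quality scores), no
GC correction, no genome-wide calling; HGVS grammar covers the descriptor
classes above, not inversions, repeats or mosaicism; population-database
frequencies are user-supplied inputs, never queried; gene-specific ACMG
specifications (VCEP rules) and Bayesian point systems are out of scope.
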