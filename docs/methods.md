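# Methods

## Setting and model

The toolkit targets the mapping of a fully penetrant autosomal recessive
trait in a small cohort: every affected animal is homozygous for the causal
allele, unaffected animals are not. Under that model the selection rule is
deterministic — a variant is a candidate iff it is hom-alt in all cases and
hom-alt in no control — and no statistical genotype model, kinship
correction or quality-based refinement is applied (the genotype state in
the input VCF is taken at face value). Multi-allelic records are decomposed
into biallelic rows before filtering, so "hom-alt" always refers to a
single alternate allele; a `1/2` genotype is heterozygous for each
decomposed row and homozygous for neither.

Two facts of the motivating study shape the design. First, control choice
is a modelling decision, not a constant: an epistatic phenotype group (here
the amelanotic white line, which cannot express pigment-dilution
phenotypes) must be dropped from the control set when mapping a
pigmentation trait, and conversely both other phenotype groups serve as
controls when mapping the white trait itself. Group exclusion is therefore
explicit configuration. Second, low-coverage (~5–10×) genotype matrices
contain no-calls, and the published analysis does not state how they were
treated; both policies are exposed rather than one guessed:

* `missing_case_policy` — default `disqualify`: a variant unobserved in a
  case cannot be called "common homozygous". `tolerate` lets observed
  cases carry the decision.
* `missing_control_policy` — default `not_hom_alt`: the control criterion
  is literally "not in the homozygous state", which a missing genotype
  satisfies; a warning is logged per variant. `disqualify` is the
  conservative alternative.

## Consequence terms and tiers

One most-severe term per (variant, transcript), ranked
splice_donor > splice_acceptor > stop_gained > frameshift > stop_lost >
start_lost > missense > inframe_indel > synonymous > splice_region >
intron > UTR > upstream > downstream > intergenic, with the conventional
impact tiers (the first six are HIGH). Fixed geometric conventions,
counted in transcription orientation so minus-strand genes behave as
mirrored plus-strand genes:

* donor = intronic +1/+2; acceptor = −2/−1 (the canonical GT/AG bases);
* splice_region = intronic 3–8 from either junction, or the first/last 3
  exonic bases of an internal junction;
* upstream/downstream window 5 kb from the transcript span;
* indels: length difference mod 3 decides frameshift vs in-frame; an indel
  touching donor/acceptor bases is the (more severe) splice call.

Coding SNVs are resolved by codon comparison against the reference;
classification raises a data error (call skipped, logged) when the VCF REF
allele disagrees with the reference sequence.

## Coordinates

Internally all genomic coordinates are 0-based half-open on the plus
strand; GFF3 (1-based inclusive) and VCF (1-based) convert at the I/O
boundary. Exons are stored in transcription order, so "first exon" and
"the donor of exon k" are strand-agnostic. HGVS-style `c.` positions are
normalised for whitespace and case before parsing (published notation
prints spaces, e.g. `C.901 + 1 G > A`), and `map_coding_position` requires
`+k`/`−k` offsets to sit at a genuine donor/acceptor of the transcript.

## Isoform augmentation

Alternative-promoter isoforms are modelled as: one new first exon (with
its own CDS start offset), optionally a shared linker exon, then the
shared downstream exon block; the grafted transcript inherits the genomic
CDS end of the base transcript. First-exon coordinates are *input* (a TSV
spec), not inferred by homology — this keeps the module deterministic and
testable; a non-ATG start of a grafted CDS is a warning, not an error,
since real annotations contain such isoforms. The first intron of a
grafted isoform is the gap between its first exon and the next included
exon, which defines "the first intron" in the retention analysis.

## Splice-disruption outcomes

The model enumerates rather than predicts: for an internal-exon donor both
exon skipping and intron retention are reported (the motivating study
observed skipping at one locus and retention at the other); for a
first-exon donor only retention is modelled. Retention translation carries
the ALT base inside the retained sequence and reads through the intron
into the next exon if no stop occurs in the intron (degenerate but defined
behaviour). Two stop-counting conventions are reported side by side —
`stop_codon_aa_position` (the stop codon's own 1-based index) and
`peptide_length` (residues excluding the stop) — because published
truncation sizes are quoted in either convention; for a retention with 33
coding nt upstream of the junction and an in-frame stop after 51 intronic
nt these give 29 and 28 respectively, with 11 wild-type residues retained.
Domain status is assessed against the last wild-type-identical residue of
the mutant peptide: frameshifted residues never count as domain-bearing.
The NMD flag applies the 50-nt rule (premature stop more than 50 nt
upstream of the last exon–exon junction of the *mutant* structure); it is
a flag only, with no abundance prediction — which is also why in-silico
RT-PCR on a retention transcript still yields a (larger) product even when
the physical assay shows an empty lane.

## In-silico PCR

Exact matching by default (validation primers are exact designs); a
mismatch tolerance exists for robustness experiments only. IUPAC
degenerate primer bases match their expansion sets; template `N` matches
nothing. Only the forward-on-sense / reverse-on-antisense orientation is
searched unless the swapped-orientation flag is set. Product size counts
both primer footprints.

## Cosegregation statistics

Carrier concordance = fraction of carrier-phenotype animals that are
hom-alt; non-carrier concordance = fraction of non-carrier animals that
are not; the carrier flag is explicit per table row because published
tables mix coat-colour names with genotype shorthand. The Fisher exact
test is two-sided by the method of small p-values and is computed with
exact integer binomial-coefficient arithmetic, so probability ties are
resolved exactly rather than within a floating-point tolerance.

## Synthetic cohorts

The generator emulates the study design: 3 affected genomes filtered
against unaffected genomes (defaults: 3 cases, 3 controls, two 30 kb
contigs, 4 multi-exon genes alternating strands, exons 60–300 bp, introns
100–600 bp with canonical GT/AG ends, stop-free coding sequences with ATG
start and terminal stop). The planted variant is a donor +1 (or +2) G>A in
transcription orientation, hom-alt in every case; each control is het with
probability 0.5 (else hom-ref), emulating a segregating recessive allele.
Background SNVs are placed per-base at 10⁻³/bp with Hardy–Weinberg
genotypes at a uniform allele frequency in [0.05, 0.95); by default they
avoid the donor/acceptor dinucleotides of every intron so the planted
variant is the unique splice-site HIGH candidate by construction (a flag
disables this for negative tests). Missing genotypes are injectable at a
configurable rate on background rows; the planted row is never masked.
Randomness comes from one `SeedSequence` per run spawned into four child
streams (reference, causal genotypes, background, missingness) in a fixed
order, so changing the background rate never perturbs the causal draw and
identical configs give byte-identical FASTA/GFF3/VCF/TSV/JSON outputs.

What the generator does **not** emulate: read-level errors, depth/quality
annotations, linkage and recombination structure, pedigrees, population
stratification, and genome-scale variant counts. Passing the recovery
tests therefore demonstrates the correctness of the selection and
annotation logic under the stated recessive model, not calling performance
on real sequencing data.

## Problem sizes and numerical choices

The test suite and acceptance checks run the recovery property over 20
seeded cohorts of ~60 kb each and compare the core operations
(recessive filtering, consequence classification, ORF analysis, amplicon
search, Fisher test) against independent brute-force oracles on 100–500
random instances each — sizes chosen so the whole suite completes in a few
seconds while each property is exercised across many gene geometries.
The two published-arithmetic checks (frameshift stop at codon 308 after an
internal-exon skip; the 29/28-residue retention truncation) run on
synthetic reconstructions whose exon geometry matches the published loci
(a 106-nt seventh exon ending at coding position 901; a first exon with 33
coding nt), since the real reference assembly is not bundled. Fisher
p-values are exact rationals rendered to float; all other tolerances are
exact comparisons.

## Known limitations

* Splice-strength scoring, cryptic-site discovery and transcript abundance
  are out of scope; the outcome model enumerates canonical mis-splicing
  modes only.
* The filter assumes full penetrance and complete genotype concordance;
  phenocopies or genotyping error would require relaxing the all/none
  rule.
* Variant normalisation (left-alignment) is assumed done upstream; merging
  of per-sample VCFs matches sites exactly on contig/pos/ref/alt.
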