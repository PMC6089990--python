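# Methods

## Scope and data model

`strainvar` models the downstream half of a mutate-and-screen
comparative-genomics study: variant calls already exist (read alignment
and calling are upstream and out of scope), and the question is which
mutant-private variants change coding sequences, and how. The in-memory
model is deliberately small: a `Genome` (chromosome → uppercase
A/C/G/T/N string), `GeneModel`s (stranded, possibly multi-segment CDS
interval sets), normalized `Variant` 4-tuples, and per-variant-per-gene
`Consequence` records.

All coordinates are 1-based inclusive throughout, matching both GFF3
and VCF, so no off-by-one conversion occurs at module seams.

## Variant identity and normalization

Variant identity is the normalized `(chromosome, pos, ref, alt)` tuple.
Genotype and zygosity are ignored: strain call sets are treated as flat
haploid lists, which is how published per-strain supplementary variant
tables are laid out. Normalization trims shared terminal bases and
left-aligns indels against the reference (the VCF community's normal
form), and is idempotent; the property suite checks, by brute-force
enumeration of all equivalent anchored representations in a window,
that normalization maps the whole equivalence class to its single
leftmost member. Filtered (non-PASS) records are dropped by default
when reading VCF but kept when reading bare tables, which carry no
FILTER semantics; the table reader's column mapping is configuration
because published supplementary layouts vary.

The differential set is the exact set difference mutant ∖ parent. No
allele-frequency or quality reasoning is applied — with two clonal
strains sequenced against the same reference, subtraction is the
correct operation, and anything fuzzier belongs upstream.

## Consequence classification

For a substitution, the affected codon index is
`(cds_offset − 1) // 3 + 1` on the spliced, strand-corrected CDS; the
codon is rebuilt with the alternate base (complemented for minus-strand
genes) and both codons translated with the standard nuclear code.
Category priority: synonymous (including stop → stop), stop-loss
("sense"), stop-gain (nonsense), start-loss (codon 1 ATG destroyed),
then missense split by substitution-matrix score. Only the standard
nuclear code is implemented; the mitochondrial code is unsupported
because the pipeline targets nuclear gene sets.

Design choices that were genuinely open:

* **"Sense mutation"** is implemented as stop-loss (stop codon → sense
  codon, read-through). The term is used in screen reports without
  definition; stop-loss is the reading that makes the category disjoint
  from missense and synonymous.
* **Conservativeness** is `BLOSUM62(ref_aa, alt_aa) ≥ 0`, threshold
  configurable (`--blosum-threshold`). BLOSUM62 is taken from
  Biopython's substitution-matrix collection; a sign-based cut at 0 is
  the standard reading of "conservative by BLOSUM62", but nothing in
  the method depends on the exact cut.
* **Stop → stop substitutions are synonymous** (the protein is
  unchanged).
* **MNVs** (equal-length ref/alt > 1) are decomposed into per-base SNVs
  and classified independently; hits landing in one codon are counted
  as `codon_collisions` in the summary rather than being merged into a
  combined codon call. Merging would require phasing assumptions the
  input does not carry.
* **Per-gene multiplicity**: a variant overlapping k genes yields k
  consequences. The summary counts variant-gene pairs and distinct
  variants separately.

### Indel notation and strand symmetry

Indels are reported at the nucleotide level: insertion `+SEQ p/p+1`
(between CDS offsets p and p+1), deletion `-SEQ p`, with the sequence
and offsets in transcript orientation. Within a repeat an indel has
several equivalent placements; the notation uses the 5′-most placement
on the transcript, computed from the reference and mutated CDS strings
(maximal common suffix). This matters: genomic left-alignment
corresponds to the transcript 3′-most placement on minus-strand genes,
so a naive genomic-coordinate notation would change under the
strand-mirror transform (reverse-complement every chromosome, flip
strands, remap coordinates). With transcript-level canonicalization the
whole call set is mirror-invariant, which the suite asserts on every
synthetic run. ASCII `+`/`-` are used in notation strings.

Indels that cross a CDS boundary (into an intron-like gap or past
either CDS end) are flagged `complex` and excluded from codon-level
claims. Genes whose annotated CDS length is not divisible by 3 are kept
for locating variants but excluded from codon-level classification,
with a logged warning — fail-soft on imperfect annotations. CDS length
is reported in codons including the stop codon.

### Inactivating policy

CDS-inactivating is a policy over categories, not a fixed constant:
default {nonsense, frameshift, start-loss, sense}, and
`--inactivating include-inframe` adds in-frame indels. Published
inactivating-mutation lists are not always consistent with their own
category tallies (a list can include an in-frame insertion while the
running text counts it separately, and printed nonsense/indel totals
may not reconcile with the accompanying table); the switch lets either
reading be matched, and the summary reports both totals rather than
forcing agreement.

## Oracle structure

Two independent routes exist for every planted variant:

1. the incremental classifier (codon rebuild at the located offset);
2. full-ORF re-application: rebuild the spliced CDS via the gene's
   transcript-ordered genomic position list, apply the edit to that
   list, re-translate both proteins and diff them.

The generator labels its truth records with route 2, and the test suite
asserts route 1 ≡ route 2 (category and notation) on every planted
variant, at a scale of ≥1000 variants across both strands in the
acceptance tests. The exact binomial test is likewise checked against a
rational-arithmetic enumeration oracle, and the DE stage against the
generator's planted truth.

## Synthetic data generator

The generator emulates the structure of the study, not its biology:

* **Genome**: 2–4 chromosomes of i.i.d. uniform base composition; genes
  packed left-to-right with random intergenic gaps (60–240 bp default),
  ~25% of genes split into two CDS segments by a 40–90 bp spacer to
  exercise splicing; strands drawn with probability 0.5. Every CDS is
  ATG…stop with no internal stop, by construction.
* **Mutation spectrum**: NTG (nitrosoguanidine) is an alkylating
  mutagen with a strong O6-methylguanine signature, so the default
  spectrum puts 0.8 of the substitution mass on G:C → A:T transitions
  (G→A and C→T jointly), the remainder uniform over the other ten
  substitution types; no screen's true spectrum is known, so the mass
  is a parameter. Planted events are ~15% small indels (±1 and ±3 nt).
* **Strain pair**: parent and mutant share a background substitution
  set; the mutant additionally carries the private load (default 60,
  ~15% intergenic). Category-coverage mode first plants one of each
  consequence category by codon search, so recovery statistics are
  never vacuous. Planted variants avoid the start codon (unless
  start-loss coverage is requested), keep a ±6 bp exclusion zone around
  each other so truth labels stay single-variant, and are redrawn if
  normalization would move them (placement in a repeat would make the
  constructed notation ambiguous).
* **Expression**: probe-level log2 baselines ~ U(6, 12), i.i.d. normal
  replicate noise (sd 0.1 default), planted probes shifted by ±2 log2
  units (fourfold), 3 replicates per condition — the standard
  triplicate two-condition microarray design.

What the generator does *not* emulate: linkage between variants,
selection on the resistance phenotype, mutator-allele dynamics,
probe-level summarization artifacts, or intensity-dependent microarray
noise. Passing tests therefore demonstrate the correctness of the
arithmetic and classification logic under clean conditions, not
robustness to real-data pathologies (miscalled variants, annotation
drift, batch effects).

All draws go through `numpy.random.default_rng(seed)`; outputs are
bit-identical for a fixed seed.

## Expression stage

Retention is strict on both thresholds: p < α AND fold change > ratio
(or < 1/ratio for down-regulation); a probe at exactly the boundary is
excluded. The t-test is Welch two-sided on log2 intensities by default;
a pooled-variance flag and a linear-scale flag exist because screen
reports often do not state which variant was used. The fold change is
the linear ratio of replicate means. No multiple-testing correction is
applied — deliberately, to mirror the thresholding style of classic
microarray screens; the retained set is a candidate list, not an
inference. The transcriptome fraction is `100·n_DE/n_probesets` rounded
half-up to 2 decimals. Probe-level summarization (e.g. PLIER) is not
reimplemented; the stage consumes an already-summarized matrix.

## Genetics stage

A monogenic recessive trait in a haploid × haploid cross segregates
2:2 in every complete tetrad and 1:1 in bulk spores. The tetrad test
reports per-tetrad conformity and contrasts the probability of an
all-conforming sample under the monogenic model (exactly 1) with a
simulated two-gene-independent null (both loci 2:2, resistance
requiring both mutant alleles). The spore test is the exact two-sided
binomial (summation of outcome probabilities ≤ the observed one), via
`scipy.stats.binomtest` and cross-checked against exact rational
enumeration. Counts reconstructed from printed percentages return both
rounding candidates when the percentage is ambiguous; 53% of 2,300 is
exactly 1,219, and the resulting p ≈ 4.3×10⁻³ is surfaced as-is — a
"nearly 1:1" ratio can still be nominally significant at n = 2,300,
and interpretation is left to the user.

## Problem sizes

Default test and acceptance scales are chosen so the full suite runs in
well under a minute on one core: 24–80 genes (≈35–100 kb genomes),
60–1000 planted variants, 1000-probe expression matrices, 500 simulated
tetrads. All quantities reported by `scripts/acceptance.py` are
recomputed at run time from the seed passed on the command line.

## Known limitations

* No splice-site, UTR, promoter or regulatory-effect prediction; CDS
  only.
* Multi-variant interactions within one codon are reported, not
  re-phased into combined codon calls.
* The two-gene tetrad null is the only alternative segregation model.
* The mirror-invariance guarantee covers category and notation; genomic
  anchor coordinates of ambiguous indels legitimately differ between a
  genome and its mirror image.
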