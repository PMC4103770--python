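# Methods

`rddscout` detects RNA-DNA differences (RDDs) — candidate RNA-editing
events — from per-site allele counts of paired DNA and RNA sequencing of the
same specimens, and characterizes the resulting call set.  This note
describes the model, the tunable parameters, the synthetic cohorts used for
verification, and the numerical choices made where the design was open.

## Calling model

For each specimen, every site with both a DNA and an RNA record is
genotyped by a simple frequency rule (a stand-in for a full likelihood
caller, adequate for count-level data): `NoCall` below `min_depth` (default
2) total reads; homozygous reference (AA) when the reference-base fraction
is at least `hom_fraction` (default 0.9); homozygous variant (BB) when a
single non-reference base reaches that fraction; heterozygous (AB)
otherwise, with the most frequent non-reference base as the variant (ties
broken alphabetically).

Sites where the DNA and RNA genotypes agree calibrate three per-specimen
coverage thresholds: `C_DNA,AA`, the mean reference DNA read count over
concordant AA sites, and `C_RNA,AB` / `C_RNA,BB`, the mean variant RNA read
count over concordant AB / BB sites.  An empty category yields a threshold
of 0 with a warning.  A discordant site (DNA AA, RNA AB or BB) is a
**high-coverage RDD** when its DNA reference reads strictly exceed
`C_DNA,AA` *and* its RNA variant reads strictly exceed the threshold of the
matching RNA genotype class.  Thresholds are per specimen by default; a
cohort-wide mode exists behind a flag.

**Low-coverage rescue.**  Shallow DNA (a few reads per site) misses many
real events, so sites failing the coverage rule are re-examined under the
assumption that the site is edited in every specimen.  The cohort-pooled
editing ratio is `r = e / t`, where `e` is the sum over all specimens of
RNA reads carrying the edited base and `t` the sum of all RNA reads at the
site (the specimen under evaluation is included in the pool; specimens
without RNA coverage contribute zero to both sums).  The edited base is the
most frequent pooled non-reference RNA base, ties alphabetical.  For a
specimen with `x` reference DNA reads and `y` edited RNA reads the site is
**rescued** when

    (1 - r)^x < alpha    and    r^y < alpha    and    y > 3

with `alpha = 0.05`.  The two powers are implemented literally (not as
binomial tails): they are the probabilities of drawing `x` consecutive
unedited DNA-representing reads and `y` consecutive edited reads under the
pooled ratio.  Edge cases follow from `0^0 = 1`: with `r = 0` no site is
ever rescued, and with `r = 1` the RNA criterion `r^y = 1` can never pass —
fully edited sites must enter through the high-coverage rule.  The rule is
monotone in both `x` and `y`, which the tests verify against an independent
log-space evaluation.

## Filter cascade

Five independent per-call flags; a call is retained iff all are false, so
the retained set does not depend on stage order.

1. **Known variants** — positions present in a dbSNP-like or COSMIC-like
   mask, alt-agnostic.  dbSNP records flagged as transcript-derived
   (`MOLTYPE=cDNA` in the INFO column; key configurable) are *excluded*
   from the mask, since such entries can themselves be editing sites.
2. **DNA support** — the edited base observed in at least one DNA read of
   any specimen anywhere in the cohort.
3. **Splice proximity** — intronic positions within `k = 8` bases of an
   exon boundary of any transcript; exonic bases at junctions are kept
   (the filter targets mismapped splice-spanning reads, which deposit
   mismatches on the intronic side).
4. **Contamination** — a 61 bp genomic flank with the edited base
   substituted at the center is aligned to a decoy genome (e.g. mouse).
   The call is flagged when the substituted flank scores strictly higher
   than the unsubstituted flank, the best hit covers the edited position
   and its identity exceeds 0.90 (identity = matches / aligned query
   length, strict).  Without a decoy the stage is skipped with a warning.
5. **Paralogs** — 61 bp and 101 bp flanks, with *every* candidate RDD
   position inside the window substituted, are aligned to the host genome.
   The origin window is masked out of the target and scored separately; a
   hit elsewhere scoring greater than or equal to the origin alignment
   flags the call (either width suffices).  The ≥ rule is the deliberate
   asymmetry: a paralog that explains the edited reads *as well as* the
   true locus is disqualifying.

Alignment uses Smith-Waterman local alignment (match +1, mismatch −2,
linear gap −3), both strands, ties broken by leftmost target start.  The
implementation wraps Biopython's `PairwiseAligner`; an independent
dynamic-programming oracle in the test suite confirms scores on random
pairs.  The per-(site, alt, window) filter decisions are pure functions of
the genome and decoy, so repeated runs in one process (e.g. the
down-sampling evaluation) share a decision cache; this changes nothing but
run time.  Genome-scale alignment performance is out of scope — target
genomes are kilobase-scale.

## Annotation and summaries

Because RNA libraries are non-strand-specific, the 12 ordered substitutions
collapse into 6 strand-ambiguous classes; A>G|T>C is the canonical
A-to-I deamination signature.  Sites are stratified as Alu, non-Alu repeat
or non-repeat (Alu precedence), and assigned one genic feature with
precedence CDS > UTR5/UTR3 > ncRNA exon > intron > intergenic (ties between
transcripts go to the first in file order).  Coding consequences rebuild
the codon on the coding strand; minus-strand genes complement the
reference-strand alleles first.  A CDS whose spliced length is not a
multiple of 3 yields `unknown` with a warning.

**Clusters** combine two marking rules — consecutive sites at most 50 bp
apart, and any 100 bp window holding at least 3 sites (window span ≤ 99
bases, i.e. 100 covered positions) — and take connected components of their
union, which is the only way both printed rules yield maximal clusters.
**Recurrence** is keyed on (chrom, pos, class), so the same event reported
from opposite strands in two specimens counts as recurrent (threshold ≥ 2
specimens).

The **Alu-based FDR estimate** assumes every non-canonical call inside Alu
elements is a false positive: `FDR = 1 − fraction(A>G|T>C in Alu)`,
reported as a percent to one decimal.  Densities per Mb use merged
(non-overlapping) track lengths to avoid double counting.

## miRNA-target expression association

Raw gene counts are normalized by median-of-ratios: the size factor of a
specimen is the median, over genes expressed in all specimens, of its
count divided by the gene's geometric mean.  Note a subtlety: rescaling one
library by `c` moves the geometric-mean reference itself, so its size
factor scales by `c^((n-1)/n)` and the whole normalized matrix by the
common factor `c^(1/n)`; all between-specimen ratios — and hence every
log-fold-change below — are invariant, which is the property that matters
and the one the tests assert.

Only protein-coding genes with approximate RNA coverage
`reads × read_length / transcript_length` strictly above 10X are evaluated
(the coverage proxy is configurable).  Genes carrying both miRNA-target
RDDs and coding-region RDDs are removed; the remaining coding-region-RDD
genes form the negative control category.  Per gene, specimens split into
with/without groups and

    logFC = log2((mean_with + 1) / (mean_without + 1))

on normalized values (log base 2, pseudocount 1 — the reporting convention
adopted here).  Welch's t-test is attached when both groups have ≥ 3
specimens ("more than 2").  The up/down proportion table uses cutoffs
0, ±0.5, ±1 with ties counted as not-up (strict >).  The category contrast
(up vs not-up, mirT vs control) uses a two-sided Fisher exact test summing
hypergeometric probabilities not exceeding the observed table's (relative
tie guard 1e−7, the convention shared with standard implementations); it is
implemented with vectorized log-gamma arithmetic and cross-checked in the
tests against both scipy and exact integer enumeration.

## Down-sampling evaluation

Thinning replaces each base count by a binomial draw with the keep
probability — equivalent in distribution to per-read subsampling, and with
the property that thinned counts never exceed the originals.  Thinned data
are re-called **with the full-depth coverage thresholds** (the experiment
asks how much of the original call set survives with fewer reads, so the
read-depth criteria stay fixed); together with the subset property this
makes high-coverage calls nested within the full run's, and novel sites —
thinned-run calls absent from the full run — can arise only through shifts
in the pooled ratio.  Recovery is keyed on (specimen, chrom, pos, class):
reported are the detected fraction of full-run high-coverage calls, the
share of those detections only reachable via rescue, and the novel-site
count and rate.

## Synthetic cohorts

The generator builds everything the pipeline consumes from one integer
seed; identical seeds give byte-identical outputs.

* **Genome**: 2 contigs × 10 kb of uniform random sequence.  Alu-like
  repeats are 300 bp copies of a single consensus, mutated at 8% per copy,
  written into intronic/intergenic space (10 per contig), so repeat copies
  genuinely cross-align and exercise the paralog filter; a second consensus
  provides non-Alu repeats (400 bp, 15% divergence).  Genes sit on a fixed
  grid (3 coding + 1 ncRNA per contig, alternating strands, three coding
  exons, UTRs, two 20 bp miRNA-target sites per 3′UTR); CDS blocks double
  as the conserved track.  The decoy genome is four 500 bp host segments
  mutated at 20% plus random sequence — diverged enough that its hits fail
  the 90% identity gate except where a decoy mutation coincides with the
  planted edit.
* **Truth**: 300 edit sites, 85% inside Alu intervals; canonical-class
  fraction 0.97 inside Alu and 0.55 elsewhere; 40% of Alu edits laid down
  in runs of 3-5 sites with 10-40 bp gaps (satisfying the cluster rule by
  construction).  Per-site editing level β ~ Beta(2, 1) clipped to
  [0.02, 1]: validated editing ratios in this kind of assay span roughly
  5-95% and skew toward levels strong enough to detect, which Beta(2, 1)
  (mean 2/3) emulates.  Every specimen is edited at a planted site
  (penetrance 1.0), consistent with the rescue rule's own every-site-edited
  assumption; the four explicitly planted miRNA-target edits use penetrance
  0.5 so that with/without expression groups exist.  100 SNPs are placed at
  distinct positions with Hardy-Weinberg genotypes (allele frequency
  uniform on 0.05-0.5); all SNP positions populate the dbSNP-like mask.
* **Counts**: depths Poisson(4) for DNA and Poisson(30) for RNA per site
  and specimen (the emulated study design pairs shallow genomes with
  deeper transcriptomes); reads drawn from the genotype (or the β-mixture
  at edited sites) with uniform per-base error 0.002.
* **Expression**: negative binomial with gene means log-normal around 300,
  dispersion size 10, log-normal specimen scaling factors (sd 0.3, which
  exercises normalization), and mean multiplied by `2^δ` (default δ = 1)
  in specimens edited at a miRNA-target site of the gene.

What the generator does **not** emulate: read-level artifacts (mapping
bias, base-quality structure, strand bias), realistic human repeat
taxonomy, linkage between SNPs, transcript-level expression structure, or
editing-level correlation between neighboring sites.  Passing tests
therefore demonstrate the correctness and statistical behavior of the
pipeline's rules on count-level data, not robustness to alignment
artifacts, which the flank filters only approximate.

## Problem sizes and verification experiments

The verification experiments in the test suite use these cohort sizes,
chosen as the package's own study conditions:

* Parameter recovery and rescue value-add: the default cohort above
  (6 specimens, DNA 4X / RNA 30X, 300 edits, 100 SNPs), averaged over ten
  seeds.  Expected behavior: recall above 0.8 on edits with β ≥ 0.3, zero
  planted SNPs among final calls, Alu-FDR estimate within ±3 points of the
  truth-based false-discovery proportion over distinct sites, and strictly
  higher recall with rescue enabled at equal-or-better truth FDR.
* Down-sampling: a saturated-baseline variant (one specimen, DNA 27X /
  RNA 33X) thinned at keep fractions 0.7 / 0.5 / 0.3, ten seeds: detection
  monotone in the keep fraction and the novel-site rate below the full
  run's Alu-FDR estimate.
* miRNA-target recovery: 20 genes per category, 8 specimens, δ = 1.

## Known limitations

* The genotype rule is frequency-based; it has no quality model and will
  call AA through up to 10% contaminating alt reads at high depth (the
  DNA-support filter compensates downstream).
* The rescue statistic uses the printed power form rather than binomial
  tails; a binomial-tail variant exists as an option but is off by default,
  and the two disagree for intermediate ratios.
* The paralog and contamination checks are exact local alignments over
  kilobase genomes; they do not scale to real genomes without an external
  aligner (a PSL-style adapter can stand in for the built-in aligner).
* With penetrance 1.0 most genes lack a without-group, so the expression
  association on the default cohort evaluates few genes; the dedicated
  miRNA-target cohort exists for that analysis.
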