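# Methods

`cksrna` reimplements, as a tested library, the computational core of a
cross-kingdom RNA-interference (ck-RNAi) discovery analysis for a plant root
colonized by a beneficial fungal endophyte. Because the real deposited
sequencing libraries are not desk-scale inputs, the package pairs the
analysis pipeline with a synthetic-data generator that emulates the
statistical structure such an experiment produces and keeps a machine-readable
ground-truth ledger, so that every stage of the pipeline is checkable against
planted truth or an independent oracle.

## The analysis model

Three sRNA-seq sample classes are analyzed jointly: mock-treated plant root
(`Bd-C`), colonized root (`Bd-Si`, a physical mixture of plant and fungal
RNA), and axenic fungal culture (`Si-ax`). After 3' adapter removal, reads of
15–35 nt with no ambiguous bases are collapsed to unique sequences with
per-sample counts. Each unique sequence is then assigned one origin per
sample by consecutive filters: structural (substring of a tRNA/rRNA reference
set, checked first and excluded from everything downstream), then exact
presence in the plant genome, the fungal genome, both (*ambiguous*, excluded
from both analysis branches because the origin cannot be resolved), or
neither (*unmapped*).

Counts are normalized to reads per million (RPM) **within organism and
sample**: a plant-origin read in the colonized sample is divided by the total
of plant-mapped reads in that sample, a fungal-origin read by the
fungal-mapped total. Induction is `log2(RPM_colonized / RPM_control)` with
the control being `Bd-C` for plant reads and `Si-ax` for fungal reads. A read
absent from the control but present in the colonized sample is
*colonized-exclusive* and carries `NA` instead of a fold change (no
pseudocount is used); reads with `log2FC > 1` are additionally flagged highly
upregulated. The ck-candidate branch keeps induced reads of one fixed length
(default 21 nt, the canonical ck-sRNA size) and screens them against the
partner organism's transcriptome; the endogenous branch clusters a read's
genome alignments into sRNA loci.

### Mapping

The mapper is an exact-match (0-substitution by default) search over both
strands via a 15-mer hash index with full verification, reporting every
occurrence as 0-based half-open coordinates. Exactness is a deliberate
choice: it is standard for sRNA genome-matching, it makes origin
classification crisp, and it makes the mapper equivalent to a naive
all-offsets scan, which the test suite asserts on random instances. A
substitution-tolerant mode (naive scan) exists for matching locus products
against a mature-miRNA reference, where 1 mismatch is conventionally allowed.

### Locus calling and DicerCall

Genome alignments of endogenous reads are merged by single linkage whenever
the gap between intervals on one contig is at most `merge_gap` (default
75 nt); loci with fewer than `min_total_reads` (default 5) reads are dropped.
These defaults mirror common ShortStack-style settings and are exposed in the
API. A locus's DicerCall is the modal read length within 20–24 nt when the
count-weighted fraction of in-window reads is at least 0.8 (boundary
inclusive); otherwise `N`. The predominant (highest-count, ties
lexicographic) sequence is matched against the mature-miRNA reference by
Hamming distance over equal lengths, at most 1 substitution, ties broken by
fewest mismatches then reference order. No hairpin secondary-structure
validation is performed; matching a provided mature reference stands in for a
database comparison.

### Target prediction

Target scoring is a seed-weighted complementarity expectation in the style of
plant sRNA target predictors: the sRNA is aligned antiparallel and gapless to
every window of every transcript (sense strand only — the sRNA binds the
mRNA); per position from the sRNA 5' end, a Watson–Crick pair costs 0, a G:U
wobble 0.5, a mismatch 1.0, with costs doubled at seed positions 2–13; the
expectation is the sum (0 = perfect). Any non-match at central positions 9–11
switches the predicted mode from cleavage to translational inhibition. Sites
with expectation at most `cutoff` (default 5.0) are kept, best site per
transcript, ties to the smaller start. Gapless scoring keeps the scan exactly
equal to its brute-force definition, which the tests exploit with an
independently coded scalar scorer (agreement to 1e-9). Bulged duplexes and
thermodynamic scoring are out of scope; results are cutoff-sensitive and the
cutoff is a parameter.

### Confirmation against differential expression

Predicted (sRNA, transcript) pairs are confirmed when the transcript's gene
is significantly downregulated in the partner organism's DE table
(`padj < 0.05` **and** `log2FC < 0`, no effect-size floor). Transcript ids
map to gene ids by stripping a trailing `.N` isoform suffix (overridable).
Coverage is confirmed unique targets as a percentage of all DEGs, rounded
half-up (one decimal by default). Note one documented wrinkle: a source
worked example prints 49/317 as 15.4%, which is truncation — half-up rounding
gives 15.5; the package reports standard rounding and the acceptance test
accepts the printed value at its printed precision.

### Phenotype statistics

Trait tables (trait, group, replicate, value) are analyzed per repetition:
Shapiro–Wilk on both groups and a two-sided F-ratio variance check at
alpha 0.05 route the comparison to a pooled t test (normal, homoscedastic),
Welch t (normal, heteroscedastic), or the two-sided Mann–Whitney–Wilcoxon
(exact for group sizes ≤ 8). "Pairwise" comparisons are read as unpaired
two-sample tests because treated and control plants are distinct individuals.
Benjamini–Hochberg correction is applied within each repetition's trait
family (the family definition is configurable; whether correction should run
across repetitions as well is genuinely open), significance stars are
assigned to the across-repetition **average** of adjusted p values
(`***` ≤ 1e-4, `**` ≤ 1e-3, `*` ≤ 0.05), and the treatment effect is
`100 × (mean_treated − mean_control) / mean_control`. Groups with zero range
skip the (undefined) normality test and are treated as normal.

## The synthetic generator

Defaults (all in `SimulationConfig`): 50 kb plant / 25 kb fungal genomes over
two contigs each; 8 plant miRNA loci (120-nt windows holding a dominant
mature sequence and its embedded reverse complement, so reads multi-map
within the hairpin; one locus carries a conserved MIR156-family mature
sequence verbatim for an exact reference match); 8 plant 24-nt siRNA clusters
(200-nt windows, 40 read positions each, first base set to A with probability
0.7); 6 fungal 26-nt and 6 fungal 29/30-nt clusters; 20 ck-sRNAs per
direction at 21 nt (half colonized-exclusive, half induced fourfold in raw
counts); ~10⁴ reads per sample; 2% noise reads matching neither genome;
adapter `TGGAATTCTCGGGTGCCAAGG` appended to every read with constant
Phred+33 qualities (no quality model — quality filtering is a pass-through).

Two properties are enforced by construction rather than sampled:

* **Cross-genome uniqueness.** The fungal genome is generated base by base,
  rejecting any trailing 15-mer present (either strand) in the finished
  plant genome. 15 is the minimum accepted read length, so every mappable
  read has exactly one possible origin and classifier precision/recall are
  exactly computable. Optional decoy segments — verbatim plant substrings
  spliced into the fungal genome — create intentional ambiguous reads and
  are recorded in the truth ledger.
* **Deterministic counts.** Read counts are expected values, not multinomial
  draws: endogenous loci get identical counts in colonized and control
  samples (so no endogenous read is spuriously induced) and planted ck-sRNAs
  get exactly their configured control/colonized counts. This makes the
  end-to-end recovery check exact (precision = recall = 1.0) instead of
  probabilistic. miRNA loci emit 90% dominant mature reads and 10%
  one-base-shifted variants to exercise the DicerCall dominance threshold.

Transcriptomes are random 500-nt transcripts (200 plant / 150 fungal genes);
each planted ck-sRNA's perfect complement is written into one distinct
partner gene, and the DE tables give those genes `log2FC = −1.5` with
`padj < 0.01` while all other genes draw symmetric-around-zero fold changes
and uniform padj. The generator therefore emulates the *statistical shape*
of the real experiment — length peaks at 21/24 nt (plant) and 26/29–30 nt
(fungus), 5'-A bias at 24 nt, induced 21-nt ck-sRNAs with complementary
partner sites, planted downregulated targets — but not realistic base
composition, sequencing error, hairpin thermodynamics, or biological count
dispersion. Passing tests demonstrate the pipeline's correctness and
internal consistency on data satisfying its assumptions, not performance on
real libraries.

## Numerical notes and limitations

* The 5'-A fraction estimator's spread is governed by the number of distinct
  24-nt cluster positions (8 × 40 = 320 Bernoulli draws, sd ≈ 0.026), not by
  read depth, because position first-bases are fixed in the genome.
* Problem sizes (50 kb + 25 kb genomes, ~10⁴ reads/sample, 350 transcripts)
  were chosen so a full simulate→confirm run completes in seconds while still
  exercising every filter; all sizes scale through `SimulationConfig`.
* RPM totals per organism sum to 10⁶ exactly up to float summation error
  (asserted at 1e-6 relative tolerance).
* `log2FC` of a control-only read is −∞; such reads are excluded upstream of
  fold-change computation (they cannot be induced), and a both-zero ratio is
  an error.
* The endogenous and ck branches may overlap — a read can be analyzed
  against its own genome and forwarded to partner-target prediction; the
  filters are not nested.
* Venn-style set comparisons report integer counts and percentages of the
  union at one decimal in machine output.
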