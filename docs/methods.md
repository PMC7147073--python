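# Methods

This note documents the models, numerical choices and open design decisions
behind each stage, and what the synthetic benchmarks do and do not show.

## Coordinates, alphabet, orientation

Transcripts are sense-strand full-length cDNA over {A, C, G, T, N}; U is
mapped to T on input. Intervals are 0-based half-open in memory and 1-based
inclusive in files (the convention of BLAST-style HSP tables). N is a valid
base but never counts as a match in any identity or score computation.
Reverse-complement comparison is off: full-length cDNA collections are
assumed orientation-normalised, and nothing downstream flips strands.

## Redundancy collapse

Greedy longest-first clustering: sequences are sorted by length descending
(ties broken lexicographically by id), and each sequence joins the first
existing cluster whose representative it matches at ≥ threshold (default
0.99), else founds a new cluster. Because the order is re-derived
internally, the result is invariant to input permutation, and the
representative is always the longest member.

Identity is matched columns / alignment columns of the optimal semiglobal
(infix) alignment of the shorter sequence onto the longer, computed with
edlib's edit-distance alignment path. Using the shorter sequence's aligned
span as denominator makes contained fragments collapse into their parents,
which is the observed behaviour of word-based greedy clusterers at a `-c`
style cutoff. The threshold comparison is `>=` (identity exactly at the
cutoff joins). A shared 12-mer prefilter (≥ 5 shared, capped by the smaller
distinct-k-mer set so low-complexity sequences are never skipped) avoids
all-vs-rep alignment of unrelated pairs; tests assert it never changes the
clustering relative to the unfiltered algorithm.

## AS event detection

The caller mirrors how an internal splice difference appears between two
full-length transcripts without a genome: the pairwise alignment splits
into exactly two HSPs around a gap on the gapped molecule. Scoring is
BLASTN-like: match +1, mismatch −2, a gap of length L costs 5 + 2L, minimum
HSP score 50. The best local alignment (Biopython `PairwiseAligner`) is
split into separate HSPs at any internal gap run longer than 30 bp — an
X-dropoff extension would never bridge a gap costing > 65 — then its query
footprint is masked and the alignment repeated, collecting at most three
HSPs (three are enough to reject a pair, since acceptance requires exactly
two). Ties among co-optimal layouts resolve to the aligner's first
(leftmost) alignment; everything is deterministic, no seeds involved.

Acceptance criteria, applied symmetrically to the pair: both lengths
strictly > 1000 bp; exactly two qualifying HSPs, collinear on both
sequences; gap (the larger inter-HSP jump, measured where the HSPs are
discontiguous) strictly > 100 bp; the gap junction ≥ 100 bp from the 5′ and
3′ ends on both sequences (each HSP supplies ≥ 100 bp of aligned flank);
HSP overlap ≤ 5 bp on either sequence. Pairs splitting into ≥ 3 HSPs are
rejected rather than re-chained — the conservative reading of the two-HSP
rule (a flag relaxing this was considered and deliberately not added until
a concrete need appears). The flank rule is enforced on both molecules,
the conservative choice where the published wording does not name one.

The catalog tests each unordered pair once behind a shared 12-mer
prefilter (≥ 30 shared, capped as above); at ≤ 1% substitution noise a pair
passing the score threshold shares far more 12-mers than the bound, and
tests verify the filtered catalog equals the unfiltered one. Isoform count
of a transcript = 1 + number of distinct partners in accepted events,
binned {1, 2–10, >10}.

## Expression and differential expression

FPKM uses the column sum of the count matrix as library size. "Expressed in
a group" means mean FPKM across the group's replicates > 0.1 (replicate
aggregation by mean; the alternative, any-replicate, was rejected as noise
sensitive). Specific transcripts are binned by their on-group mean with
boundaries at 2 and 10; values exactly on a boundary fall in the lower bin
(the printed intervals are open, so a convention is required).

The DE test is an exact conditional test on per-group sums of
median-of-ratios-normalised counts (fallback to total-count scaling when
fewer than 50 transcripts are everywhere-positive; size factors are
geometric-mean centred). Conditional on the total t, the split is
Binomial(t, n_A/(n_A+n_B)) under Poisson, and under NB the two group sums
are NB(n_g·μ, φ/n_g) with the two-sided p summing all splits no more
probable than the observed one. Dispersion φ is estimated per transcript by
the method of moments, pooled across groups, and moderated toward the
common value with 20 prior degrees of freedom against the ~5 residual df of
a 3 vs 4 design; the common value is the mean of the raw (unclipped)
estimates, because clipping at zero or taking the median biases it low and
makes the test anti-conservative. Normalised sums are rounded to integers
before the conditional test — a quantile-free approximation that is
accurate at the modest library-size spread the generator emulates
(factors in [0.7, 1.3]).

Fold change is log₂((mean FPKM_B + 0.1)/(mean FPKM_A + 0.1)); a DEU
requires |log₂FC| strictly > 1 and BH FDR < 0.05. Transcripts expressed in
exactly one group keep their direction but display the infinite-ratio
sentinel "inf" instead of the pseudocounted value. This replaces the
empirical-Bayes PPDE machinery of EBSeq-style tools with a fully
specifiable test whose calibration is itself acceptance-tested (null
rejection at nominal 0.05 must land in [0.035, 0.065] over 2,000 null
transcripts).

Pathway enrichment is the one-sided hypergeometric upper tail
P[X ≥ overlap] with BH correction, enriched iff corrected p < 0.05. BH is
implemented as the standard step-up (monotone and bounded; note it is *not*
idempotent — re-adjusting adjusted values inflates them — so adjusted
p-values are computed exactly once per test family).

## lncRNA consensus filtering

The decision structure is a four-way intersection: a transcript > 200 nt is
a lncRNA candidate only when every available scorer votes noncoding; one
coding vote suffices for a coding call, which makes the call monotone in
each scorer. The four scorers stand in for the usual four-program Venn
screen while remaining self-contained:

* **Longest ORF** — ATG…stop on the sense strand, three frames, stop
  included in the nucleotide length (protein aa = length/3 − 1); a stop-less
  run to the frame end is reported but flagged. Coding if ≥ 100 aa.
* **Fickett TESTCODE** — the published position-asymmetry
  (max/(min+1) over the three codon positions) and composition parameters
  per base, mapped through the published probability/weight tables. The
  coding cut is 0.74, the classic boundary below which TESTCODE labels a
  window noncoding.
* **Hexamer log-likelihood ratio** — mean log(f_coding/f_noncoding) over
  in-frame hexamers (step 3 inside the longest ORF when present), with
  tables trained on labelled sets: in-frame counts from coding ORFs,
  any-frame counts from noncoding sequences, add-one smoothing, tables
  normalised to sum to 1. Cut at 0 (coding-like usage).
* **Domain hits** — an optional externally produced hit table; when absent
  the scorer is marked unavailable and cannot veto a candidate.

An exon-count gate cannot be evaluated without a genome; an exon-count
column, when supplied, is honoured as metadata and otherwise skipped.

## Panel characterisation and phylogeny

Translation uses the standard code, stop excluded from the protein; UTR
lengths fall out of the ORF position so full length = 5′UTR + ORF + 3′UTR
by construction, and both identities are asserted against the bundled
published characterisation rows. Molecular weight uses average residue
masses plus one water (Biopython ProtParam), reported in kDa; isoelectric
point is deliberately out of scope (pKa-set dependent).

Phylogeny consumes a user-supplied protein multiple alignment (building the
MSA is out of scope). Columns with non-gap coverage below 0.95 are dropped
(partial-deletion treatment), then p-distance excludes remaining gap
columns pairwise. Neighbor joining is the standard Saitou–Nei Q-criterion
agglomeration, deterministic with lexicographic tie-breaking; a negative
branch length is clamped to zero and its deficit moved to the sibling edge,
preserving the pair's summed length. On additive matrices the produced tree
reproduces the input path-length matrix exactly (tested, and cross-checked
against scikit-bio's NJ topology). Bootstrap support resamples alignment
columns with replacement, rebuilds the NJ tree, and reports the percentage
of replicates containing each internal bipartition of the full-data tree;
replicates whose resample leaves a pair with no usable sites are skipped.

## Synthetic data: what it emulates, and what it does not

The generator produces the structures the pipeline is meant to recover, at
desk scale: i.i.d. uniform-composition parents (1.2–3 kb), single-deletion
isoforms with the gap placed so that detectability under the AS criteria is
decidable from geometry alone and recorded in the truth table,
point-substituted near-duplicates at a target identity q, coding
transcripts with codon-biased stop-free ORFs inside random UTRs, noncoding
transcripts mononucleotide-matched to the coding set with stops planted to
cap the longest ORF at 100 aa, and negative-binomial counts for a 3-testis
vs 4-ovary design with log-uniform baselines, library-size factors in
[0.7, 1.3], and planted effects (defaults: 5% group-specific, 10% at
|log₂FC| = 3 — roughly the DEU fraction a strongly sex-dimorphic tissue
contrast produces).

Deliberate simplifications: one deletion per isoform (the pairwise
two-HSP criteria detect exactly one internal gap, so multi-gap isoforms
would only populate the rejected ≥ 3-HSP class); substitution noise only,
no indel or chimera artefacts; no read-level simulation, positional bias or
GC effects in counts; coding/noncoding sets are cleanly separated in ORF
length (300–500 aa vs ≤ 100 aa). Passing the recovery suites therefore
shows the algorithms are correct under their stated assumptions — exact
family recovery at q ≥ 0.995, AS precision = recall = 1 for gaps in
[120, 500] bp with ≥ 150 bp flanks at ≤ 1% noise, DE sensitivity/precision
≥ 0.95, lncRNA sensitivity/specificity ≥ 0.9 — not that real Iso-Seq data
meet those assumptions; borderline gaps, high-identity paralogs and
overlapping ORF-length distributions will degrade all of these.

Problem sizes in the default test and acceptance runs (40 families for the
AS suite, 2,000 transcripts for the DE suites, 200 transcripts for the
lncRNA suite, 20 families for clustering) were chosen as the smallest sets
at which the binomial noise on the measured rates is clearly inside the
asserted bands.

## Determinism

Every stochastic step takes a seed; the pipeline fans a single global seed
out to per-stage substreams by hashing the stage name, so adding a stage
never perturbs earlier stages' randomness. Identical config and inputs give
byte-identical stage outputs.
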