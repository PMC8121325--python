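# Methods

## Data model and conventions

A genome is a DNA string over {A,C,G,T,N} plus an ordered list of gene
features with **1-based inclusive** coordinates, the convention of genome
organisation tables; coordinates are converted only at I/O boundaries.
Strand `H` is the deposited (majority) strand, `L` its complement; a
feature's coding sequence is the deposited-strand substring for `H` and
its reverse complement for `L`. Circular genomes may carry features that
wrap the origin (`end < start`). The control region is always an explicit
feature — it is never inferred from gaps. Gene names are normalised to a
compact vocabulary (`cox1..3`, `nad1..6`, `nad4L`, `atp6/8`, `cytb`,
`trnX`, `12S`, `16S`, `CR`) via a shipped synonym table, because public
records label the same genes inconsistently (`COI`, `ND5`, `s-rRNA`, ...).
`N` bases are tolerated everywhere and excluded from all composition
denominators.

## Composition and skews

AT-skew = (A−T)/(A+T), GC-skew = (G−C)/(G+C), computed either from raw
counts or from already-tabulated percentages (`skew_from_fractions`), so a
printed table can be validated without sequences. Region rows: "PCGs"
concatenates the coding-strand sequences of the protein-coding genes in
genome order; codon-position rows split each gene by its own reading
frame and then pool, so a gene of length 3k+1 contributes its extra base
to position 1. (Published per-position totals sometimes derive from
splitting the raw concatenation instead; the frame-aware rule is the
biologically meaningful one and is what this package reports.)

Group aggregation defaults to the mean of per-species percentages with
skews recomputed from the means; a pooled-count mode is available
(`mode="pooled"`). The two agree to printed precision when member genomes
are of similar size.

## Codon usage

Counts are pooled over all protein-coding genes, read in frame from the
first codon; a trailing partial codon is dropped (padding would
double-count polyadenylated stops). In-frame stops before the final codon
are logged, not fatal — real annotations contain read-through edge cases.
RSCU uses pooled synonymous families under the chosen NCBI translation
table (default 5), i.e. Leu is one 6-member and Ser one 8-member family;
the UAA/UAG stop pair is reported as its own 2-member family, separate
from the 62-codon sense total. Within every used family the RSCU values
sum exactly to the family size, and RSCU is invariant to scaling all
counts.

## Nucleotide diversity

Pi is the mean pairwise proportion of differing sites. Columns containing
any gap or N are removed globally before computation (complete deletion,
matching the classical tools' default); a pairwise-deletion mode exists
for sensitivity analysis. Sliding windows (default 200/20 bp) are defined
on the filtered matrix — window coordinates therefore refer to the
trimmed concatenation, which is also the x-axis convention of published
sliding-window figures. The number of windows is
`floor((L_used − window)/step) + 1`; a final partial window is dropped;
the midpoint of a window starting at s is `s + window/2 − 1`. When
windows tile the matrix exactly, the mean of window values equals global
Pi to machine precision.

## Ka/Ks (Nei–Gojobori 1986)

Per codon, synonymous site counts are the per-position fractions of the
nine single-base neighbours that preserve the amino acid; mutations into
stop codons count as nonsynonymous, and syn + nonsyn = 3 exactly.
Observed differences are averaged equally over all minimal substitution
pathways (1, 2 or 6 orderings); pathways through stop codons are excluded
and the remainder reweighted; a codon pair connected only through stops
is skipped and logged. Site totals average the two sequences. Proportions
are Jukes–Cantor corrected, `K = −(3/4)·ln(1 − 4p/3)`, undefined at
p ≥ 3/4 (saturation). ω = Ka/Ks when Ks > 0; pairs with undefined ω are
excluded from the per-gene mean and their count reported — setting them
to a sentinel would bias gene means toward whatever the sentinel is. The
method assumes equal codon frequencies and no transition/transversion
bias; it is the classical counting estimator, not a likelihood codon
model.

## Tandem repeats

The detector compares the sequence with itself shifted by each candidate
period p (default 10–300 bp, clamped to half the sequence length) and
finds maximal stretches of the resulting match array whose identity stays
at or above the threshold (default 0.8). A stretch of length m implies an
array spanning m + p with (m+p)/p copies (fractional trailing copies are
real and reported). Two guards keep the scan from creeping into random
flanking sequence: a mismatch gap is only bridged when the run beyond it
contributes more identity than the gap costs, and boundary runs whose
local identity falls below (1 + threshold)/2 are trimmed. Overlapping
candidates across periods are resolved by largest span, then highest
identity, then smallest period — this also discards the period-multiple
aliases of a true array, whose copy number falls below the minimum. The
unit is the majority-rule consensus over full copies. The detector is
deterministic and parameter-transparent; it does not emulate any
particular alignment-scoring automaton (e.g. TRF's match/mismatch/indel
weights), so copy boundaries can differ from TRF's by a few bases on
degenerate arrays.

The CR-size/repeat-count correlation is a plain Pearson r with the
two-sided t-test on n−2 degrees of freedom, treating species as
independent points. That is how such correlations are usually reported,
but it ignores phylogenetic non-independence; treat the p-value as
descriptive.

## Supermatrices

Concatenation takes per-gene alignments (the package consumes alignments;
it does not build them), unions the taxa, pads missing genes with gaps
(logged), and emits a partition table that tiles the matrix exactly.
Codon-position subsets require in-frame blocks. Amino-acid translation
renders the gap codon `---` as `-`, any other gapped/ambiguous codon as
`X`, and stops as `*`; by default every column containing a stop is
removed (common practice before tree inference), with `X`-masking and
keep modes available.

## Synthetic data

The genome generator draws bases i.i.d. from the composition implied by
the target A+T% (default 77.9, the across-subfamily average for
leafhoppers) and the target skews (defaults +0.08 / −0.10), then lays out
13 PCGs, 22 tRNAs and 2 rRNAs with tRNA punctuation, two-strand
assignment, small spacers, and a terminal control region, and finally
overwrites PCG termini with ATN/TTG starts and TAA/TAG stops (optionally
trailing-`T` incomplete stops). A repeat spec plants a tandem array in
the CR, with mismatches confined to the final copy so the planted
identity is exact. Because the sequence is i.i.d., PCG interiors contain
in-frame stops — the generator models composition and layout, not
translatability; codon-usage realism comes from the alignment generator
and from real inputs.

The alignment generator evolves codon sequences from a uniform-random
sense-codon ancestor along a **star tree**: each tip receives a Poisson
number of accepted substitutions targeting divergence/2 per site, with
synonymous proposals accepted always, nonsynonymous with probability ω,
and stop-creating proposals rejected. This matches the Nei–Gojobori
assumptions (uniform codon frequencies, no ts/tv bias), which is exactly
why recovery tests are informative about the estimator rather than about
model mismatch; it also means a green recovery test does not establish
robustness to biased codon usage, rate variation, indels or a structured
phylogeny — none of which the generator produces. The star tree keeps
expected pairwise statistics analytically tractable.

## Numerical choices

- Skew/RSCU table output rounds to 3 and 2 decimals respectively;
  comparisons against printed tables allow half an ulp of the printed
  precision plus 0.005 for the source's own rounding.
- Preferred-codon ranking breaks RSCU ties by raw count, then
  alphabetically, and flags fully tied inputs.
- Spacer accounting sorts features by start, excludes nested features
  from pair accounting, and reports totals both with and without the
  circular origin-spanning pair, since published totals rarely state
  their rule.
- All generators take integer seeds and are bit-reproducible;
  `numpy.random.default_rng` streams are never shared across objects.

## Known limitations

- No annotation ab initio (ORF/tRNA finding), no alignment computation,
  no tree inference, no tRNA secondary structure.
- The repeat detector reports match-array identity (adjacent-copy
  identity), which approximates but does not equal mean all-pairs copy
  identity for 3+ degenerate copies.
- Ka/Ks is the NG86 counting estimator; for deep divergences or strong
  codon bias a likelihood model would differ systematically.
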