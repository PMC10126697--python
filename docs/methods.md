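# Methods

## Model and assumptions

`repcore` counts *exact* occurrences of germline-derived search strings in
repertoire reads. That is only meaningful when a substantial proportion of
reads carry unmutated germline sequence — IgM/naive libraries, not
class-switched or heavily hypermutated ones — and when the reference
database is full length at the recombination-proximal ends ("end
corrected"). A database allele truncated at its 3' (V) or 5' (J) end shifts
the apparent recombination region and corrupts both the core derivation and
the truncation-scan diagnostic; the J-database validator therefore warns
when a J allele does not end in the conserved `TCAG` splice-proximal motif,
and the truncation scan itself is the recommended check for suspect V ends
(a count curve still rising steeply at the default trim suggests a
truncated reference).

Reads are assumed plus-strand and pre-filtered (the IgDiscover "filtered"
table is the canonical input dialect); matching is substring-anywhere
because reads carry primer/UTR prefixes of varying length. `N` bases in
reads never match and simply fail to count.

## Core derivation

Per gene, with alleles aligned at the conserved end (5' for V, 3' for J):

* trim = default (V 3': 6 nt; J 5': 6 nt) when no allele pair of the gene
  differs within the variant window (6 nt) of the recombination-proximal
  end;
* otherwise trim only down to the most terminal distinguishing position, so
  that position remains the terminal core base (possibly trim 0).

The variant window and default trim are separate parameters: the window is
where variants are *looked for*, the default trim is what is removed when
none are found. Both default to 6 nt: the truncation scan plateaus at a
trim of 4–5 nt on both real and simulated data, and 6 adds a safety margin;
a larger trim costs specificity (shorter cores) with no count gain beyond
the plateau. D genes default to 4+4 nt trims with a per-allele trimming
table override, because D junctional loss varies strongly by gene; a
per-allele table can give different trims to alleles of one gene, in which
case the equal-trim-per-gene guarantee is deliberately traded for the
table's empirical values.

Within-gene cores that end up identical except for length (alleles
differing only by length) are a hard error: exact matching cannot attribute
counts between them. Identical cores across genes (duplicated genes sharing
alleles) are merged under a joined `a/b` name rather than silently double
counted. D cores must not occur inside any other gene's full allele (gene
specificity); violations are hard errors pointing at the trims.

The LCS D mode enumerates all substrings of each D allele with length
≥ ceil(`min_fraction` × allele length) (default 0.5; the fraction is the
user's specificity/sensitivity dial) that occur in no other database
allele. At count time a read is credited to at most one D allele — the one
with the longest matching specific substring, ties to the alphabetically
first allele with the read flagged ambiguous. This captures rearrangements
whose D survival is biased to either end of the gene and would miss a
central fixed core.

## Counting

A read contributes one raw count to every core it contains; UMI counts are
the number of distinct UMI strings among contributing reads; the CDR3
length histogram and unique-CDR3 count are accumulated per core (empty
CDR3s bin at length 0). The implementation is a direct per-record scan
(CPython's substring search is effectively multi-pattern-fast at these
scales); its contract, asserted in tests, is exact equality with a naive
per-record, per-pattern oracle. The LCS counter pre-filters candidates with
the allele's minimum-length windows — a read shares a ≥ m-length substring
with an allele iff one of the allele's m-length windows occurs in it —
before searching the specific substrings longest-first.

The truncation scan counts, for t = 0..max, reads containing the allele
truncated by t nucleotides from the chosen end. Counts are non-decreasing
in t by construction. Note one subtlety the simulator exposes: junction
bases (N-insertions or the following segment) can coincidentally equal the
trimmed-off germline suffix, so a read's effective germline match can
exceed its recombination trim; the scan measures the effective value, which
is the biologically observable one.

## Genotype filtering

Stages, per gene, in order: allelic ratio (count / top allele count of the
gene; default 0.1 for V and J, 0.2 for D because short D cores convert
single errors into sibling-allele counts at higher rates), minimum count
(default 10), expected-frequency table (exclusion below the per-allele
minimum; rescue of ratio-failures at or above it), and the two CDR3
diversity filters (modal CDR3-length share ≤ 0.6; unique-CDR3 fraction
≥ 0.1). Design choices that were genuinely open:

* The ratio denominator is the gene's top single-allele count, not the gene
  total: heterozygous pairs then sit near 0.5–1.0, far from the 0.1 cutoff.
* The filtering basis defaults to UMI counts when a UMI column exists
  (consensus molecules are the natural evidence unit), raw counts
  otherwise; both are always reported.
* Rescue by expected frequency overrides only the allelic ratio — never the
  minimum count (too little evidence is too little evidence) and never the
  CDR3 filters (a clone is a clone).
* The minimum count and CDR3 thresholds were calibrated on the simulator's
  operating curves (noiseless and 0.003/nt-error libraries at 2×10⁴ reads)
  and are exposed in `FilterConfig`.
* Expected-frequency tables are consumed, not derived; deriving one from a
  cohort (mean allele frequency across libraries times a safety factor of
  ~0.1) is a documented recipe, not a packaged computation.

The end-variant test modifies the terminal base of a target allele in all
reads containing it full length (reads with recombination-truncated copies
stay untouched), supplements the database with the variant, and re-runs
genotyping; the gene then carries a final-nucleotide variant, core
derivation keeps it full length, and the genotype discriminates variant
from original at that base.

Haplotype inference counts, per V allele, reads where its core co-occurs
with each of the two anchor-gene allele cores (reads matching neither or
both anchors are ignored) and assigns haplotype 1/2 when the anchor-1
fraction is ≥ 0.9 / ≤ 0.1 (default threshold; the published cutoff for this
style of analysis is not stated), "both" in between, "unassigned" at zero
co-occurrences. Counting from core matches keeps the module independent of
upstream caller columns; a call-trusting mode exists for pre-annotated
tables.

## Simulator

The simulator is the package's study-condition generator, not a
biologically calibrated repertoire model. It emulates: a diploid genotype
(per gene and haplotype, presence with probability 0.9 and a uniform allele
draw); per-gene usage weights drawn log-uniformly over a configurable span —
V defaults to 3 orders of magnitude, matching the >1000-fold spread between
the most and least used alleles in deep IgM data, D to 1.5 and J to 1
(small loci, flatter usage); geometric junctional trimming
(P(trim = 0) = 0.5, cap 8 nt) at V3'/D5'/D3'/J5'; Poisson(4) random
N-insertions at both junctions; a random 10–30 nt 5' pad (primer/UTR);
molecules carrying random 12-mer UMIs read Poisson(1.5) times (PCR
duplicates share sequence and UMI); and independent per-read substitution
error at 0.003/nt (MiSeq-like). Somatic hypermutation is off by default and
exists only as a robustness knob. Trimming is pure deletion; the
replacement component of junction remodelling is approximated by the
N-insertions. The recorded CDR3 runs from the last 6 nt of the trimmed V
through the first 6 nt of the trimmed J, taken from provenance rather than
motif scanning.

What passing tests on simulated data do *not* show: robustness to real
primer and chimera artifacts, to biased UMI families, to allele-specific
expression quirks, or to reference databases with truncated or missing
alleles — those remain the user's responsibility via the validation
warnings and the truncation scan.

## Problem sizes and numerical choices

The recovery studies use 2×10⁴ reads over a 40-gene / 55-allele V
reference (15 heterozygous genes), 10 D genes / 15 alleles and 6 J genes /
7 alleles, with a 1-order usage spread so every expressed allele draws a
few hundred reads — adequate depth is a stated precondition for exact
recovery, and under the 3-order spread the rarest genes would fall below
any sane minimum count at this depth (that regime is exactly what the
subsampling study measures instead). The subsampling study uses a 10⁵-read
library with the 3-order V spread and a realistic J profile whose rarest
gene takes 3% of reads, so the 1% fraction (10³ reads) still yields ~30
reads for it. Ten Bernoulli replicates per fraction; thinning is Bernoulli
rather than exact-k so replicate size variance matches repeated random
sampling (an exact-k mode exists). All randomness flows through explicit
integer seeds; identical inputs give byte-identical outputs throughout.

Degenerate inputs: empty libraries genotype to all-OUT tables with zero
counts; alleles with no allele-specific LCS substring are excluded from LCS
counting with a warning; a fully trimmed-away D segment yields an empty D
part (the read simply cannot count for D); zero-count genes give allelic
ratio 0 for all their alleles.
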