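# Methods

## The assay and its data model

Digital gene expression (DGE) tag profiling measures a transcriptome by
counting short restriction-anchored tags. NlaIII cuts cDNA at every CATG;
MmeI then releases the 17 nt immediately downstream of the 3'-most CATG,
so each transcript is represented by a 21-nt tag (CATG + 17 nt) and
expression becomes a count of tag copies. The pipeline compares two
libraries — here named Ste (sterile) and Fer (fertile), after the floral
phenotypes of the study system, a Brassica cytoplasmic-male-sterility /
restorer pair carrying an introgressed alien chromosome — but nothing in
the code is specific to that system.

The unit of data is the pair (tag sequence, copy count). Reads are
collapsed to such pairs on ingest; quality strings play no further role.

## Virtual reference-tag index

All CATG+17-nt substrings of the reference (transcriptome, optionally
genome) are indexed, on both strands. Design points:

* **All sites, not only the 3'-most.** The wet protocol mainly emits the
  3'-most site, but partial digestion and internal priming produce others;
  indexing every site makes the index a superset of anything sequencable.
  The 3' preference is instead a property of the *sampling model* in the
  synthetic generator (`three_prime_bias`, default 0.85).
* Overlapping sites (CATGCATG...) each yield a tag; a site with fewer than
  17 nt downstream, or an N anywhere in the 21 nt, yields none.
* Coordinates are 0-based; `position` is the forward-strand offset of the
  C of the CATG anchor for both strands (an antisense tag occupies
  `[position-20, position+1)`). Reports use 1-based positions only for
  display.
* A reference tag is *unambiguous* when its site list names exactly one
  gene id. Shared tags between isoforms of one gene would therefore count
  as unambiguous; with distinct ids per record they do not.

## Filtering and accounting

Filters run in a fixed order — N-containing tags, adaptor tags, then
distinct tags whose remaining copy number is 1 — so the three accounting
rows are disjoint and the conservation identities

    clean_stage1 = raw − N − adaptor,   clean = clean_stage1 − singletons

hold exactly (property-tested on arbitrary libraries). A count-1 tag
containing N is booked under N, not under singletons. An "adaptor tag" is
one that equals or extends (as a prefix) a configured adaptor sequence;
the published accounting does not state the rule it used, so the exact,
configurable list keeps the bookkeeping deterministic. Copy-number bins
are 2–5, 6–10, 11–20, 21–50, 51–100, >100, partitioning [2, ∞).

## Mapping cascade

Each distinct clean tag is assigned by the first non-empty level of

    perfect sense → 1-mm sense → perfect antisense → 1-mm antisense
      → genome perfect → genome 1-mm → unknown,

with "1→1" vs "1→n" decided by the number of distinct genes hit (distinct
positions for the genome). The cascade order makes the category table a
partition; the source study's taxonomy implies mutual exclusivity but not
the tie-break, which is our choice (perfect > mismatch, sense > antisense,
transcriptome > genome). Mismatches are confined to the 17-nt variable
region by default — the CATG anchor is created enzymatically, so an
anchor mismatch means a different cut site, not a sequencing error — and
the 1-mm search probes the 51 single-substitution neighbours against the
hash index (O(1) each) rather than scanning it. An exhaustive
Hamming-distance scan over the whole index serves as the test oracle.

## Quantification

A gene's count is the summed copies of its sense 1→1 tags, perfect and
1-mismatch (the study does not say whether 1-mm tags entered its counts;
`perfect_only=True` gives the stricter reading). TPM is
`count × 10⁶ / total_clean_tags`, the denominator being the library's
total clean tags rather than the mapped total — "per million clean tags"
taken literally. Antisense 1→1 copies are tallied separately as evidence
of bidirectional transcription but never enter TPM. The qPCR utility
returns 2^−ΔΔCT with ΔΔCT = (CT_target − CT_ref)_treatment −
(CT_target − CT_ref)_control.

## The exact test

Under the null that a gene has equal expression proportion in both
libraries (sizes N1, N2; counts x, y), y conditional on x follows

    P(y|x) = (N2/N1)^y (x+y)! / (x! y! (1+N2/N1)^(x+y+1)),

a negative binomial with x+1 successes and success probability
N1/(N1+N2). The two-sided p doubles the smaller conditional tail, capped
at 1; the minimum-likelihood convention (sum of all outcomes no likelier
than y) is available via `method="minlike"`. Tails are summed in
log-space with compensated (`math.fsum`) summation; only the smaller tail
is summed directly and the larger follows by complementation, so relative
accuracy survives into the far tail (verified to <1e-12 relative error
against exact rational summation, and independently against the
negative-binomial CDF).

Caveats worth knowing:

* The test is *not* exactly exchangeable under swapping the libraries.
  The kernel satisfies p(y|x; N1,N2) = (N1/N2)·p(x|y; N2,N1); at equal
  depths the kernel is symmetric but the two tails are summed along
  different axes after conditioning on x, so the swapped p can differ by
  up to a factor 2 at small counts (e.g. (x,y)=(1,0) vs (0,1)).
* Genes, not tags, are the multiple-testing family; m = number of genes
  with x+y > 0. Adjustment is Benjamini–Yekutieli step-up (valid under
  arbitrary dependence), delegated to statsmodels.

Significance requires FDR ≤ 0.001 **and** |log2(TPM ratio)| ≥ 1. Genes
seen in one library only carry ±∞ log2 sentinels (no pseudocounts), which
satisfy the ratio criterion and place them in the Fer-/Ste-specific
subclasses of up-/down-regulated.

## Enrichment

The enrichment p-value for a term with M annotated background genes, m of
them in the n-gene DEG query, against a background of N annotated genes,
is the hypergeometric upper tail P(X ≥ m) (scipy's exact survival
function; an exhaustive rational enumeration validates every composition
with N ≤ 60 in tests and N ≤ 25 in the acceptance script). The background
N is the *annotated* genes of the scheme, not the whole universe, so
unannotated DEGs drop out of n. GO terms use Bonferroni over tested
(m ≥ 1) terms; pathway "Q values" use Benjamini–Hochberg step-up (the
name suggests an FDR-type quantity and no procedure was published; both
corrections are switchable). Significance is corrected p ≤ 0.05,
inclusive. Monotonicity of the tail in m is strict only where m−1 lies in
the hypergeometric support; degenerate compositions (n = N, M = N) give
flat stretches at P = 1.

## Saturation

Depths on the grid (default 5% increments of library size) are *nested*
without-replacement subsamples: each depth extends the previous draw by a
conditional multivariate hypergeometric increment, so each prefix is
marginally a uniform subsample and the detected-gene counts are
non-decreasing for every seed — as for prefixes of one sequencing run.
Genes are counted as detected by any mapped tag and, separately, by
unambiguous tags only. The closed form E[detected] = Σ_g (1 −
C(T−t_g, d)/C(T, d)) checks the sampler. A library is flagged saturated
when the marginal new-gene rate drops below 1 gene per 10⁵ extra tags
(the published claim — saturation near 2 million tags — is qualitative;
the threshold is a parameter).

## Synthetic data: what it emulates and what it does not

Defaults are the study conditions at desk scale: 2,000 genes of 300–1,500
nt, two libraries of 5×10⁵ tags, 100 DE genes planted at |log2| = 2
(split symmetrically, ×2 in one library and ÷2 in the other), 30
Fer-specific and 10 Ste-specific genes, and 10 *alien* genes excluded
from the reference and genome whose tags therefore surface only in Fer
and map nowhere — the synthetic counterpart of transcripts from an
introgressed alien chromosome. Noise: per-copy corruption probability
1−(1−ε)^17 with ε = 0.001/nt and a single uniform substitution in the
variable region (enough to exercise every 1-mm path; indels are out of
scope); N-reads at 0.4% and adaptor reads at 4% of depth, matching the
published accounting fractions; site choice within a gene puts 85% of
mass on the 3'-most CATG site.

Baseline abundances are log-normal with σ = 1.2. Planted DE and
library-specific genes are drawn only from genes whose baseline expected
count is ≥ 50 at the configured depth: a fold change planted on an
effectively silent gene is not a recoverable signal and would make
recovery statistics meaningless (the σ-sweep in
`analysis/07_calibrate_sigma.py` shows recovery is then insensitive to σ
over 0.8–1.8). Counting noise puts the per-gene log2-ratio standard error
at √(1/x+1/y)/ln 2 ≈ 0.29 at x = y = 50, so per-gene recovery is asserted
within max(0.3, 3·SE) and mean recovery within ±0.2.

Not emulated: the real libraries' ratio of transcriptome size to depth.
At 40,000+ genes under ~2.7M tags, >80% of distinct tags sit below 10
copies; at 2,000 genes under 5×10⁵ tags the mean gene gets ~250 copies
and the low-copy fraction is ~52%. Passing tests therefore demonstrate
correct accounting, mapping, inference and recovery mechanics — not that
the synthetic copy-number distribution matches the real one
quantitatively. Also absent: PCR duplicates, quality-score structure,
indels, isoforms sharing tags, and poly(A)-driven low-complexity tags.

All randomness derives from one seed through spawned NumPy generators;
outputs are byte-reproducible and tagged with a config hash.

## Numerical and degenerate-input choices

* Tail sums: log-space with max-shift rescaling and `fsum`; remainder of
  the infinite upper tail bounded by a geometric series and truncated at
  1e-15 relative.
* Percentages are stored unrounded and rounded to 2 decimals only for
  display (`pct_display`).
* Zero distinct tags → mapping percentages reported as 0, not NaN; zero
  total clean tags → TPM is an error; zero transcripts → coverage
  percentage is an error.
* `classify_degs` gives x = y = 0 genes p = 1, class "unchanged", log2 0.
* Ties in BY/BH are handled by statsmodels' step-up implementation;
  outputs return in input order.

## Problem sizes

Tests and the acceptance script run the default simulation (2,000 genes,
5×10⁵ tags per library, ~6,000 distinct clean tags), a 60-gene end-to-end
fixture, 200-case rational-oracle grids for the exact test, all ~44,000
hypergeometric compositions with N ≤ 25, and 200-replicate saturation
checks; the whole suite completes in well under two minutes on one CPU.
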