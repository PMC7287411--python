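# Methods

## Scope and data model

The pipeline consumes orthologous alignment blocks (MAF), a rooted binary
species tree with branch lengths in substitutions/site (Newick), and gene
models for one reference species (GFF3).  Internally every interval is
0-based half-open; GFF3 is converted at the boundary and BED is emitted
natively.  Species identifiers are the MAF source token before the first
`.` (a species-map file can rename nonconforming inputs).  Nucleotides are
handled case-insensitively; `N` is missing data — never a match, never a
mismatch.  The packaged 8-taxon *Oryza* AA-genome tree (SAT, RUF, NIV,
BAR, GLA, GLU, LON, MER; total length 0.057882) is the default phylogeny
for simulation and the worked examples.

## Neutral model and column scoring

For a column in which the species subset S carries unambiguous bases, the
neutral expectation is `E(S) = λ · L(S)`, where `L(S)` is the branch
length of the tree induced by S (edges that separate S into two non-empty
parts; degree-≤1 paths pruned) and λ rescales the input branch lengths to
the data.  λ is fitted as the mean Fitch parsimony count per
fully-present, non-CDS column divided by the total tree length; fully
present columns make the ratio well defined.  The estimate requires at
least 1,000 such columns, otherwise the fit aborts and an explicit λ
(e.g. 1) must be supplied.

Observed substitutions O are Fitch parsimony counts on the fixed topology,
computed column-vectorised with bit-mask state sets; absent species
propagate transparently, which equals Fitch on the induced subtree.  We
deliberately use parsimony rather than a per-column rate fit: at total
tree lengths well below 0.1 substitutions/site multiple hits are
negligible (the λ recovered from pure neutral simulations is ≈ 0.99), and
parsimony is deterministic and exactly testable against exhaustive
minimisation.  The rejected-substitutions score is `RS = E − O`; columns
with fewer than `min_species` (default 4) bases, or overlapping the coding
mask, are unusable and carry RS = 0.  Only CDS is masked — conserved
elements are expected and allowed in UTRs and introns.

One caveat of parsimony at this scale: O is not monotone under adding
species.  Adding a base identical to one already present can raise the
count (e.g. leaf pattern T,G,G on a quartet has O = 1, but T,G,G,T has
O = 2).  E, by contrast, is monotone in S by construction, and a
monomorphic column keeps O = 0 under any addition; the tests assert those
two properties.

## Element calling

At congeneric divergence the per-column signal is tiny: a substitution-free
column scores `+λ·L(S)` (≈ +0.05) *whatever its conservation class*, and a
substituted column scores ≈ −0.95.  Column-threshold run logic therefore
cannot separate conserved from neutral sequence — only the *density* of
substituted columns differs — so the default caller aggregates evidence
over segments:

1. **Scan** (`mode="msp"`): a local-alignment pass over cumulative RS;
   the running sum resets at ≤ 0, a candidate closes when the sum drops
   `xdrop` (default 5.0) below its running maximum, and the candidate span
   is reset-point → argmax.
2. **Depletion filter**: a candidate is kept only if its pooled observed
   count is significantly below its pooled expectation under a one-sided
   Poisson test, `P(X ≤ O_seg | E_seg) ≤ alpha_element` (default 0.01).
   This is what rejects the chance excursions of the near-driftless
   neutral RS walk.
3. **Boundary refinement**: boundaries are re-placed at the maximal-sum
   subsegment of the per-column log-likelihood ratio between the
   candidate's own substitution rate and the neutral expectation, iterated
   to a fixed point (≤ 4 rounds).  Columns without data are charged the
   neutral-prior expected score so that masked or gappy runs cannot act as
   free bridges into flanking neutral sequence.
4. **Filters**: reference length ≥ `min_element_length` (default 10 bp)
   and positive summed RS.  Elements never cross block boundaries, and no
   usable element column overlaps the coding mask (exact invariant).

On the ground-truth fixture (below) this recovers ≈ 92 % of conserved
bases while including ≈ 4 % of neutral bases; boundary placement is
fuzzy at the ±30–100 bp scale, which is the information-theoretic limit
when the neutral rate itself is only ~0.05 events/column.

A transparent alternative (`mode="runs"`) implements plain greedy runs:
maximal stretches of usable columns with RS above `rs_floor` (default 0),
tolerating interior gaps of ≤ `max_gap_run` (default 3) non-positive or
unusable columns, kept when the summed RS is positive and the reference
length reaches the minimum.  It is exactly testable and useful on deeply
diverged alignments, but for the reason above it cannot resolve
conservation classes at *Oryza*-scale divergence and is not the pipeline
default.

## Rate statistic and tests

Per element, pairwise distances `d_ij` are computed over the columns where
both species carry an unambiguous base; the default correction is JC69,
`d = −(3/4) ln(1 − 4p/3)` (raw p-distances by flag).  A pair saturates at
p ≥ 0.75, falls back to the raw proportion, and logs a warning.  Pairs
with zero overlap are missing: excluded from the mean's pair count and
from all pooled counts, never imputed.  The element's *nucleotide
substitution frequency* is `2 Σ_{i<j} d_ij / (n(n−1))` over defined pairs,
with n the number of species having usable coverage.

The baseline pools integer counts across all elements:
`p0 = Σ diffs / Σ sites` (count-weighted), with the unweighted mean of
per-element frequencies also reported; the pooled version feeds the tests
because it keeps null counts coherent.  Each element is tested by a 1-df
goodness of fit of its pooled counts (D, N) against p0, flagged *rapid*
iff p < 0.001 **and** D/N > p0 (one-sided by direction).  Expected counts
below 5 set a low-expected-count flag but the test still runs.  Per
species, the analogous test of (D_s, N_s) against a per-species pooled
baseline (global baseline by flag) yields the species-specific set, and
group contrasts use a 2×2 χ² without continuity correction on the pooled
per-species counts of two disjoint groups within the rapid set.  No
multiple-testing correction gates the fixed p < 0.001 rule; a
Benjamini–Hochberg column is emitted alongside for users.

### Calibration caveat (important)

The χ² treats pooled per-pair counts as binomial, but the 28 pairs of an
8-species panel share tree branches: one substitution on a branch
separating a | (8−a) leaves creates a(8−a) pairwise differences at once.
The resulting design effect, `c = Σ_e b_e k_e² / Σ_e b_e k_e` with
`k_e = a_e (8 − a_e)`, is ≈ 8.9 on the packaged tree, so the statistic is
roughly nine-fold overdispersed and the nominal p < 0.001 cut-off is
strongly anti-conservative: on pure-null simulations ~14 % of elements are
flagged.  This is a property of the classic frequency-contrast
construction that the package intentionally reproduces, not of the code;
a variance-corrected test would be nearly powerless here, because a 500 bp
conserved element at these branch lengths carries only ~6 expected
substitution events and a 5× single-branch acceleration adds ~4.5 more —
too few for any calibrated α = 0.001 test.  Measured under the fixture's
study conditions: type-I flag rate ≈ 0.14, power on truth-rapid elements
≈ 0.55, and the accelerated species is recovered in > 90 % of flagged
truth-rapid elements (the per-species test conditions on the element
already being extreme, so its direction information is reliable even
though the element-level error rate is not).  Rankings, per-species
frequencies, and group contrasts remain meaningful; absolute significance
levels should not be taken at face value.

## Genomic context and enrichment

Per gene, strand-aware intervals: upstream/downstream 2 kb windows off the
full transcript extent (first to last exon — not the CDS extent), introns
as gaps between merged exons, and UTRs from the model (inferred as exon
minus CDS when absent), clipped at position 0.  Multiple transcripts
contribute the union per feature class.  A region receives every category
it overlaps by ≥ 1 base; summaries count multi-category regions once per
category (a documented double-count), with a precedence mode
(5′UTR > 3′UTR > intron > upstream > downstream) for single labels.  Note
that mirroring coordinates *and* strands preserves categories (the flanks
mirror with the gene), whereas flipping strand in place swaps
upstream ↔ downstream; both invariants are tested.  Enrichment is an
upper-tail hypergeometric per term over study versus background gene sets
with BH adjustment, reported only for terms with ≥ 1 study hit.

## Synthetic data

Columns evolve independently down the tree under JC69 (uniform root
composition by default): per branch, a column changes with probability
`(3/4)(1 − e^{−4t/3})` and then picks one of the three other bases
uniformly, so path probabilities compose exactly and simulated p-distances
match the closed form `(3/4)(1 − e^{−4T/3})` (asserted within 3 binomial
SE at 10⁵ columns).  Effective branch length is `b` (neutral), `r_c · b`
(conserved, default r_c = 0.2), or `r_c · m · b` on the one accelerated
terminal branch of a rapid segment (default m = 5 on LON).  No indels are
simulated; gap handling is exercised by hand-built fixtures.  Ground truth
records the segment tiling and realized per-branch substitution counts.

The default fixture layout is one 5 kb block per orthologous segment:
1.5 kb neutral / 0.5 kb conserved / 1 kb neutral / 0.5 kb rapid-slot /
1.5 kb neutral, the rapid slot accelerated in every fourth block and
realized as plain conserved otherwise.  That gives ~20 % constrained
bases, ~500 bp constrained segments, and a minority of rapid segments —
the regime the method targets.  One toy gene per block places the
conserved segment in a flank window and the rapid segment in the 5′UTR
(even blocks, + strand) or intron (odd blocks, − strand), with CDS kept
clear of both so the coding mask does not interact with recovery.

What the simulator does **not** emulate: indels and alignment error,
GC-content and context-dependent mutation, rate variation within segments,
incomplete lineage sorting, and real gene architecture.  Passing tests
demonstrate the statistical machinery recovers planted structure under the
stated model, not performance on real alignments.

## Problem sizes and determinism

The test suite and the acceptance script run everything at desk scale:
200-block (1 Mb × 8 species) fixtures for recovery, 2,000 simulated
elements for calibration, 10⁵ columns for closed-form checks; the whole
suite completes in well under a minute on one core.  All randomness flows
from explicit integer seeds through `numpy.random.default_rng`; analysis
stages are seed-free, writers use fixed number formatting (≥ 6 significant
digits) and fixed sort orders, and a full rerun is byte-identical.
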