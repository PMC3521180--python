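# Methods

This note documents the model behind `seednet`, the conventions and
numerical choices of the implementation, what the synthetic-data generator
does and does not emulate, and the design decisions taken where the
procedure was genuinely open.

## Scoring model

A weight matrix is stored as per-position nucleotide frequencies (rows sum
to 1 within 1e-9); count matrices are normalised at read time. The matrix
similarity score of a window is information-weighted and min-max
normalised:

- I(i) = Σ_b f(i,b)·ln(4·f(i,b)), with 0·ln 0 = 0, so 0 ≤ I(i) ≤ ln 4;
- Current = Σ_i I(i)·f(i, b_i); Min and Max replace f(i, b_i) by the
  per-position minimum/maximum;
- MSS = (Current − Min)/(Max − Min); a completely uninformative matrix
  (Max = Min) scores 1.0 by convention.

An ambiguous base `N` contributes the per-position *minimum* — the most
pessimistic choice, so N-rich windows rarely reach a threshold. The gap
symbol is `-` and may appear only in alignments, never in scanned
sequences.

Each matrix carries a minFN threshold: the minimum MSS over the known
binding sites it was built from, i.e. the largest cutoff that retains every
training site. Scanning keeps windows with MSS ≥ threshold (ties kept) on
both strands; reverse-strand hits are scored against the
reverse-complemented matrix and reported at the + strand coordinate of
their leftmost base. A Match-style 5-position core pre-filter (the
information-richest consecutive run) is implemented but off by default,
since threshold profiles here are defined by minFN alone.

## Conservation filter

Scanning operates on gap-stripped per-species sequences; hits are mapped
back to alignment columns through a strictly increasing coordinate map.
A human site is conserved when (a) mouse, dog and cow each carry an
independently predicted hit of the same matrix on the same strand whose
column interval shares the human site's start column or end column, and
(b) that shared boundary column is a non-gap symbol in all four rows. This
is the strictest reading of "shares a conserved site that starts or ends at
a non-gap symbol": it requires both cross-species prediction and the
boundary rule. A relaxed mode (`relaxed_boundary`) keeps any human site
whose start or end column is gap-free in all rows, without ortholog
support, for sensitivity analysis. Conservation is a pure filter: it never
alters scores or coordinates.

Promoters must be present in all four species; blocks with missing rows are
rejected at parse time rather than partially processed.

## Profiles, networks, expansion

Profiles are cut per matrix: the p% profile keeps the ⌈p/100·n⌉
best-scoring conserved sites of each matrix. The ceiling guarantees every
matrix stays represented even at p = 1 on small n, and makes profiles
nested across percentiles. Ties at the cut are broken deterministically by
(promoter, start, strand); a `keep_ties` mode admits all boundary ties
instead.

Network edges are gene-level: all sites of matrix m in any promoter of
gene g collapse to one edge per TF gene of m, with the site count kept as
edge support. Self-edges (autoregulation) are allowed. Expansion copies,
per bottommost classification clade, the *union* of the matrix-bearing
members' direct target sets to every member — the union is the only
order-independent choice when several members carry matrices. Expanded
edges carry `expanded` provenance and never overwrite `direct` ones; the
operation is idempotent and purely additive. TFs absent from the
classification pass through with a warning. Only gene-level edges are
expanded; site coordinates are not copied. Clades with two or more
matrix-bearing members are used to cross-validate the assumption via the
pairwise Jaccard overlap of their direct target sets.

## Validation counting

The four confusion categories are evaluated per promoter so that they
partition a common universe (TP+FP+FN+TN = number of promoters) and
PPV/SPC/TPR are all well-defined: TP — some predicted site lies inside a
ChIP region; FP — predictions but none inside; FN — no prediction but a
ChIP region overlapping the promoter by at least 500 nt; TN — neither.
"Inside" means full containment of the site interval, the natural reading
for ~10–20 nt sites against fragment-scale regions; an overlap-based mode
and a site-level TP/FP counting mode are available by flag. The 500-nt
FN rule is applied exactly as stated. Zero denominators yield NaN metrics,
never exceptions. Because profiles are nested, TPR is non-decreasing and
specificity non-increasing along the percentile sweep; the tests assert
this invariantly.

## Tissue networks and degree statistics

Expression is binary presence/absence per tissue (the default panel is
brain, heart, kidney, liver, ovary, prostate, spleen, testis); no abundance
threshold exists in the model. A tissue network is the induced subgraph on
expressed genes — an edge needs both endpoints expressed — which makes the
filter monotone and idempotent. A TF counts as present in a tissue network
only when *active* (out-degree > 0); a node-presence mode exists by flag.

Degree distributions are summarised as the inverse cumulative
F(d) = |{nodes with degree ≥ d}| / n for observed d ≥ 1. Zero-degree nodes
are excluded from the support but included in the denominator (so F(1) is
the fraction of regulated/regulating nodes); a flag switches to
positive-only denominators, another to absolute counts. The exponential
fit is unweighted least squares of ln F(d) on d over all points with
F(d) > 0, requiring ≥ 3 points; a constant distribution returns slope 0
with r = NaN. For a geometric degree distribution with success probability
p the tail is (1−p)^(d−1), so the fitted slope estimates ln(1−p); with
5000 nodes the estimate is within ~10% of truth (tail points are sparsely
populated and equally weighted, which biases the slope slightly steep).

Expansion ratios (eTTN over TTN mean degrees and counts) treat an
unchanged degenerate quantity (0 → 0) as a unit ratio and growth out of
zero as NaN.

## Synthetic data: what it emulates, and what not

The generator reproduces the *statistical structure* the pipeline assumes,
at desk scale (defaults: 60 promoters of 1000 nt, 8 matrices of length
8–12 built from 10 training sites each, 2 planted sites per promoter,
GC-rich background (0.23, 0.27, 0.27, 0.23), ortholog substitution rate
0.25, gap rate 0.05, conservation probability 0.7, ChIP sensitivity 0.7
with 0.5 noise fragments per promoter and 600-nt fragments, 8 tissues,
clades of 2–4 members):

- planted sites are sampled from the matrix distribution and rejected
  until they reach the matrix's own minFN threshold, so every planted site
  is guaranteed recoverable by the scanner;
- a conserved site is copied intact into all three ortholog rows; a broken
  site is overwritten in one random ortholog by a background window
  *verified* to score below threshold, so the four-species filter provably
  rejects it;
- gap columns are inserted only outside planted-site footprints (one
  column margin), so planted conserved sites always sit on gap-free
  boundary columns. Recovery of planted labels is therefore exact by
  construction (100% / 0% at conservation probability 1 / 0) — a check of
  implementation correctness, not of statistical power;
- ChIP sets cover each planted site with a centred fragment at the given
  sensitivity plus uniform noise; two sets drawn independently emulate two
  cell lines with partial overlap;
- matrix-bearing TFs draw broad expression (per-tissue probability 0.9),
  matrix-less clade members 1–2 tissues, nonTF targets 0.6 per tissue —
  the mixture behind the contrast in tissue breadth between original and
  expansion-added TFs.

Not emulated: realistic indel/substitution evolution, promoter GC
heterogeneity and CpG islands, correlated binding of cooperating factors,
ChIP fragment-length and peak-shape realism, and expression abundance.
Passing tests therefore demonstrate correctness of the algorithms and the
qualitative behaviours (curve shapes, breadth contrast, exponential-like
degree decay), not genome-scale performance figures.

## Sizes and determinism

All randomness flows from a single integer seed through
`numpy.random.default_rng`; child generators receive seeds drawn below
2³¹. Rerunning any stage or the full pipeline with the same configuration
and seed reproduces every output byte-identically. The bundled end-to-end
analyses use 60–150 promoters and 8 matrices — large enough for stable
curve shapes and degree fits at interactive runtimes; scaling up is purely
a configuration change.

## Conventions and degenerate inputs

All coordinates are 0-based half-open; BED I/O is native. Readers reject
malformed input (duplicate identifiers, all-zero count rows, unequal
alignment rows, missing species, inverted intervals, non-binary expression
values) instead of repairing it. Writers round-trip: matrices to within
1e-12 in frequency, all discrete structures exactly. Sequences shorter
than a matrix scan to an empty result; empty BED files are empty region
sets; empty degree sequences and empty site lists for threshold derivation
are errors.

## Known limitations

- The conservation rule's strict reading (independent prediction in all
  four species) is implemented as the default; the literature-standard
  alternatives (column-conservation only) are reachable via the relaxed
  mode but not separately validated.
- Cross-species supporting sites must pass the same minFN threshold as the
  human site; species-specific threshold calibration is not modelled.
- Matrix-to-gene mapping is taken from the library annotation as-is;
  resolving species-specific protein synonyms to human symbols is out of
  scope.
- Expansion inherits complete target sets; partial specificity divergence
  within a clade is not modelled (the per-clade Jaccard report quantifies
  how optimistic that is on a given dataset).
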