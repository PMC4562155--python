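# Methods

## Scope and model

`ppicliffs` scores the reliability of directed protein–protein
interactions from annotated literature evidence and locates the interfaces
between established and emerging knowledge (knowledge cliffs). The
pipeline is: evidence table → per-edge raw score → log compression →
min–max normalization → zone labels → cliff detection → degree-preserving
permutation test.

## Weighting

Evidence-quality categories (12 by default) are ordinal: experts rank them
from most (rank 1) to least reliable. The rank-sum linear scheme converts
a rank `r` among `n` factors into `W_r = 2(n+1−r)/(n(n+1))`, i.e. the
inverse rank normalized by the sum of inverse ranks. It is the simplest
MCDM weighting that is strictly decreasing in rank and sums to one, and it
needs nothing beyond the ordinal ranking itself.

Expert disagreement is resolved by arithmetic mean rank, re-ranked into a
permutation with ties broken by factor listing order. Mean-rank consensus
was chosen over Borda or pairwise methods because expert panels here are
small and the inputs are full permutations; with a single expert it reduces
to the identity.

Journal impact factors are reduced to a venue-confidence weight in two
steps: quantile binning into `n_bins = 12` ranks (rank = `floor(n_bins·q)+1`
where `q` is the fraction of journals with strictly greater impact factor),
then the same rank-sum weight with `n = 12`. This empirical-quantile rule
is scale-invariant, keeps tied impact factors in one bin, and degrades
gracefully when fewer distinct values than bins exist (a warning is
emitted; the all-equal case collapses to rank 1). A 5-bin quintile mode is
available through `n_bins=5` for users who prefer coarser venue classes.
Journals absent from the table get the worst rank rather than an error:
an evidence line must never be unscoreable.

## Scoring

The raw score of a directed pair is the signed weighted sum over its
evidence lines, `S = Σ σ·W_factor·W_journal` with σ = ±1 for
support/contradiction. Each line contributes a default count of one; the
two quality weights multiply because they are independent discounts on the
same report (what kind of experiment, and where it was published).
Consequences used as test invariants: S is additive in evidence lines,
symmetric support/contradiction pairs cancel exactly, and appending a
supporting (contradicting) line strictly increases (decreases) S.

Raw scores are compressed with the signed logarithm
`sign(S)·ln(1+|S|)`. A plain logarithm would be undefined for the zero or
negative totals that contradictions produce; log1p keeps the map strictly
increasing, odd, and fixes 0, while still flattening the heavy right tail
created by the most-studied interactions. The base is immaterial after
normalization's affine invariance.

Normalization is min–max to [0, 1] over all edges of one network. It is
deliberately strict about degeneracy: fewer than two distinct log scores
raises instead of silently emitting constants, since a single-edge or
all-equal network has no meaningful relative confidence. Normalized scores
are therefore *relative to the corpus*, not comparable across networks.

Zone boundaries default to emerging < 0.5 ≤ buffer < 0.75 ≤ established:
0.5 splits off the sparsely studied majority, 0.75 matches the default
cliff threshold so the established zone is exactly what a cliff must drop
from. Both are configuration values, not constants.

## Cliffs and the permutation null

A cliff is an ordered triple `(i, j, k)` of pairwise distinct vertices with
edges `i→j`, `j→k`, both weights positive, and drop `w_ij − w_jk ≥ c`.
The comparison is `≥` and the admissible threshold range is
[0.1, 0.99] (overridable with `force`). Longer descending paths are
reported as their qualifying triples rather than merged chains; the triple
is the defined unit and merging semantics would be arbitrary. Requiring
`i ≠ k` excludes two-cycles, which are reciprocal disagreements rather
than chains. The detector is checked against exhaustive `|V|³` triple
enumeration on hundreds of random digraphs.

"Preserving the degree distribution" is implemented in its strictest
reading: every node keeps its exact in-degree and out-degree. Each
randomization attempts `swaps_per_edge × |E|` directed double-edge swaps
(pick edges (a,b), (c,d), rewire to (a,d), (c,b)), rejecting self-loops
and duplicate edges; `swaps_per_edge = 10` attempted swaps per edge is the
common rule of thumb for mixing edge identities. Networks admitting no
swap are returned unchanged with a warning — their edges are forced by the
degree sequence and correctly get null probability 1.

Edge occurrence probabilities use a pseudo-count of 1:
`(occurrences + 1)/(n_randomizations + 1)`, keeping probabilities in
(0, 1] so that cliff p-values (products of the two edge probabilities,
edges assumed independent) never collapse to an unreachable 0. With the
default 10,000 randomizations the pseudo-count shifts a probability by at
most 1e-4. No multiple-testing correction is applied across cliffs; the
reported flag is raw p < alpha (0.05 default), and the run report records
n, seed, swaps, and pseudo-count for reproducibility.

## Synthetic data

The generator emulates a curated disease-specific evidence corpus, not any
particular dataset. Defaults: 300 proteins, 340 directed interactions
(the scale of a single-disease curation effort), preferential-attachment
edge placement (`hub_fraction = 0.7` of endpoint draws are
degree-proportional) so a few hubs dominate; per-edge evidence counts
`1 + NegBin(size = 0.6, mean = 2)` giving mean 3 lines per edge with a
heavy right tail (mean > median); contradiction probability 0.05 per line,
reflecting how rarely negative interaction statements are published;
category ids drawn with probability ∝ id so the most reliable classes are
the rarest; 100 journals with log-normal impact factors (log-mean 1.0,
log-sd 0.6, a realistic right-skewed IF distribution); 5 experts whose
rankings are identity permutations with a few adjacent swaps. Scoring such
a corpus concentrates most normalized scores below 0.5, matching the
low-score dominance expected of emerging literature.

What the generator does *not* emulate: annotator disagreement, text or
abstracts, correlated evidence (the same study reported in several
articles), temporal publication dynamics, or biased venue–quality
coupling. Passing tests therefore demonstrate the correctness of the
algorithms under the stated statistical shape, not calibration against any
real corpus.

The cliff testbed plants ground-truth cliffs: background edges get
mid-band evidence volumes (uniform 3–8 mid-quality lines), each planted
chain attaches a maximal-evidence upstream edge (300 top-quality lines) to
a high-out-degree background node and a minimal downstream edge (one
weakest-quality line, unlisted venue) to fresh nodes. Two isolated anchor
edges pin the extremes of the normalization range so background score
differences stay far below 0.5 while planted drops are ≈ 1; the low anchor
is strictly weaker than the planted downstream edges so those keep the
positive weight the cliff definition requires. Planted edges touch
low-degree nodes, so the degree-preserving null regenerates them rarely
and their cliffs come out significant.

## Numerical and interface choices

- All tables are UTF-8, tab-separated, LF-terminated with `.` decimals;
  writes are byte-deterministic and `read∘write` is the identity on valid
  corpora.
- Protein symbols are opaque case-sensitive strings; self-interactions are
  accepted but flagged in the validation report. Lenient reading skips and
  reports malformed rows, never silently (accepted + warned = input rows).
- All randomness flows through `numpy.random.default_rng` seeded
  explicitly; CLI runs record their seed in a manifest.
- Problem sizes in the test-suite and acceptance runs: detector/oracle
  equivalence on 200 digraphs of 5–50 nodes; null-probability checks at
  10,000 randomizations on toy and testbed networks (46 edges); the
  end-to-end pipeline at the default 300-protein scale with 300
  randomizations for the significance annotation — sizes chosen to make
  Monte-Carlo error negligible relative to the assertions (3σ binomial
  bands at n = 10,000 are ±0.015).

## Known limitations

- Scores are corpus-relative (min–max); adding one edge can shift every
  normalized score.
- The edge-independence assumption behind the cliff p-value is an
  approximation; edges sharing a hub are negatively correlated under the
  degree-preserving null, and the product rule is anti-conservative there.
- Impact factor is a venue-level proxy for article-level trust, inherited
  from the attribute design; the binning softens but does not remove its
  biases.
- The permutation loop is pure Python; ~10,000 randomizations of a
  few-hundred-edge network take on the order of a minute. For much larger
  networks reduce `n_randomizations` or `swaps_per_edge` first.
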