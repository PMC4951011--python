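# Methods

## Model and assumptions

seedpath implements guilt-by-association gene prioritization on a weighted
PPI network.  The modelling assumptions, in decreasing order of strength:

1. Proteins connected by high-confidence interactions tend to share
   function, and chains of high-confidence interactions propagate that
   tendency: all nodes on a low-weight path between two genes of known
   function plausibly share that function.
2. The edge weight `w = 1000 − Q` makes path weight a monotone surrogate
   for "chained confidence".  Only the *ordering* of path weights matters;
   no probabilistic semantics (e.g. independence of edges) is assumed.
3. The permutation null — uniform same-size gene-set resampling — captures
   exactly one confounder: network topology (hubs and dense regions lie on
   many shortest paths for any terminal set).  It deliberately does not
   preserve degree sequences, so a gene's FDR reflects its specificity to
   the seed set relative to arbitrary gene sets, not relative to
   degree-matched sets.  No analytic null, edge rewiring, or
   Benjamini–Hochberg correction is applied; those would answer different
   questions.

## Betweenness counting

Distances and path counts are exact: weights are integers in [1, 850], so
distances are integers and shortest-path counts σ are integers computed by
Dijkstra with predecessor-structure accumulation (arbitrary precision —
path counts grow combinatorially and would overflow fixed-width integers
or lose precision as floats).  For a seed pair (s, t), node v ≠ s, t lies
on a shortest s–t path iff dₛ(v) + dₜ(v) = dₛ(t); the pair then credits v
with:

- `all-paths` (default): σₛ(v)·σₜ(v), the number of distinct shortest s–t
  paths through v.  This reads "all shortest paths between any two seeds"
  literally while never enumerating paths explicitly.
- `per-pair`: 1.  Retained because "the number of paths containing each
  gene" is also consistent with one-path-per-pair pipelines; the mode in
  effect is recorded in every output header.

Pair endpoints are never credited for their own pair; seed genes *are*
credited as inner nodes of other pairs and can therefore re-emerge as
validated candidates.  Disconnected seed pairs are skipped and tallied
(`skipped_pairs`), never an error.  An exhaustive simple-path enumeration
oracle (feasible to 14 nodes; positive weights make every shortest path
simple) provides an independent check, and the test suite verifies
equality on hundreds of random graphs in both modes.

## Permutation FDR

For each of N random sets (default N = 1000, matching the seed-set size,
drawn uniformly without replacement), the betweenness computation is
repeated.  Per gene, `FDR(g) = M/N` with M the number of random sets whose
betweenness for g exceeds the observed value; genes absent from a run have
betweenness 0 there.  Conventions, each configurable and echoed in all
outputs:

- Comparison is strict `>` by default (`ge` available as the more
  conservative standard permutation-p convention); ties do not count
  toward M.
- The sampling universe is all network nodes by default (seed genes may
  appear in null sets); `non-seed-nodes` is available.
- No pseudocount by default: FDR 0 is attainable and reported as printed;
  `(M+1)/(N+1)` smoothing is an option, off by default.
- The comparison is per gene: each gene's observed betweenness is compared
  with that same gene's betweenness across runs (the FDR is indexed by
  gene; no set-level scalar exists to compare).

FDR values are stored as exact rationals (`fractions.Fraction`), so
`FDR(g)·N = M` holds identically and the strict `< 0.05` filter has no
floating-point boundary artifact (a float threshold is interpreted as its
decimal literal, so 0.05 means exactly 1/20 and FDR = 0.05 is excluded).

## Numerical and procedural choices

- **Score validation** is a hard error outside [150, 999] rather than a
  clamp, to surface dialect mismatches early.
- **Duplicate pairs**: STRING dumps list each interaction in both
  directions; the parser reports raw record counts while the builder
  stores deduplicated undirected edges, and both tallies appear in the run
  report.  Conflicting scores for one pair keep the maximum score
  (minimum weight): the strongest evidence wins.
- **Identifier normalization** strips the taxon prefix and collapses one
  trailing `.<digits>` isoform suffix by default (results are reported at
  gene level); both behaviours are flags.
- **Determinism**: the heap tie-break is a monotone counter (node labels
  are never compared), all output rows have total orderings, random sets
  are drawn from a sorted universe with a seeded `numpy` generator, and
  outputs contain no timestamps — identical inputs and seed give
  byte-identical outputs.
- **Checkpointing**: all N random sets are pre-generated from the seed;
  per-permutation tables can be persisted and a capped run
  (`--max-permutations`) resumed later, reproducing the single-shot run
  exactly.  A checkpoint directory records a network fingerprint and the
  null configuration and refuses to resume under a mismatch.  If fewer
  than N permutations have been completed, the FDR is computed over the
  completed ones and `n_permutations_completed` is reported.
- **Degenerate inputs**: fewer than two in-network seeds, an empty
  permutation sequence, a sampling universe smaller than the set size, and
  an empty seed intersection are errors with stage context; an empty
  network writes a header-only edge table.

## Synthetic benchmark

The generator emulates the STRING dialect (header row, both-direction
duplicate lines, `<taxid>.<gene>.<isoform>` identifiers, integer scores in
[150, 999]) around a planted functional module: a sparse Erdős–Rényi
background (default 400 nodes, edge probability 0.02, scores U[150, 400])
containing a dense module (30 nodes, edge probability 0.6, scores
U[850, 999]), each module node wired to the background by at least one
background-strength bridge.  15 module members are designated seeds; the
other 15 are hidden members to be recovered.  Decoy seeds (background
nodes added to the seed list) default to 0 — the reference benchmark has
none — and exist so tests can confirm off-module seeds do not inflate
module FDRs.  Scores are uniform on intervals rather than fit to STRING's
empirical distribution because the method depends only on the ordering of
path weights; the separation between the module and background intervals
is the controlled variable, and the spec warns when the intervals overlap.

What passing benchmark tests show: the pipeline preferentially recovers
genes embedded in a coherent high-confidence neighbourhood of the seeds,
above size-matched random gene sets.  What they do not show: performance
on real interactomes, whose degree distributions are heavy-tailed, whose
scores are biased by study effort, and whose "modules" are neither
disjoint nor uniformly dense.  Recovery numbers on the benchmark are not
estimates of precision/recall on *Arabidopsis* data.

## Problem sizes

The test suite and acceptance script run the benchmark at its default
scale (≈430 nodes, ≈1900 edges, 15 seeds, 200 permutations, 10 generator
seeds) and verify the shortest-path engine against the enumeration oracle
on 200 random graphs of up to 12 nodes; a full STRING-scale analysis
(≈25k nodes, ≈3.1M undirected-equivalent records, 994 seeds, 1000
permutations) uses the identical code path with checkpointed permutations.

## Known limitations

- The uniform null does not control for degree; a hub adjacent to many
  seeds can retain a low FDR for topological reasons.
- Betweenness counts (not the FDR filter) can be dominated by a single
  tied-path-rich pair in `all-paths` mode; `per-pair` mode bounds each
  pair's influence at 1.
- Identifier normalization is string-based (prefix + isoform suffix); no
  cross-database ID mapping is attempted.
- The pipeline is single-process; permutation runs are independent and
  order-invariant, so external parallelization over checkpoint shards is
  possible but not built in.
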