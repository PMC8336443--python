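# Methods

This note documents the models, algorithms and numerical choices behind
`rawrphylo`, and what its synthetic benchmarks do and do not demonstrate.

## Resampling walks

A replicate of an MSA `A` with `L` columns is a sequence of `L` column
indices (the *trace*) plus the corresponding column gather.

**Reversal walk (`rawr`).** The walk state is (column, direction). The
start column is uniform on `[0, L)` and the start direction uniform on
{left, right}. Each step samples the current column, then updates: at an
interior column the direction reverses with probability γ; at column `0`
or `L-1` the direction reverses if and only if it faces outward, with
certainty and without consuming a γ draw. The walk then moves one column
in the (possibly reversed) direction. It stops when `L` columns have been
sampled (sequence-length convergence), so every trace has length exactly
`L` and consecutive indices always differ by ±1.

Two consequences of these rules are worth stating explicitly:

* *Boundary handling.* Allowing a γ reversal at a boundary column facing
  inward would immediately step outside the alignment, so γ applies at
  interior columns only. This matches the verbal description of the
  procedure ("reverses with certainty at the first and last site, with
  probability γ elsewhere") and keeps the walk well-defined for every γ,
  including γ = 1, where the walk oscillates between two adjacent columns.
* *Boundary sampling bias.* A reflecting walk crosses interior columns in
  both directions but visits an endpoint once per excursion, so in
  aggregate the two terminal columns receive about **half** the sampling
  mass of interior columns (measured: ≈0.53× at L = 50, γ = 0.1, 5000
  replicates; interior columns are uniform within ≈6%). The bias is
  intrinsic — the deterministic γ = 0 sweep has the same factor-two
  endpoint dip, since an endpoint appears once per period `2(L-1)` of the
  triangle wave while interior columns appear twice. Support estimation
  averages over many replicates with uniform starts, which removes
  start-position bias but not this boundary effect; for typical alignments
  (hundreds to thousands of columns) it touches 2 columns and is
  negligible downstream.

At γ = 0 the walk is the deterministic mirrored sweep from a random
start; γ well below 0.5 preserves long-range neighbor dependence; the
study grid is {1e-3, 1e-2, 2e-2, 5e-2, 1e-1, 2e-1, 3e-1} with default
**γ = 0.1**.

**Teleportation walk (`teleport`).** With probability γ a step jumps to a
uniformly random column and direction instead of reversing; boundary
reflection is unchanged. At γ = 1 every sampled column is an independent
uniform draw, so this variant interpolates between the reversal walk and
the bootstrap. **Bootstrap (`bootstrap`)** traces are `L` i.i.d. uniform
draws.

**Replicates and RNG.** Single-locus walk replicates are unaligned (gaps
dropped per row) and re-enter the full two-phase pipeline `g(f(·))`;
bootstrap replicates keep their columns and are re-estimated by `g` only,
because without neighbor preservation re-alignment is not meaningful.
Replicate `i` of `k` draws from the `i`-th stream spawned from the master
seed via `numpy.random.SeedSequence.spawn`, so runs are exactly
reproducible and replicates are independent. Site order in a replicate is
walk order, not sorted original order — this is what makes re-alignment a
real estimation problem. A taxon whose sampled columns are all gaps is
retained with an empty sequence (the taxon set is fixed for support
bookkeeping); the built-in tree backend refuses such rows rather than
inventing a placement.

## Support

Bipartitions are canonicalized as the frozenset of labels on the side not
containing the lexicographically smallest taxon, making equality invariant
to rooting. Support of an annotation-tree branch is the fraction of
re-estimated trees displaying its bipartition — always an exact multiple
of `1/k`. Defaults follow the study protocol: k = 100 replicates
("RAWR-reduced" denotes k = 10). Replicate re-estimation failures abort by
default; an explicit skip policy renormalizes by the number of successes
and warns, because silent denominator changes would bias support.

The multi-locus protocol resamples each partition independently by a walk
in *aligned* mode, drops partitions missing any of A, C, G, T (avoiding
degenerate substitution-model fits), concatenates survivors into a
supermatrix and re-estimates a tree per replicate; the annotation tree is
estimated on the full concatenation. γ for the multi-locus mode defaults
to the single-locus default (0.1).

## Re-estimation backends

The contribution of the package is resampling, not alignment or
maximum-likelihood tree search, so the built-in backends are deliberately
simple distance-based methods adequate for desk-scale benchmarking:

* **Aligner**: pairwise 3-mer distances → average-linkage guide tree
  (scipy) → progressive profile–profile Needleman–Wunsch with expected
  column-pair scores (match +2, mismatch −1, N and existing gaps 0) and a
  linear new-gap penalty of −2. Ties break deterministically
  (diagonal > up > left); empty sequences become all-gap rows.
* **Tree estimator**: Jukes–Cantor-corrected distances over gap-excluded
  pairwise sites (N counts as mismatch; saturated or incomparable pairs
  are capped at distance 5.0), neighbor joining (scikit-bio), taxa sorted
  lexicographically first so output is independent of input order.

External tools plug in through the same two contracts: a MAFFT subprocess
adapter and a generic command-template tree adapter (suitable for RAxML);
their tests skip when the binary is absent. Every aligner output is
validated to preserve the taxon set and to unalign back to its input.

## Evaluation

Confusion classes at threshold `t`: an estimated-tree bipartition is a
positive iff its support ≥ `t` (the comparison is `≥`), a true positive
iff the reference tree also displays it. The PR curve sweeps `t` over the
observed unique support values in descending order, prefixed by a sentinel
above the maximum (recall 0, precision 1 by convention); the AUC is the
trapezoid over that recall-ordered sequence with no interpolation beyond
the computed points. This reproduces `scikit-learn`'s
`precision_recall_curve` + `auc` exactly (verified in tests), which is the
convention used for the published curves. **Aggregate PR-AUC** pools
confusion counts across datasets at each threshold before forming the
curve — not a mean of per-dataset AUCs; a `mean_auc` option provides the
alternative since either reading of "aggregate" is defensible.

Other statistics: nRF normalizes the symmetric difference of non-trivial
bipartition sets by the total count over both trees (`2(n−3)` for binary
trees). SP-FN/SP-FP compare residue-pair homology sets; both alignments
must describe identical unaligned sequences. ANHD excludes sites gapped in
either row of a pair from numerator and denominator (the convention is
unstated in the benchmark tables, so printed ANHD values are treated as
directional only); a pair with no comparable sites is dropped with a
warning. Gappiness is the gap-cell fraction of the matrix.

## Benchmark simulator

Model trees: topology grown by uniform random leaf splitting (the
simplest random birth process), every edge length Uniform(0,1), then all
lengths rescaled so the maximum root-to-leaf path equals the condition
height exactly. Sequence evolution: root of length 1000 (default) drawn
from the stationary frequencies; per-branch substitutions from the GTR
transition matrix (rate matrix scaled to one expected substitution per
site per unit length, eigendecomposed once), optional Gamma(α, mean 1)
per-site rate multipliers inherited through the tree; insertions and
deletions as Poisson events per branch (rate = indel probability × branch
length × sequence length) with geometric lengths (mean 2). Every residue
carries a global column identity, giving an exact true alignment.

The published benchmark used INDELible/ROSE with GTR parameters fitted to
an empirical nematode rRNA dataset that are not printed in the source;
the simulator therefore defaults to the neutral Jukes–Cantor
parameterization (arbitrary GTR accepted), and printed benchmark summary
statistics are treated as directional anchors, not exact targets. The
10-taxon condition triples (e.g. 10.A = 10 taxa, height 0.47, indel 0.13)
ship as `CONDITIONS_10_TAXON`. The simulator captures indel-induced site
dependence and alignment uncertainty — the phenomena the resampler
targets — but not secondary-structure constraints, selection, rate
correlation between neighboring sites, or the birth–death/deviation
procedure used for the original 100-taxon trees, so passing benchmarks
here demonstrate correctness of the machinery and the direction of the
RAWR-vs-bootstrap contrast, not empirical effect sizes.

## Problem sizes and observed results

The shipped experiments are scaled to desk hardware: the benchmark
condition uses 10 taxa, height 0.7, indel rate 0.1, 1 kb roots, 10
simulated datasets and k = 20 (k = 10 for RAWR-reduced), with the
built-in backends. All reported numbers are produced at run time by
`scripts/acceptance.py` and the test suite; with seed 1 the aggregate
PR-AUC ordering comes out RAWR ≈ RAWR-reduced > bootstrap, and the
low-divergence (height 0.1) two-phase pipeline recovers model trees with
mean nRF well under 0.2. Exact-topology NJ recovery at height 0.05 is
limited by near-zero internal branches that uniform branch lengths
routinely produce (~1e-3 expected substitutions), so that check uses 16 kb
sequences.

## Known limitations

* The built-in aligner is a basic progressive method with linear gap
  costs; on divergent data its SP error is far higher than MAFFT's, which
  compresses absolute PR-AUC differences between support methods.
* The built-in tree backend is distance-based NJ, not maximum likelihood;
  partitioned likelihood for the multi-locus mode is delegated to external
  tools via the adapter.
* Boundary columns of an alignment are under-sampled by a factor of ~2 in
  walk replicates (see above).
* The convergence criterion is sequence length only; statistical stopping
  rules are out of scope.
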