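# Methods

## Terraces, stands, and what the engine computes

Let `T` be a binary unrooted tree on taxon set `X` and let a partitioned
data set sample taxon subsets `Y_1, …, Y_k` (one per locus).  Locus `j`
induces the subtree `T|Y_j` — `T` restricted to `Y_j` with degree-2 nodes
suppressed.  The *stand* of `T` under this coverage pattern is the set of
binary unrooted trees on `X` that display every `T|Y_j` (display = restrict
and obtain the identical topology).  Under parsimony or edge-unlinked
partitioned likelihood, all members of a stand score identically, and the
stand is a *terrace*.  The engine characterizes the stand implied by
coverage alone; it never evaluates a likelihood, so its output is
meaningful regardless of the inference model that produced the input tree
(with edge-linked models the members simply are not guaranteed equal
scores).

### Rooted-triplet reduction

All induced subtrees are rooted at one *comprehensive taxon* `r` (sampled
in every locus) and each is decomposed into a minimal defining set of
rooted triplets: for every internal node below the root, the triplet
`a|bc` formed by one representative leaf from each child subtree (`b`, `c`)
and one from outside the node (`a`).  A binary rooted tree is identified
among trees on its leaf set by these `n−2` triplets, so the trees
displaying the union of the per-locus defining sets are exactly the trees
displaying every induced subtree.  Unrooted trees on `X` correspond
bijectively to rooted trees on `X∖{r}`, which is the space the recursion
works in.

Instances without a comprehensive taxon are refused with an explicit
error.  A divide-and-conquer decomposition for such instances exists in
principle, but refusing is the honest contract: partial support would
silently change semantics for exotic inputs.

### The counting recursion

On a label set `L` with triplet set `R`, build the cluster graph: vertices
`L`, one edge `b–c` per triplet `a|bc` with all three labels in `L`.  Let
`C_1, …, C_m` be its connected components.  Every displaying tree's root
bipartition of `L` is a bipartition of whole components (an edge can never
be split at the root), and conversely any of the `2^(m−1) − 1` component
bipartitions extends independently on each side, so

```
count(L) = Σ over component bipartitions (G1, G2) of count(G1)·count(G2)
```

with `count(L) = 1` for `|L| ≤ 2`.  Components refine as labels leave the
set (a triplet whose `a`-label is absent imposes nothing), which the
recursion handles naturally by recomputing components per call.  Counts
are Python integers (arbitrary precision); memoization is keyed by frozen
label set.  When no triplet touches `L` at all, the closed form
`(2|L|−3)!!` replaces the recursion — without it, unconstrained regions of
an instance would cost exponential time for an answer that is a double
factorial.

The recursion is exponential in the worst case (many components under
sparse constraints).  A *work cap* bounds the number of expansions; an
exhausted budget makes remaining subproblems contribute 0, so the capped
result is a certified lower bound and is flagged as such, mirroring how
runaway empirical instances are reported rather than silently truncated.

* **Enumeration** streams the same recursion without memoization (time
  linear in trees yielded), with a tree-count cap and exhausted flag.
* **Uniform sampling** draws a component bipartition with probability
  proportional to `count(G1)·count(G2)` at every node, using the memoized
  count table; seeded via `random.Random(seed)`.
* **Strict consensus** keeps an input-tree split `A|B` iff the number of
  terrace trees forced to contain it equals the terrace size.  That forced
  count factorizes exactly: trees within the cluster `A` (triplets wholly
  inside `A`) times trees on the quotient where `A` collapses to a
  meta-leaf (triplets mapped across the boundary; a triplet needing a
  partner of an inside label outside the cluster is unsatisfiable and
  zeroes the product).  Candidates are only the input tree's splits, since
  the input tree is itself a terrace member.
* **BUILD (Adams) consensus** is the classic recursive component tree of
  the triplet system; it displays every triplet and refines the strict
  consensus.
* **Per-clade resolution counts** quotient the triplet system at each
  internal node of the strict consensus (children become meta-leaves) and
  count local arrangements.  Because every terrace member contains every
  strict-consensus cluster, local choices are independent and the product
  of the per-node counts equals the terrace size — an identity the tests
  assert against the oracle.

### Polytomies

Input-tree polytomies are treated as soft: the reported count is the sum
of terrace sizes over all binary resolutions of the polytomies.  The
number of combined resolutions is computed up front and refused above a
cap (default 10,000).  Consensus, enumeration, and sampling require binary
input; only counting supports the soft-polytomy path.

## Coverage matrices

A locus is *sampled* for a taxon when at least one site of the locus holds
a character outside the missing set.  Default missing sets are `-?Nn`
(nucleotide) and `-?Xx` (amino acid); the boundary for ambiguity codes is
a package choice — a stretch of `N`s carries no phylogenetic signal — and
is overridable.  Partition definitions use the RAxML dialect
(`DNA, name = start-end[, start-end…]`, 1-based inclusive, `\3` codon
steps expanded), the format practitioners already have on disk.

Taxon-triple coverage (the fraction of `C(n,3)` triples jointly sampled by
at least one locus) is computed exactly by iterating triples over
per-taxon locus bitsets (`O(n³)` with a cheap inner step; refused above a
configurable 2000-taxon ceiling) or by seeded Monte-Carlo sampling with a
binomial standard error.  Inclusion–exclusion over per-locus combination
counts was rejected: it is exponential in the number of loci involved in
overlaps, and `k` is large in exactly the data sets that matter.

## Decisiveness diagnostics

For uniform random sampling at density `d`, the bound on the locus count
needed for decisiveness with confidence `p` is

```
k_min = ln(C(n,3)/p) / −ln(1−d⁴)    (exact)
      ≈ ln(n³/(6p)) / −ln(1−d⁴)     (approximation; the survey convention)
```

Both forms are exposed; `d = 1` returns 0 (any sampling decisive).  Gene
sampling sufficiency is implemented as `ζ = ln(k / k_min)`.  The argument
order is deliberate: the survey's displayed equation reads `ln(k_min/k)`,
but its stated sign convention (`ζ < 0` = insufficient) and all 26 of its
printed values require `ln(k/k_min)`; the package follows the values.  `ζ`
is computed from the raw (unrounded) `k_min` by default, with an option to
use the integer ceiling, because the printed table mixes the two
conventions.

Default `p = 0.05` matches the survey.  Several printed `k_min` values
(Birds, Scincid lizards, Ficus) are not recoverable from the rounded
printed densities — the survey evidently used unrounded `d` — so
regression tests assert only the rows that do reproduce (Mammals 11,
Chameleons 14, 1000 Plants.1 7) and the sign structure of the rest.

AIC arithmetic (`AIC = 2p − 2lnL`, `ΔAIC = AIC[EL] − AIC[EUL]`, positive
favoring the edge-unlinked model) operates on externally supplied
log-likelihoods only; model fitting is out of scope.  ΔAIC is recomputed
from the stored per-model AIC columns rather than stored directly, because
the survey's printed log-likelihoods were rounded independently of its
printed AICs (they disagree by ±1–2 on several rows).

## Terrace-aware bootstrap

Given replicate trees and one coverage matrix, the pipeline computes the
ordinary majority-rule consensus of the replicates and, in parallel, the
majority-rule consensus of each replicate's terrace strict consensus.  A
split absent from any member of a replicate's terrace cannot be credited
to that replicate, so aware support is bounded above by plain support for
every split, and consensus resolution ρ (nontrivial splits divided by
`n−3`) can only drop — the package's testable version of the empirical
observation that bootstrap proportions overstate support in terraced tree
space.  The majority threshold is a strict `> 50%` (the standard
convention), configurable upward.  Replicates whose terrace computation
exceeds the work cap are excluded and counted, since a lower-bound terrace
has no well-defined strict consensus.

Replicate generation is out of scope: replicates are inputs, because the
procedure's substance is the consensus-of-consensus step, not the
bootstrap search.

## Synthetic data and the oracle

`random_binary_tree` grows a topology by uniform random edge attachment,
which yields the uniform distribution over the `(2n−5)!!` unrooted binary
topologies (verified by chi-square against full enumeration at `n = 5`).
`random_coverage_matrix` draws each cell Bernoulli(`d`), optionally forces
one all-present row (the comprehensive taxon the engine needs), and
repairs empty rows/columns by flipping single cells, deterministically
under the seed.  This emulates the uniform-sampling regime the `k_min`
theory assumes.  It does **not** emulate real matrices — missingness in
empirical supermatrices clusters by clade and by locus popularity — so
passing tests certify the combinatorics, not the field behavior of any
particular data set.

The oracle enumerates all topologies (refused above `n = 8`) and filters
by the display definition using restriction + bipartition-set equality.
Oracle and engine share only the restriction primitive, never counting
logic, so their agreement on 300 random instances per run (`n = 5–7`,
`k = 2–4`, densities 0.3–0.9, comprehensive taxon forced) is an
independent check of the whole recursion stack.  Those problem sizes keep
the exhaustive filter exact while exercising every code path — terrace
sizes in that range span 1 to several hundred.

## Numerical and representational choices

* Trees are compared by bipartition sets (label-based), never by string
  equality; Newick serialization is canonical (children ordered by
  smallest descendant label) so equal topologies print identically.
* ρ uses the unrooted convention (denominator `n−3`) even for rooted
  input, after unrooting, matching how consensus resolutions are reported
  for unrooted trees; it is undefined (error) below 4 leaves.
* Terrace sizes print as exact decimals below 10⁶ (with thousands
  separators) and as two-decimal scientific notation (`1.30E+388`) above.
* Branch lengths and support labels are parsed and discarded everywhere:
  terrace structure is a function of topology and coverage only.
* Tie-breaks (component order, bipartition enumeration order, child
  order) are all fixed and lexicographic, so every operation is
  deterministic given its seed.

## Known limitations

* Instances lacking a comprehensive taxon are refused, not decomposed.
* The strict-consensus route costs one cluster-constrained count per input
  split; on large sparse instances the work cap may trigger before the
  consensus is complete (consensus has no lower-bound analogue, so it
  simply fails loudly).
* No remediation tooling: finding the maximum defining label set, or
  re-partitioning to shrink terraces, is out of scope.
* No likelihood computation of any kind; AIC helpers only do arithmetic on
  supplied scores.
* NEXUS input, charset blocks, and branch-length-aware operations are
  unsupported.
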