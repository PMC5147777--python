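# Methods

## Model

A genotype is a sequence of `L` positions, each holding one of `K`
characters; the genotype space is the Hamming graph `H(L, K)` in which
two genotypes are adjacent iff they differ at exactly one position
(substitution-only mutation; every genotype has `(K-1)·L` neighbours).
Indices read the sequence as a base-`K` number with position 0 least
significant, so the all-zeros sequence is index 0 and the all-`K-1`
sequence is index `N-1`, `N = K**L`.

A fitness landscape assigns a scalar fitness to every genotype.  The
**House-of-Cards (HoC)** ensemble draws all `N` fitnesses i.i.d.
uniform on `[0, 1)` and swaps the maximum to index `N-1`; because the
draws are exchangeable and the Hamming graph vertex-transitive, this
is equivalent to re-indexing the graph so the global optimum is the
target genotype, without permuting anything else.

A pathway from the antipodal genotype (index 0) to the target is
**accessible** when fitness strictly increases at every step.  Steps
are classified relative to the target: *forward* (Hamming distance to
the target decreases), *backward* (increases), *distance-neutral*
(unchanged; impossible for `K = 2`).  Three pathway families are
supported: `all` (no class restriction), `no_backward` (forward and
neutral steps), and `shortest_only` (forward steps only, so every path
has length `L`).  The `no_backward` family is defined by distance to
the *target*, matching the step-class definition; defining it by
distance from the start is inequivalent for `K > 2` and is not
silently substituted.

**Accessibility** `A` is the probability that a random landscape from
an ensemble contains at least one admissible path; **coverage** is the
fraction of genotypes lying on at least one such path.

## Algorithms

Strictly increasing fitness makes the admissible edge set a DAG, so
everything reduces to single-visit traversals:

* *Accessibility*: iterative depth-first search from the start along
  admissible edges with single-visit marking and early exit at the
  target.  No backtracking is needed for a reachability question.
* *Exact path counts and statistics*: genotypes are processed in
  decreasing fitness order; each node's path count to the target (and
  pooled step-class totals, and optionally a per-node histogram over
  `(n_backward, n_neutral)`) is accumulated from its strictly fitter
  neighbours.  This is the counter-accumulating backtracking search
  collapsed into one pass per edge.  Counts use arbitrary-precision
  integers (they exceed 1e30 on large landscapes); for
  ensemble-scale runs a float64 variant keeps 15-16 significant
  digits, ample for the reported ratios.  Every bucket of the 2-D
  histogram obeys `length = L + 2·n_backward + n_neutral`.
* *Coverage*: a genotype is covered iff it is reachable from the
  start and co-reachable to the target along admissible edges; two
  reachability sweeps suffice, no path enumeration.  An inaccessible
  landscape has coverage 0 and is excluded from the primary
  (accessible-only) ensemble average; the all-landscape average,
  where it contributes 0, is reported alongside.
* The hot kernels are JIT-compiled (numba) and handle `N = 2**20`
  landscapes in tens of milliseconds (DFS) to seconds (full counting
  DP).  The exact big-integer programs are pure Python and default to
  `N <= 4096`.

Correctness of the dynamic programs is anchored by a naive recursive
enumeration oracle in the test suite: on >200 random landscapes
(`N <= 729`, all three modes) counts, class totals, histograms and
length distributions agree exactly.

## Ensemble experiments and estimators

* `A` is a binomial proportion; its standard error is
  `sqrt(A(1-A)/n)`.  Replicate sub-streams are spawned
  deterministically from one seed, so results are bit-reproducible.
* `A_inf = A(N -> infinity)` is the intercept of a least-squares line
  of `A` against `1/log2(N)` over points with `N > 2**10`.  The fit
  is weighted by inverse binomial variance because replicate counts
  shrink with `N`; the intercept is clamped to `[0, 1]`.  Desk-scale
  curves reach `N = 2**22` (K=4, L=6..11 with 30000 down to 800
  replicates) and `N = 2**20` (K=16, L=3..5 with 40000/12000/3000
  replicates; the short three-point curve needs heavy sampling because
  the intercept variance is leverage-dominated).
* Conditioning on the initial fitness `f0` is exact for i.i.d.
  ensembles: the start genotype's value is overwritten.  A replicate
  whose maximum falls below `f0` counts as inaccessible.  `f_crit`
  is the linearly interpolated crossing of `A(f0)` with 0.5 — the
  transition sharpens with `L`, so any fixed threshold converges to
  the same limit; 0.5 is symmetric and stable.  The threshold is a
  parameter.
* Step-class composition is reported under two conventions.  The
  primary *landscape-averaged* statistic takes each accessible
  landscape's per-path mean class counts, averages them over
  landscapes, and forms fractions from the ratio of means — every
  landscape carries equal weight, matching how mean pathway length
  and its class decomposition are tabulated.  The *pooled* statistic
  divides raw step totals summed over all paths of all landscapes;
  it is dominated by the path-richest landscapes and is
  systematically more backward/neutral-heavy (e.g. 4.6% vs 2.0%
  backward at `K=2, L=5`).  Both are returned.
* Default resource bounds: exact-counting experiments refuse
  `N > 2**20`, accessibility and coverage `N > 2**24`; the bounds are
  arguments, and the algorithms themselves scale further given time
  and memory.

## Empirical pipeline

Input is a TSV mapping fixed-length sequences over a declared
alphabet to positive fitness values.  Missing genotypes (sequences
absent from the table) are assigned the minimum observed fitness;
values are affinely mapped onto `[0, 1]`.  Both steps are
rank-preserving for the observed genotypes, and accessibility depends
only on fitness ranks.

Two sub-landscape families are sampled uniformly without replacement
(seeded rejection sampling):

* *fixed background*: fix `|i|` positions to a random character
  background; the free positions span a `K**(L-|i|)` landscape.
  There are `C(L, |i|) · K**|i|` distinct specs (258,048 for a
  10-mer with 5 fixed positions, `K = 4`).
* *binary pair*: choose an unordered character pair per position;
  the induced landscape is the `2**L` hypercube on those characters
  (`C(K,2)**L` specs; ~6.05e7 for the 10-mer, `K = 4`).

Each sub-landscape is re-indexed by per-position character
relabelling so its fittest genotype becomes all-`K-1` and a randomly
chosen antipodal genotype (uniform over the `(K-1)**L` candidates)
becomes all-zeros.  The forced assignments alone do not always form a
permutation of the alphabet at a position (the character `K-1` may
already be in use elsewhere), so each per-position rule is completed
to a permutation: unassigned characters stay fixed whenever possible,
leftovers are matched in ascending order.  Row-wise permutations
guarantee the map is a graph isomorphism — every genotype keeps its
neighbour set — which the test suite verifies together with
invariance of path counts.

Before f0-resolved analyses, sub-landscape fitnesses are
rank-uniformised: rank `r` (ties broken by ascending genotype index)
maps to `(r + 0.5)/N`, making the marginal uniform on `(0, 1)` while
preserving order.  Curves of accessibility, path count and coverage
are binned by the uniformised initial fitness on a fixed grid of
width 0.05 (bin centers reported).  Every sub-landscape is paired
with a fitness-shuffled counterpart (random permutation of the
values, maximum re-pinned), which preserves the fitness distribution
but destroys fitness-to-distance correlations.

## Synthetic tables

The generator emulates the two features of real genotype-fitness
tables that the HoC model lacks: a negative correlation of fitness
with distance to the global optimum, and missing genotypes.  Raw
scores `s = (1-w)·u + w·(1 - d/L)` (with `u` i.i.d. uniform and `d`
the distance to the all-`K-1` genotype) are rank-uniformised into
fitness values, so the weight `w` acts purely through the fitness
order; `w = 0` is exactly HoC, `w = 1` makes fitness a function of
distance alone.  A uniformly chosen fraction `m` of non-target
genotypes is then deleted; the default `m = 0.04` mirrors the ~4%
of genotypes without measurable fitness in the smaller published
data set this pipeline is shaped around.

What the synthetic tables do *not* emulate: local (neighbour-scale)
epistatic correlation structure beyond the global distance trend,
measurement noise, and any biophysical model of binding.  Tests
passing on synthetic fixtures therefore demonstrate that the
pipeline's machinery (completion, extraction, re-indexing,
uniformisation, shuffling contrasts) is correct, and that the
qualitative effects of fitness-to-distance correlation — higher
accessibility, more paths, higher critical initial fitness than the
shuffled baseline — are reproduced; they do not calibrate any
quantitative claim about a specific experimental system.

## Numerical choices and edge cases

* Admissible steps require *strictly* increasing fitness; ties
  (possible in empirical tables, measure-zero in simulation) are
  never crossed.  Rank ties in uniformisation break by ascending
  genotype index, deterministically.
* Fitness values live in `[0, 1]` (empirical normalisation maps the
  maximum to exactly 1; random draws stay in `[0, 1)`).
* `set_initial_fitness` rejects `f0` at or above the target fitness
  (the conditioning would be ill-posed: no strictly increasing path
  could exist).
* The 2-D histogram dynamic program guards its memory with a
  configurable cell bound and refers callers to the pooled-totals
  variant when exceeded.
* One explicit seed per experiment; per-replicate and per-component
  sub-streams are spawned from it, so no global RNG state is shared.

## Problem sizes in the default runs

The test suite and the acceptance script run everything at desk scale
on one CPU: accessibility ensembles up to `N = 2**22`, exact counting
ensembles up to `N = 2**20` (K=16, L=5), coverage at `N = 2**20`, and
sub-landscape ensembles of 500-1000 samples at `N <= 64` per
sub-landscape.  The same code paths scale to the larger grids
(`N = 2**28` accessibility, full-table histograms) given proportional
time and memory; those sizes are simply not part of the default runs.

## Known limitations

* Exact big-integer statistics are pure Python and impractical above
  `N ~ 10**4`; the float64 ensemble variants lose exactness (but not
  accuracy of ratios) and cannot represent counts above ~1e308.
* `A_inf` extrapolation from desk-scale curves carries an intercept
  standard error of roughly 1-2 percentage points; the published
  asymptotes were fitted over larger `N` ranges.
* Sub-landscape sampling without replacement enumerates a seen-set;
  sampling close to the total spec count degenerates to full
  enumeration.
* Pathways are unweighted: no realisation probabilities are attached
  to paths, and no evolutionary dynamics beyond the accessibility
  question is modelled.
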