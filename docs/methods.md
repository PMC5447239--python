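# Methods

## Model

`ptpdelim` delimits species on a single-locus phylogeny whose branch
lengths are measured in expected substitutions per site.  A *delimitation*
of a rooted binary tree `T = (V, E)` assigns every edge either to one
between-species (speciation) process or to exactly one of `k`
within-species (coalescent) processes.  It is encoded by the set of
*coalescent roots*: the roots of the maximal subtrees whose internal edges
are all within one species.  The edge leading into a coalescent root
belongs to the speciation process, and a tip may itself be a coalescent
root (a singleton species contributing no within-species edges).

Branch lengths within each process are modelled as i.i.d. exponential.
With `E_s` the speciation edges and `E_1 … E_k` the per-species coalescent
edge sets, the multi-rate model (mPTP) maximizes

    L = ∏_{x ∈ E_s} λ̂_s e^{−λ̂_s ℓ(x)} · ∏_i ∏_{x ∈ E_i} λ̂_i e^{−λ̂_i ℓ(x)}

with closed-form rate MLEs λ̂ = n/Σℓ per edge set, so each set contributes
`n·ln(n/Σℓ) − n` to the log-likelihood.  The single-rate model (PTP) pools
`E_1 … E_k` into one coalescent fit.  For a fixed delimitation the
multi-rate log-likelihood is therefore never below the single-rate one
(per-group ML fits dominate the pooled fit), which makes the single-rate
model nested in the multi-rate model and the likelihood-ratio test in
`evaluate` well-defined.

### Model selection and parameter counting

Competing delimitations are compared with AICc,

    AICc = −2 lnL + 2p + 2p(p+1)/(n − p − 1),

where `n` is the number of *informative* branches (see `minbr` below).
The parameter count is `p = k + 1`: one coalescent rate per delimited
species plus the speciation rate (the speciation term is dropped for the
null model, which has no speciation edges).  Species whose within-species
edges are absent (singletons) or entirely uninformative still count one
rate: the model posits a rate per species whether or not the data identify
it.  This choice matters.  If only *fitted* rates were counted, a
delimitation consisting of one short-branch cherry plus all-singleton tips
would cost almost no parameters while harvesting a large likelihood gain
from the two shortest branches in the tree, and model selection would
over-split rate-homogeneous trees badly; with `p = k + 1` the null model
is returned for the large majority of trees simulated with a single rate,
while recovery under strong rate separation is unchanged.  When
`n − p − 1 ≤ 0` the model is inadmissible at that sample size and its AICc
is `+∞`, which lets selection proceed on very small trees.  Exact AICc
ties (ties within 1e-9, which arise mathematically — the null and the
all-singleton delimitations induce the same single-fit likelihood) are
broken toward fewer species.

### Minimum informative branch length

Identical or nearly identical sequences produce (near-)zero-length
branches that carry no information about either process and would drive a
rate estimate to infinity.  Branches shorter than `minbr` (default 1e-4
substitutions/site, exposed on the CLI) are excluded from every fit and
from the AICc sample size; they are still classified, so the three-way
edge classification always covers `E`.

## Maximum-likelihood search

The exact optimum over all delimitations is found by a greedy dynamic
program.  Every node `u` carries an array indexed by `i`, the number of
informative speciation edges inside its subtree.  Entry 0 is the
single-process null for the subtree, precomputed in one post-order pass
from subtree edge-count/length-sum accumulators.  An entry `i > 0` at an
inner node is assembled from child entries `j` and `k` with
`i = j + k + 2`; when an out-edge of `u` falls below `minbr` it occupies
no slot and the `+2` becomes `+1` or `+0`.  Candidates are scored by the
likelihood restricted to the subtree plus the set `S` of edges incident to
the root-to-`u` path — the smallest set forced into the speciation process
once the subtree contains speciation edges.  `S`'s informative edge count
and length sum are precomputed top-down, so scoring a candidate pair is
O(1); the inner loop is vectorized over `k` with numpy.  Only the best
`(j, k)` pair per entry is kept (ties to the smallest `j` for
determinism), which is what makes the search greedy rather than exact;
exhaustive enumeration (`brute_force_best`) provides the independent
oracle on small trees and agrees with the DP in ≥ 90% of strongly
separated simulations in the test suite.  With both out-edges of a node
uninformative a `(0,0)` combination would collide with the reserved null
entry at index 0; the colliding candidate is dropped — a documented,
rarely exercised limitation of the entry indexing.

At the tree root `S = ∅`, so each root entry's score is the exact model
log-likelihood of its backtracked delimitation.  AICc is evaluated per
root entry (the species count `k` is carried through the recursion), the
argmin is backtracked via stored child pointers, and the result is
re-scored from scratch as a guard.  The same recursion serves the
single-rate model by carrying the pooled coalescent sufficient statistics
(count, length sum), which are additive, and fitting the pooled rate at
scoring time.

## MCMC

The sampler targets the distribution that assigns each delimitation a
probability proportional to its Akaike weight `exp(−AICc/2)`, so per-node
support values are sums of Akaike weights over the sampled delimitations
containing that node in the speciation process.  Split and merge moves are
chosen with equal probability; the Hastings correction uses the uniform
candidate counts of the move and its reverse, and a move type drawn with
zero candidates is a self-transition.  States with infinite AICc have zero
weight and are never accepted (a chain started in one escapes immediately).

Because a coalescent process's fit depends only on static subtree
accumulators of its root, a move updates the score, the candidate lists
(swap-pop arrays) and the per-node membership states in O(1): the per-step
cost is independent of tree size, and 10^6 steps on a 2000-tip tree take
seconds.  The incremental score is checked against a full recomputation
every 10^5 steps and at the end of every run.

"Part of the speciation process" is operationalized per node class: an
inner node counts when both of its out-edges are speciation edges; a tip
counts when it is a singleton species.  This is the reading under which
ASV equals 1 when the sampler visits only the ML delimitation.  ASV
averages `f(u)` over the ML delimitation's singleton tips and `1 − f(u)`
over its inner coalescent roots; since every delimitation has at least one
coalescent root, the average is always defined (for the null delimitation
it reduces to `1 − f(root)`).  ASDDSV averages the across-run sample
standard deviation (n−1 denominator) of `f(u)` over inner nodes only —
tip supports are largely redundant with their parents.

Defaults: 10 runs of 10^6 steps, burn-in 10% of steps, sampling every
step, each run started from an independent random delimitation (each
visited node becomes a coalescent root with probability 1/2), per-run
seeds spawned deterministically from a master seed (default 42).

## Synthetic data

The generator draws data exactly from the model the estimators assume: a
species backbone topology built by uniform sequential random joins with
every backbone edge `Exp(λ_s)`, and each backbone leaf replaced by a
random-join within-species subtree with every edge `Exp(λ_i)`.  Defaults
(4 species × 4 tips, λ_s = 1, λ_i = 50) give the 50-fold separation
between within- and between-species branch lengths typical of barcoding
datasets with distinct species.  Because lengths come straight from the
exponential mixture, recovery tests exercise the estimator, not model
misspecification; passing them says nothing about robustness to real-data
violations — non-exponential coalescent depth structure, tree-inference
error, rate variation within a species, or unsampled lineages.

## Problem sizes used in the checks

The bundled checks run at sizes where the independent oracles are exact
and the whole suite stays interactive: 200 random 4–8-tip trees for
DP/recomputation consistency, 1000 random (tree, delimitation) pairs for
the nesting inequality, exhaustive enumeration plus a 10^6-step chain on a
fixed 6-tip tree for the stationary-distribution check (±0.02), 100
replicates per condition for recovery, ten 6×10^4-step chains for the
ASDDSV diagnostic, and a 2000-tip tree (100 species × 20 tips) for the
scale smoke test.

## Known limitations

- The DP is greedy: groupings outside the subtree and forced path set are
  not explored, so the global AICc optimum is not guaranteed (the
  exhaustive oracle bounds the gap on small trees).
- Precision/recall use the pairwise operationalization; per-cluster purity
  variants would give different absolute values.
- Rooting on the longest terminal branch splits that branch at its
  midpoint; placement elsewhere on the branch would change only the two
  root-adjacent lengths but can change the delimitation near the root.
- Inner-node labels in input newick are preserved on output but ignored by
  the model.
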