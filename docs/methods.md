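# Methods

## Model

`hmtree` tests the family of nested null hypotheses attached to a GO-style
DAG of gene sets. Each node carries the null "this gene set's multivariate
expression distribution is identical across conditions"; because a null set
forces all its subsets null, the hypothesis states are logically
constrained along edges. The package models the states jointly rather than
testing them sequentially.

### Tree transformation

Computation happens on a spanning tree of the (transitively reduced) DAG.
Each multi-parent node keeps the incoming edge from the parent with the
largest gene set — the choice that preserves the most gene-set overlap —
with ties broken by the lexicographically smallest parent identifier so
runs are deterministic. All other incoming edges are severed, which is
equivalent to removing the child's genes from the parents that lost the
edge.

Carved tree gene sets are built from annotation *origins*: a gene's origin
terms are the DAG nodes where it is not explained by any child
(`G_v \ ∪_children G_c`), and the origins are propagated upward along the
retained tree. Since every tree descendant is also a DAG descendant, the
carved set of a tree node is contained in every DAG node lying above its
origins, which makes the reconstruction identity
`G_j = ∪ {T_k : T_k ⊆ G_j}` hold by construction. (An alternative
formulation — top-down subtraction of severed children's gene sets — looks
equivalent on small examples and matches the four-node worked example, but
violates the reconstruction identity on larger random DAGs: a subtracted
gene can end up only in tree nodes that are not subsets of some DAG node
containing it. The origin-propagation rule was adopted for exactly that
reason; the identity is still asserted at build time and raises a
`StructuralError` naming the offending node rather than patching around a
violation.) Nodes carved empty have no testable p-value; they head
necessarily-empty subtrees, which are dropped and recorded in the map so
`GT_j` stays well defined.

Tree nodes are re-indexed with the root first and positions sorted by
(depth, identifier); all arrays in the package line up with this order.

### Probability model

States `S_i ∈ {0,1}` on tree nodes follow a Markov tree: the root is DE
with probability π; a DE parent passes state 1 on with persistence ω; a
null parent forces null children (transition matrix rows `(1, 0)` and
`(1−ω, ω)`). P-values are conditionally independent given states with

- alternative: `beta(α, β)`, `α ∈ (0,1]`, `β > 1` — strictly decreasing,
  as expected for tests with power;
- null: `λ·U(0,1) + (1−λ)·beta(α0, β0)`, `α0, β0 > 1` — an empirical null:
  the unimodal beta component absorbs the mild, positive-dependence-induced
  departures from uniformity that overlapping gene sets produce. With
  `λ = 1` it degenerates to the textbook uniform null.

Conditional independence is an approximation: overlapping gene sets share
genes, so their p-values are correlated beyond what the tree explains. The
empirical null mitigates but does not remove this; see Limitations.

### Inference

The upward-downward algorithm is implemented in its scaled form: per node,
`τ_i(k) = P(S_i=k | subtree p-values)` with a normalizer `N_i` such that
`Σ_i log N_i` is the log-likelihood; edge quantities `τ_ρ(i),i(k)` and the
downward `κ_i(k)` yield smoothed posteriors `τ_i(k)·κ_i(k)`. The sweeps
are vectorized over depth levels, so a full pass is O(N_T) with numpy-level
constants; on a ~8700-term ontology a fit completes in seconds.

EM: π and ω update in closed form (π ← root posterior,
ω ← P₁₁/(P₁₁+P₁₀) from the pairwise expectations); the two emission blocks
are separable in the complete-data objective and are maximized with
L-BFGS-B inside their boxes (inset 1e-6 from open bounds; shapes capped at
1e6). The alternative block reduces to sufficient statistics
(`Σ w log p`, `Σ w log(1−p)`), so its objective and analytic gradient are
O(1) per evaluation. If an optimizer step would decrease its block
objective, the block keeps its previous values and the fallback is counted
in the fit record.

Because the likelihood is multimodal, `fit_em` runs plain EM from
`n_restarts` random starting points (π, ω ~ U(0.05,0.95), α ~ U(0.1,1),
β ~ U(1.5,20), λ ~ U(0.5,1), α0, β0 ~ U(1.1,5)) plus one
deterministic-annealing run in which the E-step uses emission densities
raised to an inverse temperature stepped through {0.1, 0.3, 0.5, 0.8} (25
iterations per rung) before a final run at temperature 1; the run with the
largest final log-likelihood wins. The ladder and rung length are
config-exposed; this is one standard maximum-entropy DA scheme, chosen for
simplicity. Convergence: relative log-likelihood change < 1e-8 or maximum
absolute parameter change < 1e-6; defaults `n_restarts=20`, `max_iter=500`.
If final log-likelihoods agree across runs while (π, ω) disagree
materially, the fit is flagged `flat_likelihood` (uninformative emissions
make the model unidentifiable in the transition parameters) instead of
being reported as a clean convergence.

### DAG-level posteriors

With `c_i = P(S_i=1 | p, S_ρ(i)=1) = ω·τ_i(1)/(τ_ρ(i),i(1)·P(S_i=1))` and
`c_1 = τ_1(1)`, the probability that any member of a target set is DE
factorizes over the minimal subtree spanning the targets (states are
independent across branches given the parent state). `PDE_j` applies this
to `GT_j`; traversal is restricted to the spanning subtree so the whole
table costs O(Σ_j |GT_j|·depth) rather than O(N_G·N_T). `c_i` values
outside [0,1] by more than 1e-8 raise an error (beyond rounding means a
bug); smaller excursions are clipped.

Rejection takes all nodes with PDE ≥ threshold (0.99 default; 0.95 as a
looser alternative) and reports the FDR estimate `1 − mean(PDE over R)`.
PDE monotonicity along DAG edges makes every rejection set ancestor-closed.
No FWER pre-screen is built in; the rejection report carries a reminder
that FDR control is not guaranteed under gene-set overlap and that an
FWER-controlling first step gives weak FWER control.

## Synthetic data

The generator emulates the model's own assumptions at desk scale: a random
rooted tree (children attach to a uniformly chosen node that still has
capacity, `max_children` 4 by default) with a `multi_parent_fraction`
(default 0.15) of nodes receiving an extra non-redundant, acyclicity-
preserving parent; genes assigned to leaf terms (each leaf at least one)
and propagated upward; states simulated down the tree from (π, ω); p-values
from the emission mixture. Default study conditions used across the tests:
trees of ~2000 nodes, θ* = (π=.95, ω=.6, α=.3, β=10, λ=1, α0=2, β0=2) for
recovery and calibration, and (π=.9, ω=.7) for the ranking comparison —
p-value signal strength (α=.3, β=10) in the range a well-powered gene-set
test produces.

What it does *not* emulate: real expression matrices, gene-gene
correlation, p-value dependence across overlapping sets (p-values are
conditionally independent here by construction), annotation-database
idiosyncrasies, or GO's actual degree distribution. Passing tests
demonstrate correctness of the machinery and behaviour under the model's
assumptions — not robustness to their violation.

Enumeration oracles sum over logically consistent configurations only (the
up-closed 1-sets; a path of n nodes has n+1 of them) and are capped at 20
nodes. They validate likelihood, posteriors, E-step expectations, `c_i`,
and the PDE dynamic program to 1e-9 on hundreds of random instances.

## Numerical choices

- P-values are clipped to [1e-15, 1−1e-15] before density evaluation (beta
  densities diverge at the boundary for shape < 1; external tests can emit
  exact 0 or 1).
- 0/0 in the κ recursion and E-step (possible only for states made
  impossible by the zero transition) is resolved to 0; x/0 with x > 0
  raises a `NumericalError` naming the computation.
- Prior marginals `P(S_i=1) = π·ω^depth` are checked against underflow
  (error below 1e-300) — irrelevant for ontology-scale depths but fatal if
  hit silently.
- Exit codes in the CLI: 0 success, 2 input/structural error, 3 numerical
  error.

## Problem sizes in the shipped checks

Oracle-equivalence checks use 200 random instances of ≤ 12 nodes; EM
behaviour is checked on 20 datasets of ~300 nodes; recovery and calibration
use 10 simulations of 2000 nodes; the ranking comparison uses 20
simulations of 2000 nodes with fitted parameters (restarts set to 2–3 plus
the DA run for these well-behaved simulated likelihoods); one
ontology-scale run uses ~8700 DAG nodes. These sizes were chosen so the
whole suite exercises every scale the method targets while remaining quick
to run on a laptop core.

## Limitations

- **π is estimated from one effective observation.** The M-step update
  π ← E(S₁ | p) is exact, but a single tree contains a single root, so π̂
  is essentially the root's posterior — near 0 or 1 on any one dataset.
  This is intrinsic to single-tree empirical Bayes, not a defect of the
  optimizer; ω̂'s precision likewise scales with the number of DE nodes
  (typically tens to hundreds), so expect sampling error of a few
  hundredths under the default conditions.
- **No dependence modeling across overlapping sets** beyond the empirical
  null; FDR estimates are plug-in quantities without control guarantees.
- **No uncertainty on θ̂**: the method deliberately replaces the fully
  Bayesian treatment with a point estimate for speed; PDEs are plug-in
  posteriors and do not propagate θ̂'s sampling error.
- Only `is_a`-style edges are supported when reading OBO files; other
  relation types, evidence codes, and multi-ontology merging are out of
  scope.
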