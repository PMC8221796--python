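# Methods

This note documents the statistical procedures implemented in `stpcover`,
the defaults and why they were chosen, the numerical conventions, what the
synthetic-data generator does and does not emulate, and known limitations.

## Aberration calling

DNA calls are deterministic: a gene is aberrant in a sample iff it carries a
non-synonymous somatic mutation or an extreme copy-number state (GISTIC-style
code −2 or +2). Heterozygous deletions (−1) and single-copy gains (+1) are
excluded because their functional impact is ambiguous. Mutation input is
either a pre-collapsed binary gene × sample table or a minimal MAF-like
table (`Hugo_Symbol`, `Tumor_Sample_Barcode`, `Variant_Classification`);
the collapser keeps a configurable set of non-synonymous classes
(missense, nonsense, frameshift, in-frame indels, splice site, etc.).

RNA calls use rank divergence from a normal baseline. Within each sample,
genes receive fractional ranks (average ties) normalized by (G − 1) so the
scale is [0, 1]. For each gene, the q and 1 − q quantiles (linear
interpolation) of its rank across baseline samples define its normal
interval; a tumor gene is aberrant iff its rank falls strictly outside this
interval. The interval is closed, so with q = 0 a baseline sample re-called
against its own cohort is never aberrant, which is the natural sanity
anchor for the convention. The single free parameter is the symmetric tail
mass **q, default 0.025** (a 2.5%/97.5% interval); the exact tolerance
scheme of the divergence literature is not prescribed here, so this
symmetric-tail quantile rule is this package's declared convention. Calls
for a tumor sample depend only on that sample's profile and the fitted
baseline — never on other tumor samples — so cohort composition cannot leak
into individual calls.

Degenerate inputs: fewer than two baseline samples, NaN expression, or tumor
genes absent from the baseline model raise errors rather than silently
producing zeros.

## Source–target pair catalog

The catalog is a pure network property. For each candidate source a
breadth-first search bounded at k_max − 1 links finds shortest chains over
both edge kinds; appending a "controls-expression-of" edge closes a pair.
**k_max defaults to 3.** Recorded lengths are minimal by construction and
the witness path is the lexicographically smallest among shortest chains
(BFS expands sorted adjacency in lexicographic path order), which makes
catalog output independent of edge input order. Self-pairs arising from
cycles are kept: the chain definition admits them, and downstream filters
remove vacuous ones. Parallel edges of both kinds between the same genes
act as alternative links.

## Filtering

Pair variables are products of the source DNA call and target RNA call. The
dependence filter builds each pair's 2 × 2 contingency table over tumor
samples and keeps the pair iff Pearson's χ² (1 df, **no continuity
correction**, two-sided) rejects independence at the 5% level. No
multiple-testing correction is applied — the filter is deliberately
permissive at this stage, and correcting would make it *more* conservative
about keeping pairs, not less. Yates correction is available behind a flag
since the plain-vs-corrected choice is a genuine convention fork.
Dependence of either sign passes by default; a positive-association-only
switch exists but is off, because negative dependence is still dependence.
Tables with a zero margin carry no information and are dropped.

The frequency filter removes features aberrant in fewer than **2%** of
samples (weak inequality: a feature exactly at the threshold stays). It is
applied independently at the pair, source and target levels after the χ²
step, in that fixed order.

## Coverings

The minimal r-covering problem is solved as a mixed-integer program with
binary selection variables ψ_j and per-sample coverage indicators Y(ω),
via `scipy.optimize.milp` (HiGHS), which proves optimality. Defaults follow
the covering semantics of the three levels: **r = 1 at pair and source
level, r = 3 at target level** (RNA aberrations are much more frequent than
DNA aberrations, so demanding three target events is the level-appropriate
notion of "covered"), each at the smallest feasible α (α* = 1 − fraction of
samples with ≥ r aberrant features). Requesting α < α* raises an error
naming α*. Weights default to 1; the weighted objective is retained.

Because optima are non-unique, core and union membership are computed by
**exact forcing certificates** rather than by intersecting an enumeration:
j is in the core iff fixing ψ_j = 0 worsens the optimum (or is infeasible),
and in the union iff fixing ψ_j = 1 preserves it. This is 2m MILP solves
but independent of how many optima exist. Enumeration through no-good cuts
(Σ_{j∈J*} ψ_j ≤ |J*| − 1 per found optimum J*) is kept for reporting, with
a default cap of 1000 solutions. The representative covering maximizes the
summed aberration frequency subject to optimality; remaining ties are
broken deterministically by greedily preferring the earliest feature
indices. Integrality is interpreted at tolerance 1e−6; HiGHS is
deterministic for fixed inputs, so all covering output is reproducible.

## Entropy estimation

Configuration entropy is estimated in bits. The plug-in estimator is biased
downward by roughly (2^|J| − 1)/(2N ln 2), which is severe at cohort sizes,
so per-block entropies use the Grassberger-corrected form

    Ĥ_c = log2(e) Σ_z (N_z/N) (ln N − ψ(N_z) − (−1)^{N_z} / (N_z (N_z + 1))),

summing over observed configurations only. Useful checkpoints: a single
configuration observed twice gives log2(e)(ln 2 − ψ(2) − 1/6) ≈ 0.1496
bits (the estimator's floor never reaches exactly zero), and a 500/500
split at N = 1000 gives ≈ 1.0014 bits, converging to 1 bit as N grows.

Joint estimation is limited to blocks of at most **L = 4** variables; the
variable set is partitioned by greedy aggregation: starting from
singletons, repeatedly merge the pair of blocks with the largest entropy
saving Ĥ_c(A) + Ĥ_c(B) − Ĥ_c(A ∪ B) among pairs fitting under the cap,
stopping only when no pair fits. The merge proceeds even when the best
saving is negative — this is the literal reading of the aggregation
procedure; a saving-must-be-positive variant would leave more, smaller
blocks and a looser bound. Ties take the smallest block indices. The block
sum upper-bounds the joint entropy by subadditivity.

Confidence intervals use a parametric bootstrap under the product model
π̂*: blocks independent, within-block distributions empirical. The model
entropy H(π̂*) is the *exact* entropy of that model (sum of plug-in block
entropies — no correction, since π̂* is fully known). **M = 1000**
replicate cohorts of size N are drawn from π̂*; each replicate's corrected
block-entropy sum is computed on the *fixed* partition found on the real
data (re-running the greedy partition per replicate is available behind a
flag; the fixed-partition reading keeps the replicate statistic identical
in form to the observed one). With Ĥ_c^(β), Ĥ_c^(1−β) the empirical β and
1 − β quantiles (inclusive, type-7) of the replicates, the interval at
level 1 − 2β is

    [Ĥ_c + H(π̂*) − Ĥ_c^(1−β),  Ĥ_c + H(π̂*) − Ĥ_c^(β)],

with **β = 0.025** by default (a 95% interval). All randomness flows
through a single seeded generator.

## Coding trees

Trees are unsupervised in the splits and supervised only through sample
weights: each sample is weighted by the inverse of its *global* subtype
size (the node-local alternative would re-weight as the tree grows; the
global reading keeps the weighting fixed and the split criterion
comparable across nodes). Candidate events are single features plus, for
the pair families, all two-feature disjunctions (`pairs_or`) or
conjunctions (`pairs_and`); with more than 80 features the pair events are
restricted to the 80 most frequent features and the cap is logged. The
chosen event minimizes the absolute weight difference between children;
event-true samples go left. Degenerate events (all samples on one side) are
never chosen; a node terminates when all configurations are identical, no
event separates its samples, or depth d (**default 5**) is reached. Ties
are broken by (event arity, lexicographic feature names).

The permutation test keeps the tree fixed and permutes phenotype labels.
The default statistic is the χ²-type distance between phenotype-conditional
bin distributions with pooled-margin expected counts (total-variation
distance is available for two phenotypes); the test statistic is not
prescribed by the tree construction itself, so the χ² distance was chosen
for its sensitivity to multi-bin redistribution. The p-value uses the
add-one estimator (1 + #{perm ≥ obs})/(1 + n_perm), so p = 1/(1 + n_perm)
is the attainable minimum.

## Synthetic data generator

The generator plants source–target pairs with specified marginal DNA rate
p_dna, conditional RNA rate p_rna_given_dna, background RNA rate, and
per-subtype rate multipliers, then emits matched tables whose calls recover
the planted binary states. Expression values live in rank zones: most genes
sit at fixed well-separated levels; planted/decoy targets are drawn across
a densely crowded zone so their baseline rank intervals are wide; aberrant
targets are placed in a "sky" zone above a block of fixed "ceiling" genes,
which guarantees their ranks exceed any baseline interval even when every
target is aberrant simultaneously; non-aberrant tumor targets are drawn
from the central 60% of the crowd zone, safely inside the baseline interval
after the small rank displacement caused by other targets leaving the zone.
Consequently DNA recovery is exact and RNA recovery is essentially exact
(worst-case rank displacement is bounded by the number of targets, which
the crowd margin absorbs).

The default toy study (500 samples, 5 planted pairs, 30 decoys) forces
coverage: sample i's assigned planted pair (i mod 5) is aberrant, and the
first 8 samples of each assignment block are "private" — no other feature
is aberrant there — so every planted pair is necessary in any covering and
the planted set is simultaneously the optimum, the core and the union.
Decoy pairs (p_dna = 0.3, p_rna_given_dna = 0.8) are dependent enough to
survive the χ² filter but each covers ≈ 24% of samples, well short of
competing with planted pairs. Two subtypes with rate multipliers 1.0 and
0.8 are generated by default so per-phenotype machinery always has labels
to work with. Without coverage forcing, planted pair variables are
independent Bernoulli(p_dna · p_rna_given_dna) and the configuration
entropy has the closed form Σ_i h(p_i) (h the binary entropy), which is
what the calibration checks use.

What the generator does **not** emulate: mutational signatures, CNV segment
structure, expression covariance between genes, direction of RNA
divergence, and tissue-realistic network topology. Passing tests therefore
demonstrate that the algorithms recover planted structure under the model's
assumptions (independent samples, rank-separable aberrations), not that
real cohorts satisfy those assumptions.

## Problem sizes

The shipped test and acceptance workloads use cohorts of 200–2000 samples,
catalogs of tens of pairs, covering instances up to 15 features for
oracle comparisons (exhaustive search grows as 2^m), 50 replicate cohorts
for CI calibration, and M = 200–300 bootstrap replicates in the faster
paths (M = 1000 remains the analysis default). These sizes exercise every
code path while keeping the full suite in the low tens of seconds.

## Known limitations

- The χ² filter treats each pair marginally; no joint model of pair
  dependence is attempted before the covering stage.
- Core/union certificates require 2m MILP solves; for very large feature
  sets (thousands) enumeration-free certification dominates runtime.
- The entropy upper bound inherits the greedy partition's arbitrariness;
  two near-tied merge sequences can give slightly different bounds.
- The bootstrap CI quantifies sampling variability under the product
  model, not model misspecification: dependence *between* blocks widens
  the true uncertainty but not the interval.
- Methylation, fusion and proteomic aberrations are out of scope, as is
  any up/down annotation of RNA divergence.
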