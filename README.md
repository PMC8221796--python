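# stpcover

Integrated analysis of paired DNA–RNA aberrations in tumor cohorts:
source–target pairs over a regulatory network, minimal coverings by exact
integer programming, and entropy-based quantification of cross-sample
heterogeneity.

## The problem

Tumor populations are massively heterogeneous: the identity and frequency of
DNA aberrations (mutations, copy-number changes) vary across patients with
the same diagnosis, and this variation propagates to the transcriptome.
Cataloguing aberrations one gene at a time misses both the mechanism (which
DNA change plausibly explains which expression change) and the population
structure (how many distinct ways the disease is realized). `stpcover` is
for computational biologists who have matched mutation, copy-number and
expression data for a tumor cohort plus normal-tissue baselines, and want a
compact, mechanism-aware, quantitative summary of that heterogeneity.

## The model

**Binary aberrations.** A gene g is *DNA-aberrant* in a sample
(X^dna_g = 1) if it carries a non-synonymous mutation, a homozygous deletion
(copy-number code −2) or a two-copy gain (+2); heterozygous losses and
single-copy gains are excluded. A gene is *RNA-aberrant* (X^rna_g = 1) if
its within-sample expression rank falls outside the normal interval of that
rank estimated from baseline samples (the q and 1−q rank quantiles across
baselines, q = 0.025 by default).

**Source–target pairs (STPs).** From a directed interaction network with
"controls-state-change-of" and "controls-expression-of" edges, the pair
(g_s ⇒ g_t) is an STP if a chain of at most k links (default k = 3) leads
from g_s to g_t with the final link controlling expression. The pair
variable is the product Z_λ = X^dna_{g_s} · X^rna_{g_t}. Source-level
events Z^(s)_g = max{Z_λ : s(λ) = g} and target-level events
Z^(t)_g = max{Z_λ : t(λ) = g} collapse pairs to genes. Pairs whose DNA/RNA
events are independent (Pearson χ², 5% level, no multiple-testing
correction) are discarded, as are features aberrant in fewer than 2% of
samples.

**Minimal coverings.** An r-covering at level α is a feature set J such
that at least r features of J are aberrant in a fraction ≥ 1 − α of the
samples. A minimal covering minimizes σ(J) = Σ_{j∈J} w_j (unit weights by
default) and is found exactly as a mixed-integer program (HiGHS backend):

    min Σ_j w_j ψ_j   s.t.   Σ_j ψ_j Z_j(ω) ≥ r Y(ω) ∀ω,   Σ_ω Y(ω) ≥ N(1−α)

Optima are usually non-unique; the package computes the **core** (features in
every optimum) and **union** (features in some optimum) by exact forcing
certificates, enumerates optima with no-good cuts, and reports a
representative optimum maximizing the summed aberration frequency.

**Heterogeneity.** With a covering J, each sample realizes one of 2^|J|
binary configurations; the Shannon entropy of the configuration distribution
measures population heterogeneity. Entropies are estimated per variable
block with the Grassberger bias-corrected estimator

    Ĥ_c = log2(e) Σ_z (N_z/N) [ln N − ψ(N_z) − (−1)^{N_z}/(N_z(N_z+1))]

after greedily partitioning J into blocks of at most L = 4 variables
(subadditivity makes the block sum an upper bound on the joint entropy).
Confidence intervals come from M = 1000 parametric-bootstrap cohorts drawn
from the independent-blocks product model.

**Coding trees.** A depth-d binary tree (d = 5) splits the cohort on single
features or two-feature AND/OR events, choosing at each node the event that
best balances the subtype-weighted sample mass; phenotype-conditional
histograms over the terminal bins are compared with a label-permutation
test.

## Worked example

Generate a synthetic toy study (4 planted source–target pairs that jointly
cover every sample, 10 decoy pairs, 200 tumor samples in two subtypes) and
run the full workflow:

```
$ stpcover simulate --out demo --n-samples 200 --n-planted 4 --n-decoys 10 --seed 11
wrote toy study (200 samples, 4 planted pairs) to demo

$ stpcover run-all --data demo --out demo_out --m-replicates 300
pair: optimum=4 covered=1.000 core=4 union=4
source: optimum=4 covered=1.000 core=4 union=4
target: optimum=14 covered=0.710 core=14 union=14
reports written to demo_out
```

Reading the output: at the pair level the smallest feature set covering
every sample (r = 1, smallest feasible α = 0) has exactly 4 members — the
planted pairs — and the core/union certificates show the optimum is unique.
At the target level, samples are required to carry at least three aberrant
target events (r = 3), so more features (14) are needed and only 71% of
samples can be covered at all. `demo_out/entropy.json` holds the
heterogeneity estimates for the representative pair covering:

```
"All": {"n": 200, "h_sum_bits": 3.89,  "ci": [3.822, 3.957]},
"A":   {"n": 100, "h_sum_bits": 3.384, "ci": [3.215, 3.55]},
"B":   {"n": 100, "h_sum_bits": 3.286, "ci": [3.095, 3.516]}
```

i.e. the pooled cohort's covering configurations carry ≈ 3.9 bits of
entropy; subtype B, generated with a 0.8× aberration-rate multiplier, is
slightly less heterogeneous than subtype A, with overlapping confidence
intervals at this sample size.

The same steps are available individually (`stpcover call`, `catalog`,
`cover`, `entropy`, `tree`) and as library functions; real cohorts are
supplied as gene × sample TSV tables plus an extended-SIF network.

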