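# Methods

`mkasr` reconstructs ancestral states of discrete phenotypic traits on
rooted phylogenies and summarizes those reconstructions over samples of
trees. This note documents the models, the decision rules, the synthetic
data the package is validated on, and the numerical choices.

## The Mk model and its two classes

A k-state trait evolves along each branch as a continuous-time Markov chain
with instantaneous rate matrix Q (off-diagonal q_ij ≥ 0, rows summing to
zero). Branch lengths are in expected substitutions per site, so the rates
are per unit of molecular branch length. Two model classes are exposed:

* **restricted (equal rates, ER)** — a single shared rate, q_ij = q for all
  i ≠ j (1 free parameter);
* **unrestricted (all rates different, ARD)** — all k(k−1) off-diagonal
  rates free.

Transition probabilities are P(t) = exp(Qt). Root state frequencies default
to uniform 1/k — the common default of the likelihood tools this package
mirrors, and the choice that keeps the ER model exactly symmetric under
state relabeling. A stationary-of-Q alternative can be passed explicitly
(`root_freq=`). Likelihoods are computed by Felsenstein's pruning algorithm
with per-node rescaling; tip observations enter as indicator vectors, with
polymorphic cells multi-hot over their member states and missing cells
fully ambiguous.

### Model choice

For each trait, ER and ARD fits are compared by their maximized
log-likelihood difference. The difference is called significant when
**strictly greater than 2** natural-log units. Which class the pipeline
then uses is a policy flag: `always-unrestricted` (the default, convenient
when batching many characters) or `by-test` (keep ER unless the test is
significant).

### Ancestral states by node fixing

The state at a focal node is scored by successively conditioning the
likelihood on each possible state at that node (collapsing the node's
conditional-likelihood vector to one state after its subtree pass) and
comparing the resulting log-likelihoods. A state call is significant when
every competing state is **at least 2** log units worse (inclusive). The
two thresholds deliberately differ in strictness (>2 for model choice,
≥2 for node states), matching the two conventions they come from; both are
configuration-exposed (`--threshold-model`, `--threshold-node`).

By default the rates are re-optimized under each fixing, warm-started at
the unconstrained MLE; `reoptimize=False` freezes them at the MLE instead.
In frozen-rate mode the fixed-state likelihoods obey the exact
decomposition Σ_s L(fixed at s) = L(unconstrained), which is also how
marginal state probabilities are computed (softmax of the fixed-state
log-likelihoods). Impossible fixings return −∞ rather than raising, so a
fixed-state scan can include zero-likelihood states.

## Parsimony

Generalized (Sankoff) parsimony over an arbitrary cost matrix; unit costs
reproduce Fitch parsimony, and a separate Hartigan-style down-pass
(`fitch_length`) serves as an internal cross-check. For every node the
**MPR set** — the states attained in at least one globally optimal
reconstruction — is computed exactly by combining subtree ("inside") and
rest-of-tree ("outside") minimal costs; no ACCTRAN/DELTRAN resolution is
applied. A node is **unequivocal** when its MPR set is a singleton; over a
tree sample only unequivocal reconstructions are counted toward a state.
Parsimony outputs are invariant to branch lengths by construction, and the
tests assert this under multiplicative jitter. Polytomies are handled
natively by the dynamic program.

## Summaries over tree samples

Focal nodes are defined by taxon sets and matched in each tree by **strict
monophyly**: the node exists in a tree only when the MRCA of the defining
taxa contains exactly those taxa. An MRCA always exists, so only strict
matching can register a node as absent — which is what lets the summaries
account for topological uncertainty. All per-state fractions use the
**total number of trees** as denominator, so the bookkeeping identity

    Σ_s support(s) + equivocal + (1 − fraction_present) = 1

holds exactly for every summary; the tests assert it to 1e-9.

Three methods are summarized per node × trait × coding:

* **ML** — node fixing on a single reference tree; reported as per-state
  ΔlnL with the ≥2 significance flag.
* **ML_BMCMC** — per-tree ML over the sample: the model is fitted per tree
  (warm-started from the previous tree's MLE, since successive sample trees
  differ only by small rearrangements), the focal node scanned at the
  fitted rates, and a state counted for that tree when all competitors are
  ≥2 log units worse; otherwise the tree counts as ambiguous. The per-tree
  rule uses the same 2-unit threshold as the single-tree analysis to keep
  the two ML methods commensurable. Mean marginal probabilities over the
  trees containing the node are reported alongside.
* **MP** — unit-cost Sankoff per tree, counting unequivocal nodes only.

A summary's headline state is its best-supported state; for the tree-sample
methods it is flagged significant when it carries a majority (>0.5) of all
trees.

## Character coding

Each trait can be analyzed **multistate** (one k-state character, indices
in declared-alphabet order) or **binary** (k derived presence/absence
characters, "state s present?"). Polymorphic cells become ambiguity sets in
the multistate coding and score present in every member's derived
character. Alphabets are declared, not inferred, so states unobserved in a
subsample keep their index. For the binary coding, each derived character
is analyzed independently; the trait-level headline is the derived
character with the strongest supported "present", and disagreements among
derived characters are kept visible rather than silently resolved. For
2-state traits the two codings are mathematically equivalent up to state
relabeling, and the acceptance tests assert identical headline results.

In the method × coding concordance grid, a node × trait cell is classified
`all-agree` (all available cells name one state, all significant),
`agree-without-support` (one state, support lacking somewhere), or
`conflict` (different states named).

## Synthetic data

The generator provides birth–death trees (dendropy), forward Mk simulation
with recorded node states, and **pseudo-posterior** tree samples: copies of
a source tree with Poisson-distributed random NNI moves and multiplicative
lognormal branch-length noise. This is deliberately not an MCMC — it is a
cheap, seedable stand-in that reproduces the one feature of Bayesian
samples the summaries must handle, namely that a focal clade can be absent
from some trees. It does not emulate posterior correlations among clades,
branch-length/topology covariation, or clade frequencies calibrated to any
posterior, so passing tests say nothing about those aspects of real
samples.

The `scenario_parmelioid` preset emulates a published study design for
parmelioid lichens: tips split into 9 named clades joined by a fixed
backbone (clades 1+2 nested in 1+2+3 nested in the whole group, giving 12
focal nodes), and four traits with alphabets of 5 (growth form), 2
(epicortex), 2 (pseudocyphellae) and 3 (cortical chemistry) states. Each
clade has a designated ancestral state per trait; the character evolves
within each clade from that state under a slow ER model. Defaults and why:

| parameter | default | rationale |
| --- | --- | --- |
| `n_tips` | 120 (`full_size` → 323) | desk-scale version of the 323-OTU study |
| `n_trees` | 1000 (tests use 100) | size of the study's posterior sample |
| clade height / stem length | 0.5 / 1.0 substitutions per site | long stems isolate clades, the regime in which clade ancestors are recoverable |
| `within_clade_rate` | 0.02 | strong clade bias: ≈0.05 expected changes per clade per trait, so clades are enriched for their designated state but not constant |
| `nni_rate` | 1.0 | ≈1 rearrangement per sampled tree: focal clades present in ~95–100% of trees, exercising the node-absence accounting |
| `length_jitter` | 0.1 (lognormal σ) | mild branch-length uncertainty |

The designated states are patterned after the study system (most clades
foliose; epicortex/pseudocyphellae split by clade; chemistry atranorin vs
melanin vs usnic acid) but are not a claim about the original data beyond
alphabet structure.

## Numerical choices

* **Matrix exponential**: spectral decomposition of Q when the eigenvector
  matrix is well conditioned (cond < 1e8), vectorized over all branches;
  otherwise a scipy `expm` fallback per distinct branch length. Rows are
  clipped to [0,1] and renormalized (row-stochastic to 1e-12); zero-length
  branches get the exact identity, with no epsilon padding, so conflicting
  states across a zero-length cherry give likelihood exactly 0 (reported as
  −∞).
* **Rate optimization**: log-scale parameterization bounded in [1e-8, 1e3].
  ER uses a coarse log-grid plus bounded scalar minimization; ARD uses
  L-BFGS-B with 5 restarts by default (near-flat likelihoods at small rates
  make multi-start worthwhile), tolerance 1e-8 on lnL. Per-tree fits inside
  the tree-sample summary and per-fixing refits use 1 warm-started restart
  at tolerance 1e-6/1e-7 — the optimum being nearby — and the per-fixing
  refit never reports a value below the frozen-rate likelihood.
* **Ties**: argmax takes the lowest state index; an exactly symmetric
  instance is therefore reported with the first state as "best" and, by the
  ΔlnL rule, never significant.
* **Structurally impossible data** (all rates give likelihood 0, e.g.
  conflicting states across zero-length branches) make `fit_mk` raise; in
  tree-sample summaries per-tree failures are logged, counted as ambiguous,
  and more than 10% failing is an error.
* No ascertainment ("variable-only") correction is applied; the trait
  matrices this package targets are not collected that way.

## Problem sizes used in the checks

The acceptance checks run the full three-method × two-coding grid at 120
tips and a 100-tree sample (the desk-scale version of the emulated study),
oracle comparisons on 200 random instances of ≤6 tips × k≤3 (where
exhaustive enumeration over internal-node assignments is exact and cheap),
and ER rate recovery at q = 0.5 on 200-tip trees with 100 characters × 20
replicates, asserting the pooled median MLE within 20% of truth.

## Known limitations

* ARD fits at deep nodes are often equivocal even with clean data (rates
  *into* the majority state can be inflated to make any root state nearly
  equally likely); this is a property of the model, not a defect, but it
  means root-state calls under ARD should be read cautiously.
* The per-tree ML decision threshold inside the tree-sample summary is a
  convention (2 log units); other tools may use marginal-probability
  cutoffs instead, and results near the threshold will differ.
* Strict-monophyly node matching is one of at least two defensible ways to
  track a clade across trees; matching by "MRCA regardless of extras" would
  never report absence and is intentionally not offered.
* The pseudo-posterior generator is not a posterior; see above.
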