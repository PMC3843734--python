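# mkasr

Ancestral state reconstruction for discrete phenotypic traits on rooted
phylogenies, with honest accounting of topological uncertainty.

`mkasr` is written for comparative biologists who have (i) a reference tree,
(ii) a sample of trees from a Bayesian analysis over the same taxa, and
(iii) a matrix of discrete traits (growth form, presence/absence of a
structure, chemistry, ...), and who want to know which state the ancestor
of a named clade most likely had — and whether that call survives changes
of reconstruction method and of character coding.

## What it computes

**Mk-model maximum likelihood.** A k-state trait evolves as a continuous-
time Markov chain with rate matrix Q; the package fits either the
*restricted* (equal-rates, 1 parameter) or *unrestricted* (all-rates-
different, k(k−1) parameters) model by maximizing the pruning-algorithm
likelihood. The two classes are compared by ΔlnL = lnL(ARD) − lnL(ER),
significant when strictly > 2 natural-log units.

**Node fixing.** The state at a focal node is scored by conditioning the
likelihood on each state s in turn and re-maximizing:
ΔlnL(s) = lnL(best) − lnL(s). A call is significant when every competing
state is ≥ 2 log units worse. Marginal probabilities
P(s) = L(s)/Σ L(s′) at frozen rates are available alongside.

**Reconstruction over a tree sample.** Focal nodes are defined by taxon
sets and matched per tree by strict monophyly, so a node can be *absent*
from some trees. Per node the package reports the fraction of trees
supporting each state (per-tree ML at the 2-log-unit rule, or unequivocal
parsimony — singleton MPR set — under unit-cost Sankoff), the equivocal
fraction, and the missing mass from trees lacking the node:
support + equivocal + (1 − fraction_present) = 1, always.

**Coding comparison.** Every trait can be run *multistate* (one k-state
character) and *binary* (k derived presence/absence characters), and the
3-method × 2-coding grid is classified per node as all-agree /
agree-without-support / conflict.

A synthetic-data module generates birth–death trees, pseudo-posterior tree
samples (random NNI moves + branch-length jitter), Mk-evolved characters
with recorded ancestral truth, and a preset emulating a parmelioid-lichen
study design (9 clades, 12 focal nodes, 4 traits with 5/2/2/3-state
alphabets). See `docs/methods.md` for models, defaults, and limitations.

## Worked example

```python
import mkasr

tree = mkasr.parse_newick(
    "(((t1:0.2,t2:0.2):0.8,(t3:0.3,t4:0.3):0.7):0.5,(t5:0.6,t6:0.6):0.9);")
ch = mkasr.CodedCharacter(
    "pseudocyphellae", ("present", "absent"),
    {"t1": frozenset([0]), "t2": frozenset([0]), "t3": frozenset([0]),
     "t4": frozenset([1]), "t5": frozenset([1]), "t6": frozenset([1])})

fit_u = mkasr.fit_mk(tree, ch, mkasr.ModelClass.UNRESTRICTED, seed=0)
fit_r = mkasr.fit_mk(tree, ch, mkasr.ModelClass.RESTRICTED, seed=0)
choice = mkasr.compare_models(fit_u, fit_r)

node = mkasr.NodeDefinition("left", {"t1", "t2", "t3", "t4"})
rec = mkasr.ml_node_reconstruction(
    tree, ch, mkasr.ModelClass.UNRESTRICTED, node, seed=0)
res = mkasr.sankoff_reconstruct(tree, ch)
```

prints (via the obvious f-strings):

```
lnL unrestricted = -4.030, restricted = -4.049, delta = 0.019, significant = False
  state present: delta lnL = 0.000
  state absent: delta lnL = 0.092
best = present, significant = False
parsimony length = 2, MPR at node = ['absent', 'present'], unequivocal = False
```

Read: the unrestricted model buys only 0.019 log units over equal rates
(far below the >2 bar); at the focal node "present" is the best state but
"absent" is only 0.092 log units worse (far below the ≥2 bar), and
parsimony likewise leaves the node equivocal (MPR set {present, absent}).
Six tips genuinely cannot settle this ancestor — which is exactly what the
output says.

## Command-line pipeline

```
mkasr simulate --n-tips 120 --n-trees 1000 --seed 7 --out demo
mkasr reconstruct --trees demo/tree.nwk --tree-sample demo/tree_sample.nwk \
    --matrix demo/matrix.csv --nodes demo/nodes.yaml \
    --alphabets demo/alphabets.yaml --seed 1 --out demo/recon
mkasr compare --grid demo/recon/grid.tsv --out demo/cmp
```

`reconstruct` writes a long-format `reconstructions.tsv` (one row per
node × trait × coding × method), a `model_choice.tsv`, and a per-node
`grid.tsv`; `compare` summarizes agreement, e.g.

```
{
  "agreement_counts": {"all-agree": 9, "agree-without-support": 3},
  "concordance_rate": 1.0,
  "n_cells": 12
}
```

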