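# epihost

Analysis toolkit for **host-tree preference of atmospheric bromeliads**
(*Tillandsia* spp.) — epiphytes that absorb water and nutrients from
aerosols through leaf scales and can in principle colonise any substrate,
yet pile up on some trees and avoid others. The package asks, for a survey
of trees in replicated vegetation patches: is this distribution
stochastic, or do functional traits of the host (deciduousness, bark
type, peeling, light guild, thorns, needles, size, canopy openness) drive
how many bromeliads a tree carries and *where in its crown* they sit?

It is aimed at canopy/epiphyte ecologists who have a tree-level survey
(per-tree bromeliad counts split into trunk vs branch attachment, species
traits, and a host phylogeny) and want the complete inferential chain as
reproducible, seeded, machine-readable pipeline stages.

## What it computes

**Per-tree statistics.** `AB_abund` is the total bromeliad count on a
tree; the within-crown distribution is

```
AB_dst = A_trunk / A_total          (1 = all on the trunk, 0 = all on branches)
```

**Diversity metrics.** Faith's PD (branch length spanning a species set,
include-root convention), functional diversity FD as spanning branch
length on a Gower/UPGMA trait dendrogram, and the phylogenetic-species
family PSV / PSR / PSE / PSC computed from the phylogenetic correlation
matrix, matching the standard picante definitions.

**Null models.** Three seeded randomisation procedures with empirical 95%
envelopes: (i) every bromeliad individual of a patch re-assigned uniformly
to the patch's trees (host richness / PD / FD null, default 10,000
replicates); (ii) phylogeny tip shuffling against the correlation between
Schoener's co-occurrence index `S_ij = 1 − ½ Σ_k |p_ik − p_jk|` and
phylogenetic distance (default 1,000 runs); (iii) within-species abundance
shuffling that preserves each species' total and occurrence frequency,
against PSV / PSR / PSE / PSC.

**Hierarchical partitioning, from scratch.** For k predictors all 2^k
GLMs are fitted (R² for gaussian, deviance explained for Poisson and
binomial responses) and each predictor's *independent contribution* I_x is
the average fit increase over all k! entry orderings, computed by level
averaging. Significance comes from a randomisation test (response
permutation, z = (I − mean I₀)/sd I₀, one-tailed z ≥ 1.65, plus exact
permutation p-values). The batched IRLS backend keeps the ~10⁵ fits of a
1,000-permutation test in seconds.

**Recursive trait trees.** The partitioning test is applied recursively:
each node splits on its most significant remaining trait (categorical →
one child per level; quantitative → two-way split at the node median),
the used trait is removed from all descendants, and growth stops when no
candidate survives a per-node Bonferroni-controlled permutation test.
Leaf means then classify trees into **host patterns**: Best (> 400
individuals), Worst (< 10), Trunk (> 90% trunk share), Branches (> 90%
branch share).

**Association statistics.** Poisson / binomial GLM patch comparisons with
Holm-adjusted pairwise contrasts and compact letter displays, OLS of the
responses on plot diversity, centered PCA of the pattern-assignment
matrix, GLMs on PC1 scores, pairwise likelihood-ratio tests between
patterns, and Euler-style species overlap counts.

**Synthetic surveys.** Five named scenarios (`null`,
`deciduousness_only`, `two_stage`, `tp_like`, `mixed_forest`) generate
datasets with the study's structure — 5 patches × 5 plots, trait-rule
Poisson abundances, bark-driven trunk/branch allocation, and a heavily
skewed epiphyte mix with one hyper-dominant species — so every stage is
testable without field data.

## Worked example

```python
from epihost import (named_scenarios, simulate_dataset, grow_tree,
                     assign_patterns, PatternThresholds)
from epihost.association import pattern_pca

ds = simulate_dataset(named_scenarios()["tp_like"], seed=11)
print("trees:", len(ds.trees), "| bromeliad individuals:", int(ds.trees.a_total.sum()))

abund = grow_tree(ds, "abund", n_rand=499, seed=21)   # Poisson, all trees
dist  = grow_tree(ds, "dist",  n_rand=499, seed=22)   # binomial, hosts only
print(dist.render())

asg = assign_patterns(abund, dist, PatternThresholds())
print(asg.sum().to_dict())
pca = pattern_pca(asg, "all")
print("PC1 variance: %.1f%%" % pca.pct_variance)
print(pca.loadings.round(3).to_dict())
```

prints

```
trees: 200 | bromeliad individuals: 25761
split on bark (z=34.74, 54.1%)
  bark = smooth:
    leaf n=54 mean=0.967
  bark = reticulated:
    leaf n=44 mean=0.0397
  bark = flaky:
    leaf n=40 mean=0.906
  bark = grooved:
    leaf n=47 mean=0.504
{'best': 13, 'worst': 90, 'trunk': 94, 'branches': 44}
PC1 variance: 56.1%
{'best': -0.178, 'worst': 0.575, 'trunk': 0.592, 'branches': -0.536}
```

Read: bark type alone explains 54% of the partitioned deviance in where
bromeliads sit — smooth-barked trees hold them on the trunk (mean trunk
share 0.97), reticulated-barked trees on the branches (0.04). Of 200
trees, 13 qualify as Best hosts and 90 as Worst; the first principal
component of the four pattern assignments separates Worst + Trunk
(positive loadings) from Best + Branches (negative), i.e. good hosts are
branch hosts in this landscape.

The same analyses run from the shell:

```bash
epihost simulate --scenario tp_like --seed 11 --out survey/
epihost traittree --trees survey/trees.csv --traits survey/traits.csv \
    --phylo survey/phylogeny.nwk --response dist --rand 499 --seed 22 --out dist_tree.json
epihost all --run-config run.yaml      # every stage + checksummed manifest
```

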