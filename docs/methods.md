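# Methods

This note records the statistical model behind each pipeline stage, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical conventions that pin down exact
reproducibility.

## Data model

The observation unit is a surveyed tree: patch and plot membership,
species, DBH (cm) and height (m), plot-level leaf area index (LAI,
dimensionless), six species-level functional traits (deciduousness,
bark type, peeling, light guild, thorns, needles) and per-bromeliad-species
counts split into trunk vs branch attachment. A tree is a *host* iff it
carries at least one individual. `AB_abund` is the total count;
`AB_dst = A_trunk/A_total` is defined for hosts only (an error otherwise —
non-hosts are excluded upstream, never imputed).

Trait kinds (categorical / binary / quantitative) are declared, never
inferred from dtypes when reading files: silently treating bark type as a
number would corrupt both the Gower dissimilarity and the trait-tree
splits. Categorical level order is first-appearance order, making dummy
coding and child enumeration deterministic. Missing trait values are an
error, not imputed.

## Diversity metrics

**Faith's PD** of a species set is the summed branch length of the
minimal rooted subtree spanning the set *plus the root*. The include-root
convention matches the common toolchain default and keeps singleton sets
well defined. Internally each species' root path is precomputed as an
edge-incidence matrix, so PD of one set is a masked sum and PD of
thousands of null replicates is two matrix products.

**Functional diversity** is the same spanning-length functional applied
to a trait dendrogram: Gower dissimilarity (equal weights; quantitative
traits range-normalised over the species pool; categorical and binary
traits simple matching; a zero-range quantitative trait contributes 0)
followed by UPGMA. Tie-breaking in UPGMA merges the pair whose smallest
member labels sort first — ties are real for coarse binary traits, and an
unpinned rule would make FD run-dependent.

**PSV / PSR / PSE / PSC** follow the standard definitions on the
phylogenetic correlation matrix C: PSV = 1 − mean off-diagonal
correlation among species present; PSR = richness × PSV;
PSE = (N·Σaᵢ − aᵀCa)/(N² − N·mean(a)) for abundances a (equal to PSV at
even abundance); PSC = 1 − mean nearest-neighbour correlation. C is the
shared root-to-MRCA depth divided by total depth after ultrametricising
the tree by extending terminal branches to the maximum tip depth — host
phylogenies assembled from megatrees are not guaranteed ultrametric, and
the correlation interpretation needs a unit diagonal. Phylogenetic
distances D keep the original (unextended) path lengths. The
implementation reproduces the reference R implementation (picante) to
10 significant figures on a hand-checked fixture.

**Schoener's index** S_ij = 1 − ½ Σ_k |p_ik − p_jk| uses each species'
own relative distribution over samples, hence is invariant to scaling any
species' abundances.

## Null models

All three procedures return the observed statistic, the vector of null
draws, the empirical 2.5%/97.5% quantiles (type-7, numpy's linear
interpolation — pinned so envelope fixtures are exact), and a verdict
below/within/above.

1. *Individual randomisation* (default 10,000 replicates): every
   bromeliad individual of a patch is re-assigned independently and
   uniformly to one of the patch's individual trees — not to species, and
   not weighted by tree size; uniform-per-tree is the minimal reading of
   "randomise individuals over hosts", and a size-weighted variant would
   presuppose part of what is being tested. The patch total is conserved
   by construction. Host richness, PD and FD of species receiving ≥ 1
   individual are recomputed per replicate.
2. *Tip shuffling* (default 1,000 runs): leaf labels are permuted; the
   Schoener matrix never changes, so each run only re-indexes the
   distance matrix before recomputing the co-occurrence/distance Pearson
   correlation (two-sided verdict).
3. *Frequency-preserving abundance shuffle*: abundances are permuted
   within species columns across samples, preserving each species' total
   and number of occupied samples exactly; PSV/PSR/PSE/PSC are
   recomputed on the focal row. Verdicts are read as Underdispersed /
   Random / Overdispersed. Rows are vegetation patches by default
   because the dispersion question is posed per patch; with a single row
   the shuffle is the identity and the envelope is degenerate at the
   observed value (reported as "within", not an error).

Calibration was checked by generating data *from* the uniform-placement
mechanism: the observed richness falls inside the 95% envelope in ≈95–97%
of repetitions (slightly conservative because richness is discrete), and
fully clustered placements (all individuals on one of ≥ 20 species) fall
below the envelope in 100% of repetitions.

## Hierarchical partitioning

Goodness of fit is R² (gaussian) or deviance explained
1 − D(model)/D(null) (Poisson counts, binomial (trunk, branch) pairs);
the empty model scores 0. For k predictors all 2^k subsets are fitted —
a categorical trait enters and leaves as its whole dummy block, because a
trait is one explanatory unit. The independent contribution averages the
entry increment over all orderings via the level weights
s!(k−1−s)!/k!, so Σ I_x equals the full-model fit to machine precision;
joint contributions are J_x = R({x}) − I_x. k is capped at 12 (4,096
fits).

The randomisation test permutes the response (for binomial, the
(successes, trials) pair rows jointly — response permutation, not
residual permutation, matching a "randomise all data" scheme),
recomputes the full partition per permutation and scores
z = (I − mean I₀)/sd I₀ with the conventional one-tailed criterion
z ≥ 1.65, reported alongside exact permutation p-values
(1 + #{I₀ ≥ I})/(n_rand + 1). A predictor whose null contributions have
zero spread (a constant column) gets z = NaN and is never significant.
Measured type-I rate of the z criterion at n = 100, k = 5, 199
permutations: 4.5–7.5% per predictor.

All fits run through a batched IRLS (one Newton solve per iteration for
all permutation columns simultaneously, ridge of 1e−10·tr/p against exact
collinearity, η clipped at ±30 so separated binomial fits saturate at
deviance ≈ 0 / fit = 1). This is what makes 2^k × 1,000 fits affordable;
statsmodels reproduces the single-fit deviances to 1e−7 in the tests.
Design columns are always stacked in sorted predictor order — iteration
order of subset sets would otherwise leak hash randomisation into the
last float bit and break bit-reproducibility.

**Reported percentages.** `pct_x = 100·I_x/Σ I_x` (share of the summed
independent contributions) is the headline number, with I_x itself also
reported, since a per-variable share can be read either against Σ I or
against total deviance.

## Recursive trait tree

At each node the remaining candidates (those actually varying within the
node) are tested by the randomisation partition; the node splits on the
most significant one — smallest exact permutation p, ties broken by
larger z. Categorical splits make one child per observed level;
quantitative splits cut at the node members' median with ties going to
the ≤ side (a printed threshold needs a pinned side to be reproducible).
Node medians, not dataset medians, implement "split the group at its
median". The used variable is removed from every descendant's candidate
set. Nodes stop when smaller than `min_node` (default 10 — GLM fits need
residual degrees of freedom; the expected shallow trees mean stopping is
normally by significance, with `min_node` as a backstop), when the
response is constant, or when no candidate passes.

**Family-wise control.** A split requires permutation p ≤ α/m with m the
number of candidates at the node (α = 0.05 default). Testing each of m
candidates at a raw 5% would give a ≈1 − 0.95^m false-split rate per node
and recursive trees that essentially always overfit; Bonferroni on exact
permutation p-values keeps the per-node rate at ≤ α regardless of the
skewness of the null I distribution (a normal z cutoff demonstrably
under-controls here). Consequence: n_rand must satisfy
1/(n_rand+1) ≤ α/m, so the default n_rand = 1000 supports up to 50
candidates.

Leaf means (arithmetic for counts, pooled trunk share Σtrunk/Σtotal for
the binomial response) drive the host patterns with default thresholds
Best > 400 individuals, Worst < 10, Trunk > 0.9 trunk share,
Branches < 0.1. Best/Worst and Trunk/Branches are mutually exclusive by
construction; intermediate leaves carry no label. Non-host trees get
trunk/branches = False rather than NaN so the all-trees pattern matrix
stays complete for the PCA.

Structure recovery was verified generatively: the two-stage scenario
(deciduousness gate, then a DBH rule inside the deciduous arm, Poisson
means 400 vs 3, ≈200 trees per arm) is recovered exactly in ≥ 90% of
seeds, and the no-effect scenario returns a single leaf in ≥ 90% of
seeds — the two sides of the same α.

## Association statistics

Patch comparisons use Poisson (abundance, all trees) or binomial on
(trunk, branch) counts (distribution, hosts only; hosts are weighted by
their abundance, treating the trunk share as proportion data) GLMs with
a likelihood-ratio χ² against the intercept model. Pairwise contrasts
are per-pair likelihood-ratio tests with **Holm** adjustment and an
insert-and-absorb compact letter display. Holm was chosen over
single-step Tukey HSD on GLMs deliberately: multivariate-t machinery on
non-gaussian GLMs is toolchain-specific, while Holm is exact-level,
assumption-free and reproducible. Poisson is used plain (no
overdispersion correction) to keep χ² values on the conventional scale; a
practitioner worried about overdispersion can fit the same design with a
negative-binomial family in statsmodels directly.

Diversity regressions are per-predictor OLS (slope, F, p) of plot-level
`ab_abund`/`ab_dst` on plot richness, PD and FD.

The pattern PCA is a centered covariance PCA of the 0/1 assignment matrix
— columns are *not* scaled to unit variance, so loadings live on the
original assignment scale; the PC1 sign is fixed so the Best loading is
negative, making scores increase toward Worst/Trunk assignment. GLMs of
the survey responses on PC1 scores report LR χ², slope and deviance R².
Pairwise pattern association uses the 2×2 likelihood-ratio χ²
2 Σ O ln(O/E) (identical to the binomial GLM LR test), with direction
from the (continuity-corrected) log odds ratio, and degenerate margins
reported untestable rather than raised.

## Synthetic surveys

The generator emulates the study design: five patches × five 10 m × 10 m
plots, trees drawn from per-patch species pools with trait syndromes,
plot-level LAI, per-tree totals Poisson with the mean given by the first
matching trait rule, counts split over four bromeliad species by a
heavily skewed mix (0.94/0.03/0.02/0.01 — the single-dominant structure
the metrics must face), and each individual attaching to the trunk with
a bark-driven probability. Abundance and allocation are conditionally
independent given traits, mirroring the separate abundance/distribution
analyses. Phylogenies are pure-birth (coalescent-style construction,
ultrametric) or star trees.

Scenario defaults: `two_stage` holds height and LAI fixed so that
deciduousness and DBH are the only varying candidates — it is a
controlled experiment for topology recovery, not a realistic landscape;
`tp_like` gives each silviculture patch one functional syndrome
(hyperabundant deciduous small-DBH reticulated-bark patch at mean 400,
needle conifers at 30, others at 2–3) and reproduces the qualitative
field pattern (most individuals on branches, smooth bark ⇒ trunk hosts);
`mixed_forest` spreads all syndromes over all patches with mild effects.

What the generator does **not** emulate: spatial autocorrelation within
and between plots, dispersal limitation, neighbour shading interactions,
temporal dynamics, and observation error in counts. Passing tests
therefore certify the inferential machinery under the assumed sampling
model, not the field behaviour of bromeliads.

## Numerical conventions and reproducibility

- Envelope quantiles: type-7. Median splits: ties left. UPGMA ties:
  lexicographic. Dummy reference level: first appearance.
- One global seed per pipeline run, expanded through
  `numpy.random.SeedSequence.spawn` into independent per-stage streams,
  so disabling one stage never shifts another's draws; every stochastic
  output records its seed in a header line and the run manifest carries
  SHA-256 checksums. Reruns are bit-identical.
- Problem sizes used by the shipped checks: oracle enumeration at
  k ≤ 4, n = 50; calibration at n = 100, k = 5, 199 permutations, 200
  repetitions; tree recovery over 20 seeds at ≈400 trees; envelope
  coverage over 200 repetitions of 1,000-replicate envelopes. These sizes
  give binomial standard errors comfortably inside the asserted bands.

## Known limitations

- Hierarchical partitioning is exponential in predictors (capped at 12).
- The binomial trait tree weights hosts by abundance; a hyper-abundant
  host can dominate its leaf mean.
- No analytic p-values for independent contributions; inference is
  purely permutation-based.
- The published abundance table shipped as a fixture contains one
  internal inconsistency for the TP patch (printed dominant-species
  share 82.1% vs 95.5% recomputed from its cells); the package uses the
  cells and leaves the discrepancy flagged rather than "fixing" either
  number.
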