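# Methods

This note documents the models behind each stage, the defaults and why,
the numerical conventions, and what the synthetic benchmark does and does
not establish.

## Wagner parsimony on copy numbers

Gene-family copy numbers are treated as integer character states on a
rooted species tree. A branch on which the state changes from parent `a`
to child `b` costs `gain_cost·max(0, b−a) + loss_cost·max(0, a−b)`; the
reconstruction minimizes the total cost (Sankoff dynamic programming with
linear, possibly asymmetric, per-copy costs). The defaults are symmetric
(1/1); an asymmetric gain penalty is exposed as `gain_cost` for users who
want gains to be "harder" than losses, since the neutral symmetric setting
is otherwise the least-assuming choice.

Implementation notes:

- Under linear costs an optimal ancestral state never exceeds the family's
  maximum observed tip count, so the state space is capped there (tests
  compare against a cap raised by two).
- The min-plus product per branch uses the linear-cost decomposition into
  a prefix minimum and a suffix minimum, making the step O(S) per family
  instead of O(S²); this matters when simulated copy numbers reach the
  hundreds.
- Ties are broken by the smallest state at every choice point, applied
  root-down, so reconstructions are bit-reproducible.
- `brute_force_cost` enumerates all ancestral assignments (≤ 7 internal
  nodes) and is the oracle the DP is tested against on hundreds of random
  instances with mixed cost ratios.

Branch events count families whose inferred state strictly increases
(gain) or decreases (loss) along each branch; `net = gains − losses` is
the statistic used to scale branch widths in ancestral-genome figures.

## Lifestyle inference

A random forest (100 trees; the forest library's historical default of 10
is less stable) maps raw copy-number profiles to lifestyle labels. Counts
are left unscaled because tree ensembles are scale-invariant; the SVM
stage below standardizes instead, and the two stages deliberately mirror
that difference in treatment. Accuracy is estimated by leave-one-out
cross-validation with a full refit per fold; the literature this package
follows reports that quantity as "R²", here it is named `cv_accuracy`.
Lifestyles with a single genome make their fold trivially unpredictable —
the fold is kept and a warning is emitted. Ancestral profiles from the
Wagner stage are passed to the fitted forest as-is (integer states, no
rounding needed); reported probabilities are ensemble vote fractions.

## Phylogeny-corrected repertoire comparison

Phylogenetic position is summarized by the first four principal
components of the patristic distance matrix (each genome's feature vector
is its row of path-length distances; column-centered PCA). These enter
every comparison **before** the lifestyle term, so "lifestyle" always
means "lifestyle after phylogeny".

*Distances.* Copy-number profiles are compared by the quantitative
Jaccard distance `J = 2B/(1+B)` derived from Bray–Curtis
`B = Σ|x−y|/Σ(x+y)`; pairs of all-zero profiles get `J = 0`.

*PERMANOVA.* The Gower-centered inner-product matrix
`G = −½·J·D²·J` is partitioned by sequential (type-I) sums of squares
over the nested model sequence — each PC, then lifestyle, then
PC:lifestyle interactions — using hat-matrix traces; pseudo-F per term is
tested against the residual. Significance comes from jointly permuting
rows and columns of `D`, with the observed statistic counted in numerator
and denominator: `p = (1 + #{F* ≥ F}) / (1 + n_perm)`, 999 permutations by
default, seeded. An exhaustive mode enumerates all `n!` permutations for
`n ≤ 8` and is verified in tests against an independent enumeration over
distinct group assignments. Aliased model columns are dropped with a
warning; in pairwise runs on small groups the covariates can saturate the
subset, in which case the pair is reported as skipped rather than tested.

*dbRDA.* The condition matrix is regressed out of `G` on both sides
(projection complement); the constraint matrix (also residualized on the
condition) then defines the subspace whose projection of the residual `G`
is eigen-decomposed. Negative eigenvalues of the non-Euclidean geometry
are dropped and reported; no additive-constant correction is applied.
Group geometry uses 1-sd data ellipses of the first two axis scores with
area `π·√(λ₁λ₂)`; single-member groups get area 0.

*Lifestyle network.* Lifestyles are connected when their pairwise
(BH-adjusted by default; a flag switches to raw) p is **not** below α —
edges mean "not distinguishable". Node size is the ellipse area; edge
weight is the inverse centroid distance, capped at 10⁶ for coincident
centroids.

*Category ANOVAs.* Per-genome category counts (CAZymes, proteases,
lipases, SSPs, PCWDEs, FCWDEs) are modeled by sequential OLS with the
same formula; interactions are dropped with a warning when genomes are
fewer than parameters. The Tukey HSD post hoc compares covariate-adjusted
lifestyle means (response minus the fitted covariate part) using the full
model's residual mean square and the studentized range; the compact
letter display uses insert-and-absorb.

*Discriminant loadings.* "Which families drive the separation" is
answered by a label-constrained redundancy analysis on per-family
standardized counts; the top |loading| families on each of the first
(groups − 1, at most `n_axes`) constrained axes are reported with sign.

## Discriminative-family discovery

1. **Pre-filter**: per-family one-way ANOVA F between the two groups,
   BH-adjusted, keep `q < 0.05`. Zero-variance families are skipped; a
   NaN F (degenerate within-group variance) is treated as "no evidence"
   (p = 1).
2. **SVM-RFE**: linear-kernel SVM (C = 1, exposed) on per-family
   standardized counts; each round drops the `step = 10` features with the
   smallest |weight| until `min_features = 10` remain, recording
   leave-one-out accuracy at every intermediate set. The **smallest** set
   achieving the maximal recorded accuracy is returned — "minimal set"
   semantics. Standardization statistics are computed on the full matrix
   before cross-validation, matching the reference behavior of the
   tooling this stage models; a `per_fold_scaling` flag provides the
   leakage-free variant. Elimination is not re-run inside each fold, so
   the accuracy of the *final selected* set is optimistically biased under
   the null — the null tests therefore check the pre-elimination accuracy
   and the instability of the selected sets.
3. **Fisher enrichment**: one-sided exact test of the selected set against
   a caller-chosen family universe for an annotation category; the odds
   ratio is the conditional MLE, `inf`/0 for degenerate but margined
   tables, undefined for empty margins.
4. **Phylogenetic screen**: per family, logistic regression of group
   membership on the standardized count plus the four phylogenetic PCs;
   the Wald p of the count coefficient asks whether the family separates
   the groups beyond phylogenetic position. This eigenvector adjustment
   is an *approximation* of a penalized-likelihood phylogenetic GLM and
   is labeled as such; complete separation falls back to a small ridge
   (10⁻³) with a per-family note. A Wald test has little power against a
   perfectly separating family (Hauck–Donner); the screen is meant for
   graded effects.

## Ecology

Samples with ≤ 1000 total reads are removed (strict inequality). A taxon
is "present" in a sample when its relative abundance strictly exceeds
0.01%; coverage is the fraction of retained compartment samples present,
and two mean-RA summaries are kept deliberately: over positive samples
only (the per-taxon abundance statistic) and over all retained samples
(the enrichment input). Root-vs-soil enrichment uses the two-sided
Mann–Whitney U — exact null when both groups have ≤ 8 observations and no
ties, normal approximation with tie correction otherwise — BH-adjusted
across taxa. log2FC compares compartment means over all retained samples
with a pseudocount of half the smallest nonzero compartment-mean RA
(scale-free, keeps ratios finite and rank-preserving; whether the
original analyses used a pseudocount is unknowable from the outside, so
it is configurable). A taxon is flagged enriched when `q < 0.05` **and**
log2FC > 0: compositional renormalization makes taxa significantly
*depleted* wherever others are planted enriched, and an undirected flag
would call those enriched too.

## Host phenotype

`PPI = mean SFW of grown plants × (plants grown / seeds sown)` per plate;
plates where nothing grew get PPI 0 with the mean flagged undefined.
Effects versus mock are Hedges' *g* (pooled SD, small-sample correction
`J = 1 − 3/(4·df−1)`). Classification runs a global Kruskal–Wallis, then
Dunn z tests of each strain against mock on tie-corrected pooled ranks,
Holm-adjusted over the strain-vs-mock family (BH available); detrimental
= adjusted p < α and median below mock, beneficial = above, otherwise
neutral. The colonization index is `2^(−Cq(ITS1)/Cq(UBQ10))` — the
exponent is the full Cq ratio; the alternative reading `2^(−Cq)/Cq` is
rejected as a mis-parse of the displayed formula. Spearman correlations
use average ranks; for n ≤ 9 the two-sided p is computed by exhaustive
enumeration of rank permutations (vectorized over the cross-product),
otherwise by the t approximation.

## Transcriptome aggregation

Per-gene DE results (log2FC, BH-adjusted p) are summed per orthogroup
over genes with `padj < 0.05` — **both signs** are summed, because the
upstream convention sums "significant log2FC values", not "positive
ones"; an orthogroup is over-expressed when the sum is positive. A
`positive_only` flag provides the alternative reading, since membership
of the shared core changes with it. The cross-strain core is the
intersection of per-strain over-expressed sets, reported together with
exact combination counts (a Venn partition of the union). Bray–Curtis
PCoA of expression profiles reuses the same Gower-centering code as the
dbRDA stage — one implementation, asserted by test.

## The synthetic benchmark

The generator emulates the structure of a 120-genome comparative study at
desk scale (60 genomes × 2000 families by default; < 1 s to generate):

- **Tree**: pure-birth with unit rate, `n_tips = 60`, branch lengths
  rescaled to mean 1 (exactly-zero sampled edges floored at 10⁻⁶ first).
- **Lifestyles**: Markov switching along branches, switch probability
  `1 − exp(−s·t)` with `s = 0.3` — two to three transitions per
  root-to-tip path, enough conservation for ancestral inference to be
  meaningful, enough scatter that lifestyle is not a clade label.
- **Copy numbers**: per branch, a discretized birth-death chain (steps
  ≤ 0.05): gains Poisson with rate `λ·(1+n)` (innovation plus per-copy
  duplication), losses binomial with per-copy rate `μ`. Defaults
  `λ = 1.2`, `μ = 4.8` per unit branch give a subcritical stationary mean
  of λ/(μ−λ) ≈ 0.33 copies and fast relaxation, so extant repertoires
  track the *current* lifestyle rather than deep history — the regime in
  which repertoire-based lifestyle classification is biologically
  plausible, and convergent evolution of the same lifestyle in distant
  clades leaves the same signature.
- **Planted discriminative families**: `k = 10` families whose gain rate
  is multiplied by `e = 4` on branches whose child is in the target group
  (mycobiota members + endophytes). The multiplier acts on the rate, not
  the tip counts, so the planted signal carries realistic phylogenetic
  autocorrelation and the correction stages have real work to do.
- **Lifestyle signatures**: every *non-target* lifestyle additionally
  gets 10 signature families (same ×4 gain multiplier in that lifestyle);
  the target group's signature is the planted set itself. Without
  signatures the five non-target lifestyles would be genomically
  identical and no classifier could tell them apart even in principle.
- **Annotations**: planted families are flagged CAZyme/secreted with
  enriched probability (0.6/0.8 vs 0.1/0.3 background); one planted
  family is designated the "aggressiveness family" (a secreted
  pectate-lyase PL1_7 analogue).
- **Survey**: Dirichlet-multinomial; root samples have the Dirichlet
  concentration of 10 designated taxa multiplied by `f = 8`; depths are
  lognormal around 8000 with σ = 1, so a tail of samples falls under the
  1000-read filter by design.
- **Phenotypes**: strain effect `δ = −c·z + noise` with `c = 0.3`, where
  `z` is the aggressiveness-family count, median-centered and sd-scaled
  across strains. Median centering keeps the typical strain neutral (the
  count distribution is right-skewed), which is what recolonization
  panels look like and what gives the Dunn-vs-mock test its power. Plate
  SFW is normal around `50·(1+δ)` mg (σ = 10, truncated positive),
  germination binomial with probability `0.9 + 0.3·δ` clipped to
  [0.05, 1], seven seeds per plate, 15 plates per strain and Pi level.
  Cq(ITS1) decreases with aggressiveness (`22 + 6·δ` plus noise), so the
  colonization index rises for harmful strains and the planted
  colonization–performance correlation is negative.
- **Expression**: six strains share a planted core of 26 orthogroups with
  positive significant log2FC in every strain; each strain adds ~100
  strain-specific significant genes in random non-core orthogroups and
  ~200 non-significant ones.

Every stage's random stream is spawned independently from the single
seed, and two runs with the same (config, seed) are byte-identical.

**What passing the benchmark shows — and does not.** Recovery of the
planted truths shows the statistics are implemented correctly and have
power under the stated effect sizes; it does not validate the biological
assumptions on real data. The generator makes no attempt to model
sequencing/annotation error, unequal genome quality, correlated family
evolution (shared pathways), lifestyle assignment uncertainty, or
compositional effects beyond the Dirichlet-multinomial; real surveys and
DE tables are messier in all these ways. Quantities reported by
`scripts/acceptance.py` are properties of this synthetic world at the
given seed, with small-sample noise of their own (ancestral-lifestyle
recovery, the most variable, ranges roughly 60–90% across seeds).

## Problem sizes and determinism

Default problem sizes (60 × 2000; 200 parsimony oracle instances; 100–200
null replicates for calibration checks) were chosen so that the full test
suite and the acceptance script each complete in a few minutes on a
single CPU while keeping Monte-Carlo margins tight enough to be
meaningful. All randomness flows through explicit integer seeds; derived
seeds stay below 2³¹.
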