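# Methods

This note documents the statistical procedures the package implements, the
modelling assumptions behind the synthetic-data generator, the numerical
conventions, and the known limitations.

## Rarefaction and alpha diversity

Rarefaction draws each sample's reads **without replacement** — a
multivariate hypergeometric draw per sample — so a sample whose total equals
the target depth is returned unchanged and every rarefied row sums exactly to
the depth. The expected rarefied richness therefore follows the closed form
Σᵢ [1 − C(N−xᵢ, d)/C(N, d)], which the test suite checks by simulation.

Shannon entropy is reported in nats (natural log) by default with a config
flag for bits, since diversity software varies in the base it uses. Good's
coverage 1 − F₁/N (F₁ = singleton count) is computed on the rarefied table,
alongside the other rarefaction-based indices. Alpha indices are averaged
over repeated independent rarefactions (default 100 replicates), each
replicate seeded by a child seed derived from (master seed, replicate index).
Rarefaction curves use *nested* draws within a replicate — a random
permutation of the sample's reads truncated at each depth — so per-replicate
richness is non-decreasing in depth by construction.

## Abundance partition

Global categories use each OTU's share of the grand read total with **strict
inequalities**: abundant above 1 %, rare below 0.01 %, values exactly at a
threshold intermediate. Per-sample categories use within-sample relative
abundance with the same convention, plus an explicit `absent` state.
Conditionally rare-to-abundant taxa (CRAT) use the per-sample thresholds
< 0.1 % (rare somewhere) and > 1 % (abundant elsewhere); both per-sample and
global thresholds live in the configuration because the two rarity scales
serve different questions. Whether absence (p = 0) counts as "rare in a
sample" is an opt-in flag, off by default: a taxon never observed in a
sample is not evidence it was rare there rather than missing.

## Bray–Curtis statistics

All beta-diversity statistics operate on relative abundances of the rarefied
table (equal depths make counts and proportions equivalent up to a constant).
PCoA is classical scaling of the Gower-centered −½D² matrix; negative
eigenvalues are reported but excluded from the proportion-explained
denominator and carry no coordinates, and axis signs are fixed
deterministically. UPGMA is group-average agglomeration with ties broken by
the lexicographically smallest cluster-representative pair, which makes the
dendrogram reproducible under sample reordering; the output is ultrametric
with leaf depth equal to half the final merge height.

ANOSIM ranks all n(n−1)/2 pairwise distances (ties averaged) and computes
r = (mean between-group rank − mean within-group rank)/(M/2). SIMPER assigns
OTU i the contribution |xᵢⱼ − xᵢₖ| / Σₘ(xₘⱼ + xₘₖ) per between-group sample
pair and averages over pairs, so contributions sum exactly to the mean
between-group Bray–Curtis dissimilarity; the reported selection is the
shortest descending prefix reaching the cumulative cut (default 50 %).

## Permutation conventions

Every permutation p-value uses the (1 + count)/(1 + n_perm) estimator, so p
is never zero and has resolution 1/(n_perm + 1); a reported p of 0.001
therefore implies at least 999 permutations. ANOSIM defaults to 999
permutations and Mantel tests to 1000. Mantel r is Pearson correlation of
the off-diagonal distance vectors by default (the test's historical form),
with Spearman available by rank-transforming the off-diagonal multiset once
and permuting the rank matrix — valid because relabeling samples permutes
that multiset. Mantel p-values are one-sided for positive association
(distance–distance hypotheses are directional: "environmentally closer pairs
are compositionally closer"); a two-sided option exists. The partial Mantel
null permutes the second matrix and recomputes the full partial statistic
each draw. A constant control matrix collapses the partial test exactly to
the simple test; perfect collinearity with the control yields a flagged
degenerate result rather than a number. Pairs with missing metadata are
dropped per variable and the retained n is reported, so different variables
may be tested on different sample subsets.

Type-I error of ANOSIM, simple Mantel, and partial Mantel is verified
empirically in the test suite: at α = 0.05 over 1000 simulated
independent-matrix nulls each, rejection rates must lie in [0.03, 0.07].

## Assembly-process inference

βMNTD between samples j and k is the abundance-weighted mean distance from
each taxon present in one sample to its nearest phylogenetic neighbour
present in the other:
½[Σᵢ∈ⱼ fᵢⱼ minᵢ′∈ₖ d(i,i′) + Σᵢ∈ₖ fᵢₖ minᵢ′∈ⱼ d(i,i′)], with patristic
distances d from the user-supplied rooted tree. A taxon shared by both
samples contributes zero, so βMNTD = 0 exactly when supports coincide.
The unweighted (presence/absence) variant is available by flag.

The βNTI null shuffles taxon labels across the whole pooled cophenetic
matrix, holding the community data fixed; βNTI is the z-score of the
observed βMNTD against 999 such randomizations (sd with one delta degree of
freedom). One shared sequence of permutations is reused across all pairs for
a given seed: this is what makes the run reproducible and keeps the cost at
O(n_null) matrix work rather than O(n_null × pairs). The implementation is
vectorized through the nearest-taxon matrix M[k, i] = minᵢ′∈ₖ d(i, i′),
giving all pairs at once as ½(WMᵀ + (WMᵀ)ᵀ). Degenerate nulls with zero
spread (e.g. a star phylogeny, or a pair of identical communities, whose
βMNTD is zero under every relabeling) leave βNTI undefined; such pairs are
flagged and classified from RC_bray alone.

The Raup–Crick null preserves each sample's observed OTU richness and read
total: membership is drawn without replacement with probability proportional
to occupancy (the number of samples containing the OTU), each drawn OTU
receives one read, and the remaining reads are allocated multinomially in
proportion to the OTU's share of the regional pool. RC_raw is the fraction
of null Bray–Curtis values below the observed one, ties counted at half
weight so RC has expectation 0 under exchangeability, rescaled to [−1, 1].

Classification follows βNTI first (> +2 heterogeneous/variable selection,
< −2 homogeneous selection), then RC_bray (> +0.95 dispersal limitation,
< −0.95 homogenizing dispersal), else drift — the "not dominated by any
single process" class, also exposed under the alias *undominated*. Note the
asymmetric vocabulary sometimes seen for these classes ("homogenizing
selection") conflates the two selection directions; this package keeps
selection terms for βNTI calls and dispersal terms for RC calls. Raising the
RC cut can only move pairs from the dispersal classes into drift, never into
or out of the selection classes (tested invariant).

βNTI and RC_bray are computed on the rarefied table: the null models assume
comparable read depths, and rarefaction is the depth normalization used by
the rest of the pipeline.

## Synthetic-data generator

The generator emulates a 27-sample, four-habitat marine survey at 9634 reads
per sample with ~3300 OTUs (defaults), and smaller configurations for
experiments. Components and the features of real data they do and do not
capture:

- **Phylogeny**: Yule (pure-birth) tree, unit rate, exponential waiting
  times from two crown lineages, with a final Exp(n) hang time so every
  pendant edge is positive. Real gene trees have rate variation and
  uncertainty; none of that is modelled.
- **Habitat preference**: a Brownian-motion trait on the tree (root 0,
  per-edge Normal(0, branch length) increments), standardized across tips.
  This plants the phylogenetic signal in habitat preference that makes βNTI
  informative; real traits are only partially conserved.
- **Regional pool**: lognormal relative abundances (σ = 2.5), which at
  study scale yields order-10 OTUs above 1 % of reads and thousands below
  0.01 %, mirroring a heavy-tailed protistan survey.
- **Selection**: sample weights multiply the pool by a Gaussian filter
  exp(−s²(z − h_g)²/2) around the habitat optimum h_g (the habitat's trait
  quantile); s = `selection_strength`, 0 = neutral. Filtering is soft, so
  the rare tail survives and βNTI responds continuously to s.
- **Dispersal**: each habitat has a membership pool (`group_pool_fraction`
  of the species list, 1 = everything) mixed with the global pool at rate
  `dispersal_rate` (1 = fully mixed). Dispersal limitation is planted as
  membership turnover because that is what RC_bray detects. This is one of
  several possible mechanisms (distance-decay kernels are another) and is
  chosen for transparency.
- **Drift**: sample-specific lognormal noise (sd `drift_noise`, default
  0.35) multiplies the weights before the multinomial read draw,
  representing independent demographic stochasticity in each local
  community. This term is essential to the neutral regime: *without* it,
  exchangeable multinomial draws from one pool are more similar than the
  Raup–Crick null expects and are correctly classified as homogenizing
  dispersal, not drift. The default magnitude is the value at which neutral
  per-pair turnover sits centered within the RC null envelope (RC ≈ 0,
  essentially all pairs inside ±0.95), i.e. the generator's definition of
  drift matches the framework's.
- **Metadata**: salinity, depth, and temperature follow per-habitat anchor
  values (salinity 31.5–34.5, depth 5–1000 m, temperature 29–5 °C) with ~1 %
  of the across-habitat range as within-group noise; nutrients rise with
  depth, chlorophyll peaks at the DCM-analogue habitat, picoplankton and
  viral abundances decay with depth over decades; coordinates follow a
  linear estuary-to-basin transect. These are generator parameters chosen to
  look like a subtropical marginal-sea transect, not claims about any
  particular dataset.

Three presets plant recoverable regimes: `selection` (strong filter, full
mixing), `dispersal_limited` (no filter, 30 % membership pools, 5 % mixing),
and `neutral` (no filter, full mixing, drift noise only). The test suite
verifies recovery at 27 samples × 300 OTUs × 299 randomizations: the
selection preset puts the majority of between-habitat pairs at |βNTI| > 2,
the dispersal preset makes dispersal limitation the modal class, and the
neutral preset makes drift modal. Passing these tests shows the inference
stack detects regimes *of the kind the generator plants*; it does not
validate the biological assumptions of the null models on real communities.

## Numerical conventions

- Counts are integers; relative abundances are derived views.
- Every stochastic operation takes a seed; pipeline stages derive child
  seeds from the master seed by stable (SHA-256) hashing of stage names, so
  one integer reproduces a whole run bit-for-bit and results do not depend
  on stage order.
- Real numbers serialize to TSV with 10 significant digits, which
  round-trips distances within 10⁻⁹.
- Permutation-test comparisons use a 10⁻¹² tolerance when counting null
  statistics ≥ the observed one, so floating-point jitter cannot flip a
  tie; Raup–Crick tie detection uses 10⁻¹⁰.
- Geographic distances are great-circle on a 6371-km sphere. Against
  ellipsoidal calculators the difference is below 0.5 % at regional scales.

## Problem sizes

Default analysis parameters follow the survey design the package mirrors
(9634-read rarefaction, 999 randomizations, 1000/999 permutations). The
bundled experiments and the acceptance script run at a reduced but
structurally identical scale — 27 samples × 300 OTUs × 299 randomizations,
199–499 permutations — which the recovery analyses above show is ample to
separate the planted regimes.

## Limitations

- The phylogeny is user-supplied; the package does not build trees from
  sequences, and βNTI inherits whatever error the tree carries.
- The Raup–Crick null treats the observed table as the regional pool;
  conclusions about dispersal are relative to that pool definition.
- Mantel-type tests have known sensitivity to spatial autocorrelation;
  the package reports them as the field uses them without correcting for it.
- Abundant/rare sub-community distance matrices are renormalized after
  subsetting, an explicit assumption; the alternative (keeping total-table
  proportions) reflects total-count artifacts in the subset.
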