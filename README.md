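# planktonic

Community-ecology inference for marine protistan (and other microbial) OTU
tables: rarefaction-based diversity, rare-biosphere partitioning, Bray–Curtis
beta-diversity statistics, environmental-driver screens, and null-model
quantification of community assembly processes.

The package is written for researchers analysing amplicon surveys — e.g. an
estuary-to-basin transect where samples fall into habitat groups (surface,
coastal subsurface, deep-chlorophyll-maximum, deep water) — who want the full
inference stack behind such a study as tested, scriptable Python rather than a
chain of GUI tools.

## What it computes

Given a samples × OTUs count table, a sample metadata table, and a rooted
phylogeny of the OTUs:

- **Diversity** — rarefaction without replacement (multivariate
  hypergeometric) to a common depth; OTU richness, Shannon entropy
  *H* = −Σ *p*ᵢ ln *p*ᵢ, and Good's coverage 1 − *F*₁/*N*, averaged over
  repeated resampling; rarefaction curves.
- **Rare-biosphere partition** — abundant OTUs (> 1 % of all reads), rare
  OTUs (< 0.01 %), per-sample categories, and conditionally rare-to-abundant
  taxa (CRAT: < 0.1 % of a sample's reads somewhere but > 1 % elsewhere).
- **Beta diversity** — Bray–Curtis dissimilarity
  BC(x, y) = 1 − 2 Σᵢ min(xᵢ, yᵢ) / Σᵢ (xᵢ + yᵢ) on relative abundances;
  principal coordinate analysis; UPGMA dendrograms; the rank-based ANOSIM
  permutation test (statistic *r*, global and pairwise); SIMPER decomposition
  of between-group dissimilarity into per-OTU contributions.
- **Environmental association** — haversine geographic distances,
  per-variable environmental distances, simple and partial Mantel permutation
  tests (*r*ₓᵧ.𝓏 = (*r*ₓᵧ − *r*ₓ𝓏*r*ᵧ𝓏)/√((1−*r*ₓ𝓏²)(1−*r*ᵧ𝓏²))) for the
  total, abundant, and rare community fractions, and Spearman screens of
  alpha diversity or taxon abundances against environmental variables.
- **Assembly processes** — abundance-weighted βMNTD (beta mean
  nearest-taxon distance) on the phylogeny; its z-score βNTI against a
  999-randomization taxon-label null; the Bray–Curtis-based Raup–Crick
  metric RC_bray against a null that preserves each sample's richness and
  read depth; and the standard five-way classification — βNTI > 2
  heterogeneous selection, βNTI < −2 homogeneous selection, otherwise
  RC_bray > 0.95 dispersal limitation, RC_bray < −0.95 homogenizing
  dispersal, else drift — with per-pair results and process percentages.

A synthetic-data generator (Yule phylogeny, Brownian habitat-preference
trait, lognormal abundance pool, Gaussian habitat filtering, per-habitat
dispersal pools, demographic drift noise) produces complete datasets with
known planted regimes, so every stage is testable without sequence data.

## Worked example

```python
import planktonic as pk
from planktonic.simulate import scenario_presets, simulate_communities

scenario = scenario_presets(seed=7)["selection"]      # 27 samples, 300 OTUs
table, metadata, tree = simulate_communities(scenario)
rarefied = pk.rarefy(table, depth=9634, seed=7).drop_empty_otus()

part = pk.partition_all(rarefied)
print(part.summary.round(2))

dm = pk.bray_curtis(rarefied)
res = pk.anosim(dm, metadata["group"], n_perm=999, seed=7, pairwise=False)[0]
print(f"global ANOSIM r = {res.r_statistic:.3f}, p = {res.p_value:.3f}")

pairs, summary = pk.assembly_analysis(rarefied, tree, n_null=299, seed=7)
for proc, pct in summary.percent.items():
    print(f"{proc:<25s} {pct:5.1f}%")
```

prints

```
              n_otus  pct_otus  pct_reads
category
abundant          21      7.61      76.03
intermediate     165     59.78      23.67
rare              90     32.61       0.30
global ANOSIM r = 0.997, p = 0.001
heterogeneous_selection    60.7%
homogeneous_selection       0.3%
dispersal_limitation       10.5%
homogenizing_dispersal     13.4%
drift                      15.1%
```

The partition summary says 21 of 276 surviving OTUs carry 76 % of the reads
while the 90 rare OTUs carry 0.3 % — the heavy-tailed abundance structure the
generator plants. ANOSIM *r* ≈ 1 with p = 0.001 (the smallest value 999
permutations can resolve) confirms the four habitat groups are maximally
separated in Bray–Curtis space. Because this scenario plants strong habitat
filtering on a phylogenetically conserved trait, the assembly stage
attributes most between-habitat turnover to heterogeneous selection
(|βNTI| > 2), with the remainder spread over the stochastic classes.

The same analyses run from the shell:

```bash
planktonic simulate --preset selection --seed 7 --out data/
planktonic assembly data/community.tsv --tree data/tree.nwk --nulls 299 \
    --seed 7 --out results/
planktonic run config.yaml          # the full pipeline from a YAML config
```

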