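# benthodiv

Downstream statistics for benthic archaeal zOTU communities sampled along
environmental gradients — the analysis stack used for deep-sea sediment
16S surveys where paired DNA (entire community) and RNA (potentially
active community) amplicon libraries are screened against water-column and
sediment geochemistry.

The package is for microbial ecologists who have a denoised zOTU count
table, a rooted phylogeny of those zOTUs, and a table of per-station
covariates, and who want the classical rarefaction-based battery with
honest resampling-based significance:

* **Alpha diversity under repeated rarefaction.** Libraries are rarefied
  without replacement to a common depth; richness *S*, Shannon
  H′ = −Σ pᵢ ln pᵢ (nats) and root-inclusive Faith's PD are averaged over
  (by default) 100 rarefaction iterations. Per-sample coverage comes from a
  Michaelis–Menten fit *y* = *d·x*/(*e* + *x*) to the analytic
  (hypergeometric) rarefaction curve, coverage = 100·S_obs/*d̂*.
* **Four dissimilarities, from first principles.** Weighted and binary
  Bray–Curtis, and weighted (normalized) and unweighted UniFrac computed by
  a single post-order traversal of branch-wise descendant proportions.
* **Repeated-rarefaction PERMANOVA.** Single-covariate pseudo-F in the
  McArdle–Anderson formulation (Gower-centered −D²/2, trace sums of
  squares). The count table is rarefied R = 999 times; each rarefied table
  gets its own K = 999 covariate permutations, and exceedance counts are
  pooled into one p-value with an epsilon correction so floating-point ties
  with the observed statistic count as exceedances:
  p = (1 + Σ_r #{k : F_{r,k} ≥ F_obs,r − ε_r}) / (1 + R·K).
* **Environment screens.** Spearman rank tests (exact by full enumeration
  for n ≤ 9 without ties, t-approximation otherwise) of covariate
  inter-correlations and of alpha indices against covariates; PERMANOVA
  screens of community and predicted-function profiles, with DNA and RNA
  arms always modelled separately and sub-threshold libraries removed
  first.
* **A synthetic transect generator** that emulates a 9-station abyssal
  transect — copula-correlated covariates mapped to measured ranges, a
  random zOTU phylogeny, Dirichlet-multinomial counts with a planted
  chlorophyll effect carrying phylogenetic signal, an RNA-enriched clade,
  and one deliberately under-sequenced RNA library — with a ground-truth
  record so every inference stage can be scored.

## Worked example

```python
import benthodiv as bd
from benthodiv.synthetic import SyntheticConfig, simulate_dataset

ds = simulate_dataset(SyntheticConfig(seed=42), out_dir="demo")
dna = ds.counts.split_fractions()["DNA"]

profile = bd.alpha_profile(dna, ds.tree, depth=9058, iterations=100, seed=42)
print(profile.data[["richness", "shannon", "faith_pd"]].round(2).head(3))

chl = ds.env.aligned_to(dna.sample_ids).data["chlorophyll_sum"].to_numpy()
res = bd.permanova_rarefied(dna, chl, "bray_weighted", depth=9058,
                            rarefactions=999, n_perm=999, seed=42,
                            covariate="chlorophyll_sum")
print(f"chlorophyll: F={res.F:.2f}, R2={res.R2:.3f}, p={res.p:.2e}")
```

prints

```
          richness  shannon  faith_pd
sample
st01_dna    198.28     4.61     11.10
st02_dna    211.92     4.62     11.10
st03_dna    199.08     4.56     11.24
chlorophyll: F=5.29, R2=0.430, p=2.10e-05
```

The nine DNA libraries carry ~200 of the 300 simulated zOTUs each at the
9,058-read rarefaction depth. The PERMANOVA recovers the planted signal:
chlorophyll explains R² ≈ 0.43 of the weighted Bray–Curtis variation (the
generator's default plants ≈ 0.40), and the pooled permutation p over
999 rarefactions × 999 permutations is far below 0.05.

The same stages are scriptable from the shell:

```bash
benthodiv simulate --seed 42 --out demo/
benthodiv run --config config.yaml --profile desk
```

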