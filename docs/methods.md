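# Methods

This note documents the statistical models implemented in `benthodiv`, the
choices made where several defensible conventions exist, what the synthetic
generator does and does not emulate, and the numerical details that affect
reproducibility.

## Rarefaction and alpha diversity

Libraries are subsampled **without replacement** to a common depth
(`rarefy_counts`); the rarefied count of taxon *i* in a library of depth
*N* with *Nᵢ* reads is multivariate-hypergeometric, so its expectation is
*n·Nᵢ/N*. Libraries shallower than the target depth must be removed first
(`drop_low_depth`), mirroring the pre-analysis removal of under-sequenced
RNA libraries; the filter's report names every removed library and its
depth. Default depths are 9,058 reads for the DNA arm and 4,941 for the
RNA arm.

Per rarefied table we compute richness *S* (taxa with count > 0), Shannon
H′ = −Σ pᵢ ln pᵢ in **nats** (natural log is the canonical base; the
surveyed communities' values of 5–6 at richnesses of several hundred are
only consistent with nats), and **Faith's PD** as the total branch length
of the minimal subtree connecting the present tips *and the root*
(root-inclusive convention, i.e. every edge with at least one present
descendant contributes). The whole battery is repeated over 100
rarefaction iterations (child seed per iteration) and arithmetic means are
reported. With one iteration the profile equals a single-pass computation,
a property the tests pin down.

**Analytic curves.** Rarefaction curves use the exact hypergeometric
expectation E[Sₙ] = Σᵢ [1 − C(N−Nᵢ, n)/C(N, n)] (no resampling; evaluated
in log-gamma space). Sample-based species accumulation uses the analogous
"exact" incidence form over samples.

**Coverage.** The Michaelis–Menten curve *y = d·x/(e+x)* is fitted by
bounded least squares (initialised at *d₀* = max *y*, *e₀* = the *x* whose
*y* is nearest *d₀*/2; relative parameter tolerance 1e-8; a constant-*y*
input is reported as non-converged rather than silently fitted). Coverage
is 100·S_obs/*d̂*. By default the fit uses the **mean analytic rarefaction
curve across iterations**; fitting per iteration and averaging the
coverages is available (`coverage_method="per_iteration"`) since the
convention is not fixed by common usage. Transect-level "fraction of zOTUs
recovered" statements use the same fit applied to the sample-based
accumulation curve.

A caveat that matters at reduced problem sizes: the MM hyperbola
approaches its asymptote like 1/x, much more slowly than a hypergeometric
rarefaction curve saturates. When the community is small relative to the
sequencing depth the fitted asymptote can fall slightly *below* the
observed richness and coverage exceeds 100%. Such values are returned
as-is with an explicit flag (`coverage_exceeds`), never clamped. At the
survey's own scale (~1,500 zOTUs, 9,058 reads) the generator produces
still-rising curves and coverages in the 90s.

## Beta diversity

Four measures, all bounded in [0, 1], symmetric, and zero iff the two
samples are compositionally identical (presence-identical for the
unweighted variants):

* weighted Bray–Curtis Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ);
* unweighted (binary) Bray–Curtis (A+B−2J)/(A+B), the Sørensen form;
* weighted UniFrac, **normalized** form Σ_b l_b|p_b−q_b| / Σ_b l_b(p_b+q_b),
  where p_b is the fraction of a sample's reads descending from branch b —
  this equals the classical normalized weighted UniFrac and GUniFrac's d₁
  (α = 1); the raw unnormalized variant is deliberately not offered;
* unweighted UniFrac Σ_b l_b|𝟙(p_b>0)−𝟙(q_b>0)| / Σ_b l_b 𝟙(p_b>0 ∨ q_b>0).

UniFrac operates on within-sample proportions (multiplying one sample's
counts by a constant changes nothing) computed by one post-order traversal
that accumulates descendant read sums per edge. The root's own edge, if
present in the Newick, is excluded; zero-length branches contribute zero,
so collapsing them never changes a value. **No rarefaction happens inside
the distance functions** — the repeated-rarefaction design owns that step.
All four implementations are cross-checked in the tests against
scikit-bio/scipy to ≤ 1e-10 on random tables.

## PERMANOVA with repeated rarefaction

Single-covariate McArdle–Anderson formulation: A = −D∘D/2 is
double-centered to G (its trace is the total sum of squares by the Huygens
identity), the covariate's hat matrix H (intercept plus one numeric column,
or dummy-coded groups) gives SS_model = tr(HGH) and
F = (SS_model/df_m)/(SS_resid/df_r). On Euclidean distances this equals
classical ANOVA/regression F exactly, which the tests verify against raw
sums of squares. A perfect fit (residual zero to round-off) reports F = ∞
rather than a round-off artefact; degenerate distance matrices (all
samples identical) report F = 0 with p = 1 semantics.

Significance: permutations of the covariate vector (equivalently of D's
rows/columns) — free permutation, no strata, matching a single-factor
transect design. To keep one arbitrary rarefaction from dictating the
answer, `permanova_rarefied` rarefies R = 999 times, computes each
rarefied table's own observed F and its own K = 999 permuted statistics,
and pools:

    p = (1 + Σ_r #{k : F_{r,k} ≥ F_obs,r − ε_r}) / (1 + R·K)

with ε = √(machine ε)·max(1, |F_obs|), so permuted statistics numerically
tied with the observed one count as exceedances (the standard guard
against anti-conservative p from floating-point ties). The +1 continuity
correction means p ≥ 1/(1+R·K): the estimator never returns 0. Reported F
and R² are means over rarefactions; the per-rarefaction trace is kept.
The pooling rule lives in one function (`pool_exceedances`) so an
alternative aggregation can be swapped in; drawing fresh permutations per
rarefaction is the default, with a shared-permutation mode available
(`permute_per_rarefaction=False`) since either reading of the protocol is
defensible. An exhaustive mode enumerates all n! relabelings for small n,
which the tests compare against independent enumeration.

Multiple testing: screens flag p ≤ 0.05 per cell with **no correction** by
default (matching the analysis convention for these screen grids); a
Benjamini–Hochberg option exists but is off.

## Spearman screens

ρ is Pearson's correlation on midranks after pairwise-complete deletion.
The p-value is exact — full enumeration of all n! rank permutations — for
n ≤ 9 with no ties (9! ≈ 3.6·10⁵ permutations, sub-second), and otherwise
uses t = ρ√((n−2)/(1−ρ²)) on n−2 df. At the transect's n = 9 the two
branches agree within 0.02 for moderate ρ, a cross-check in the tests.
Ammonium and phosphate are excluded from screens by default (below
quantification limit in the motivating survey); a flag re-includes them.
A constant alpha index yields an NA row with a diagnostic note rather than
aborting a whole screen. Chlorophyll integration sums all readings in the
top 500 m of a CTD profile.

DNA and RNA arms are never pooled in any model: different extraction
chemistry makes the fractions non-exchangeable, so every screen row is
tagged with its fraction and fitted on that arm alone.

## Synthetic transect generator

What it emulates: 9 stations spanning 27°S–59°N; covariates drawn from a
Gaussian copula with a target Spearman structure (Spearman→Pearson via
2·sin(πρ/6)) and mapped monotonically onto measured ranges (chlorophyll
sum 41.9–122.9 mg/m³, water depth 3,258–5,909 mbsl, TOC skewed around
0.6% with rare ~1.3% excursions); one covariate ("null_property") drawn
independently as a negative control; a random coalescent-style rooted
phylogeny with exponential waiting times; station compositions
softmax(base + effect·z_chl·loading) with loadings simulated as Brownian
motion along the tree so that phylogenetic and purely compositional
distances respond differently; Dirichlet-multinomial library draws
(concentration 200, i.e. visible overdispersion across rarefaction
replicates) at log-uniform depths; an RNA arm that re-uses station
compositions with a designated clade (~0.3% baseline, chosen as an
internal clade holding 3–15% of tips) multiplied by 40 and renormalized —
yielding the ~10% active-fraction vs <1% entire-fraction contrast — and
one forced 50-read RNA library to exercise depth filtering.

Key defaults and why: `base_log_sd = 1.0` reproduces the surveyed
communities' high evenness (Shannon ≈ ln S − 1) and, at the survey's own
scale, rarefaction curves that are still rising at full depth;
`effect_size_chl = 0.65` plants a chlorophyll effect whose weighted
Bray–Curtis PERMANOVA R² averages ≈ 0.40 across transects, the
"chlorophyll explains >40% of variance" regime. With `effect_size_chl = 0`
station compositions are exchangeable, so chlorophyll-keyed tests must
reject at the nominal rate — the type-I calibration the acceptance checks
run. Everything derives from one seed via named child seed sequences;
identical configs give byte-identical output files.

What it does **not** emulate: raw reads, chimeras or denoising artefacts;
taxonomy strings; real functional prediction (the synthetic function table
is a fixed linear readout of composition plus multiplicative noise, enough
to exercise the function screen but carrying no annotation realism);
spatial autocorrelation beyond what the covariate copula induces; and any
DNA/RNA difference other than the single boosted clade. Passing tests on
this generator therefore demonstrate calibration and recovery under a
clean compositional-gradient model, not robustness to the full messiness
of amplicon data.

## Problem sizes and numerics

Tests and the acceptance script run the generator at 300 zOTUs (120 for
fixtures) and the resampling protocols at R = 50 rarefactions × K = 99
permutations — the package's scaled-down analysis profile (`--profile
desk`); the full profile (999 × 999, 100 alpha iterations) is the default
for real runs. Calibration checks use 200 null transects and 100
planted-effect transects. Binomial coefficients are evaluated via log-gamma
differences; the copula requires a positive-definite target (an
eigenvalue-clipping repair helper is provided but never applied silently);
Michaelis–Menten fits are bounded below by 0 with honest convergence
flags; and every TSV/JSON writer emits deterministic column order so runs
with the same seed are byte-reproducible.

## Known limitations

* One covariate per PERMANOVA model; sequential multi-term decomposition,
  dispersion (PERMDISP) tests and ordination are out of scope.
* The exact pooling arithmetic used by any particular published
  repeated-rarefaction analysis can differ in the continuity correction;
  the rule here is documented above and isolated in one function.
* MM-based coverage inherits the model-mismatch bias described above; at
  small community sizes treat coverage near or above 100% as "saturated"
  rather than as a precise estimate.
* The exact-Spearman branch refuses ties (falls back to the t
  approximation), which is the usual compromise for midranked data.
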