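# Methods

## The rhythm test

The core detector is a nonparametric test of association between an
observed time series and a family of cosine reference waveforms. For a
reference with period *T* and phase lag φ evaluated on the ZT grid, the
statistic is

    S = Σ over observation pairs (i, j) with r_i ≠ r_j of
        sign((x_i − x_j)(r_i − r_j))

where `r` is the reference value of each observation's time group. Pairs
whose reference values tie (replicates within a ZT, and cosine-symmetric
time points, which share a value) are excluded from the pair universe;
pairs tied in the data contribute 0 and shrink the attainable maximum, so
τ = S/max|S| is a tau-b-like normalization.

**Exact null.** Under exchangeability of continuous data, the number of
discordant pairs is distributed as the inversion count of a random
multiset permutation whose block multiplicities are the reference tie
blocks. Its generating function is the Gaussian q-multinomial — a product
of Gaussian binomials — which we evaluate by exact integer convolution
(Pascal-type recurrence on the q-binomials, cached per block structure).
Two-sided p = P(|S| ≥ |S_obs|). Above 50 observations (configurable) a
normal approximation with the Jonckheere–Terpstra variance
(N²(2N+3) − Σ bᵢ²(2bᵢ+3))/72 and a continuity correction is used and the
regime is flagged per series. When the data themselves contain ties and
the series has ≤ 8 observations, the null is instead enumerated over the
distinct orderings of the data multiset; larger tied series fall back to
the untied null, which is conservative (ties only shrink |S|).

**Reference grid and multiplicity.** Default grid: the 24 h period only,
one phase lag per sampling interval (12 lags for 2 h sampling); waveforms
whose group rank pattern duplicates an earlier one are removed. The
reported p is the minimum over the grid, Bonferroni-corrected by the
number of distinct *two-sided* rank patterns (a lag and its antiphase give
the same |S|, so 12 lags form 6 classes). We adopted this as the default
after observing that the unadjusted minimum is markedly anti-conservative
under a pure-noise null (empirical CDF exceedance ≈ 0.37 over uniform at
12 time points), which would corrupt every downstream BH step; the
unadjusted behaviour remains available as `multiplicity="min-p"`.
Ties on p resolve toward positive concordance — the reference whose peak
aligns with the data peak rather than its trough — then the smaller lag.

**Phase and amplitude.** Phase is the winning lag. Amplitude — half the
peak-to-trough excursion — is not part of the rank statistic; it is the
absolute least-squares cosine coefficient fitted to the group means at the
winning (period, phase). A constant series returns p = 1, amplitude 0.

## Stages

*Global cycling.* Each gene's organ values at a ZT form one replicate
group (one animal per organ per time point). BH runs across all tested
genes; a gene is a global cycler at adjusted p < 0.05. The expression
filter keeps genes with values strictly above 0 at ≥ half of the time
points per organ, combined across organs with an `all` rule by default so
the stacked series has no organ gaps (`any` available for sensitivity).
Leave-one-organ-out reruns the full detection per left-out organ.
Phase concordance uses the circular median (cost-minimizing data point,
ties to the smaller ZT) of per-organ phases of organs where the gene is
per-organ rhythmic (per-organ BH at the same alpha), and Pearson r on the
linear ZT scale; near the period boundary the linear convention deflates r,
which is logged rather than corrected to keep the field's plotting
convention.

*Rhythmic interactions.* Spearman correlations use average ranks; a ZT
where either gene has zero variance across organs yields a flagged
undefined ρ, and pairs with > 25% undefined time points are excluded with
a reason. The ρ series is a single-replicate series for the same engine
(12 observations → exact null). BH is applied within each sampled batch,
matching per-experiment adjustment; the z-score transform uses the
population (divide-by-n) standard deviation over the fixed time points.

*Networks.* Unsigned adjacency |cor|^β, β = 16. Fundamental concepts
follow the standard weighted-network definitions: kᵢ = Σⱼaᵢⱼ;
clusterCoefᵢ = (ΣⱼΣ_l aᵢⱼa_{jl}a_{li})/((Σⱼaᵢⱼ)² − Σⱼaᵢⱼ²);
MARᵢ = Σⱼaᵢⱼ²/Σⱼaᵢⱼ; density = Σkᵢ/(n(n−1));
centralization = n/(n−2)·(max k/(n−1) − density);
heterogeneity = sd(k)/mean(k) with the population sd. Isolated nodes get
MAR and clustering coefficient 0, flagged. Module detection is a
deliberately simplified, fully deterministic procedure: unsigned TOM
ω = (L + a)/(min(kᵢ,kⱼ) + 1 − a) with L = A², average-linkage clustering
of 1 − ω, a fixed-height cut (default 0.95) and a minimum module size
(default 30); clusters below the minimum are left unassigned. This
diverges from adaptive dynamic tree cutting on purpose — module *counts*
on real data are descriptive, not reproducible, and determinism here buys
byte-identical reruns. Eigengenes are unit-norm first principal components
of the standardized member matrix, sign-oriented to correlate positively
with members; module rhythmicity groups the eigengene (and the module mean
expression) by ZT with organs as replicates and calls a module rhythmic if
either variant passes BH across modules.

*Day/night and network comparison.* Day is the half-open window
[0, 12) h by default, so ZT06 is day and ZT12–ZT22 are night. Per-ZT
networks are built from the genes × organs matrix at that time point.
Differential connectivity uses fold = max(k_A,k_B)/min(k_A,k_B) > 2 with a
machine-epsilon pseudo-count only when one side is exactly zero (flagged).
Pair weight differences default to the raw correlation scale (adjacency
un-powered by 1/β) because β = 16 drives almost all weights to zero and
would make medians degenerate; the powered scale is a flag. Module
similarity is the Jaccard index on gene sets; consensus modules are
mutual best matches with J ≥ 0.3.

*Network medicine.* d_s is the mean, over mapped disease genes, of the
shortest-path distance to the nearest other disease gene; d_AB is the
symmetric closest-distance average defined in the README. Both restrict to
the graph's largest connected component (the common convention; a
drop-infinite mode exists). Disease-module nulls draw uniform same-size
node sets, proximity nulls draw degree- and size-matched sets from
logarithmic (base-2) degree bins merged upward until each holds ≥ 10
nodes; empirical p uses the add-one estimator (1 + #extreme)/(n_perm + 1),
so p is never zero and is slightly conservative. The day/night contrast
tests Δ = d_s(day) − d_s(night) two-sidedly against same-size random sets
evaluated in both graphs, which absorbs the part of Δ that mere density
differences would produce.

## The synthetic atlas

The generator emulates the statistical skeleton of a multi-organ
circadian atlas; defaults describe a desk-scale study of 20 organs
sampled every 2 h over one 24 h cycle with 1,000–2,000 genes (individual
analyses state their sizes).

- **Baselines**: log-normal, exp(N(μ_o, 0.3)) with organ-level log-means
  μ_o ~ N(1.6, 0.2) — a shared organ "size" effect plus per-(gene, organ)
  spread, giving FPKM-like positive values around 5.
- **Global cyclers** (20%): value = baseline + A·cos(2π(t − φ)/24) + ε,
  one φ per gene shared across organs, φ drawn from a 50/50 von Mises
  mixture (κ = 4) peaked at ZT06 and ZT18 (noon/midnight bimodality).
  Default A = 2, ε ~ N(0, 1). An optional log-normal per-(gene, organ)
  amplitude jitter exists (default off).
- **Organ cyclers** (10%): the same rhythm applied only in a random ~30%
  organ subset with organ-specific mixture phases.
- **Coupled pairs**: both members load a pair-specific organ latent
  L(o) ~ N(0,1); one member with constant loading κ, the other with
  κ·cos(2π(t − ψ)/24). The asymmetry is essential: with both loadings
  cosine-modulated the cross-organ covariance is a product of cosines and
  therefore 12 h-periodic, invisible to a 24 h test; the asymmetric form
  makes the Spearman series 24 h-periodic with its peak at ψ. Pair members
  are drawn across cycling strata with a configurable mix (default
  0.5/0.3/0.2 both/one/neither) — under the additive cosine model a shared
  phase contributes a *constant* per time point across organs, so
  cycler-ness alone cannot create rhythmic co-expression, and the stratum
  gradient seen in real atlases is planted explicitly and recorded in the
  ground truth.
- **Modules**: members share an organ latent with loading chosen to hit a
  target within-module correlation against the empirical residual
  variance; rhythmic modules re-align their members' phases to the module
  phase. The latent is organ-level co-regulation, so it acts as replicate
  noise for the stacked test — module-member cyclers are genuinely harder
  to call, and module-rhythmicity scenarios use 25 organs to restore
  power.
- **Day/night dimorphism**: a body-wide organ factor w(o) with loading
  ν(t) = ν₀(1 + δ·cos(2π(t − 18)/24)) (default off; scenarios use ν₀ = 1,
  δ = 0.5) makes cross-organ correlations, hence per-ZT connectivity and
  density, higher at night.
- **Cycler rewiring**: because covariances of pure cosines are
  12 h-periodic, the ZT06 and ZT18 networks of a purely additive-cosine
  atlas are statistically identical. Scenarios that need noon/midnight
  rewiring give each global cycler a phase-modulated loading
  κ_c(1 + 0.6·cos(2π(t − φ_g)/24)) on the shared factor, so a cycler's
  neighbourhood strengthens at its own peak time.
- Negative values are clipped at 0 (FPKM non-negativity) and the clip
  fraction is reported so tests can bound the distortion.

All randomness flows from one integer seed through named substreams;
identical seeds give bit-identical atlases. The interactome generator
produces a connected preferential-attachment (or Erdős–Rényi) graph,
grows planted modules by randomized BFS so their induced subgraphs are
connected, and places planted proximal set pairs inside the planted set's
hop neighbourhood.

What the generator does **not** model: read-count noise (negative
binomial), library-size or batch structure, non-sinusoidal waveforms,
unevenly spaced sampling, and within-organ cell-type mixtures. Passing
tests therefore demonstrate correctness and calibration of the
statistics under a clean generative model, not robustness to every
artefact of real sequencing data.

## Numerical choices and degenerate inputs

- BH adjustment rejects p outside (0, 1]; empty inputs pass through.
- Constant series: statistic 0, p = 1, amplitude 0 — never an error.
- Zero-variance genes are dropped from networks (relative tolerance
  10⁻¹⁰ on the row scale) and reported; zero-variance ZTs flag undefined
  correlations.
- Hub extraction breaks ties lexicographically on gene id; module names
  order by decreasing size then smallest member id — both choices exist
  only to make reruns byte-identical.
- Permutation tests require n_perm ≥ 1; degree bins widen (merge upward)
  when underpopulated, and the widening is recorded.
- Problem sizes in the scripted analyses (2,000 genes × 20 organs for
  detection power and FDR; 200 × 25 for module scenarios; 600-node
  interactomes with 200 × ~200-repeat calibrations and 1,000-permutation
  planted tests) were chosen as the smallest sizes at which the targeted
  effects are stable across seeds.

## Known limitations

- The fixed-height module cut has no adaptive branch sensitivity; deeply
  nested modules merge or vanish where dynamic cutting would split them.
- Phase estimates are quantized to the lag grid (2 h by default).
- The normal-approximation regime is slightly conservative for tied data.
- Leave-one-out is O(organs × full detection); at atlas scale it is the
  slowest stage and is sized down in the scripted analyses.
- Pearson-on-linear-ZT phase concordance underestimates agreement for
  phases straddling ZT0/ZT24; an optional circular correlation is the
  escape hatch.
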