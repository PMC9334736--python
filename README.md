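# chronet

Body-wide circadian co-expression network analysis.

Multi-organ circadian atlases sample every organ of an animal every few
hours across one day, giving a gene × organ × time-point expression cube.
`chronet` implements the statistics that turn such a cube into a picture of
body-wide temporal organisation, and ships a synthetic-atlas generator with
planted ground truth so every stage is testable without any external data:

1. **Global cycling genes** — pool the organ values at each Zeitgeber time
   (ZT) and test the stacked series for 24 h rhythmicity with a
   nonparametric cosine-reference test (Kendall-type statistic *S* with an
   exact convolution null; Benjamini–Hochberg across genes, call at
   adjusted *p* < 0.05). Robustness by leave-one-organ-out; phase summaries
   compare the body-wide phase with the per-organ circular-median phase.
2. **Rhythmic interactions** — for a gene pair, compute the Spearman
   correlation of the two genes across organs at every ZT
   (ρ₁, …, ρ₁₂), then rhythm-test that correlation series itself. Sampled
   pair batches estimate the rhythmic proportion; results stratify by how
   many members are global cyclers; z-scored series
   ρ′ᵢ = (ρᵢ − ρ̄)/σ_ρ export for heatmaps.
3. **Weighted co-expression networks** — unsigned soft-thresholded
   adjacency *a*ᵢⱼ = |cor(xᵢ, xⱼ)|^β with β = 16; the six fundamental
   network concepts (connectivity *k*, clustering coefficient, maximum
   adjacency ratio, density, centralization, heterogeneity); modules from
   average-linkage clustering of topological-overlap dissimilarity;
   module eigengene and mean-expression rhythmicity.
4. **Day/night topology** — one network per ZT; Wilcoxon rank-sum contrasts
   of every index between day and night time points; pairwise comparison of
   the noon (ZT06) and midnight (ZT18) networks: >2-fold differential
   connectivity, per-node Euclidean distance, |Δcor| by cycling stratum,
   module Jaccard similarity with mutual-best consensus.
5. **Network medicine** — disease-module distance
   *d_s* (mean nearest-other-member shortest-path distance) with uniform
   permutation nulls on thresholded (Pearson r > 0.8) per-ZT graphs, its
   day/night contrast, and gene-set proximity

   d_AB = (Σ_{a∈A} min_{b∈B} d(a,b) + Σ_{b∈B} min_{a∈A} d(a,b)) / (‖A‖+‖B‖)

   against degree- and size-matched random sets (logarithmic degree bins).

## Worked example

```python
from chronet import SimulationConfig, simulate_atlas
from chronet.cycling import detect_global_cycling

atlas, truth = simulate_atlas(SimulationConfig(n_genes=400, n_organs=20,
                                               seed=1))
table = detect_global_cycling(atlas, alpha=0.05)
called = table[table.is_global_cycler]
planted = set(truth.genes_of_class("global_cycler"))
print(len(called), "called;",
      f"recall {len(set(called.gene) & planted) / len(planted):.2f}")
```

prints

```
85 called; recall 1.00
```

— 80 genes were planted as global cyclers (cosine amplitude twice the
noise, one shared phase per gene drawn from a noon/midnight bimodal
mixture); the stacked test recovers all of them plus a handful of
organ-restricted cyclers whose pooled signal is real.

The full study is the numbered scripts under `analysis/`
(`01_simulate.py` … `07_network_medicine.py`); run them in order with
`python analysis/01_simulate.py --seed 1` etc. Each prints what it found
and writes its tables under `results/study/`. On the default seed the
sequence reports, among others: 19.2% of genes called globally cycling with
90.6% recall of the planted set and 98.7% reproduced in every
leave-one-organ-out run; phase concordance r = 0.92; rhythmic-interaction
proportions 0.22 / 0.04 / 0.02 for pairs with both / one / neither member
cycling; all three planted modules recovered with eigengene phases at the
planted ZT06 and ZT18 peaks; night networks denser than day networks
(rank-sum p < 0.01); and planted disease-module and proximity signals at
permutation p ≈ 0.001 with z < −4.

There is also a `chronet` command-line wrapper (`chronet run-all --seed 7
--out out/`) that executes the whole pipeline end to end and is
byte-reproducible for a fixed seed.

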