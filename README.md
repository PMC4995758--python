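# polygwas

Continuous-genotype association mapping for polyploid crops.

## The problem

Genome-wide association in a hexaploid crop must distinguish seven dosage
classes (0–6 copies of the B allele) per marker. On SNP-array data the
classes appear as clusters of the log2 allele-signal contrast

    theta = log2(B) - log2(A),        s = (log2(A) + log2(B)) / 2,

but with 2n+1 clusters squeezed into the same signal range the clusters
overlap into a continuum and genotype *calling* — assigning every sample a
discrete class — misclassifies heavily. `polygwas` skips calling and
associates the continuous theta values directly with the trait, for
breeders and geneticists working with bi-parental polyploid populations.

## What the package does

- **`polygwas.simulate`** — a polysomic F1 simulator: linkage maps with the
  two-probes-per-SNP / ≤3-SNPs-per-contig structure of a genotyping array,
  phased hexaploid parents, offspring via strictly bivalent meiosis
  (random homolog pairing, Haldane crossovers, no double reduction; gamete
  dosages follow the hypergeometric law), log-scale allele intensities, and
  phenotypes with heritability h² split over causal probes as
  `Y_i = sqrt(1 - Σπ_j)·N(0,1) + Σ_j a_ij·sqrt(π_j / (ploidy·f_j(1-f_j)))`.
- **`polygwas.signal`** — quantile normalization, theta/s transformation,
  the theta-range ≥ 2 segregation filter, per-probe mean-centering.
- **`polygwas.breeding`** — REML fit of the repeated-measurements mixed
  model `y = α + block + plate + g + e`, BLUPs with prediction error
  variances, and deregressed breeding values `debv = ebv / r²` with
  `r² = 1 - PEV/σ²_g`.
- **`polygwas.linear`** — vectorized per-probe regression
  `Y = α + βx + ε`, Storey q-values (π₀-adaptive step-up), significance at
  q ≤ 0.01, and the F ≥ 4 prefilter.
- **`polygwas.bayes`** — joint Bayesian variable selection with a
  spike-and-slab mixture prior on probe effects
  (`a_k ~ π₀ N(0, σ²_g0) + π₁ N(0, σ²_g1)`, π₀ = 0.99, σ²_g0 = 0.001,
  σ²_g1 = 0.1, Beta(10,1) hyperprior on π₀), Gibbs sampling
  (50,000 sweeps, 10,000 burn-in, thinning 200), per-probe Bayes factors,
  significance at BF ≥ 10.
- **`polygwas.pls`** — partial least squares on the prefiltered subset:
  seeded 80/20 split, 10-fold × 20-repeat CV over 1–10 latent variables by
  RMSE, variable-importance scores (mean-square-1 calibrated), VIM ≥ 2.
- **`polygwas.calling`** — the comparator the continuous approach is
  measured against: a naive nearest-center caller on theta plus a paired
  continuous-vs-class scan comparison.
- **`polygwas.pipeline`** — end-to-end trait runs with overlap summaries,
  the replicated simulation study, and probe/SNP/contig duplication
  reports.

A thin `polygwas` CLI (`simulate`, `transform`, `ebv`, `assoc-lr`,
`assoc-bayes`, `assoc-pls`, `call`, `compare`, `run`, `simstudy`) wraps the
library for shell pipelines; `examples/` holds one narrative script per
capability.

## Worked example

```sh
python examples/04_three_association_engines.py
```

simulates 400 probes × 228 offspring with two causal probes (h² = 0.8) and
runs all three engines:

```
significant probes per engine: {'lr': 14, 'bayes': 6, 'pls': 2}
pairwise/triple overlaps: {'bayes&lr': 4, 'bayes&pls': 2, 'lr&pls': 2, 'bayes&lr&pls': 2}
causal probes: ['AX-00000226', 'AX-00000218']
causal in the triple intersection: ['AX-00000218']
linear-scan hits: 14 probes = 12 in duplicate pairs (6 SNPs with both probes) + 2 single-probe SNPs
```

The linear scan flags the causal probes plus their duplicate partners
(the second probe of the same SNP) and linked flanking probes — genuine
associations under linkage. The Bayesian engine is the most conservative,
and probes found by all three methods concentrate on the causal SNPs.
`examples/05_continuous_vs_classes.py` shows the motivating comparison: at
intensity noise that miscalls ~half the dosages, the scan on continuous
theta recovers more causal probes than the scan on called classes.

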