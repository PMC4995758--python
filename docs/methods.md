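# Methods

This note documents the models behind `polygwas`, the defaults and why
they were chosen, what the simulator does and does not emulate, and the
numerical decisions that matter for reproducing results.

## Polysomic F1 simulator

**Meiosis model.** Strictly bivalent polysomic meiosis: at each meiosis the
`ploidy` homologs of a chromosome pair uniformly at random into `ploidy/2`
bivalents; the transmitted chromatid of a bivalent is a two-state walk over
the ordered loci that switches homolog between adjacent loci with the
Haldane recombination fraction `r = (1 - exp(-2d/100))/2` (`d` in cM, no
interference); one chromatid per bivalent is transmitted. At a single locus
this is exactly the hypergeometric gamete-dosage law
`P(k) = C(d,k)·C(p-d, p/2-k)/C(p, p/2)`. Multivalents, double reduction and
preferential pairing are deliberately excluded — this is the simplest
polysomic model, and a known limitation for taxa with appreciable double
reduction. Odd ploidy is rejected.

**Map.** Default maps place SNPs uniformly on 18 chromosomes of 100 cM
(map lengths are a stand-in; no reference lengths exist for this design).
A SNP is interrogated by two probes (same position, forward/reverse assay)
except for a `single_probe_frac = 0.15` fraction; consecutive SNPs group
into contigs of 1–3. Both probes of a SNP copy the same underlying
genotype, so duplicate probes carry identical signal — the property that
makes duplicate-pair counts a plausibility check on significant sets.

**Parents.** Per-SNP B-allele frequencies are uniform on
`allele_freq_range = (0.1, 0.9)` and homolog alleles are i.i.d. Bernoulli.
Real parents of an elite cross are not in mutation–drift equilibrium; the
uniform range is a neutral default that produces segregating markers of
all dosage classes.

**Intensities.** Log2 signals with expected theta affine in dosage over
`[-2, 2]` (equally spaced cluster centers, the diploid ±2 convention
extended to `ploidy+1` classes), mean signal strength lower for homozygous
classes (`homozygous_s_drop = 0.5` on the log2 scale), and i.i.d. Gaussian
noise `noise_sd` on each log-signal, so within-class theta sd is
`sqrt(2)·noise_sd`. The default `noise_sd = 0.25` puts neighboring cluster
centers (spacing 2/3 for a hexaploid) about 1.9 within-class sd apart —
the continuum regime the method is designed for; `noise_sd ≈ 0.05` gives
cleanly separated clusters. The generator does not emulate probe-specific
affinity differences, batch effects, or outlier samples.

**Phenotypes.** `Y_i = sqrt(1-Σπ_j)·z_i + Σ_j a_ij·c_j` with
`c_j = sqrt(π_j/(ploidy·f_j(1-f_j)))`, `a_ij` the raw (uncentered) dosage
and `f_j` the *empirical offspring* B-allele frequency (mean dosage /
ploidy); monomorphic causal probes are rejected. The scaling assumes
binomial dosage variance `ploidy·f(1-f)`; F1 dosages are sums of two
hypergeometric gametes and have smaller variance, so the realized
heritability of an F1 run sits below the nominal `Σπ_j` (typically ~0.6
when 0.78 is configured). Calibration checks therefore draw dosages
binomially, where `R²(Y ~ causal dosages) → Σπ_j` holds exactly; F1 runs
report realized, not nominal, heritability. The default study conditions
are 228 offspring, 55,825 probes, 18 chromosomes, hexaploid, heritability
0.78 over 5 causal probes (tests and examples scale the probe count down;
the statistical structure is unchanged).

**Repeated measurements.** Records
`y = α + block + plate + g_i + N(0, σ²_e)` with random block/plate
assignment per record; defaults 2 reps, 2 blocks, 4 plates,
`σ²_e = 0.5`, block/plate effects drawn with sd 0.3/0.2. With unit-scale
genetic values this gives record-level repeatability ≈ 0.6 and EBV
reliabilities ≈ 0.75 — the regime where deregression visibly matters.

**Determinism.** One seed feeds a `SeedSequence` that spawns independent
streams per stage; identical config + seed reproduces every output
bit-for-bit.

## Signal transformation

Quantile normalization maps every sample column onto the mean
order-statistic distribution (ties averaged). `theta = log2 B - log2 A`
and `s = (log2 A + log2 B)/2` elementwise; non-positive observed signals
are errors naming probe and sample, missing values propagate and all
per-probe statistics use pairwise-complete samples (no imputation). The
segregation filter removes probes with observed theta range < 2 *after*
normalization and transformation, *before* centering; centering subtracts
the per-probe mean. The multi-allelic extension
`theta_i = log2(G_i) - Σ_{j≠i} log2(G_j)` over four allele counts is
exposed as a library function; note it scales with total depth through the
summed log terms — it is provided as defined, not depth-corrected.

## Mixed model and deregression

`y = α + block + plate + g + e` with `g ~ N(0, σ²_g)`, `e ~ N(0, σ²_e)`,
samples unrelated (no kinship matrix — appropriate within a single
bi-parental F1 family, and a known simplification otherwise). REML is
profiled to the single ratio `γ = σ²_g/σ²_e`; all quantities reduce to
per-sample group sums, and the profiled criterion is minimized by bounded
scalar search on `log γ` (tolerance 1e-12, boundary `σ²_g = 0` checked
explicitly), so balanced designs match closed-form ANOVA estimators to
≤1e-6 relative error. BLUPs are `ĝ_i = γ·r_i/(1+γ·n_i)` from residual
group sums.

PEV is taken as `Var(g_i - ĝ_i) = σ²_g/(1 + γ·n_i)` with fixed effects
treated as known. The alternative — the g-block diagonal of the full
mixed-model-equation inverse — contains the non-estimable mean direction
and tends to `σ²_g/q` rather than 0 as noise vanishes, which would make
reliabilities of small designs spuriously low; under the chosen form
`Var(ebv_i) = σ²_g - PEV_i`, consistent with using EBV variances as the
PEV measure. Deregression: `r²_i = 1 - PEV_i/σ²_g`, `debv_i = ebv_i/r²_i`;
`σ²_g ≤ 0` or `PEV_i ≥ σ²_g` are errors.

## Linear engine and q-values

Per-probe OLS of the response on the centered genotype; two-sided p from
the t distribution with n-2 df; probes with (near-)zero genotype variance
are reported degenerate with p = 1 and excluded from the multiple-testing
count m (they carry no test). π₀ is estimated from the tail spectrum
`π₀(λ) = #{p > λ}/(m(1-λ))` on λ = 0.05…0.90 (step 0.05) with a cubic
polynomial extrapolated to λ → 1, clamped to (0, 1]; below m = 100 the
estimate is unstable and π₀ = 1 (the Benjamini–Hochberg limit) is used.
q-values are the π₀-scaled step-up minima; significance at q ≤ 0.01.

## Bayesian engine

All probes enter one regression; each effect has the two-component normal
mixture prior with defaults π₀ = 0.99, σ²_g0 = 0.001, σ²_g1 = 0.1. The
Beta(10,1) hyperprior is placed on the *null*-component proportion
(mean 10/11, consistent with π₀ = 0.99 a priori) and updated each sweep
from Beta(10 + #null, 1 + #effect). Component and residual variances are
sampled from flat-prior scaled inverse-χ² conditionals (each updated only
when its component holds > 2 effects; σ²_g0 is capped at σ²_g1 to prevent
label switching); both can be held fixed via configuration, which is also
how the enumeration oracle in the tests pins the model. Each probe's
(indicator, effect) pair is drawn jointly from its exact bivariate
conditional — the spike component is a narrow normal, not a point mass, so
the marginal likelihood ratio is available in closed form and the sampler
avoids the stickiness of single-move spike-and-slab updates. Default
schedule 50,000 sweeps / 10,000 burn-in / thinning 200 (single chain;
stationarity checked by a split-half ratio of the residual-variance trace).

Posterior inclusion probabilities are averaged over **every** post-burn-in
sweep; the 200 thinned samples serve diagnostics and effect summaries.
Thinning discards information, and 200 draws cannot estimate a
probability to ±0.02 — the ergodic average over 40,000 sweeps can. A
pseudo-count guard `p̂ = (count + 0.5)/(N + 1)` keeps Bayes factors finite
when a finite chain never (or always) includes a probe. The Bayes factor
is the posterior-to-prior odds of the effect component,
`BF = [p̂/(1-p̂)]/[π₁/(1-π₁)]`; significance at BF ≥ 10. The numerics run
through a numba-compiled kernel; identical inputs and seed give identical
chains.

## PLS engine

Protocol: seeded 80/20 calibration/test split (plain shuffle, no
stratification variable exists) → component count chosen on the
calibration set by 10-fold CV repeated 20 times over 1–10 latent
variables, minimizing mean RMSE (ties to fewer components) → final fit at
the chosen count → importance scoring. The core fit is the
orthogonal-scores (NIPALS) algorithm for a univariate response via
scikit-learn, X standardized by default (toggleable); per-component
coefficient increments and explained-variance weights are recovered from
the fitted weights/loadings, which also gives incremental fold predictions
from a single fit per fold. With as many components as the rank, PLS
equals OLS (verified to 1e-8).

Note on selection: CV-RMSE typically keeps improving slightly past the
true latent dimension (extra components denoise finite-sample fold
predictions), so argmin selection tends to land a component or two above
it; the dimension shows as an elbow. This is a property of argmin
selection generally, not of this implementation.

**VIM.** The importance of probe j is the explained-variance-weighted sum
of its absolute per-component regression-coefficient increments, rescaled
so the mean square over probes is 1 (the same calibration as VIP, for
which `Σ_j VIM_j² = p`). On this scale the conventional threshold 2 means
"four times the average squared importance"; as the prefiltered subset
grows the score of a causal probe saturates near
`sqrt(π_j / E[r² | kept])`, so threshold 2 selects major-effect probes
(π_j ≳ 0.15–0.2 under the default study conditions) — weaker causal probes
rank high but sit below 2. The classical VIP variant is available via
`score="vip"`. The exact normalization of the original tooling is not
recoverable, so the scale is calibrated, documented and tested rather than
matched.

## Genotype-class comparator

Nearest-center calling on theta with `ploidy+1` strictly increasing
centers: global fixed grid equally spaced on [-2, 2] (default), or an
adaptive per-probe grid over the central 95% theta span clamped to
[-2, 2] — the fairer comparator when cluster positions drift. Ties go to
the lower dosage; every sample is assigned (no outlier class —
deliberately mirroring the behavior under criticism). The association
covariate is the first-minus-second allele count `(ploidy - d) - d`, an
affine function of dosage. The comparison module pairs two scan results
probe-by-probe and labels agreement (both / continuous-only / class-only /
neither).

## Pipeline

A trait run chains normalization → theta/s → range filter → centering →
linear scan → Bayesian scan → F ≥ 4-prefiltered PLS → overlap summary,
with every intermediate table and a manifest (thresholds, seeds, input
hashes, counts) written when an output directory is given; a stage failure
aborts naming the stage. The simulation study re-simulates population and
phenotypes per replicate and counts q ≤ 0.01 probes of the linear engine
against true dosages; because linked and duplicate probes carry genuine
signal, counts exceed the causal number, and spreading a fixed h² over
more causal probes weakens per-probe power.

## Problem sizes and limitations

Tests and examples run at 200–5,000 probes and 80–228 samples with
shortened Gibbs schedules where the full 50k-sweep chain is not the thing
under test; the acceptance checks use the stated sizes (10,000 individuals
for the heritability calibration, 10⁵ gametes for the meiosis law, 100
null datasets of 5,000 probes × 228 samples for FDR control, the default
chain for the Gibbs oracle). Known limitations: no double reduction or
preferential pairing; no kinship in the mixed model; no multi-allelic
probe simulation; no GBS read-count mode (the multi-allelic theta is a
library function only); the Bayesian engine's per-sweep cost is linear in
probes × samples, so full-array runs at the default schedule are
long-running by design.
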