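"""Run all three association engines on one simulated trait.

Transforms intensities to centered theta, then runs the per-probe linear
scan (q <= 0.01), the spike-and-slab Bayesian scan (BF >= 10) and PLS on
the F >= 4 subset (VIM >= 2), and summarizes the overlap of the three
significant sets.  The Gibbs chain is shortened here to keep the example
snappy; the default schedule is 50,000 sweeps.
"""

from polygwas import bayes, pipeline, pls, simulate as sim

ds = sim.simulate_dataset(
    sim.SimulationConfig(n_probes=400, n_offspring=228, n_chromosomes=4,
                         n_causal=2, h2=0.8, noise_sd=0.2, seed=4)
)

cfg = pipeline.TraitRunConfig(
    mcmc=bayes.MCMCConfig(iterations=10_000, burn_in=2_000, thin=40, seed=1),
    pls_config=pls.PLSConfig(seed=2),
    seed=3,
)
res = pipeline.run_trait_association(ds.a_signal, ds.b_signal, ds.phenotypes, cfg)

print("significant probes per engine:", res.manifest["significant_counts"])
print("pairwise/triple overlaps:",
      {k: v for k, v in res.overlap.counts.items() if "&" in k})
triple = (res.overlap.sets["lr"] & res.overlap.sets["bayes"]
          & res.overlap.sets["pls"])
print(f"causal probes: {ds.causal_probes}")
print(f"causal in the triple intersection: {sorted(set(ds.causal_probes) & triple)}")
print("(probes sharing a SNP with a causal probe carry the same signal, so "
      "duplicate partners appear among the hits)")

contig = pipeline.summarize_contig_structure(
    sorted(res.overlap.sets["lr"]), ds.lmap
)
print(f"linear-scan hits: {contig.n_significant_probes} probes = "
      f"{contig.n_duplicate_probes} in duplicate pairs "
      f"({contig.n_snps_both_probes} SNPs with both probes) + "
      f"{contig.n_snps_one_probe} single-probe SNPs")
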