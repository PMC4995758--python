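"""Simulate a hexaploid F1 dataset and look at its structure.

Builds a scaled-down population (1,000 probes, 228 offspring) with the
structure of the full design: 18 chromosomes, two probes per SNP, at most
three SNPs per contig, dosages from polysomic meiosis, log-scale allele
intensities and a phenotype with heritability 0.78 over five causal probes.
"""

import numpy as np

from polygwas import simulate as sim

cfg = sim.SimulationConfig(n_probes=1_000, n_causal=5, h2=0.78, seed=1)
ds = sim.simulate_dataset(cfg)

d = ds.dosages.to_numpy()
print(f"dosage matrix: {ds.dosages.shape[0]} probes x {ds.dosages.shape[1]} offspring")
print(f"dosage range: {d.min()}..{d.max()} (hexaploid, 0..6)")
print(f"chromosomes: {len(ds.lmap.chromosomes)}")
per_snp = ds.lmap.to_frame().groupby("snp_id").size()
print(f"SNPs with two probes: {(per_snp == 2).sum()}, with one: {(per_snp == 1).sum()}")

# offspring allele frequency tracks the parental mid-frequency
mid = (ds.parents.dosage(0) + ds.parents.dosage(1)) / 12.0
obs = ds.dosages.mean(axis=1).to_numpy() / 6.0
print(f"corr(offspring freq, parental mid-freq) = {np.corrcoef(obs, mid)[0, 1]:.3f}")

print(f"causal probes: {ds.causal_probes}")
print(f"phenotype variance: {ds.phenotypes.var():.3f} "
      "(below 1: F1 dosages have sub-binomial variance, so realized "
      "heritability sits below the nominal 0.78)")
print(f"repeated measurements: {len(ds.records)} records "
      f"({cfg.reps} per offspring, {cfg.n_blocks} blocks, {cfg.n_plates} plates)")
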