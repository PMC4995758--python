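"""Continuous genotypes versus nearest-center genotype classes.

At high intensity noise the seven hexaploid dosage clusters merge into a
continuum; forcing each sample into a class then discards information.
This example scans the same simulated traits twice — on continuous theta
and on class-derived covariates — and aggregates recovered causal probes
over replicates (any single replicate can go either way; the advantage is
a property of the ensemble).
"""

import numpy as np
import pandas as pd

from polygwas import calling, linear, signal as sg, simulate as sim


def one_replicate(seed, noise_sd, n_probes=300, n_samples=200):
    rng = np.random.default_rng(seed)
    f = rng.uniform(0.25, 0.75, n_probes)
    dos = pd.DataFrame(
        rng.binomial(6, f[:, None], (n_probes, n_samples)),
        index=[f"p{i}" for i in range(n_probes)],
        columns=[f"S{i}" for i in range(n_samples)],
    )
    causal = list(dos.index[:3])
    y = sim.simulate_phenotypes(dos, causal, np.full(3, 0.2), seed=seed)
    a, b = sim.simulate_intensities(dos, noise_sd=noise_sd, seed=seed + 1)
    theta, _ = sg.compute_theta_s(a, b)
    calls = calling.call_nearest_cluster(theta, ploidy=6, mode="fixed")
    cont = linear.genome_scan_lr(sg.mean_center(theta), y)
    cls = linear.genome_scan_lr(sg.mean_center(calls.covariate), y)
    miscall = (calls.dosage.to_numpy() != dos.to_numpy()).mean()
    return (
        miscall,
        int(cont.loc[causal, "significant"].sum()),
        int(cls.loc[causal, "significant"].sum()),
    )


for noise in (0.05, 0.35):
    rows = [one_replicate(2_000 + s, noise) for s in range(10)]
    miscall = np.mean([r[0] for r in rows])
    cont_hits = sum(r[1] for r in rows)
    class_hits = sum(r[2] for r in rows)
    print(f"noise_sd = {noise}: mean miscall rate {miscall:.2f}; causal "
          f"recovered over 10 replicates x 3 probes: continuous {cont_hits}, "
          f"classes {class_hits}")
print("at low noise calls are exact and the two routes agree; at high noise "
      "misclassification erodes the class-based scan first")
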