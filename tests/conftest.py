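"""Shared fixtures: small simulated populations reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from polygwas import simulate as sim


@pytest.fixture(scope="session")
def small_map() -> sim.LinkageMap:
    return sim.random_linkage_map(n_probes=400, n_chromosomes=4, seed=11)


@pytest.fixture(scope="session")
def single_probe_map() -> sim.LinkageMap:
    return sim.LinkageMap(
        pd.DataFrame(
            {
                "probe_id": ["p1"],
                "chrom": ["c1"],
                "pos_cm": [0.0],
                "snp_id": ["s1"],
                "contig_id": ["g1"],
            }
        )
    )


@pytest.fixture(scope="session")
def small_population(small_map):
    """Parents + 150 offspring dosages on the 400-probe map."""
    parents = sim.simulate_parents(small_map, ploidy=6, seed=21)
    dosages = sim.simulate_offspring(parents, small_map, n_offspring=150, seed=22)
    return parents, dosages


def binomial_dosages(
    n_probes: int, n_samples: int, ploidy: int = 6,
    freq_range=(0.2, 0.8), seed: int = 0,
) -> pd.DataFrame:
    """Unlinked dosage matrix with exact binomial variance ploidy*f*(1-f)."""
    rng = np.random.default_rng(seed)
    f = rng.uniform(*freq_range, size=n_probes)
    d = rng.binomial(ploidy, f[:, None], size=(n_probes, n_samples))
    return pd.DataFrame(
        d,
        index=[f"p{i:05d}" for i in range(n_probes)],
        columns=[f"S{i:04d}" for i in range(n_samples)],
    )
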