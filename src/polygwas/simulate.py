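"""Simulation of hexaploid F1 mapping populations.

Generates everything the association pipeline consumes: a linkage map with
the probe/SNP/contig structure of a two-probe genotyping array, phased
parental genomes, F1 offspring dosages via polysomic (bivalent) meiosis,
paired allele-signal intensities on the log2 scale, and phenotypes with a
prescribed heritability partitioned over a set of causal probes.

The meiosis model is strictly bivalent: at each meiosis the ``ploidy``
homologs of a chromosome pair at random into ``ploidy/2`` bivalents, each
bivalent recombines under the Haldane map function (no interference), and
one recombinant chromatid per bivalent is transmitted.  There is no double
reduction and no preferential pairing.  At a single locus this reduces to
the hypergeometric gamete-dosage law
``P(k) = C(d,k) C(p-d, p/2-k) / C(p, p/2)`` for a parent of dosage ``d``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LinkageMap",
    "ParentalGenome",
    "SimulationConfig",
    "SimulatedDataset",
    "random_linkage_map",
    "simulate_parents",
    "simulate_gametes",
    "simulate_offspring",
    "simulate_intensities",
    "simulate_phenotypes",
    "choose_causal_probes",
    "simulate_repeated_measurements",
    "simulate_dataset",
]


# ---------------------------------------------------------------------------
# linkage map

@dataclass(frozen=True)
class LinkageMap:
    """Probe-level genetic map.

    ``table`` has one row per probe with columns ``probe_id``, ``chrom``,
    ``pos_cm``, ``snp_id`` and ``contig_id``.  Two probes (forward and
    reverse strand assay of the same SNP) may share a ``snp_id`` and then
    sit at the same cM position; at most three SNPs share a ``contig_id``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"probe_id", "chrom", "pos_cm", "snp_id", "contig_id"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"linkage map is missing columns: {sorted(missing)}")
        if self.table["probe_id"].duplicated().any():
            raise ValueError("duplicate probe_id in linkage map")
        if (self.table["pos_cm"] < 0).any():
            raise ValueError("negative cM position in linkage map")
        for _, sub in self.table.groupby("chrom", sort=False):
            if not sub["pos_cm"].is_monotonic_increasing:
                raise ValueError("positions must be sorted within chromosome")
        # a probe maps to one chromosome by construction (one row per probe);
        # a SNP must not straddle chromosomes
        if (self.table.groupby("snp_id")["chrom"].nunique() > 1).any():
            raise ValueError("snp_id spans more than one chromosome")
        per_contig = self.table.groupby("contig_id")["snp_id"].nunique()
        if (per_contig > 3).any():
            bad = per_contig[per_contig > 3].index[:5].tolist()
            raise ValueError(f"contigs with more than three SNPs: {bad}")

    @property
    def probe_ids(self) -> np.ndarray:
        return self.table["probe_id"].to_numpy()

    @property
    def n_probes(self) -> int:
        return len(self.table)

    @property
    def chromosomes(self) -> list:
        return list(pd.unique(self.table["chrom"]))

    def chromosome_slices(self) -> list[tuple[object, np.ndarray]]:
        """(chrom label, integer row indices) per chromosome, map order."""
        out = []
        codes = self.table["chrom"].to_numpy()
        for chrom in self.chromosomes:
            out.append((chrom, np.flatnonzero(codes == chrom)))
        return out

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()


def random_linkage_map(
    n_probes: int = 55_825,
    n_chromosomes: int = 18,
    chrom_length_cm: float = 100.0,
    single_probe_frac: float = 0.15,
    seed: int | np.random.Generator = 0,
) -> LinkageMap:
    """Draw a map with the array's probe/SNP/contig structure.

    SNP positions are uniform on ``n_chromosomes`` chromosomes of
    ``chrom_length_cm``; a fraction ``single_probe_frac`` of SNPs is
    interrogated by one probe, the rest by two probes at the same position;
    consecutive SNPs on a chromosome are grouped into contigs of 1-3 SNPs.
    """
    rng = np.random.default_rng(seed)
    if n_probes < 1:
        raise ValueError("n_probes must be positive")
    # decide how many SNPs give n_probes in expectation, then trim exactly
    snp_probe_counts: list[int] = []
    total = 0
    while total < n_probes:
        k = 1 if rng.random() < single_probe_frac else 2
        if total + k > n_probes:
            k = 1
        snp_probe_counts.append(k)
        total += k
    n_snps = len(snp_probe_counts)

    chrom = rng.integers(0, n_chromosomes, size=n_snps)
    pos = rng.uniform(0.0, chrom_length_cm, size=n_snps)
    order = np.lexsort((pos, chrom))
    chrom, pos = chrom[order], pos[order]
    counts = np.asarray(snp_probe_counts)[order]

    # contigs: runs of 1-3 consecutive SNPs within a chromosome
    contig = np.empty(n_snps, dtype=np.int64)
    cid = 0
    i = 0
    while i < n_snps:
        size = int(rng.integers(1, 4))
        j = i
        while j < n_snps and j - i < size and chrom[j] == chrom[i]:
            contig[j] = cid
            j += 1
        cid += 1
        i = j

    rows = {
        "probe_id": [],
        "chrom": [],
        "pos_cm": [],
        "snp_id": [],
        "contig_id": [],
    }
    probe_no = 0
    for s in range(n_snps):
        for _ in range(counts[s]):
            rows["probe_id"].append(f"AX-{probe_no:08d}")
            rows["chrom"].append(f"chr{chrom[s] + 1:02d}")
            rows["pos_cm"].append(float(pos[s]))
            rows["snp_id"].append(f"SNP-{s:07d}")
            rows["contig_id"].append(f"CTG-{contig[s]:07d}")
            probe_no += 1
    return LinkageMap(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# parents

@dataclass(frozen=True)
class ParentalGenome:
    """Two phased parents: boolean B-allele per homolog per probe."""

    haplotypes: tuple[np.ndarray, np.ndarray]  # each (ploidy, n_probes) bool
    probe_ids: np.ndarray

    def __post_init__(self) -> None:
        h1, h2 = self.haplotypes
        if h1.shape != h2.shape:
            raise ValueError("parents must have identical shapes")
        if h1.shape[0] % 2 != 0:
            raise ValueError(
                "odd ploidy is not supported: bivalent meiosis requires an even "
                "number of homologs"
            )
        if h1.shape[1] != len(self.probe_ids):
            raise ValueError("haplotype width does not match probe_ids")

    @property
    def ploidy(self) -> int:
        return self.haplotypes[0].shape[0]

    @property
    def n_probes(self) -> int:
        return self.haplotypes[0].shape[1]

    def dosage(self, parent: int) -> np.ndarray:
        """B-allele dosage per probe for parent 0 or 1."""
        return self.haplotypes[parent].sum(axis=0).astype(np.int64)


def simulate_parents(
    lmap: LinkageMap,
    ploidy: int = 6,
    allele_freq_range: tuple[float, float] = (0.1, 0.9),
    seed: int | np.random.Generator = 0,
) -> ParentalGenome:
    """Draw two phased parents with per-SNP B-allele frequencies.

    A frequency is drawn per SNP from ``allele_freq_range`` and every
    homolog allele (both parents) is Bernoulli at that frequency; both
    probes of a SNP copy the same underlying SNP alleles, so duplicate
    probes carry identical genotypes as on the real array.
    """
    if ploidy % 2 != 0:
        raise ValueError("odd ploidy is not supported by the bivalent meiosis model")
    lo, hi = allele_freq_range
    if not (0.0 <= lo <= hi <= 1.0):
        raise ValueError("allele_freq_range must satisfy 0 <= lo <= hi <= 1")
    rng = np.random.default_rng(seed)

    snp_ids = lmap.table["snp_id"].to_numpy()
    uniq, inverse = np.unique(snp_ids, return_inverse=True)
    freq = rng.uniform(lo, hi, size=len(uniq))
    haps = []
    for _parent in range(2):
        snp_alleles = rng.random((ploidy, len(uniq))) < freq[None, :]
        haps.append(snp_alleles[:, inverse])
    return ParentalGenome((haps[0], haps[1]), lmap.probe_ids.copy())


# ---------------------------------------------------------------------------
# meiosis

def _haldane_recomb_fraction(d_cm: np.ndarray) -> np.ndarray:
    """Recombination fraction between adjacent loci, Haldane map function."""
    return 0.5 * (1.0 - np.exp(-2.0 * d_cm / 100.0))


def simulate_gametes(
    haplotypes: np.ndarray,
    lmap: LinkageMap,
    n_gametes: int,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Simulate gamete dosages for one parent.

    Parameters
    ----------
    haplotypes : (ploidy, n_probes) boolean array of phased parent alleles.
    lmap : map providing chromosome membership and cM positions.
    n_gametes : number of independent meioses.

    Returns
    -------
    (n_gametes, n_probes) int8 array of gamete B-allele dosages, each value
    in ``[0, ploidy/2]``.
    """
    rng = np.random.default_rng(seed)
    ploidy, n_probes = haplotypes.shape
    if ploidy % 2 != 0:
        raise ValueError("bivalent meiosis requires even ploidy")
    if n_probes != lmap.n_probes:
        raise ValueError("haplotypes do not match the linkage map probe count")
    n_biv = ploidy // 2
    out = np.zeros((n_gametes, n_probes), dtype=np.int8)

    for _chrom, idx in lmap.chromosome_slices():
        m = len(idx)
        pos = lmap.table["pos_cm"].to_numpy()[idx]
        hap = haplotypes[:, idx]  # (ploidy, m)

        # random bivalent pairing: a permutation of homologs, consecutive pairs
        perm = np.argsort(rng.random((n_gametes, ploidy)), axis=1)
        pairs = perm.reshape(n_gametes, n_biv, 2)

        # chromatid walk per bivalent: state 0/1 = which homolog of the pair,
        # switching between adjacent loci with the Haldane fraction
        state = np.empty((n_gametes, n_biv, m), dtype=np.int8)
        state[:, :, 0] = rng.integers(0, 2, size=(n_gametes, n_biv))
        if m > 1:
            r = _haldane_recomb_fraction(np.diff(pos))
            switches = rng.random((n_gametes, n_biv, m - 1)) < r[None, None, :]
            cum = np.cumsum(switches, axis=2)
            state[:, :, 1:] = (state[:, :, :1] + cum) % 2

        # homolog index per (gamete, bivalent, locus), then its allele
        homolog = np.take_along_axis(pairs, state.astype(np.int64), axis=2)
        alleles = hap[homolog, np.arange(m)[None, None, :]]
        out[:, idx] = alleles.sum(axis=1, dtype=np.int8)
    return out


def simulate_offspring(
    parents: ParentalGenome,
    lmap: LinkageMap,
    n_offspring: int = 228,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """F1 dosage matrix: one gamete from each parent per offspring.

    Returns a probes x samples DataFrame of integer dosages in
    ``[0, ploidy]`` with sample columns ``S0001`` ...
    """
    if n_offspring <= 0:
        raise ValueError("n_offspring must be positive")
    rng = np.random.default_rng(seed)
    g1 = simulate_gametes(parents.haplotypes[0], lmap, n_offspring, rng)
    g2 = simulate_gametes(parents.haplotypes[1], lmap, n_offspring, rng)
    dosage = (g1 + g2).T.astype(np.int8)
    samples = [f"S{i + 1:04d}" for i in range(n_offspring)]
    return pd.DataFrame(dosage, index=pd.Index(parents.probe_ids, name="probe_id"),
                        columns=samples)


# ---------------------------------------------------------------------------
# intensities

def simulate_intensities(
    dosages: pd.DataFrame,
    ploidy: int = 6,
    noise_sd: float = 0.25,
    signal_level: float = 12.0,
    theta_span: float = 4.0,
    homozygous_s_drop: float = 0.5,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired A/B signal intensities for a dosage matrix.

    The expected log2-ratio theta is affine in dosage, spanning
    ``[-theta_span/2, theta_span/2]`` (the diploid convention of clusters
    near -2, 0, +2 extended to ``ploidy+1`` equally spaced centers).  The
    mean log2 signal strength s is ``signal_level`` for balanced
    heterozygotes and drops linearly to ``signal_level - homozygous_s_drop``
    for the homozygous classes, reproducing the lower s of homozygotes on
    the log scale.  Independent Gaussian noise of sd ``noise_sd`` is added
    to each log2 signal, so within-class theta has sd ``sqrt(2)*noise_sd``;
    at the default noise the seven hexaploid classes merge into a continuum.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    d = dosages.to_numpy(dtype=np.float64)
    theta_mean = theta_span * (d / ploidy - 0.5)
    s_mean = signal_level - homozygous_s_drop * np.abs(theta_mean) / (theta_span / 2)
    log2a = s_mean - theta_mean / 2.0 + rng.normal(0.0, noise_sd, d.shape)
    log2b = s_mean + theta_mean / 2.0 + rng.normal(0.0, noise_sd, d.shape)
    a = pd.DataFrame(np.exp2(log2a), index=dosages.index, columns=dosages.columns)
    b = pd.DataFrame(np.exp2(log2b), index=dosages.index, columns=dosages.columns)
    return a, b


# ---------------------------------------------------------------------------
# phenotypes

def simulate_phenotypes(
    dosages: pd.DataFrame,
    causal_probes: list[str] | np.ndarray,
    pi: np.ndarray,
    ploidy: int = 6,
    seed: int | np.random.Generator = 0,
) -> pd.Series:
    """Phenotypes with heritability partitioned over causal probes.

    ``Y_i = sqrt(1 - sum(pi)) * N(0,1)
    + sum_j a_ij * sqrt(pi_j / (ploidy * f_j * (1 - f_j)))``
    where ``a_ij`` is the raw dosage and ``f_j`` the empirical B-allele
    frequency (mean dosage / ploidy) of causal probe ``j``.  With dosages
    of binomial variance the fraction of phenotypic variance explained by
    the causal dosages equals ``sum(pi)``.
    """
    pi = np.asarray(pi, dtype=float)
    causal_probes = list(causal_probes)
    if len(pi) != len(causal_probes):
        raise ValueError("pi must have one entry per causal probe")
    if (pi < 0).any() or pi.sum() > 1.0 + 1e-12:
        raise ValueError("pi must be non-negative with sum <= 1")
    missing = [p for p in causal_probes if p not in dosages.index]
    if missing:
        raise KeyError(f"causal probes not in dosage matrix: {missing[:5]}")
    rng = np.random.default_rng(seed)

    a = dosages.loc[causal_probes].to_numpy(dtype=np.float64)  # (k, n)
    f = a.mean(axis=1) / ploidy
    if np.any((f <= 0.0) | (f >= 1.0)):
        bad = [causal_probes[i] for i in np.flatnonzero((f <= 0) | (f >= 1))]
        raise ValueError(
            f"monomorphic causal probe(s) {bad[:5]}: allele frequency in {{0,1}} "
            "makes the effect-size scaling undefined"
        )
    coef = np.sqrt(pi / (ploidy * f * (1.0 - f)))
    n = a.shape[1]
    y = np.sqrt(1.0 - pi.sum()) * rng.standard_normal(n) + coef @ a
    return pd.Series(y, index=dosages.columns, name="phenotype")


def choose_causal_probes(
    dosages: pd.DataFrame,
    n_causal: int,
    h2: float,
    ploidy: int = 6,
    seed: int | np.random.Generator = 0,
) -> tuple[list[str], np.ndarray]:
    """Pick polymorphic causal probes and split ``h2`` equally among them."""
    if not 2 <= n_causal or n_causal > dosages.shape[0]:
        raise ValueError("n_causal out of range")
    rng = np.random.default_rng(seed)
    f = dosages.mean(axis=1).to_numpy() / ploidy
    eligible = np.flatnonzero((f > 0.02) & (f < 0.98))
    if len(eligible) < n_causal:
        raise ValueError("not enough polymorphic probes to choose causal set")
    pick = rng.choice(eligible, size=n_causal, replace=False)
    probes = dosages.index.to_numpy()[pick].tolist()
    pi = np.full(n_causal, h2 / n_causal)
    return probes, pi


# ---------------------------------------------------------------------------
# repeated measurements (fixture for the mixed model)

def simulate_repeated_measurements(
    genetic_values: pd.Series,
    n_blocks: int = 2,
    n_plates: int = 4,
    sigma2_e: float = 1.0,
    block_effects: np.ndarray | None = None,
    plate_effects: np.ndarray | None = None,
    reps: int = 2,
    mean: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Repeated phenotype records with block and plate fixed effects.

    Each sample is measured ``reps`` times; every record gets a random block
    and plate assignment, value ``mean + block + plate + g_i + N(0, sigma2_e)``.
    Returns long-format rows (sample_id, block, plate, value).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if sigma2_e < 0:
        raise ValueError("sigma2_e must be non-negative")
    rng = np.random.default_rng(seed)
    if block_effects is None:
        block_effects = np.zeros(n_blocks)
    if plate_effects is None:
        plate_effects = np.zeros(n_plates)
    block_effects = np.asarray(block_effects, dtype=float)
    plate_effects = np.asarray(plate_effects, dtype=float)
    if len(block_effects) != n_blocks or len(plate_effects) != n_plates:
        raise ValueError("effect vectors must match n_blocks / n_plates")

    n = len(genetic_values)
    total = n * reps
    sample_id = np.repeat(genetic_values.index.to_numpy(), reps)
    g = np.repeat(genetic_values.to_numpy(dtype=float), reps)
    block = rng.integers(0, n_blocks, size=total)
    plate = rng.integers(0, n_plates, size=total)
    noise = rng.normal(0.0, np.sqrt(sigma2_e), size=total) if sigma2_e > 0 else 0.0
    value = mean + block_effects[block] + plate_effects[plate] + g + noise
    return pd.DataFrame(
        {
            "sample_id": sample_id,
            "block": [f"B{b + 1}" for b in block],
            "plate": [f"P{p + 1}" for p in plate],
            "value": value,
        }
    )


# ---------------------------------------------------------------------------
# full datasets

@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a full synthetic study.

    Defaults mirror the real experiment: 228 F1 offspring, 55,825 probes on
    18 chromosomes, hexaploid, heritability 0.78 split over 5 causal probes,
    intensity noise in the continuum regime.
    """

    n_offspring: int = 228
    n_probes: int = 55_825
    n_chromosomes: int = 18
    ploidy: int = 6
    n_causal: int = 5
    h2: float = 0.78
    pi: tuple[float, ...] | None = None
    noise_sd: float = 0.25
    allele_freq_range: tuple[float, float] = (0.1, 0.9)
    chrom_length_cm: float = 100.0
    single_probe_frac: float = 0.15
    # repeated-measurement layer feeding the mixed model
    reps: int = 2
    n_blocks: int = 2
    n_plates: int = 4
    sigma2_e_records: float = 0.5
    block_effect_sd: float = 0.3
    plate_effect_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not (2 <= self.n_causal <= 10):
            raise ValueError("n_causal must be in [2, 10]")
        if self.pi is not None:
            if len(self.pi) != self.n_causal:
                raise ValueError("pi must have n_causal entries")
            if sum(self.pi) > 1.0 + 1e-12:
                raise ValueError("sum(pi) must be <= 1")
        elif not 0.0 <= self.h2 <= 1.0:
            raise ValueError("h2 must be in [0, 1]")

    @property
    def explained_variances(self) -> np.ndarray:
        if self.pi is not None:
            return np.asarray(self.pi, dtype=float)
        return np.full(self.n_causal, self.h2 / self.n_causal)


@dataclass(frozen=True)
class SimulatedDataset:
    """Bundle of everything one simulated study produces."""

    config: SimulationConfig
    lmap: LinkageMap
    parents: ParentalGenome
    dosages: pd.DataFrame
    a_signal: pd.DataFrame
    b_signal: pd.DataFrame
    causal_probes: list[str]
    pi: np.ndarray
    phenotypes: pd.Series  # per-sample genetic values (the trait signal)
    records: pd.DataFrame  # repeated measurements with block/plate factors


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Run the whole generator under one seed; bit-reproducible."""
    root = np.random.SeedSequence(config.seed)
    seeds = root.spawn(8)
    lmap = random_linkage_map(
        config.n_probes,
        config.n_chromosomes,
        config.chrom_length_cm,
        config.single_probe_frac,
        np.random.default_rng(seeds[0]),
    )
    parents = simulate_parents(
        lmap, config.ploidy, config.allele_freq_range, np.random.default_rng(seeds[1])
    )
    dosages = simulate_offspring(
        parents, lmap, config.n_offspring, np.random.default_rng(seeds[2])
    )
    a, b = simulate_intensities(
        dosages, config.ploidy, config.noise_sd, seed=np.random.default_rng(seeds[3])
    )
    causal, pi = choose_causal_probes(
        dosages, config.n_causal, config.h2, config.ploidy,
        np.random.default_rng(seeds[4]),
    )
    if config.pi is not None:
        pi = np.asarray(config.pi, dtype=float)
    phen = simulate_phenotypes(
        dosages, causal, pi, config.ploidy, np.random.default_rng(seeds[5])
    )
    eff_rng = np.random.default_rng(seeds[6])
    records = simulate_repeated_measurements(
        phen,
        n_blocks=config.n_blocks,
        n_plates=config.n_plates,
        sigma2_e=config.sigma2_e_records,
        block_effects=eff_rng.normal(0, config.block_effect_sd, config.n_blocks),
        plate_effects=eff_rng.normal(0, config.plate_effect_sd, config.n_plates),
        reps=config.reps,
        seed=np.random.default_rng(seeds[7]),
    )
    return SimulatedDataset(
        config, lmap, parents, dosages, a, b, causal, pi, phen, records
    )


def write_dataset(ds: SimulatedDataset, out_dir) -> None:
    """Write the standard TSV/CSV files for a simulated dataset."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds.a_signal.to_csv(out / "A.tsv", sep="\t")
    ds.b_signal.to_csv(out / "B.tsv", sep="\t")
    ds.dosages.to_csv(out / "dosages.tsv", sep="\t")
    ds.lmap.to_frame().to_csv(out / "map.tsv", sep="\t", index=False)
    pd.DataFrame({"probe_id": ds.causal_probes, "pi": ds.pi}).to_csv(
        out / "causal_probes.tsv", sep="\t", index=False
    )
    ds.records.to_csv(out / "phenotypes.csv", index=False)
    ds.phenotypes.rename("value").rename_axis("sample_id").reset_index().to_csv(
        out / "genetic_values.csv", index=False
    )
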