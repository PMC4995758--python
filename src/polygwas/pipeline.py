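"""End-to-end orchestration: trait runs, the simulation study, summaries.

``run_trait_association`` chains signal transformation, the three
association engines and the overlap summary on one dataset;
``run_simulation_study`` repeats the genotype + phenotype simulation and
counts linear-scan discoveries across replicates (the power/false-positive
envelope of the design); ``summarize_contig_structure`` reports how
significant probes distribute over two-probe SNPs and multi-SNP contigs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from . import signal as sigmod
from . import bayes, linear, pls
from .simulate import (
    LinkageMap,
    SimulationConfig,
    SimulatedDataset,
    simulate_dataset,
    choose_causal_probes,
    simulate_offspring,
    simulate_parents,
    simulate_phenotypes,
    random_linkage_map,
)

__all__ = [
    "TraitRunConfig",
    "TraitRunResult",
    "OverlapSummary",
    "ContigSummary",
    "overlap_summary",
    "run_trait_association",
    "run_simulation_study",
    "summarize_contig_structure",
]


@dataclass(frozen=True)
class OverlapSummary:
    """Significant-set sizes and all intersection counts across methods."""

    sets: dict
    counts: dict

    def check_inclusion_exclusion(self) -> bool:
        """Union size equals the inclusion-exclusion alternating sum."""
        names = sorted(self.sets)
        union = set().union(*(self.sets[n] for n in names)) if names else set()
        total = 0
        for r in range(1, len(names) + 1):
            for combo in combinations(names, r):
                inter = set(self.sets[combo[0]])
                for n in combo[1:]:
                    inter &= set(self.sets[n])
                total += (-1) ** (r + 1) * len(inter)
        return total == len(union)


def overlap_summary(sets: dict) -> OverlapSummary:
    """Pairwise and higher-order intersection counts of significant sets."""
    sets = {k: set(v) for k, v in sets.items()}
    counts = {k: len(v) for k, v in sets.items()}
    names = sorted(sets)
    for r in range(2, len(names) + 1):
        for combo in combinations(names, r):
            inter = set(sets[combo[0]])
            for n in combo[1:]:
                inter &= sets[n]
            counts["&".join(combo)] = len(inter)
    return OverlapSummary(sets=sets, counts=counts)


@dataclass(frozen=True)
class TraitRunConfig:
    """Thresholds and options for a full trait association run."""

    q_threshold: float = 0.01
    bf_threshold: float = 10.0
    f_min: float = 4.0
    min_theta_range: float = 2.0
    quantile_normalize: bool = True
    ploidy: int = 6
    run_bayes: bool = True
    run_pls: bool = True
    mcmc: bayes.MCMCConfig = field(default_factory=bayes.MCMCConfig)
    prior: bayes.MixturePriorConfig = field(default_factory=bayes.MixturePriorConfig)
    pls_config: pls.PLSConfig = field(default_factory=pls.PLSConfig)
    seed: int = 0


@dataclass
class TraitRunResult:
    """All per-stage outputs of one trait association run."""

    lr: pd.DataFrame
    bayes: bayes.BayesScanResult | None
    pls: pls.PLSResult | None
    overlap: OverlapSummary
    filter_report: pd.DataFrame
    genotypes: pd.DataFrame  # centered theta actually used for association
    manifest: dict


def _hash_frame(df: pd.DataFrame) -> str:
    h = hashlib.sha256()
    h.update(pd.util.hash_pandas_object(df, index=True).to_numpy().tobytes())
    return h.hexdigest()[:16]


def run_trait_association(
    a_signal: pd.DataFrame,
    b_signal: pd.DataFrame,
    y: pd.Series,
    config: TraitRunConfig | None = None,
    out_dir: str | Path | None = None,
) -> TraitRunResult:
    """Transform intensities and run the three association engines.

    ``y`` is the per-sample response (DEBVs, or simulated phenotypes).
    Stages: optional quantile normalization -> theta/s -> theta-range filter
    -> mean-centering -> linear scan with q-values -> spike-and-slab scan ->
    F-prefiltered PLS -> overlap summary.  When ``out_dir`` is given every
    intermediate table plus a manifest (config, seeds, input hashes) is
    written there.
    """
    config = config or TraitRunConfig()
    stage = "signal_transform"
    try:
        a, b = a_signal, b_signal
        if config.quantile_normalize:
            a = sigmod.quantile_normalize(a)
            b = sigmod.quantile_normalize(b)
        theta, _s = sigmod.compute_theta_s(a, b)
        theta, report = sigmod.filter_by_theta_range(theta, config.min_theta_range)
        x = sigmod.mean_center(theta)

        stage = "assoc_linear"
        lr = linear.genome_scan_lr(x, y, q_threshold=config.q_threshold)
        sets = {"lr": set(lr.index[lr["significant"]])}

        bayes_res = None
        if config.run_bayes:
            stage = "assoc_bayes"
            bayes_res = bayes.gibbs_sample(
                x, y, config.prior, config.mcmc, config.bf_threshold
            )
            sets["bayes"] = set(
                bayes.select_significant_bf(bayes_res, config.bf_threshold)
            )

        pls_res = None
        if config.run_pls:
            stage = "assoc_pls"
            keep = linear.prefilter_by_f(lr, config.f_min)
            if len(keep) > 0:
                pls_res = pls.run_plsr_association(
                    x.loc[keep], y, config.pls_config
                )
                sets["pls"] = set(pls_res.significant)
            else:
                sets["pls"] = set()
    except Exception as exc:
        raise RuntimeError(f"trait association failed at stage {stage!r}") from exc

    overlap = overlap_summary(sets)
    manifest = {
        "config": {
            "q_threshold": config.q_threshold,
            "bf_threshold": config.bf_threshold,
            "f_min": config.f_min,
            "min_theta_range": config.min_theta_range,
            "quantile_normalize": config.quantile_normalize,
            "seed": config.seed,
            "mcmc": {
                "iterations": config.mcmc.iterations,
                "burn_in": config.mcmc.burn_in,
                "thin": config.mcmc.thin,
                "seed": config.mcmc.seed,
            },
        },
        "inputs": {"A": _hash_frame(a_signal), "B": _hash_frame(b_signal)},
        "n_probes_input": int(a_signal.shape[0]),
        "n_probes_retained": int(x.shape[0]),
        "n_samples": int(a_signal.shape[1]),
        "significant_counts": {k: len(v) for k, v in sets.items()},
    }
    result = TraitRunResult(
        lr=lr, bayes=bayes_res, pls=pls_res, overlap=overlap,
        filter_report=report, genotypes=x, manifest=manifest,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        lr.rename_axis("probe_id").to_csv(out / "lr_results.tsv", sep="\t")
        report.rename_axis("probe_id").to_csv(out / "filter_report.tsv", sep="\t")
        if bayes_res is not None:
            bayes_res.table.rename_axis("probe_id").to_csv(
                out / "bayes_results.tsv", sep="\t"
            )
            bayes_res.traces.to_csv(out / "bayes_diagnostics.tsv", sep="\t",
                                    index=False)
        if pls_res is not None:
            pd.DataFrame(
                {"vim": pls_res.vim,
                 "significant": pls_res.vim >= config.pls_config.vim_threshold}
            ).rename_axis("probe_id").to_csv(out / "pls_results.tsv", sep="\t")
            pls_res.cv_table.to_csv(out / "cv_table.tsv", sep="\t", index=False)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return result


def run_simulation_study(
    n_causal_grid=range(2, 11),
    replicates: int = 100,
    h2: float = 0.78,
    n_offspring: int = 228,
    n_probes: int = 55_825,
    n_chromosomes: int = 18,
    ploidy: int = 6,
    q_threshold: float = 0.01,
    seed: int = 0,
) -> pd.DataFrame:
    """Replicate the validation simulation: counts of q-significant probes.

    For each causal-probe count and replicate, a fresh F1 population is
    simulated, phenotypes are generated with total heritability ``h2``
    split equally over the causal probes, and the linear scan on the true
    (centered) dosages records how many probes reach ``q <= q_threshold``.
    Returns one row per (n_causal, replicate) with the count and the number
    of causal probes recovered.
    """
    root = np.random.SeedSequence(seed)
    rows = []
    for n_causal in n_causal_grid:
        for rep in range(replicates):
            sseq = root.spawn(1)[0]
            rng = np.random.default_rng(sseq)
            lmap = random_linkage_map(
                n_probes, n_chromosomes, seed=rng
            )
            parents = simulate_parents(lmap, ploidy, seed=rng)
            dosages = simulate_offspring(parents, lmap, n_offspring, seed=rng)
            if h2 > 0:
                causal, pi = choose_causal_probes(
                    dosages, n_causal, h2, ploidy, seed=rng
                )
            else:
                causal, pi = choose_causal_probes(
                    dosages, n_causal, 0.0, ploidy, seed=rng
                )
            y = simulate_phenotypes(dosages, causal, pi, ploidy, seed=rng)
            x = dosages.astype(np.float64)
            x = x.sub(x.mean(axis=1), axis=0)
            scan = linear.genome_scan_lr(x, y, q_threshold=q_threshold)
            sig = set(scan.index[scan["significant"]])
            rows.append(
                {
                    "n_causal": int(n_causal),
                    "replicate": rep,
                    "h2": h2,
                    "n_significant": len(sig),
                    "n_causal_recovered": len(sig & set(causal)),
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ContigSummary:
    """Probe/SNP duplication and contig multiplicity of significant calls."""

    n_significant_probes: int
    n_snps_both_probes: int  # SNPs with both of their two probes significant
    n_snps_one_probe: int
    contig_multiplicity: pd.Series  # histogram: #significant SNPs per contig

    @property
    def n_duplicate_probes(self) -> int:
        return 2 * self.n_snps_both_probes


def summarize_contig_structure(
    significant_probes, lmap: LinkageMap
) -> ContigSummary:
    """Count duplicate-probe SNPs and per-contig significant-SNP multiplicity."""
    sig = list(significant_probes)
    table = lmap.to_frame().set_index("probe_id")
    missing = [p for p in sig if p not in table.index]
    if missing:
        raise KeyError(f"significant probes missing from map: {missing[:5]}")
    if not sig:
        return ContigSummary(0, 0, 0, pd.Series(dtype=int))
    sub = table.loc[sig]
    probes_per_snp = table.groupby("snp_id").size()
    sig_per_snp = sub.groupby("snp_id").size()
    both = int(((sig_per_snp == 2) & (probes_per_snp.loc[sig_per_snp.index] == 2)).sum())
    one = int((sig_per_snp == 1).sum())
    snp_contig = table.drop_duplicates("snp_id").set_index("snp_id")["contig_id"]
    contig_counts = sig_per_snp.index.map(snp_contig).value_counts()
    multiplicity = contig_counts.value_counts().sort_index()
    multiplicity.index.name = "snps_per_contig"
    return ContigSummary(
        n_significant_probes=len(sig),
        n_snps_both_probes=both,
        n_snps_one_probe=one,
        contig_multiplicity=multiplicity,
    )
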