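"""Simulator unit and property tests: meiosis law, calibration, determinism."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from polygwas import simulate as sim
from polygwas.breeding import fit_mixed_model

from conftest import binomial_dosages


class TestLinkageMap:
    def test_structure_invariants(self, small_map):
        t = small_map.to_frame()
        assert (t["pos_cm"] >= 0).all()
        for _, sub in t.groupby("chrom"):
            assert sub["pos_cm"].is_monotonic_increasing
        assert (t.groupby("contig_id")["snp_id"].nunique() <= 3).all()
        # two probes of one SNP sit at the same position
        per_snp = t.groupby("snp_id")["pos_cm"].nunique()
        assert (per_snp == 1).all()

    def test_rejects_contig_overload(self):
        df = pd.DataFrame(
            {
                "probe_id": [f"p{i}" for i in range(4)],
                "chrom": ["c1"] * 4,
                "pos_cm": [0.0, 1.0, 2.0, 3.0],
                "snp_id": [f"s{i}" for i in range(4)],
                "contig_id": ["g1"] * 4,
            }
        )
        with pytest.raises(ValueError, match="three SNPs"):
            sim.LinkageMap(df)

    def test_rejects_unsorted_positions(self):
        df = pd.DataFrame(
            {
                "probe_id": ["p1", "p2"],
                "chrom": ["c1", "c1"],
                "pos_cm": [5.0, 1.0],
                "snp_id": ["s1", "s2"],
                "contig_id": ["g1", "g2"],
            }
        )
        with pytest.raises(ValueError, match="sorted"):
            sim.LinkageMap(df)


class TestParents:
    @pytest.mark.parametrize("freq,expected", [(1.0, 6), (0.0, 0)])
    def test_degenerate_frequency(self, small_map, freq, expected):
        parents = sim.simulate_parents(small_map, 6, (freq, freq), seed=1)
        assert (parents.dosage(0) == expected).all()
        assert (parents.dosage(1) == expected).all()

    def test_balanced_frequency_mean_dosage(self):
        lmap = sim.random_linkage_map(20_000, 10, seed=3)
        parents = sim.simulate_parents(lmap, 6, (0.5, 0.5), seed=4)
        d = parents.dosage(0)
        # mean of Binomial(6, 0.5) per probe is 3; MC standard error on the mean
        se = math.sqrt(6 * 0.25 / len(d))
        assert abs(d.mean() - 3.0) < 3 * se

    def test_odd_ploidy_rejected(self, small_map):
        with pytest.raises(ValueError, match="odd ploidy"):
            sim.simulate_parents(small_map, 5, seed=0)


class TestMeiosis:
    def test_fixed_parent_transmits_half(self, single_probe_map):
        hap = np.ones((6, 1), dtype=bool)
        g = sim.simulate_gametes(hap, single_probe_map, 500, seed=0)
        assert (g == 3).all()

    def test_triplex_gamete_law_matches_hypergeometric(self, single_probe_map):
        # P(k) = C(3,k) C(3,3-k) / C(6,3) = (1, 9, 9, 1) / 20
        hap = np.zeros((6, 1), dtype=bool)
        hap[:3, 0] = True
        n = 100_000
        g = sim.simulate_gametes(hap, single_probe_map, n, seed=42)[:, 0]
        observed = np.bincount(g, minlength=4)
        expected = n * np.array([1, 9, 9, 1]) / 20.0
        chi2 = ((observed - expected) ** 2 / expected).sum()
        assert stats.chi2.sf(chi2, df=3) > 0.001

    @pytest.mark.parametrize("dosage", range(7))
    def test_gamete_law_all_dosages(self, single_probe_map, dosage):
        hap = np.zeros((6, 1), dtype=bool)
        hap[:dosage, 0] = True
        n = 20_000
        g = sim.simulate_gametes(hap, single_probe_map, n, seed=dosage)[:, 0]
        observed = np.bincount(g, minlength=4)
        expected = n * np.array(
            [stats.hypergeom.pmf(k, 6, dosage, 3) for k in range(4)]
        )
        keep = expected > 0
        assert observed[~keep].sum() == 0
        if keep.sum() > 1:
            chi2 = ((observed[keep] - expected[keep]) ** 2 / expected[keep]).sum()
            assert stats.chi2.sf(chi2, df=keep.sum() - 1) > 0.001

    def test_zero_distance_probes_never_recombine(self):
        lmap = sim.LinkageMap(
            pd.DataFrame(
                {
                    "probe_id": ["p1", "p2"],
                    "chrom": ["c1", "c1"],
                    "pos_cm": [10.0, 10.0],
                    "snp_id": ["s1", "s2"],
                    "contig_id": ["g1", "g1"],
                }
            )
        )
        rng = np.random.default_rng(9)
        hap = np.zeros((6, 2), dtype=bool)
        hap[:3, 0] = True
        hap[:3, 1] = True  # same phase at both probes
        g = sim.simulate_gametes(hap, lmap, 10_000, rng)
        assert (g[:, 0] == g[:, 1]).all()

    def test_offspring_sum_of_gametes(self, small_map):
        lmap = small_map
        hap6 = np.ones((6, lmap.n_probes), dtype=bool)
        hap0 = np.zeros((6, lmap.n_probes), dtype=bool)
        parents = sim.ParentalGenome((hap6, hap0), lmap.probe_ids)
        dos = sim.simulate_offspring(parents, lmap, 50, seed=2)
        assert (dos.to_numpy() == 3).all()

    def test_offspring_bounds_and_shape(self, small_population, small_map):
        _, dosages = small_population
        assert dosages.shape == (small_map.n_probes, 150)
        d = dosages.to_numpy()
        assert d.min() >= 0 and d.max() <= 6

    def test_offspring_frequency_matches_parental_mid_frequency(
        self, small_population, small_map
    ):
        parents, dosages = small_population
        mid = (parents.dosage(0) + parents.dosage(1)) / 12.0
        obs = dosages.mean(axis=1).to_numpy() / 6.0
        # per-probe MC error at n=150; compare the genome-wide mean tightly
        assert abs(obs.mean() - mid.mean()) < 0.01
        assert np.corrcoef(obs, mid)[0, 1] > 0.95

    def test_rejects_nonpositive_offspring_count(self, small_population, small_map):
        parents, _ = small_population
        with pytest.raises(ValueError):
            sim.simulate_offspring(parents, small_map, 0, seed=0)


class TestIntensities:
    def test_noise_free_theta_is_affine_in_dosage(self):
        dos = pd.DataFrame(
            [np.arange(7)], index=["p1"], columns=[f"S{i}" for i in range(7)]
        )
        a, b = sim.simulate_intensities(dos, noise_sd=0.0, seed=0)
        theta = np.log2(b.to_numpy()) - np.log2(a.to_numpy())
        diffs = np.diff(theta[0])
        assert len(np.unique(theta[0].round(9))) == 7
        assert (diffs > 0).all()
        np.testing.assert_allclose(diffs, diffs[0], atol=1e-9)
        # balanced heterozygote sits at theta = 0
        assert abs(theta[0][3]) < 1e-9

    def test_homozygous_signal_strength_lower(self):
        dos = pd.DataFrame(
            [np.arange(7)], index=["p1"], columns=[f"S{i}" for i in range(7)]
        )
        a, b = sim.simulate_intensities(dos, noise_sd=0.0, seed=0)
        s = (np.log2(a.to_numpy()) + np.log2(b.to_numpy())) / 2.0
        assert s[0][0] < s[0][3] and s[0][6] < s[0][3]

    def test_within_class_theta_sd(self):
        dos = pd.DataFrame(
            np.full((1, 40_000), 2, dtype=np.int8),
            index=["p1"],
            columns=[f"S{i}" for i in range(40_000)],
        )
        a, b = sim.simulate_intensities(dos, noise_sd=0.2, seed=5)
        theta = np.log2(b.to_numpy()) - np.log2(a.to_numpy())
        # difference of two independent N(0, 0.2^2) noises
        assert abs(theta.std() - math.sqrt(2) * 0.2) < 0.005


class TestPhenotypes:
    def test_zero_heritability_is_standard_normal(self):
        dos = binomial_dosages(3, 20_000, seed=1)
        y = sim.simulate_phenotypes(dos, list(dos.index), np.zeros(3), seed=2)
        assert abs(y.mean()) < 0.03
        assert abs(y.std() - 1.0) < 0.02

    def test_single_probe_variance_contribution(self):
        # pi=0.5, f=0.5: coefficient^2 * Var(a) = (0.5/1.5) * 1.5 = 0.5
        rng = np.random.default_rng(3)
        d = rng.binomial(6, 0.5, size=(1, 50_000))
        d[0, :3] = [0, 6, 3]  # pin the empirical frequency near 0.5 harmlessly
        dos = pd.DataFrame(d, index=["p1"], columns=[f"S{i}" for i in range(50_000)])
        y = sim.simulate_phenotypes(dos, ["p1"], np.array([0.5]), seed=4)
        f = d.mean() / 6.0
        coef = math.sqrt(0.5 / (6 * f * (1 - f)))
        genetic = coef * (d[0] - d[0].mean())
        assert abs(np.var(genetic) - 0.5) < 0.02
        assert abs(y.to_numpy().var() - 1.0) < 0.03

    def test_heritability_calibration_binomial(self):
        # R^2 of phenotype on causal dosages approaches the configured h2
        dos = binomial_dosages(5, 10_000, seed=6)
        pi = np.full(5, 0.78 / 5)
        y = sim.simulate_phenotypes(dos, list(dos.index), pi, seed=7)
        x = np.column_stack([np.ones(10_000), dos.to_numpy().T])
        beta, *_ = np.linalg.lstsq(x, y.to_numpy(), rcond=None)
        resid = y.to_numpy() - x @ beta
        r2 = 1 - resid.var() / y.to_numpy().var()
        assert abs(r2 - 0.78) < 0.01

    def test_monomorphic_causal_probe_rejected(self):
        dos = pd.DataFrame(
            np.zeros((1, 50), dtype=int), index=["p1"],
            columns=[f"S{i}" for i in range(50)],
        )
        with pytest.raises(ValueError, match="monomorphic"):
            sim.simulate_phenotypes(dos, ["p1"], np.array([0.3]), seed=0)


class TestRepeatedMeasurements:
    def test_noiseless_records_equal_genetic_values(self):
        g = pd.Series([1.0, -2.0, 0.5], index=["a", "b", "c"])
        rec = sim.simulate_repeated_measurements(
            g, n_blocks=1, n_plates=1, sigma2_e=0.0, reps=3, seed=0
        )
        for sid, val in g.items():
            assert (rec.loc[rec["sample_id"] == sid, "value"] == val).all()

    def test_block_effects_show_up_exactly(self):
        g = pd.Series(np.zeros(50), index=[f"S{i}" for i in range(50)])
        rec = sim.simulate_repeated_measurements(
            g, n_blocks=2, n_plates=1, sigma2_e=0.0,
            block_effects=np.array([1.0, -1.0]), reps=4, seed=1,
        )
        v1 = rec.loc[rec["block"] == "B1", "value"]
        v2 = rec.loc[rec["block"] == "B2", "value"]
        assert (v1 == 1.0).all() and (v2 == -1.0).all()

    def test_reml_recovers_variance_ratio(self):
        rng = np.random.default_rng(8)
        g = pd.Series(rng.normal(0, 1.0, 500), index=[f"S{i}" for i in range(500)])
        rec = sim.simulate_repeated_measurements(
            g, n_blocks=2, n_plates=3, sigma2_e=1.0,
            block_effects=np.array([0.5, -0.5]),
            plate_effects=np.array([0.2, 0.0, -0.2]), reps=2, seed=9,
        )
        fit = fit_mixed_model(rec)
        realized = g.var(ddof=1)
        ratio = fit.sigma2_g / (fit.sigma2_g + fit.sigma2_e)
        truth = realized / (realized + 1.0)
        assert abs(ratio - truth) < 0.05


class TestDatasetBundle:
    def test_records_feed_mixed_model_and_recover_genetics(self):
        cfg = sim.SimulationConfig(
            n_offspring=150, n_probes=200, n_chromosomes=3, n_causal=2,
            h2=0.6, seed=77,
        )
        ds = sim.simulate_dataset(cfg)
        assert len(ds.records) == 150 * cfg.reps
        fit = fit_mixed_model(ds.records)
        from polygwas.breeding import deregress

        debv = deregress(fit).debv
        # with 2 reps and s2_e = 0.5 the reliability caps corr(debv, g)
        # near sqrt(r2) ~ 0.87; estimation noise sits below that
        corr = np.corrcoef(
            debv.loc[ds.phenotypes.index], ds.phenotypes.to_numpy()
        )[0, 1]
        assert corr > 0.75

    def test_write_dataset_round_trip(self, tmp_path):
        cfg = sim.SimulationConfig(
            n_offspring=30, n_probes=100, n_chromosomes=2, n_causal=2, seed=5
        )
        ds = sim.simulate_dataset(cfg)
        sim.write_dataset(ds, tmp_path)
        a = pd.read_csv(tmp_path / "A.tsv", sep="\t", index_col=0)
        assert a.shape == ds.a_signal.shape
        rec = pd.read_csv(tmp_path / "phenotypes.csv")
        assert set(rec.columns) == {"sample_id", "block", "plate", "value"}
        lmap = pd.read_csv(tmp_path / "map.tsv", sep="\t")
        assert len(lmap) == 100


class TestDeterminism:
    def test_identical_config_and_seed_bit_identical(self):
        cfg = sim.SimulationConfig(
            n_offspring=40, n_probes=200, n_chromosomes=3, n_causal=2, seed=123
        )
        d1 = sim.simulate_dataset(cfg)
        d2 = sim.simulate_dataset(cfg)
        pd.testing.assert_frame_equal(d1.dosages, d2.dosages)
        pd.testing.assert_frame_equal(d1.a_signal, d2.a_signal)
        pd.testing.assert_series_equal(d1.phenotypes, d2.phenotypes)
        assert d1.causal_probes == d2.causal_probes

    def test_different_seed_differs(self):
        cfg1 = sim.SimulationConfig(
            n_offspring=40, n_probes=200, n_chromosomes=3, n_causal=2, seed=1
        )
        cfg2 = sim.SimulationConfig(
            n_offspring=40, n_probes=200, n_chromosomes=3, n_causal=2, seed=2
        )
        assert not sim.simulate_dataset(cfg1).dosages.equals(
            sim.simulate_dataset(cfg2).dosages
        )
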