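"""Synthetic paired-trait generator: determinism, LD structure, liability model."""

import numpy as np
import pytest
from dataclasses import replace
from scipy import stats

from crosstrait import synth
from crosstrait.synth import SimConfig

from conftest import make_panel


class TestSimConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_snps": 0},
            {"rho": 1.0},
            {"maf_low": 0.6},
            {"maf_low": 0.3, "maf_high": 0.2},
            {"causal_fraction": 1.5},
            {"effect_correlation": 1.2},
            {"prevalence_a": 0.0},
            {"n_test_cases": 0},
            {"fst": -0.1},
        ],
    )
    def test_invalid_config_raises(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(**kwargs)


class TestSimulatePanel:
    def test_determinism(self, small_config):
        p1 = synth.simulate_panel(small_config, "test")
        p2 = synth.simulate_panel(small_config, "test")
        np.testing.assert_array_equal(p1.dosages, p2.dosages)
        assert p1.sample_ids == p2.sample_ids

    def test_cohorts_share_frequencies_but_not_genotypes(self, small_config):
        disc = synth.simulate_panel(small_config, "discovery")
        test = synth.simulate_panel(small_config, "test")
        np.testing.assert_array_equal(
            disc.variants["freq"], test.variants["freq"]
        )
        assert disc.dosages.shape[0] != test.dosages.shape[0] or not np.array_equal(
            disc.dosages, test.dosages
        )

    def test_forced_half_frequency(self):
        cfg = SimConfig(
            n_snps=200, block_size=10, rho=0.0, maf_low=0.5, maf_high=0.5,
            n_test_cases=400, n_test_controls=400, seed=3,
        )
        panel = synth.simulate_panel(cfg, "test")
        emp = panel.allele1_freqs(empirical=True)
        # each empirical frequency is a mean of 1600 Bernoulli(0.5) draws
        se = np.sqrt(0.5 * 0.5 / (2 * panel.n_samples))
        assert np.all(np.abs(emp - 0.5) < 5 * se)

    def test_dosages_are_valid(self, small_config):
        panel = synth.simulate_panel(small_config, "test")
        assert set(np.unique(panel.dosages)) <= {0.0, 1.0, 2.0}

    def test_independent_snps_show_null_r2(self):
        """With rho=0 the mean off-diagonal dosage r2 matches the null
        expectation 1/(n-1), estimated over many seeds."""
        means = []
        for seed in range(20):
            cfg = SimConfig(
                n_snps=20, block_size=10, rho=0.0, n_test_cases=100,
                n_test_controls=100, seed=seed,
            )
            panel = synth.simulate_panel(cfg, "test")
            c = np.corrcoef(panel.dosages.T) ** 2
            means.append(c[np.triu_indices_from(c, k=1)].mean())
        n = 200
        assert np.mean(means) == pytest.approx(1 / (n - 1), rel=0.25)

    def test_within_block_r2_decays_with_distance(self):
        cfg = SimConfig(
            n_snps=400, block_size=20, rho=0.9, n_test_cases=500,
            n_test_controls=500, seed=5,
        )
        panel = synth.simulate_panel(cfg, "test")
        d = panel.dosages
        m = cfg.n_snps
        by_lag = {}
        for lag in (1, 5, 15):
            r2s = []
            for start in range(0, m, cfg.block_size):
                j = start + lag
                if j < start + cfg.block_size:
                    r2s.append(np.corrcoef(d[:, start], d[:, j])[0, 1] ** 2)
            by_lag[lag] = np.mean(r2s)
        assert by_lag[1] > by_lag[5] > by_lag[15]

    def test_across_block_independence(self):
        cfg = SimConfig(
            n_snps=200, block_size=10, rho=0.95, n_test_cases=500,
            n_test_controls=500, seed=6,
        )
        panel = synth.simulate_panel(cfg, "test")
        d = panel.dosages
        # last SNP of block k vs first SNP of block k+1: adjacent but independent
        r2s = [
            np.corrcoef(d[:, 10 * k + 9], d[:, 10 * (k + 1)])[0, 1] ** 2
            for k in range(19)
        ]
        assert np.mean(r2s) < 0.02

    def test_invalid_inputs(self, small_config):
        with pytest.raises(ValueError):
            synth.simulate_panel(small_config, "test", n_samples=0)
        with pytest.raises(ValueError):
            synth.simulate_panel(small_config, "nonsense")


class TestDrawEffects:
    def test_no_causal_snps(self, small_config):
        cfg = replace(small_config, causal_fraction=0.0)
        ba, bb = synth.draw_effects(cfg)
        assert not ba.any() and not bb.any()

    def test_perfect_correlation_equal_h2(self, small_config):
        cfg = replace(small_config, effect_correlation=1.0, h2_a=0.5, h2_b=0.5)
        ba, bb = synth.draw_effects(cfg)
        np.testing.assert_allclose(ba, bb, atol=1e-10)

    def test_effect_correlation_recovered(self):
        """Sample correlation of causal effects approaches the configured
        value at large causal counts."""
        cfg = SimConfig(
            n_snps=20_000, causal_fraction=0.25, effect_correlation=0.3,
            h2_a=0.5, h2_b=0.5, seed=17,
        )
        ba, bb = synth.draw_effects(cfg)
        causal = ba != 0
        assert causal.sum() == 5000
        r = np.corrcoef(ba[causal], bb[causal])[0, 1]
        assert r == pytest.approx(0.3, abs=0.05)

    def test_variance_bookkeeping(self):
        cfg = SimConfig(
            n_snps=20_000, causal_fraction=0.25, effect_correlation=0.0,
            h2_a=0.8, h2_b=0.2, seed=18,
        )
        ba, bb = synth.draw_effects(cfg)
        assert ba @ ba == pytest.approx(0.8, rel=0.1)
        assert bb @ bb == pytest.approx(0.2, rel=0.1)


class TestAssignPhenotypes:
    def test_no_heritability_gives_genotype_independent_status(self):
        cfg = SimConfig(
            n_snps=100, block_size=10, rho=0.5, causal_fraction=0.1,
            h2_b=0.0, prevalence_b=0.5, n_test_cases=400, n_test_controls=400,
            seed=21,
        )
        panel = synth.simulate_study(cfg, "test")
        d = panel.dosages
        y = panel.phenotypes
        diffs = d[y == 1].mean(axis=0) - d[y == 0].mean(axis=0)
        se = np.sqrt(d.var(axis=0) * (1 / 400 + 1 / 400))
        # per-SNP case/control frequency differences consistent with zero
        assert np.mean(np.abs(diffs) < 2.5 * se) > 0.95

    def test_symmetric_threshold_acceptance_rate(self):
        """With prevalence 0.5 and no genetics, about half the pool become
        cases, so ascertaining equal numbers needs ~n_total draws."""
        rng_panel = synth.simulate_panel(
            SimConfig(n_snps=20, n_test_cases=500, n_test_controls=500, seed=22),
            "test",
        )
        labeled = synth.assign_phenotypes(
            rng_panel, np.zeros(20), prevalence=0.5, h2=0.0,
            n_cases=400, n_controls=400, seed=1,
        )
        assert int(labeled.phenotypes.sum()) == 400
        assert labeled.n_samples == 800

    def test_budget_exhaustion_raises(self):
        panel = make_panel(np.ones((50, 3)) , freqs=[0.5, 0.5, 0.5])
        with pytest.raises(RuntimeError, match="exhausted"):
            synth.assign_phenotypes(
                panel, np.zeros(3), prevalence=0.01, h2=0.0,
                n_cases=30, n_controls=5, seed=2,
            )

    def test_large_effect_snp_enriched_in_cases(self):
        """A single strong-effect SNP shows a higher case dosage mean in
        the majority of seeds."""
        hits = 0
        for seed in range(20):
            cfg = SimConfig(
                n_snps=50, block_size=5, rho=0.5, causal_fraction=0.0,
                h2_b=0.5, prevalence_b=0.3, n_test_cases=150,
                n_test_controls=150, seed=100 + seed,
            )
            panel = synth.simulate_panel(cfg, "test", n_samples=1500)
            beta = np.zeros(50)
            beta[7] = np.sqrt(0.5)
            labeled = synth.assign_phenotypes(
                panel, beta, 0.3, 0.5, 150, 150, seed=seed,
            )
            d = labeled.dosages[:, 7]
            y = labeled.phenotypes
            hits += d[y == 1].mean() > d[y == 0].mean()
        assert hits >= 18

    def test_study_determinism(self, small_config):
        p1 = synth.simulate_study(small_config, "test")
        p2 = synth.simulate_study(small_config, "test")
        np.testing.assert_array_equal(p1.dosages, p2.dosages)
        np.testing.assert_array_equal(p1.phenotypes, p2.phenotypes)


class TestDiscoveryGwas:
    def test_null_pvalues_uniform(self):
        """With no genetic effects, GWAS p-values are Uniform(0,1)."""
        pvals = []
        for seed in range(3):
            cfg = SimConfig(
                n_snps=300, block_size=1, rho=0.0, causal_fraction=0.0,
                h2_a=0.0, prevalence_a=0.5, n_disc_cases=250,
                n_disc_controls=250, seed=200 + seed,
            )
            panel = synth.simulate_study(cfg, "discovery")
            recs = synth.discovery_gwas(panel)
            pvals.extend(r.p_value for r in recs)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_allele_recoding_inverts_or(self, small_config):
        panel = synth.simulate_study(small_config, "discovery")
        recs = synth.discovery_gwas(panel)
        flipped = panel.subset_variants(np.arange(panel.n_variants))
        flipped.dosages = 2.0 - flipped.dosages
        a1 = flipped.variants["allele1"].copy()
        flipped.variants["allele1"] = flipped.variants["allele2"]
        flipped.variants["allele2"] = a1
        recs_flipped = synth.discovery_gwas(flipped)
        by_id = {r.snp_id: r for r in recs_flipped}
        for r in recs[:50]:
            rf = by_id[r.snp_id]
            assert rf.odds_ratio == pytest.approx(1 / r.odds_ratio, rel=1e-6)
            assert rf.p_value == pytest.approx(r.p_value, rel=1e-6)

    def test_strong_effect_detected_with_right_sign(self):
        hits = 0
        for seed in range(20):
            cfg = SimConfig(
                n_snps=30, block_size=1, rho=0.0, causal_fraction=0.0,
                h2_a=0.4, prevalence_a=0.3, n_disc_cases=200,
                n_disc_controls=200, seed=300 + seed,
            )
            panel = synth.simulate_panel(cfg, "discovery", n_samples=2000)
            beta = np.zeros(30)
            beta[4] = np.sqrt(0.4)
            labeled = synth.assign_phenotypes(panel, beta, 0.3, 0.4, 200, 200, seed)
            recs = synth.discovery_gwas(labeled)
            rec = next(r for r in recs if r.snp_id == "rs5")
            hits += rec.odds_ratio > 1
        assert hits >= 18

    def test_monomorphic_snps_dropped(self):
        d = np.array([[0, 1.0], [0, 0.0], [0, 1.0], [0, 1.0], [0, 2.0], [0, 0.0]])
        panel = make_panel(d, phenotypes=[1, 1, 1, 0, 0, 0])
        recs = synth.discovery_gwas(panel)
        assert [r.snp_id for r in recs] == ["rs2"]

    def test_quasi_separated_snp_dropped(self, caplog):
        # dosage 2 only in cases, dosage 0 only in controls: MLE diverges
        d = np.array([[1.0], [2.0], [0.0], [1.0]])
        panel = make_panel(d, phenotypes=[1, 1, 0, 0])
        with caplog.at_level("WARNING"):
            recs = synth.discovery_gwas(panel)
        assert recs == []
        assert any("separated" in m for m in caplog.messages)

    def test_requires_both_classes(self):
        panel = make_panel(np.eye(4), phenotypes=[1, 1, 1, 1])
        with pytest.raises(ValueError):
            synth.discovery_gwas(panel)

    def test_gwas_matches_statsmodels(self):
        """Per-SNP Wald statistics agree with an independent logistic fit."""
        import statsmodels.api as sm

        cfg = SimConfig(
            n_snps=20, block_size=5, rho=0.5, causal_fraction=0.2,
            h2_a=0.5, prevalence_a=0.3, n_disc_cases=150, n_disc_controls=150,
            seed=31,
        )
        panel = synth.simulate_study(cfg, "discovery")
        recs = synth.discovery_gwas(panel)
        y = panel.phenotypes
        for r in recs[:8]:
            j = list(panel.variants["snp_id"]).index(r.snp_id)
            X = sm.add_constant(panel.dosages[:, j])
            fit = sm.Logit(y, X).fit(disp=0)
            assert np.exp(fit.params[1]) == pytest.approx(r.odds_ratio, rel=1e-5)
            assert fit.pvalues[1] == pytest.approx(r.p_value, rel=1e-4)


class TestPopulationStructure:
    def test_subpop_frequencies_diverge(self):
        cfg = SimConfig(
            n_snps=500, block_size=10, rho=0.5, n_subpops=2, fst=0.1,
            n_test_cases=300, n_test_controls=300, seed=41,
        )
        panel = synth.simulate_panel(cfg, "test")
        labels = panel.subpop_labels
        d = panel.dosages
        f0 = d[labels == 0].mean(axis=0) / 2
        f1 = d[labels == 1].mean(axis=0) / 2
        # Balding-Nichols: Var(f_s - f) ~ fst * f(1-f); divergence clearly
        # above the no-structure sampling noise
        assert np.mean((f0 - f1) ** 2) > 0.005
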