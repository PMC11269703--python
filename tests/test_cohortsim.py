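"""Simulator checks: LD structure against the thresholded-Gaussian oracle,
heritability and trait-SD targets, medication assignment, outcome
calibration, and the exact PP/MAP arithmetic."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from bpmr import SimConfig, simulate_bp, simulate_cohort, simulate_genotypes
from bpmr.cohortsim import (
    ConfigurationError,
    assign_medication,
    simulate_outcomes,
)


def adjacent_r2_oracle(rho: float, p1: float, p2: float) -> float:
    """Expected squared dosage correlation of two thresholded latent normals
    with correlation rho, by direct integration of the bivariate normal."""
    t1, t2 = stats.norm.ppf(p1), stats.norm.ppf(p2)
    p11 = stats.multivariate_normal.cdf(
        [t1, t2], mean=[0, 0], cov=[[1, rho], [rho, 1]])
    cov = p11 - p1 * p2
    r = cov / np.sqrt(p1 * (1 - p1) * p2 * (1 - p2))
    return float(r * r)


class TestGenotypes:
    def test_mean_dosage_at_maf_half(self):
        cfg = SimConfig(n_individuals=20000, n_variants=50, maf_range=(0.5, 0.5),
                        fst=0.0, seed=5)
        geno = simulate_genotypes(cfg)
        mean = geno.dosage.mean(axis=0)
        # binomial(2, 0.5) mean 1.0; MC SE = sqrt(0.5/n)
        se = np.sqrt(0.5 / cfg.n_individuals)
        assert np.all(np.abs(mean - 1.0) < 3.5 * se)

    def test_no_ld_when_rho_zero(self):
        cfg = SimConfig(n_individuals=4000, n_variants=60, ld_rho=0.0,
                        fst=0.0, seed=6)
        geno = simulate_genotypes(cfg)
        corr = np.corrcoef(geno.dosage.T)
        off = np.abs(corr[np.triu_indices_from(corr, k=1)])
        assert np.median(off) < 0.03

    def test_adjacent_r2_matches_thresholded_gaussian_oracle(self):
        cfg = SimConfig(n_individuals=100_000, n_variants=20, ld_rho=0.9,
                        ld_block_size=10, maf_range=(0.3, 0.3), fst=0.0,
                        n_causal=5, n_chromosomes=1, seed=9)
        geno = simulate_genotypes(cfg)
        expected = adjacent_r2_oracle(0.9, 0.3, 0.3)
        r2 = []
        for j in range(1, cfg.n_variants):
            if j % cfg.ld_block_size == 0:
                continue  # block boundary: independent by construction
            r = np.corrcoef(geno.dosage[:, j - 1], geno.dosage[:, j])[0, 1]
            r2.append(r * r)
        assert np.mean(r2) == pytest.approx(expected, abs=0.015)

    def test_block_boundaries_break_ld(self):
        cfg = SimConfig(n_individuals=50_000, n_variants=40, ld_rho=0.9,
                        ld_block_size=10, fst=0.0, n_chromosomes=1, seed=10)
        geno = simulate_genotypes(cfg)
        for j in (10, 20, 30):
            r = np.corrcoef(geno.dosage[:, j - 1], geno.dosage[:, j])[0, 1]
            assert abs(r) < 0.03

    def test_balding_nichols_drift_spreads_frequencies(self):
        cfg = SimConfig(n_individuals=30_000, n_variants=100, n_regions=5,
                        fst=0.1, maf_range=(0.3, 0.3), seed=11)
        geno = simulate_genotypes(cfg)
        freqs = np.vstack([
            geno.dosage[geno.region == r].mean(axis=0) / 2 for r in range(5)])
        between_var = freqs.var(axis=0).mean()
        # Balding-Nichols: Var(p_r) = F p (1-p) = 0.1 * 0.21
        assert between_var == pytest.approx(0.1 * 0.3 * 0.7, rel=0.35)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_genotypes(SimConfig(n_individuals=0))
        with pytest.raises(ConfigurationError):
            simulate_genotypes(SimConfig(fst=-0.1))
        with pytest.raises(ConfigurationError):
            simulate_genotypes(SimConfig(ld_rho=1.0))


class TestPhenotypes:
    def test_zero_effects_give_null_architecture(self):
        cfg = SimConfig(n_individuals=8000, n_variants=100, h2_sbp=0.0,
                        h2_dbp=0.0, n_causal=10, seed=12)
        geno = simulate_genotypes(cfg)
        pheno, truth = simulate_bp(geno, cfg)
        assert truth.h2_realised["sbp"] == pytest.approx(0.0, abs=1e-12)
        vid = truth.causal_variant_ids[0]
        j = geno.index_of([vid])[0]
        slope = np.polyfit(geno.dosage[:, j], pheno["sbp_true"], 1)[0]
        se = pheno["sbp_true"].std() / (
            geno.dosage[:, j].std() * np.sqrt(cfg.n_individuals))
        assert abs(slope) < 3 * se

    def test_default_sbp_sd_near_target(self):
        cfg = SimConfig(seed=13)  # default: target SD 22.3 mmHg
        geno, pheno, _ = simulate_cohort(cfg)
        assert pheno["sbp_true"].std() == pytest.approx(22.3, rel=0.05)

    def test_single_causal_effect_recovered_against_ols_oracle(self):
        cfg = SimConfig(n_individuals=50_000, n_variants=10, n_causal=1,
                        h2_sbp=0.0, h2_dbp=0.0, ld_rho=0.0, fst=0.0, seed=14)
        geno = simulate_genotypes(cfg)
        pheno, truth = simulate_bp(geno, cfg)
        j = geno.index_of([truth.causal_variant_ids[0]])[0]
        x = geno.dosage[:, j].astype(float)
        y = pheno["sbp_true"].to_numpy() + 2.0 * x  # inject beta = 2 mmHg
        xc = x - x.mean()
        beta_hat = float(xc @ y / (xc @ xc))
        # closed-form OLS sampling SE
        sigma = np.std(y - y.mean() - beta_hat * xc)
        se = sigma / np.sqrt(np.sum(xc**2))
        assert abs(beta_hat - 2.0) < 3 * se

    def test_realised_h2_matches_target(self):
        cfg = SimConfig(n_individuals=20_000, n_variants=500, seed=15)
        geno = simulate_genotypes(cfg)
        _, truth = simulate_bp(geno, cfg)
        assert truth.h2_realised["sbp"] == pytest.approx(0.16, rel=0.10)
        assert truth.h2_realised["dbp"] == pytest.approx(0.16, rel=0.10)

    def test_pp_map_exact_at_phenotype_and_effect_level(self):
        cfg = SimConfig(n_individuals=2000, n_variants=100, seed=16)
        geno, pheno, truth = simulate_cohort(cfg)
        np.testing.assert_array_equal(
            pheno["pp_true"], pheno["sbp_true"] - pheno["dbp_true"])
        np.testing.assert_array_equal(
            pheno["map_true"],
            (2.0 * pheno["dbp_true"] + pheno["sbp_true"]) / 3.0)
        bt = truth.beta_true
        np.testing.assert_array_equal(bt["pp"], bt["sbp"] - bt["dbp"])
        np.testing.assert_array_equal(bt["map"], (2 * bt["dbp"] + bt["sbp"]) / 3)

    def test_seeded_determinism_is_bit_identical(self):
        cfg = SimConfig(n_individuals=500, n_variants=80, seed=17)
        a = simulate_cohort(cfg)
        b = simulate_cohort(cfg)
        np.testing.assert_array_equal(a[0].dosage, b[0].dosage)
        pd.testing.assert_frame_equal(a[1], b[1])


class TestMedication:
    def test_zero_probability_leaves_cohort_untreated(self):
        cfg = SimConfig(n_individuals=2000, n_variants=50, treat_prob=0.0, seed=18)
        geno = simulate_genotypes(cfg)
        pheno, _ = simulate_bp(geno, cfg)
        out = assign_medication(pheno, cfg)
        assert not out["medication"].any()
        np.testing.assert_array_equal(out["sbp_raw"], out["sbp_true"])

    def test_full_treatment_lowers_every_hypertensive(self):
        cfg = SimConfig(n_individuals=2000, n_variants=50, treat_prob=1.0,
                        treat_effect_sbp=15.0, treat_effect_dbp=10.0, seed=19)
        geno = simulate_genotypes(cfg)
        pheno, _ = simulate_bp(geno, cfg)
        out = assign_medication(pheno, cfg)
        hyper = (out["sbp_true"] >= 140) | (out["dbp_true"] >= 90)
        assert out.loc[hyper, "medication"].all()
        np.testing.assert_allclose(out.loc[hyper, "sbp_raw"],
                                   out.loc[hyper, "sbp_true"] - 15.0)
        np.testing.assert_allclose(out.loc[hyper, "dbp_raw"],
                                   out.loc[hyper, "dbp_true"] - 10.0)

    def test_one_third_of_hypertensives_treated(self):
        cfg = SimConfig(n_individuals=50_000, n_variants=20, n_causal=5, seed=20)
        geno = simulate_genotypes(cfg)
        pheno, _ = simulate_bp(geno, cfg)
        out = assign_medication(pheno, cfg)
        hyper = (out["sbp_true"] >= 140) | (out["dbp_true"] >= 90)
        frac = out.loc[hyper, "medication"].mean()
        se = np.sqrt((1 / 3) * (2 / 3) / hyper.sum())
        assert abs(frac - 1 / 3) < 3 * se

    def test_treated_per_allele_effects_attenuated(self):
        # medication targets hypertensives, so the treated stratum is
        # phenotype-selected and shows attenuated per-allele effects
        cfg = SimConfig(n_individuals=60_000, n_variants=40, n_causal=4,
                        h2_sbp=0.3, h2_dbp=0.3, ld_rho=0.0, fst=0.0, seed=21)
        geno = simulate_genotypes(cfg)
        pheno, truth = simulate_bp(geno, cfg)
        out = assign_medication(pheno, cfg)
        strongest = truth.beta_true["sbp"].abs().idxmax()
        j = geno.index_of([strongest])[0]
        x = geno.dosage[:, j].astype(float)
        y = out["sbp_raw"].to_numpy()
        treated = out["medication"].to_numpy()

        def slope(mask):
            xm = x[mask] - x[mask].mean()
            return abs(float(xm @ y[mask] / (xm @ xm)))

        assert slope(treated) < slope(~treated)


class TestOutcomes:
    def test_null_effects_hit_target_prevalence(self):
        cfg = SimConfig(n_individuals=40_000, n_variants=20, n_causal=5,
                        outcome_logors={"is": {}}, outcome_prev={"is": 0.1},
                        seed=22)
        geno = simulate_genotypes(cfg)
        pheno, _ = simulate_bp(geno, cfg)
        out = simulate_outcomes(pheno, cfg)
        frac = out["case_is"].mean()
        se = np.sqrt(0.1 * 0.9 / cfg.n_individuals)
        assert abs(frac - 0.1) < 3 * se

    def test_logistic_fit_recovers_per5mmhg_logor(self):
        theta = np.log(1.15)
        cfg = SimConfig(n_individuals=100_000, n_variants=20, n_causal=5,
                        outcome_logors={"is": {"sbp": theta}},
                        outcome_prev={"is": 0.1}, seed=23)
        geno = simulate_genotypes(cfg)
        pheno, _ = simulate_bp(geno, cfg)
        out = simulate_outcomes(pheno, cfg)
        design = sm.add_constant(out["sbp_true"].to_numpy() / 5.0)
        fit = sm.Logit(out["case_is"].to_numpy(float), design).fit(disp=0)
        assert abs(fit.params[1] - theta) < 3 * fit.bse[1]

    def test_outcomes_correlate_only_through_shared_bp(self):
        theta = np.log(1.5)
        cfg = SimConfig(n_individuals=200_000, n_variants=10, n_causal=3,
                        outcome_logors={"a": {"sbp": theta}, "b": {"sbp": theta}},
                        outcome_prev={"a": 0.2, "b": 0.2}, seed=24)
        geno = simulate_genotypes(cfg)
        pheno, truth = simulate_bp(geno, cfg)
        out = simulate_outcomes(pheno, cfg, truth=truth)
        # oracle: cov(A,B) = E[p_a(S) p_b(S)] - E[p_a]E[p_b] by numerical
        # integration over the SBP distribution
        from scipy.special import expit

        s = out["sbp_true"].to_numpy()
        pa = expit(truth.outcome_intercepts["a"] + theta * s / 5)
        pb = expit(truth.outcome_intercepts["b"] + theta * s / 5)
        expected = np.mean(pa * pb) - np.mean(pa) * np.mean(pb)
        observed = np.cov(out["case_a"].astype(float),
                          out["case_b"].astype(float))[0, 1]
        mc_se = 0.2 * 0.8 / np.sqrt(cfg.n_individuals)
        assert abs(observed - expected) < 4 * mc_se

    def test_bad_prevalence_rejected(self):
        with pytest.raises(ConfigurationError):
            SimConfig(outcome_prev={"is": 1.5}).validate()
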