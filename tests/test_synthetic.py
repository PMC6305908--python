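"""Generator statistics: HWE, carrier frequencies, slope structure."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from emprs.panel import RS_APOE_E2, RS_APOE_E4, RS_KLOTHO
from emprs.scoring import exclude_kl_homozygotes
from emprs.synthetic import (
    ConfigError,
    SimulationConfig,
    analytic_slope_sd,
    klvs_fixture_cohort,
    simulate_cohort,
    simulate_genotypes,
    simulate_trajectories,
    slope_effect_for_d,
    true_slopes,
)
from emprs.weights import subject_slopes


class TestConfigValidation:
    def test_zero_maf_rejected(self):
        with pytest.raises(ConfigError, match="MAF"):
            SimulationConfig(maf_per_variant={"CLU": 0.0})

    def test_maf_above_half_rejected(self):
        with pytest.raises(ConfigError, match="MAF"):
            SimulationConfig(maf_per_variant={"CLU": 0.6})

    def test_nonmonotone_visits_rejected(self):
        with pytest.raises(ConfigError, match="visit_months"):
            SimulationConfig(visit_months=(0, 36, 18))

    def test_negative_sd_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(residual_sd=-0.1)

    def test_apoe_freqs_must_sum_to_one(self):
        with pytest.raises(ConfigError, match="sum to 1"):
            SimulationConfig(apoe_haplotype_freqs={"e2": 0.5, "e3": 0.2, "e4": 0.2})


class TestGenotypes:
    def test_carrier_frequency_matches_hwe(self, panel):
        # MAF 0.2 -> carrier frequency 1 - 0.8^2 = 0.36
        config = SimulationConfig(
            n_subjects=10_000, maf_per_variant={"CLU": 0.2}, seed=5
        )
        recs = simulate_genotypes(panel.subset(["CLU"]), config)
        carriers = sum("T" in r.calls["rs11136000"] for r in recs)
        se = math.sqrt(0.36 * 0.64 / 10_000)
        assert abs(carriers / 10_000 - 0.36) < 3 * se

    def test_hwe_chi_square_across_panel(self, panel):
        config = SimulationConfig(n_subjects=10_000, seed=17)
        recs = simulate_genotypes(panel, config)
        failures = 0
        for entry in panel:
            if entry.is_apoe:
                continue
            counts = np.zeros(3)
            for r in recs:
                counts[sum(a == entry.minor_allele for a in r.calls[entry.rsid])] += 1
            n = counts.sum()
            p = (2 * counts[2] + counts[1]) / (2 * n)
            if p == 0:
                continue
            expected = n * np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
            with np.errstate(divide="ignore", invalid="ignore"):
                chi2 = np.nansum((counts - expected) ** 2 / expected)
            if stats.chi2.sf(chi2, df=1) < 0.001:
                failures += 1
        assert failures <= 2  # false-positive allowance at alpha=0.001

    def test_apoe_resolution_matches_truth_and_carriage_rate(self, panel):
        config = SimulationConfig(n_subjects=4_000, seed=23)
        recs = simulate_genotypes(panel, config)
        # no record is unresolvable (e1 is never simulated)
        assert all(r.apoe_e4_count is not None for r in recs)
        carriage = np.mean([r.apoe_e4_count >= 1 for r in recs])
        expect = 1 - (1 - 0.24) ** 2
        assert abs(carriage - expect) < 3 * math.sqrt(expect * (1 - expect) / 4_000)

    def test_kl_homozygote_fraction(self, panel):
        config = SimulationConfig(n_subjects=20_000, seed=29)
        recs = simulate_genotypes(panel, config)
        frac = np.mean([r.kl_vs == "homozygous" for r in recs])
        target = config.kl_vs_homozygote_fraction
        assert abs(frac - target) < 3 * math.sqrt(target * (1 - target) / 20_000)

    def test_determinism(self, panel):
        config = SimulationConfig(n_subjects=50, seed=3)
        a = simulate_genotypes(panel, config)
        b = simulate_genotypes(panel, config)
        assert [(r.subject, r.calls) for r in a] == [(r.subject, r.calls) for r in b]


class TestTrajectories:
    def test_noise_free_slopes_are_exact(self, panel):
        config = SimulationConfig(
            n_subjects=20, slope_effects={}, base_slope=-0.01,
            intercept_sd=0.0, residual_sd=0.0, dropout_rate=0.0, seed=1,
        )
        geno = simulate_genotypes(panel, config)
        traj = simulate_trajectories(geno, config, panel)
        slopes = subject_slopes(traj, method="ols", composite="global").slopes
        assert np.allclose(slopes["slope"], -0.01, atol=1e-12)

    def test_group_slope_difference_recovers_effect(self, panel):
        # one causal variant: carrier mean slope lower by the configured delta
        delta = 0.005
        config = SimulationConfig(
            n_subjects=300, slope_effects={"CLU": delta},
            maf_per_variant={"CLU": 0.4}, dropout_rate=0.0, seed=41,
        )
        geno = simulate_genotypes(panel, config)
        traj = simulate_trajectories(geno, config, panel)
        sl = subject_slopes(traj, "ols", "verbal_episodic_memory").slopes
        sl = sl.merge(
            pd.DataFrame(
                [(g.subject, "T" in g.calls["rs11136000"]) for g in geno],
                columns=["subject", "carrier"],
            ),
            on="subject",
        )
        diff = (
            sl.loc[~sl["carrier"], "slope"].mean()
            - sl.loc[sl["carrier"], "slope"].mean()
        )
        sd = analytic_slope_sd(config)
        n1, n0 = sl["carrier"].sum(), (~sl["carrier"]).sum()
        se = sd * math.sqrt(1 / n1 + 1 / n0)
        assert abs(diff - delta) < 3 * se

    def test_full_dropout_retains_only_baseline(self, panel):
        config = SimulationConfig(n_subjects=15, dropout_rate=1.0, seed=2)
        geno = simulate_genotypes(panel, config)
        traj = simulate_trajectories(geno, config, panel)
        assert set(traj["visit_month"]) == {0.0}
        assert traj.groupby("subject").size().gt(0).all()

    def test_empty_genotypes_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            simulate_trajectories([], SimulationConfig())

    def test_risk_enters_slope_not_intercept(self, panel):
        config = SimulationConfig(
            n_subjects=40, intercept_sd=0.0, residual_sd=0.0,
            dropout_rate=0.0, seed=9,
        )
        geno = simulate_genotypes(panel, config)
        traj = simulate_trajectories(geno, config, panel)
        base = traj[traj["visit_month"] == 0]
        assert np.allclose(base["value"], 0.0, atol=1e-12)

    def test_slope_effect_for_d_inverts_analytic_sd(self):
        config = SimulationConfig()
        d = slope_effect_for_d(0.5, config) / analytic_slope_sd(config)
        assert d == pytest.approx(0.5)


class TestCohort:
    def test_full_cohort_shape(self, small_cohort):
        assert len(small_cohort.genotypes) == 120
        assert small_cohort.trajectories.groupby("subject").size().gt(0).all()
        assert len(small_cohort.covariates) == 120
        assert len(small_cohort.suvr) == 120

    def test_covariate_ranges(self, small_cohort):
        cov = small_cohort.covariates
        assert (cov["age"] >= 60).all()
        assert set(cov["sex"]) <= {0, 1}
        assert set(cov["education"]) <= {0, 1, 2, 3}
        assert (cov["gds"] >= 0).all()

    def test_all_high_fraction_classifies_all_abeta_high(self, small_cohort):
        from emprs.composites import classify_abeta

        high = classify_abeta(small_cohort.suvr)
        assert high.all() and len(high) == 120

    def test_cohort_determinism(self):
        a = simulate_cohort(SimulationConfig(n_subjects=30, seed=7))
        b = simulate_cohort(SimulationConfig(n_subjects=30, seed=7))
        pd.testing.assert_frame_equal(a.trajectories, b.trajectories)
        pd.testing.assert_frame_equal(a.covariates, b.covariates)
        pd.testing.assert_frame_equal(a.suvr, b.suvr)
        assert [(r.subject, r.calls) for r in a.genotypes] == [
            (r.subject, r.calls) for r in b.genotypes
        ]


class TestKlvsFixture:
    def test_exact_homozygote_count_and_exclusion(self):
        recs = klvs_fixture_cohort(n_subjects=232, n_kl_homozygotes=6)
        assert len(recs) == 232
        kept, n_excluded = exclude_kl_homozygotes(recs)
        assert (len(kept), n_excluded) == (226, 6)

    def test_true_slopes_deterministic_given_genotypes(self, panel):
        config = SimulationConfig(n_subjects=25, seed=13)
        geno = simulate_genotypes(panel, config)
        assert true_slopes(geno, config, panel) == true_slopes(geno, config, panel)
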