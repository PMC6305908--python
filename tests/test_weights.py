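"""Cohort splitting, slope extraction and effect-size derivation."""

import math

import numpy as np
import pandas as pd
import pytest

from emprs.scoring import GenotypeRecord, exemplar_calls
from emprs.synthetic import (
    SimulationConfig,
    analytic_slope_sd,
    simulate_genotypes,
    simulate_trajectories,
    slope_effect_for_d,
)
from emprs.weights import (
    cohens_d,
    derive_weights,
    results_to_panel,
    split_cohort,
    subject_slopes,
)


class TestSplitCohort:
    def test_study_split_sizes(self):
        ids = [f"S{i}" for i in range(226)]
        ref, test = split_cohort(ids, 151 / 226, seed=0)
        assert (len(ref), len(test)) == (151, 75)
        assert set(ref) | set(test) == set(ids)
        assert not set(ref) & set(test)

    def test_same_seed_reproduces_partition(self):
        ids = [f"S{i}" for i in range(40)]
        assert split_cohort(ids, 0.5, seed=9) == split_cohort(ids, 0.5, seed=9)

    def test_different_seeds_both_valid(self):
        ids = ["a", "b", "c", "d"]
        for seed in (1, 2):
            ref, test = split_cohort(ids, 0.5, seed=seed)
            assert len(ref) == len(test) == 2
            assert sorted(ref + test) == sorted(ids)

    @pytest.mark.parametrize("fraction", [0.0, 1.0, -0.2, 1.5])
    def test_degenerate_fraction_rejected(self, fraction):
        with pytest.raises(ValueError, match="fraction"):
            split_cohort(["a", "b"], fraction, seed=0)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="2 subjects"):
            split_cohort(["a"], 0.5, seed=0)


def traj_frame(rows):
    return pd.DataFrame(
        rows, columns=["subject", "visit_month", "composite", "value"]
    )


class TestSubjectSlopes:
    def test_exact_line_recovered(self):
        rows = [("A", 0.0, "vem", 1.0), ("A", 18.0, "vem", 0.82), ("A", 36.0, "vem", 0.64)]
        res = subject_slopes(traj_frame(rows), method="ols")
        assert res.slopes["slope"].iloc[0] == pytest.approx(-0.01)
        assert res.slopes["n_visits"].iloc[0] == 3

    def test_single_visit_subject_excluded_and_reported(self):
        rows = [
            ("A", 0.0, "vem", 1.0), ("A", 18.0, "vem", 0.9),
            ("B", 0.0, "vem", 2.0),
        ]
        res = subject_slopes(traj_frame(rows), method="ols")
        assert res.excluded_subjects == ["B"]
        assert list(res.slopes["subject"]) == ["A"]

    def test_all_excluded_rejected(self):
        rows = [("A", 0.0, "vem", 1.0)]
        with pytest.raises(ValueError, match="excluded"):
            subject_slopes(traj_frame(rows), method="ols")

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="method"):
            subject_slopes(traj_frame([]), method="ridge")

    def test_ols_and_blup_agree_on_noise_free_cohort(self, panel):
        config = SimulationConfig(
            n_subjects=25, intercept_sd=0.5, residual_sd=0.0,
            dropout_rate=0.0, seed=4,
        )
        geno = simulate_genotypes(panel, config)
        traj = simulate_trajectories(geno, config, panel, composites=("vem",))
        a = subject_slopes(traj, "ols").slopes.set_index("subject")["slope"]
        b = subject_slopes(traj, "blup").slopes.set_index("subject")["slope"]
        assert np.allclose(a.sort_index(), b.sort_index(), atol=1e-8)

    def test_blup_shrinks_toward_population_mean(self, panel):
        config = SimulationConfig(
            n_subjects=60, residual_sd=0.6, dropout_rate=0.0, seed=6,
        )
        geno = simulate_genotypes(panel, config)
        traj = simulate_trajectories(geno, config, panel, composites=("vem",))
        ols = subject_slopes(traj, "ols").slopes.set_index("subject")["slope"]
        blup = subject_slopes(traj, "blup").slopes.set_index("subject")["slope"]
        assert blup.std() <= ols.std() + 1e-12


class TestCohensD:
    def test_hand_computed_value(self):
        d, lo, hi = cohens_d([1, 2, 3], [2, 3, 4])
        assert d == pytest.approx(-1.0)
        se = math.sqrt(6 / 9 + 1 / 8)
        assert lo == pytest.approx(-1 - 1.96 * se)
        assert hi == pytest.approx(-1 + 1.96 * se)

    def test_identical_groups_give_zero(self):
        d, lo, hi = cohens_d([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert d == 0.0 and lo < 0 < hi

    def test_antisymmetry(self):
        d_ab, _, _ = cohens_d([1, 2, 3, 4], [2, 4, 6, 7])
        d_ba, _, _ = cohens_d([2, 4, 6, 7], [1, 2, 3, 4])
        assert d_ab == pytest.approx(-d_ba)

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(ValueError, match="pooled"):
            cohens_d([1.0, 1.0], [1.0, 1.0])

    def test_tiny_groups_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            cohens_d([1.0], [1.0, 2.0])


def one_variant_cohort(delta_d, n, seed, gene="CLU"):
    """Cohort where only `gene` carriers decline faster, with analytic d
    equal to delta_d under OLS slope extraction."""
    from emprs.panel import load_reference_panel

    panel = load_reference_panel()
    config = SimulationConfig(
        n_subjects=n,
        slope_effects={gene: slope_effect_for_d(delta_d, SimulationConfig())},
        maf_per_variant={gene: 0.4},
        dropout_rate=0.0,
        seed=seed,
    )
    geno = simulate_genotypes(panel, config)
    traj = simulate_trajectories(
        geno, config, panel, composites=("verbal_episodic_memory",)
    )
    return panel, geno, traj


class TestDeriveWeights:
    def test_causal_variant_assigned_carrier_risk(self):
        panel, geno, traj = one_variant_cohort(1.0, n=2000, seed=8)
        slopes = subject_slopes(traj, "ols", "verbal_episodic_memory").slopes
        results, skipped = derive_weights(slopes, geno, panel.subset(["CLU"]))
        assert not skipped
        [res] = results
        assert res.risk_genotype == "T+"  # CLU minor-allele carriers
        assert res.d > 0.5

    def test_d_nonnegative_and_risk_is_faster_declining_group(self):
        panel, geno, traj = one_variant_cohort(0.0, n=200, seed=12)
        slopes = subject_slopes(traj, "ols", "verbal_episodic_memory").slopes
        results, _ = derive_weights(slopes, geno, panel)
        for res in results:
            assert res.d >= 0
            carrier_risk = res.risk_genotype.endswith("+")
            if res.d > 0:
                if carrier_risk:
                    assert res.carrier_mean < res.noncarrier_mean
                else:
                    assert res.noncarrier_mean < res.carrier_mean
            assert res.ci_low <= res.d <= res.ci_high

    def test_orientation_invariant_under_composite_sign_flip(self):
        panel, geno, traj = one_variant_cohort(0.8, n=400, seed=21)
        slopes = subject_slopes(traj, "ols", "verbal_episodic_memory").slopes
        flipped = slopes.copy()
        flipped["slope"] = -flipped["slope"]
        a, _ = derive_weights(slopes, geno, panel.subset(["CLU"]))
        b, _ = derive_weights(flipped, geno, panel.subset(["CLU"]))
        assert a[0].d == pytest.approx(b[0].d)
        assert a[0].risk_genotype != b[0].risk_genotype

    def test_empty_group_variant_skipped(self, panel):
        # every subject a non-carrier at SORL1 -> variant skipped
        recs = [
            GenotypeRecord.from_calls(f"S{i}", exemplar_calls(panel))
            for i in range(10)
        ]
        slopes = pd.DataFrame(
            {"subject": [f"S{i}" for i in range(10)], "slope": np.linspace(-1, 1, 10)}
        )
        results, skipped = derive_weights(slopes, recs, panel.subset(["SORL1"]))
        assert results == [] and skipped == ["SORL1"]

    def test_no_subject_overlap_rejected(self, panel):
        slopes = pd.DataFrame({"subject": ["X"], "slope": [0.1]})
        recs = [GenotypeRecord.from_calls("Y", exemplar_calls(panel))]
        with pytest.raises(ValueError, match="overlap"):
            derive_weights(slopes, recs, panel)

    def test_derived_panel_scores_subjects(self):
        panel, geno, traj = one_variant_cohort(1.0, n=300, seed=33)
        slopes = subject_slopes(traj, "ols", "verbal_episodic_memory").slopes
        results, _ = derive_weights(slopes, geno, panel)
        derived = results_to_panel(results, panel)
        from emprs.scoring import compute_emprs

        scores = compute_emprs(geno[:5], derived)
        assert all(s.emprs_with_apoe is not None for s in scores)
        total = derived.total_weight()
        assert all(0 <= s.emprs_with_apoe <= total for s in scores)
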