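"""Per-protein OLS scaling factors: fitting, CV, negative control, application."""

import numpy as np
import pandas as pd
import pytest

from plasmabridge import (SynthConfig, apply_scaling,
                          compare_factor_sets, fit_scaling_factors,
                          fit_scaling_factors_cv, generate_cohorts,
                          mismatched_control)
from plasmabridge.scaling import ScalingFactorSet

from .conftest import make_pairs


def ols_oracle(x, y):
    """Per-protein OLS via numpy.polyfit — independent of the implementation."""
    slopes, intercepts = [], []
    for j in range(x.shape[1]):
        b, a = np.polyfit(x[:, j], y[:, j], 1)
        slopes.append(b)
        intercepts.append(a)
    return np.array(slopes), np.array(intercepts)


class TestFit:
    def test_matches_polyfit_oracle_to_1e10(self):
        rng = np.random.default_rng(0)
        x = rng.normal(8, 1.5, (40, 200))
        y = 0.9 * x + 0.5 + rng.normal(0, 0.4, x.shape)
        factors = fit_scaling_factors(make_pairs(x, y))
        sl, ic = ols_oracle(x, y)
        np.testing.assert_allclose(factors.table["slope"], sl, atol=1e-10)
        np.testing.assert_allclose(factors.table["intercept"], ic, atol=1e-10)

    def test_identity_relationship(self):
        rng = np.random.default_rng(1)
        x = rng.normal(8, 1, (10, 5))
        factors = fit_scaling_factors(make_pairs(x, x))
        np.testing.assert_allclose(factors.table["slope"], 1.0, atol=1e-12)
        np.testing.assert_allclose(factors.table["intercept"], 0.0, atol=1e-10)
        np.testing.assert_allclose(factors.table["pearson_r"], 1.0)

    def test_constant_offset(self):
        rng = np.random.default_rng(2)
        x = rng.normal(8, 1, (10, 5))
        factors = fit_scaling_factors(make_pairs(x, x + 2.0))
        np.testing.assert_allclose(factors.table["slope"], 1.0, atol=1e-12)
        np.testing.assert_allclose(factors.table["intercept"], 2.0, atol=1e-10)

    def test_zero_serum_variance_skipped_not_zero_filled(self):
        rng = np.random.default_rng(3)
        x = rng.normal(8, 1, (10, 3))
        x[:, 1] = 5.0
        factors = fit_scaling_factors(make_pairs(x, x + 1))
        assert factors.skipped == ["PROT1"]
        assert list(factors.table.index) == ["PROT0", "PROT2"]

    def test_fitted_line_minimizes_rss(self):
        rng = np.random.default_rng(4)
        x = rng.normal(8, 1, (30, 10))
        y = x + rng.normal(0, 0.5, x.shape)
        factors = fit_scaling_factors(make_pairs(x, y))
        sl = factors.table["slope"].to_numpy()
        ic = factors.table["intercept"].to_numpy()
        rss = ((y - (x * sl + ic)) ** 2).sum(axis=0)
        for dsl, dic in [(1e-3, 0), (0, 1e-3), (-1e-3, 1e-3)]:
            perturbed = ((y - (x * (sl + dsl) + ic + dic)) ** 2).sum(axis=0)
            assert (perturbed >= rss - 1e-9).all()

    def test_parameter_recovery_on_synthetic_truth(self):
        cfg = SynthConfig(seed=5, n_cohorts=1, pairs_per_cohort=50,
                          n_proteins=200, slope_mean=0.8, slope_sd=0.0,
                          intercept_mean=1.5, intercept_sd=0.0, noise_sd=0.3,
                          noise_jitter=0.0, fraction_lod=0, fraction_coag=0,
                          contamination_panel_size=0, contaminated_cohort=None,
                          t1_fraction=0, n_reference_serum=4,
                          n_reference_plasma=4)
        factors = fit_scaling_factors(generate_cohorts(cfg).paired())
        assert factors.table["slope"].mean() == pytest.approx(0.8, abs=0.02)
        assert factors.table["intercept"].mean() == pytest.approx(1.5, abs=0.2)


class TestApply:
    def test_identity_factors_bit_identical(self):
        rng = np.random.default_rng(6)
        pairs = make_pairs(rng.normal(8, 1, (6, 4)), rng.normal(8, 1, (6, 4)))
        table = pd.DataFrame({"slope": 1.0, "intercept": 0.0, "n_pairs": 6},
                             index=pairs.serum.values.columns)
        scaled = apply_scaling(pairs.serum, ScalingFactorSet(table))
        assert (scaled.values.to_numpy() ==
                pairs.serum.values.to_numpy()).all()

    def test_direct_substitution(self):
        pairs = make_pairs(np.full((3, 1), 10.0), np.full((3, 1), 10.0))
        table = pd.DataFrame({"slope": [0.9], "intercept": [1.0],
                              "n_pairs": 3}, index=["PROT0"])
        scaled = apply_scaling(pairs.serum, ScalingFactorSet(table))
        np.testing.assert_allclose(scaled.values.to_numpy(), 10.0)

    def test_noiseless_round_trip(self):
        rng = np.random.default_rng(7)
        x = rng.normal(8, 1, (12, 30))
        slopes = rng.uniform(0.7, 1.3, 30)
        intercepts = rng.normal(0, 1, 30)
        pairs = make_pairs(x, x * slopes + intercepts)
        factors = fit_scaling_factors(pairs)
        scaled = apply_scaling(pairs.serum, factors)
        np.testing.assert_allclose(scaled.values.to_numpy(),
                                   pairs.plasma_values(), atol=1e-10)

    def test_missing_factor_policies(self):
        rng = np.random.default_rng(8)
        pairs = make_pairs(rng.normal(8, 1, (5, 3)), rng.normal(8, 1, (5, 3)))
        table = pd.DataFrame({"slope": [1.0, 1.0], "intercept": [0.0, 0.0],
                              "n_pairs": 5}, index=["PROT0", "PROT2"])
        factors = ScalingFactorSet(table)
        with pytest.raises(ValueError, match="PROT1"):
            apply_scaling(pairs.serum, factors, policy="error")
        dropped = apply_scaling(pairs.serum, factors, policy="drop")
        assert dropped.protein_ids == ["PROT0", "PROT2"]
        kept = apply_scaling(pairs.serum, factors, policy="passthrough")
        assert kept.protein_ids == ["PROT0", "PROT1", "PROT2"]
        assert kept.flags["PROT1"] == "not_scaled"


class TestCrossValidation:
    def noiseless_pairs(self, n=20, p=8, seed=9):
        rng = np.random.default_rng(seed)
        x = rng.normal(8, 1, (n, p))
        return make_pairs(x, 0.9 * x + 1.0)

    def test_partition_covers_each_pair_once_and_groups_patients(self):
        cfg = SynthConfig(seed=10, n_cohorts=1, pairs_per_cohort=20,
                          n_proteins=30, t1_fraction=0.4,
                          contaminated_cohort=None, contamination_panel_size=0,
                          n_reference_serum=4, n_reference_plasma=4)
        pairs = generate_cohorts(cfg).paired()
        cv = fit_scaling_factors_cv(pairs, k=4, seed=0)
        assert sorted(cv.scaled_serum.sample_ids) == \
            sorted(pairs.serum.sample_ids)
        folds = [cv.fold_of_patient[k.patient_id] for k in pairs.pair_index]
        for patient in {k.patient_id for k in pairs.pair_index}:
            patient_folds = {f for f, k in zip(folds, pairs.pair_index)
                             if k.patient_id == patient}
            assert len(patient_folds) == 1  # no patient spans folds

    def test_noiseless_data_all_folds_identical_and_exact(self):
        pairs = self.noiseless_pairs()
        cv = fit_scaling_factors_cv(pairs, k=5, seed=1)
        for fold in cv.fold_factors:
            np.testing.assert_allclose(fold.table["slope"], 0.9, atol=1e-10)
            np.testing.assert_allclose(fold.table["intercept"], 1.0,
                                       atol=1e-9)
        np.testing.assert_allclose(
            cv.scaled_serum.values.loc[pairs.serum.sample_ids].to_numpy(),
            pairs.plasma_values(), atol=1e-9)

    def test_out_of_fold_error_exceeds_in_sample_error(self):
        rng = np.random.default_rng(11)
        x = rng.normal(8, 1, (40, 150))
        y = x + rng.normal(0, 0.5, x.shape)
        pairs = make_pairs(x, y)
        cv = fit_scaling_factors_cv(pairs, k=5, seed=2)
        full = fit_scaling_factors(pairs)
        scaled_full = apply_scaling(pairs.serum, full)
        oof_sse = ((cv.scaled_serum.values.loc[pairs.serum.sample_ids]
                    .to_numpy() - y) ** 2).mean()
        in_sse = ((scaled_full.values.to_numpy() - y) ** 2).mean()
        assert oof_sse >= in_sse

    def test_k_larger_than_pairs_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            fit_scaling_factors_cv(self.noiseless_pairs(n=4), k=10)


class TestMismatchedControl:
    def test_derangement_properties(self):
        pairs = self.random_pairs()
        mm = mismatched_control(pairs, seed=3)
        orig_plasma = [k.plasma_sample_id for k in pairs.pair_index]
        new_plasma = [k.plasma_sample_id for k in mm.pair_index]
        assert sorted(orig_plasma) == sorted(new_plasma)  # same multiset
        assert all(a != b for a, b in zip(orig_plasma, new_plasma))
        assert [k.serum_sample_id for k in mm.pair_index] == \
            [k.serum_sample_id for k in pairs.pair_index]

    def random_pairs(self, n=12, p=5, seed=12):
        rng = np.random.default_rng(seed)
        return make_pairs(rng.normal(8, 1, (n, p)), rng.normal(8, 1, (n, p)))

    def test_seeded_determinism(self):
        pairs = self.random_pairs()
        a = mismatched_control(pairs, seed=5)
        b = mismatched_control(pairs, seed=5)
        c = mismatched_control(pairs, seed=6)
        assert [k.plasma_sample_id for k in a.pair_index] == \
            [k.plasma_sample_id for k in b.pair_index]
        assert [k.plasma_sample_id for k in a.pair_index] != \
            [k.plasma_sample_id for k in c.pair_index]

    def test_single_pair_has_no_derangement(self):
        with pytest.raises(ValueError, match="derangement"):
            mismatched_control(self.random_pairs(n=1), seed=0)

    def test_null_fit_centers_on_zero_slope_and_plasma_mean(self):
        cfg = SynthConfig(seed=13, n_cohorts=1, pairs_per_cohort=100,
                          n_proteins=400, n_latent=400, latent_decay=1.0,
                          fraction_lod=0, fraction_coag=0, t1_fraction=0,
                          contaminated_cohort=None, contamination_panel_size=0,
                          n_reference_serum=4, n_reference_plasma=4)
        pairs = generate_cohorts(cfg).paired()
        fm = fit_scaling_factors(mismatched_control(pairs, seed=4))
        assert abs(fm.table["slope"].mean()) < 0.05
        dev = fm.table["intercept"].to_numpy() - pairs.plasma_values().mean(0)
        assert abs(dev.mean()) < 0.1


class TestCompareFactorSets:
    def test_self_comparison_is_perfect(self):
        rng = np.random.default_rng(14)
        x = rng.normal(8, 1, (20, 40))
        f = fit_scaling_factors(make_pairs(x, x + rng.normal(0, 0.3, x.shape)))
        cmp_ = compare_factor_sets(f, f)
        assert cmp_.slope_r == pytest.approx(1.0)
        assert cmp_.intercept_r == pytest.approx(1.0)
        assert cmp_.n_shared == 40

    def test_disjoint_sets_rejected(self):
        t1 = pd.DataFrame({"slope": 1.0, "intercept": 0.0, "n_pairs": 5},
                          index=[f"A{i}" for i in range(12)])
        t2 = pd.DataFrame({"slope": 1.0, "intercept": 0.0, "n_pairs": 5},
                          index=[f"B{i}" for i in range(12)])
        with pytest.raises(ValueError, match="shared proteins"):
            compare_factor_sets(ScalingFactorSet(t1), ScalingFactorSet(t2))

    def test_attenuation_of_agreement_under_estimation_noise(self):
        # two independent noisy estimates of the same truth: expected
        # correlation σ²/(σ²+τ²)
        rng = np.random.default_rng(15)
        sigma, tau, n = 0.3, 0.3, 3000
        truth = rng.normal(1.0, sigma, n)
        ids = [f"P{i}" for i in range(n)]
        mk = lambda: ScalingFactorSet(pd.DataFrame(
            {"slope": truth + rng.normal(0, tau, n),
             "intercept": rng.normal(0, 0.1, n),
             "n_pairs": 10}, index=ids))
        cmp_ = compare_factor_sets(mk(), mk())
        expected = sigma ** 2 / (sigma ** 2 + tau ** 2)
        assert cmp_.slope_r == pytest.approx(expected, abs=0.05)
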