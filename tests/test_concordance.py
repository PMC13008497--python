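"""Concordance screen, BH adjustment, ratio classification, enrichment, PCA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from plasmabridge import (MarkerPanel, Scale, bh_adjust, panel_enrichment,
                          pc_association, protein_concordance,
                          ratio_classification, select_proteins)

from .conftest import make_matrix, make_pairs


def bh_oracle(p):
    """Literal step-up: q_i = min over j≥rank(i) of m·p_(j)/j, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    prev = np.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * m / rank)
        q[i] = min(prev, 1.0)
    return q


def fisher_two_sided_oracle(k, K, n, N):
    """Two-sided Fisher p as the hypergeometric sum of all tables with
    probability ≤ the observed table's."""
    rv = stats.hypergeom(N, K, n)
    support = np.arange(max(0, n + K - N), min(K, n) + 1)
    pmf = rv.pmf(support)
    return float(pmf[pmf <= rv.pmf(k) * (1 + 1e-7)].sum())


class TestBhAdjust:
    def test_single_p_is_identity(self):
        np.testing.assert_allclose(bh_adjust([0.03]), [0.03])

    def test_uniform_ladder(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])
        with pytest.raises(ValueError):
            bh_adjust([np.nan, 0.2])

    def test_matches_oracles_on_random_vectors(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(11)
        for _ in range(1000):
            p = rng.uniform(size=rng.integers(1, 40))
            q = bh_adjust(p)
            np.testing.assert_allclose(q, bh_oracle(p), atol=1e-12)
            np.testing.assert_allclose(
                q, multipletests(p, method="fdr_bh")[1], atol=1e-12)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_order_preserving_and_capped(self, p):
        q = bh_adjust(p)
        assert (q <= 1).all() and (q >= np.asarray(p)).all()
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(q[order]) >= -1e-15).all()


class TestProteinConcordance:
    def test_monotone_nonlinear_gives_perfect_spearman(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, (30, 4))
        table = protein_concordance(make_pairs(x, x ** 3))
        np.testing.assert_allclose(table["spearman_r"], 1.0)
        assert (table["pearson_r"] < 1.0).all()
        np.testing.assert_allclose(table["spearman_p"], 0.0, atol=1e-12)

    def test_anticorrelated(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(20, 3))
        table = protein_concordance(make_pairs(x, -x))
        np.testing.assert_allclose(table["spearman_r"], -1.0)

    def test_zero_variance_protein_flagged_not_selected(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(10, 2))
        y = x.copy()
        x[:, 0] = 5.0
        table = protein_concordance(make_pairs(x, y))
        assert table.loc["PROT0", "flag"] == "zero_variance"
        assert np.isnan(table.loc["PROT0", "spearman_q"])
        assert select_proteins(table) == {"PROT1"}

    def test_exact_small_sample_p_matches_enumeration(self):
        from itertools import permutations

        from plasmabridge.concordance import _spearman_p_exact
        n = 6
        base = np.arange(1, n + 1)
        rho_obs = 1 - 6 * np.sum((base - base[::-1]) ** 2) / (n * (n ** 2 - 1))
        null = [1 - 6 * np.sum((base - np.array(p)) ** 2) / (n * (n ** 2 - 1))
                for p in permutations(base)]
        expected = np.mean(np.abs(null) >= abs(rho_obs) - 1e-12)
        assert _spearman_p_exact(rho_obs, n) == pytest.approx(expected)

    def test_requires_five_pairs(self):
        with pytest.raises(ValueError, match="≥5"):
            protein_concordance(make_pairs(np.ones((4, 2)), np.ones((4, 2))))


class TestSelectProteins:
    def table(self):
        return pd.DataFrame(
            {"spearman_q": [0.2, 0.01, 0.01], "spearman_r": [0.9, 0.9, 0.25]},
            index=["a", "b", "c"])

    def test_q_threshold(self):
        assert select_proteins(self.table()) == {"b", "c"}

    def test_r_floor_excludes_weak_correlations(self):
        assert select_proteins(self.table(), r_floor=0.3) == {"b"}


class TestRatioClassification:
    def test_identical_matrices_all_central(self):
        rng = np.random.default_rng(3)
        x = np.exp(rng.normal(2, 1, (10, 6)))
        table = ratio_classification(make_pairs(x, x, scale=Scale.RAW_RFU))
        np.testing.assert_allclose(table["median_plasma_serum_ratio"], 1.0)
        assert (table["ratio_class"] == "central").all()

    def test_extreme_ratio_proteins_classified(self):
        rng = np.random.default_rng(4)
        serum = np.exp(rng.normal(2, 0.2, (20, 502)))
        plasma = serum * np.exp(rng.normal(0, 0.05, serum.shape))
        plasma[:, 0] = serum[:, 0] * 100.0   # fibrinogen-like, plasma-retained
        plasma[:, 1] = serum[:, 1] * 0.01    # thrombin-like, serum-accumulated
        table = ratio_classification(make_pairs(serum, plasma,
                                                scale=Scale.RAW_RFU))
        assert table.iloc[0]["ratio_class"] == "high_plasma"
        assert table.iloc[1]["ratio_class"] == "high_serum"
        assert (table.iloc[2:]["ratio_class"] == "central").all()

    def test_invariant_to_common_positive_rescaling(self):
        rng = np.random.default_rng(5)
        s = np.exp(rng.normal(2, 1, (12, 8)))
        p = np.exp(rng.normal(2, 1, (12, 8)))
        t1 = ratio_classification(make_pairs(s, p, scale=Scale.RAW_RFU))
        t2 = ratio_classification(make_pairs(7.5 * s, 7.5 * p,
                                             scale=Scale.RAW_RFU))
        np.testing.assert_allclose(t1["median_plasma_serum_ratio"],
                                   t2["median_plasma_serum_ratio"])
        assert (t1["ratio_class"] == t2["ratio_class"]).all()

    def test_requires_raw_scale(self):
        with pytest.raises(ValueError, match="raw-RFU"):
            ratio_classification(make_pairs(np.ones((5, 2)), np.ones((5, 2))))


class TestPanelEnrichment:
    def test_selection_equal_to_panel_is_extreme(self):
        universe = [f"P{i}" for i in range(1000)]
        panel = MarkerPanel("m", frozenset(universe[:20]))
        rows = panel_enrichment(set(universe[:20]), universe, [panel])
        assert rows[0].fisher_p < 1e-20
        assert rows[0].enriched

    def test_matches_hypergeometric_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(40):
            N = int(rng.integers(30, 200))
            universe = [f"P{i}" for i in range(N)]
            K = int(rng.integers(2, N // 2))
            n = int(rng.integers(1, N))
            panel = MarkerPanel("m", frozenset(rng.choice(universe, K,
                                                          replace=False)))
            selected = set(rng.choice(universe, n, replace=False))
            row = panel_enrichment(selected, universe, [panel])[0]
            k = len(selected & panel.protein_ids)
            assert row.fisher_p == pytest.approx(
                fisher_two_sided_oracle(k, K, n, N), abs=1e-10)

    def test_disjoint_panel_skipped_with_warning(self):
        panel = MarkerPanel("ghost", frozenset({"X1"}))
        with pytest.warns(UserWarning, match="disjoint"):
            rows = panel_enrichment({"P1"}, {"P1", "P2"}, [panel])
        assert rows == []

    def test_random_selection_false_positive_rate_near_fdr(self):
        rng = np.random.default_rng(7)
        universe = [f"P{i}" for i in range(400)]
        panels = [MarkerPanel(f"pan{j}",
                              frozenset(rng.choice(universe, 25, replace=False)))
                  for j in range(4)]
        hits = total = 0
        for _ in range(150):
            selected = set(rng.choice(universe, 60, replace=False))
            for row in panel_enrichment(selected, universe, panels, fdr=0.1):
                hits += row.enriched
                total += 1
        assert hits / total < 0.1  # BH keeps the panel-level FDR below target


class TestLodInflationDiagnostic:
    def test_floor_compressed_proteins_show_pearson_inflation(self):
        """LOD-floored proteins with rare high outliers: large
        Pearson−Spearman gap at small distance-from-floor, yielding a
        negative rank correlation between gap and distance."""
        from scipy import stats as sps

        from plasmabridge import SynthConfig, generate_cohorts, lod_inflation_diagnostic
        data = generate_cohorts(SynthConfig(
            seed=77, n_cohorts=1, pairs_per_cohort=40, n_proteins=200,
            fraction_lod=0.2, contaminated_cohort=None,
            contamination_panel_size=0, n_reference_serum=4,
            n_reference_plasma=4))
        pairs = data.paired()
        # plant rare concordant outliers on the LOD proteins so Pearson
        # inflates while ranks stay noise-dominated
        truth = data.truth.proteins
        lod = [p for p in pairs.protein_ids
               if truth.loc[p, "protein_class"] == "lod"]
        serum = pairs.serum.values.copy()
        plasma = pairs.plasma.values.copy()
        serum.iloc[0, [pairs.protein_ids.index(p) for p in lod]] += 6.0
        plasma.iloc[0, [pairs.protein_ids.index(p) for p in lod]] += 6.0
        from plasmabridge.core import PairedDataset, ProteomicMatrix, Scale
        planted = PairedDataset(
            serum=ProteomicMatrix(values=serum, scale=Scale.LOG2,
                                  metadata=pairs.serum.metadata),
            plasma=ProteomicMatrix(values=plasma, scale=Scale.LOG2,
                                   metadata=pairs.plasma.metadata),
            pair_index=list(pairs.pair_index))
        diag = lod_inflation_diagnostic(planted)
        assert diag.loc[lod, "pearson_minus_spearman"].median() > 0.2
        rho, _ = sps.spearmanr(diag["pearson_minus_spearman"],
                               diag["distance_from_floor"])
        assert rho < -0.3

    def test_rank_group_test_levels(self):
        from plasmabridge import rank_group_test
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 30), rng.normal(2, 1, 30)
        assert rank_group_test(np.r_[a, b], ["x"] * 30 + ["y"] * 30) < 1e-6
        with pytest.raises(ValueError, match="2 label levels"):
            rank_group_test(a, ["x"] * 30)


class TestPcAssociation:
    def test_specimen_offset_dominates_first_component(self):
        rng = np.random.default_rng(8)
        n, p = 40, 60
        x = rng.normal(0, 1, (n, p))
        labels = np.array(["serum"] * (n // 2) + ["plasma"] * (n // 2))
        x[labels == "plasma", : p // 2] += 3.0
        m = make_matrix(x)
        res = pc_association(m, labels, n_components=5)
        assert res.loc[0, "p_value"] < 0.05
        assert res.loc[0, "explained_variance_ratio"] == \
            res["explained_variance_ratio"].max()

    def test_three_level_labels_use_kruskal(self):
        rng = np.random.default_rng(9)
        m = make_matrix(rng.normal(size=(30, 20)))
        labels = np.array(["a", "b", "c"] * 10)
        res = pc_association(m, labels, n_components=4)
        assert ((res["p_value"] > 0) & (res["p_value"] <= 1)).all()

    def test_single_label_level_rejected(self):
        m = make_matrix(np.random.default_rng(10).normal(size=(10, 5)))
        with pytest.raises(ValueError, match="2 levels"):
            pc_association(m, ["x"] * 10)

    def test_permuted_labels_yield_unremarkable_p_values(self):
        rng = np.random.default_rng(12)
        m = make_matrix(rng.normal(size=(60, 40)))
        count = sig = 0
        for _ in range(25):
            labels = rng.permutation(["serum"] * 30 + ["plasma"] * 30)
            res = pc_association(m, labels, n_components=8)
            sig += (res["p_value"] < 0.05).sum()
            count += len(res)
        assert 0.0 <= sig / count < 0.15  # ≈5% expected under the null
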