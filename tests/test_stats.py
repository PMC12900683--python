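"""Inferential layer: t-tests against hand computations, NBS calibration
and power, ANOVA against the statsmodels oracle, power analysis."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from plvnet.core import DataError
from plvnet.simulate import simulate_edge_cohort
from plvnet.stats import (
    FactorialANOVA,
    NetworkBasedStatistic,
    PowerQuery,
    achieved_power,
    bonferroni_posthoc,
    nbs,
    pearson,
    power_min_n,
    ttest_from_summary,
    ttest_ind,
    two_way_anova,
    two_way_anova_from_summary,
)


class TestTTest:
    def test_identical_samples_give_zero_t(self):
        a = [1.0, 2.0, 3.0, 4.0]
        res = ttest_ind(a, list(a))
        assert res.t == 0.0 and res.p == pytest.approx(1.0)

    def test_hand_computed_four_point_fixture(self):
        """a=(1,3), b=(2,6): pooled s² = (2+8)/2 = 5,
        t = (2−4)/√(5·(1/2+1/2)) = −2/√5."""
        res = ttest_ind([1.0, 3.0], [2.0, 6.0])
        assert res.t == pytest.approx(-2 / np.sqrt(5), abs=1e-12)
        assert res.df == 2

    def test_swap_negates_t_keeps_p(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 10), rng.normal(1, 1, 12)
        r1, r2 = ttest_ind(a, b), ttest_ind(b, a)
        assert r1.t == pytest.approx(-r2.t) and r1.p == pytest.approx(r2.p)

    def test_zero_pooled_variance_rejected(self):
        with pytest.raises(DataError):
            ttest_ind([1.0, 1.0], [2.0, 2.0])

    @given(st.integers(0, 2**31 - 1))
    def test_summary_form_equals_raw_form(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(0, 2, 8), rng.normal(1, 2, 11)
        raw = ttest_ind(a, b)
        summ = ttest_from_summary(a.mean(), a.std(ddof=1), a.size,
                                  b.mean(), b.std(ddof=1), b.size)
        assert summ.t == pytest.approx(raw.t, rel=1e-12)
        assert summ.p == pytest.approx(raw.p, rel=1e-12)

    def test_published_baseline_affect_contrasts(self):
        """Printed PANAS group summaries reproduce the printed t values."""
        pa = ttest_from_summary(19.260, 2.813, 50, 30.083, 1.867, 48)
        na = ttest_from_summary(32.620, 4.280, 50, 14.583, 1.674, 48)
        assert pa.t == pytest.approx(-22.351, abs=0.05)
        assert na.t == pytest.approx(27.257, abs=0.05)
        assert pa.df == 96

    def test_equal_means_zero_t_from_summary(self):
        res = ttest_from_summary(5.0, 1.0, 10, 5.0, 2.0, 12)
        assert res.t == 0.0


class TestPearson:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        assert pearson(x, 2 * x + 1).r == pytest.approx(1.0)
        assert pearson(x, -x).r == pytest.approx(-1.0)

    def test_bivariate_gaussian_recovery(self):
        rng = np.random.default_rng(3)
        n = 10**4
        x = rng.normal(size=n)
        y = 0.5 * x + np.sqrt(1 - 0.25) * rng.normal(size=n)
        assert pearson(x, y).r == pytest.approx(0.5, abs=0.02)

    def test_constant_input_rejected(self):
        with pytest.raises(DataError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestBonferroni:
    def _cells(self):
        rng = np.random.default_rng(1)
        return {"a": rng.normal(0, 1, 10), "b": rng.normal(0.5, 1, 10),
                "c": rng.normal(1.0, 1, 10)}

    def test_single_contrast_unadjusted(self):
        cells = self._cells()
        out = bonferroni_posthoc(cells, [("a", "b")])
        assert out["p_adj"].iloc[0] == pytest.approx(out["p_raw"].iloc[0])

    def test_family_of_three_triples_p(self):
        cells = self._cells()
        out = bonferroni_posthoc(cells, [("a", "b"), ("a", "c"), ("b", "c")])
        for _, row in out.iterrows():
            assert row["p_adj"] == pytest.approx(min(3 * row["p_raw"], 1.0))

    def test_adjusted_p_capped_at_one(self):
        cells = {"a": [1.0, 2.0, 3.0], "b": [1.1, 2.1, 2.9]}
        out = bonferroni_posthoc(cells, [("a", "b")] * 5)
        assert (out["p_adj"] <= 1.0).all()

    def test_empty_family_rejected(self):
        with pytest.raises(DataError):
            bonferroni_posthoc({"a": [1, 2]}, [])


class TestPower:
    def test_published_minimum_sample_size(self):
        """d=0.80, α=0.05, power 0.95 → 84 participants in total."""
        q = PowerQuery("two_sample_t", effect_size=0.80, alpha=0.05, power=0.95)
        assert power_min_n(q) == 84

    def test_huge_effect_saturates_at_minimal_n(self):
        q = PowerQuery("two_sample_t", effect_size=10.0, power=0.80)
        assert power_min_n(q) == 4

    def test_bisection_consistency(self):
        """Power is met at the returned N and not met at N − 2."""
        q = PowerQuery("two_sample_t", effect_size=0.5, power=0.90)
        n = power_min_n(q)
        assert achieved_power(q, n) >= 0.90
        assert achieved_power(q, n - 2) < 0.90

    def test_monotone_in_effect_size_and_power(self):
        base = dict(test="two_sample_t", alpha=0.05)
        n_small = power_min_n(PowerQuery(effect_size=0.4, power=0.8, **base))
        n_large = power_min_n(PowerQuery(effect_size=0.8, power=0.8, **base))
        assert n_small >= n_large
        n_lo = power_min_n(PowerQuery(effect_size=0.5, power=0.80, **base))
        n_hi = power_min_n(PowerQuery(effect_size=0.5, power=0.95, **base))
        assert n_hi >= n_lo

    def test_anova_f_design_size(self):
        """Cohen's f = 0.40, α = 0.05, power 0.80 for a 6-cell design with
        a 2-df effect needs 64 participants in total."""
        q = PowerQuery("anova_f", effect_size=0.40, alpha=0.05, power=0.80,
                       n_groups=6, df_num=2)
        assert power_min_n(q) == 64

    def test_invalid_queries_rejected(self):
        with pytest.raises(DataError):
            PowerQuery(effect_size=0.0)
        with pytest.raises(DataError):
            PowerQuery(alpha=1.5)


class TestNBS:
    def test_null_rarely_significant(self):
        """Identical generating distributions: significant components should
        appear at roughly the nominal component alpha."""
        hits = 0
        for rep in range(20):
            Xa, _ = simulate_edge_cohort(12, 12, seed=2 * rep)
            Xb, _ = simulate_edge_cohort(12, 12, seed=2 * rep + 1)
            res = nbs(Xa, Xb, n_perm=200, seed=rep)
            hits += bool(res.significant_components)
        assert hits <= 4  # ~binomial(20, 0.05); 4 allows wide slack

    def test_planted_subnetwork_detected(self):
        off = {(i, j): 0.2 for i in range(5) for j in range(i + 1, 5)}
        Xa, pairs = simulate_edge_cohort(15, 20, noise_sd=0.1, seed=10)
        Xb, _ = simulate_edge_cohort(15, 20, noise_sd=0.1, edge_offsets=off,
                                     seed=11)
        res = nbs(Xa, Xb, n_perm=500, seed=0, pairs=pairs)
        assert res.significant_components
        top = res.significant_components[0]
        planted = set(off)
        found = set(top.edges)
        assert len(found & planted) >= 8  # most of the K5 clique recovered

    def test_component_p_uses_plus_one_convention(self):
        Xa, _ = simulate_edge_cohort(10, 8, seed=0)
        Xb, _ = simulate_edge_cohort(10, 8, edge_offsets={(0, 1): 0.5}, seed=1)
        res = nbs(Xa, Xb, n_perm=99, seed=5)
        for comp in res.observed_components:
            assert comp.p >= 1 / 100
            assert comp.p <= 1.0

    def test_deterministic_and_subject_order_invariant(self):
        Xa, _ = simulate_edge_cohort(10, 10, seed=3)
        Xb, _ = simulate_edge_cohort(10, 10, seed=4)
        r1 = nbs(Xa, Xb, n_perm=100, seed=7)
        r2 = nbs(Xa, Xb, n_perm=100, seed=7)
        np.testing.assert_array_equal(r1.null_max_sizes, r2.null_max_sizes)
        perm = np.random.default_rng(0).permutation(10)
        r3 = nbs(Xa[perm], Xb, n_perm=100, seed=7)
        np.testing.assert_allclose(np.sort(r1.edge_t), np.sort(r3.edge_t))

    def test_no_suprathreshold_edges_is_empty_result(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(1, 6))
        Xa = base + 1e-3 * rng.normal(size=(10, 6))
        Xb = base + 1e-3 * rng.normal(size=(10, 6))
        res = NetworkBasedStatistic(Xa, Xb, pairs=[(0, 1), (0, 2), (0, 3),
                                                   (1, 2), (1, 3), (2, 3)],
                                    edge_alpha=1e-9, n_perm=50).fit(seed=0)
        assert res.observed_components == []

    def test_invalid_inputs_rejected(self):
        Xa, _ = simulate_edge_cohort(5, 4, seed=0)
        Xb, _ = simulate_edge_cohort(5, 4, seed=1)
        with pytest.raises(DataError):
            NetworkBasedStatistic(Xa, Xb, n_perm=0)
        with pytest.raises(DataError):
            NetworkBasedStatistic(Xa[:1], Xb)

    def test_summary_table_lists_components(self):
        Xa, _ = simulate_edge_cohort(12, 8, seed=0)
        Xb, _ = simulate_edge_cohort(12, 8, edge_offsets={(0, 1): 0.4,
                                                          (1, 2): 0.4}, seed=1)
        res = nbs(Xa, Xb, n_perm=100, seed=0)
        table = res.summary()
        assert list(table.columns) == ["component", "size", "sign", "p",
                                       "significant", "edges"]
        assert len(table) == len(res.observed_components)


def _balanced_frame(cells: np.ndarray) -> pd.DataFrame:
    """(2, 3, n) array → long-format frame with group/condition columns."""
    rows = []
    for i, g in enumerate(["ScD", "HC"]):
        for j, c in enumerate(["NEC", "REI", "VR-EI"]):
            for v in cells[i, j]:
                rows.append({"group": g, "condition": c, "value": float(v)})
    return pd.DataFrame(rows)


class TestFactorialANOVA:
    #: 12-subject integer fixture, hand-decomposable sums of squares.
    FIXTURE = np.array([[[4, 6], [8, 10], [12, 14]],
                        [[5, 7], [6, 8], [7, 9]]], dtype=float)

    def test_matches_statsmodels_oracle(self):
        """Closed-form balanced decomposition equals OLS + anova_lm."""
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        df = _balanced_frame(self.FIXTURE)
        res = two_way_anova(df, "value")
        fit = ols("value ~ C(group) * C(condition)", data=df).fit()
        table = sm.stats.anova_lm(fit, typ=2)
        assert res["A"].F == pytest.approx(table.loc["C(group)", "F"], rel=1e-9)
        assert res["B"].F == pytest.approx(table.loc["C(condition)", "F"], rel=1e-9)
        assert res["A:B"].F == pytest.approx(
            table.loc["C(group):C(condition)", "F"], rel=1e-9)
        assert res.ss_error == pytest.approx(table.loc["Residual", "sum_sq"],
                                             rel=1e-12)

    def test_sums_of_squares_conserve_total(self):
        df = _balanced_frame(self.FIXTURE)
        res = two_way_anova(df, "value")
        parts = sum(e.ss for e in res.effects.values()) + res.ss_error
        assert parts == pytest.approx(res.ss_total, rel=1e-12)

    def test_partial_eta_squared_definition(self):
        df = _balanced_frame(self.FIXTURE)
        res = two_way_anova(df, "value")
        for e in res.effects.values():
            assert e.partial_eta_sq == pytest.approx(
                e.ss / (e.ss + res.ss_error), rel=1e-12)
            assert 0.0 <= e.partial_eta_sq <= 1.0

    def test_equal_cell_means_give_zero_f(self):
        cells = np.tile(np.array([1.0, 2.0, 3.0]), (2, 3, 1))
        res = two_way_anova(_balanced_frame(cells), "value")
        for e in res.effects.values():
            assert e.F == pytest.approx(0.0, abs=1e-20)

    def test_location_invariance(self):
        df = _balanced_frame(self.FIXTURE)
        shifted = df.assign(value=df["value"] + 100.0)
        r1, r2 = two_way_anova(df, "value"), two_way_anova(shifted, "value")
        for k in r1.effects:
            assert r1[k].F == pytest.approx(r2[k].F, rel=1e-9)
            assert r1[k].partial_eta_sq == pytest.approx(
                r2[k].partial_eta_sq, rel=1e-9)

    def test_unbalanced_design_rejected_with_counts(self):
        df = _balanced_frame(self.FIXTURE).iloc[:-1]
        with pytest.raises(DataError, match="unbalanced"):
            two_way_anova(df, "value")

    def test_model_results_summary_shape(self):
        model = FactorialANOVA.from_dataframe(_balanced_frame(self.FIXTURE),
                                              "value")
        res = model.fit()
        table = res.summary()
        assert list(table["effect"]) == ["group", "condition",
                                        "group:condition", "error"]


class TestAnovaFromSummary:
    def test_agrees_with_raw_data_decomposition(self):
        cells = TestFactorialANOVA.FIXTURE
        raw = two_way_anova(_balanced_frame(cells), "value")
        summ = two_way_anova_from_summary(cells.mean(axis=2),
                                          cells.std(axis=2, ddof=1), n=2)
        for k in raw.effects:
            assert summ[k].F == pytest.approx(raw[k].F, rel=1e-9)
            assert summ[k].partial_eta_sq == pytest.approx(
                raw[k].partial_eta_sq, rel=1e-9)

    def test_published_interaction_reconstruction(self):
        """Interaction F recomputed from the printed post-intervention
        affect cell summaries (n=15/cell) lands within 10% of the printed
        values — the printed error-term construction is not fully
        specified, so this is a consistency band, not an equality."""
        pa = two_way_anova_from_summary(
            [[15.200, 24.600, 27.267], [17.533, 18.867, 19.200]],
            [[1.146, 1.682, 1.981], [2.167, 2.722, 3.005]], n=15)
        na = two_way_anova_from_summary(
            [[28.667, 21.267, 15.933], [18.467, 18.600, 18.000]],
            [[2.093, 3.788, 1.907], [2.532, 3.019, 2.449]], n=15)
        assert pa["A:B"].F == pytest.approx(44.359, rel=0.10)
        assert na["A:B"].F == pytest.approx(38.002, rel=0.10)
        assert pa["A:B"].p < 0.001 and na["A:B"].p < 0.001
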