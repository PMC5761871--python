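"""Rank-based cohort statistics: ranks, Spearman, ANOVA, Bonferroni, normality."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lungquant import (
    PairedOutcomes,
    bonferroni_timepoint_tests,
    generate_cohort,
    rank_transform,
    shapiro_wilk_gate,
    spearman,
    two_way_anova_ranked,
)


class TestRankTransform:
    def test_strictly_increasing(self):
        assert list(rank_transform([10, 20, 30])) == [1, 2, 3]

    def test_tie_averaging(self):
        assert list(rank_transform([5, 5, 9])) == [1.5, 1.5, 3]

    def test_matches_sort_based_oracle(self, rng):
        values = rng.integers(0, 20, size=60).astype(float)  # many ties
        ranks = rank_transform(values)
        # oracle: sort, then assign each tie group the mean of its positions
        order = np.argsort(values, kind="stable")
        expected = np.empty_like(values)
        pos = 0
        sorted_vals = values[order]
        while pos < len(values):
            end = pos
            while end < len(values) and sorted_vals[end] == sorted_vals[pos]:
                end += 1
            expected[order[pos:end]] = np.mean(np.arange(pos, end) + 1)
            pos = end
        assert np.allclose(ranks, expected)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=40))
    def test_rank_sum_invariant(self, values):
        n = len(values)
        assert rank_transform(values).sum() == pytest.approx(n * (n + 1) / 2)

    def test_empty_and_singleton_rejected(self):
        with pytest.raises(ValueError):
            rank_transform([])
        with pytest.raises(ValueError):
            rank_transform([1.0])


def _brute_force_rho(x, y):
    """Oracle: Pearson correlation of tie-averaged ranks, from first principles."""
    from scipy.stats import rankdata

    rx, ry = rankdata(x), rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry)))


class TestSpearman:
    def test_perfectly_increasing(self):
        res = spearman([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        assert res.rho == pytest.approx(1.0)

    def test_self_and_negated_self(self, rng):
        x = rng.normal(size=15)
        assert spearman(x, x).rho == pytest.approx(1.0)
        assert spearman(x, -x).rho == pytest.approx(-1.0)

    def test_discordant_quadruple_matches_formula_oracle(self):
        x = [1.0, 2.0, 3.0, 4.0]
        y = [1.0, 2.0, 4.0, 3.0]  # one discordant pair
        res = spearman(x, y)
        assert res.rho == pytest.approx(_brute_force_rho(x, y))
        assert res.rho == pytest.approx(0.8)

    def test_monotone_transform_invariance(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        base = spearman(x, y).rho
        assert spearman(np.exp(x), y).rho == pytest.approx(base)
        assert spearman(x, y ** 3 + 5 * y).rho == pytest.approx(base)

    def test_exact_permutation_p_for_small_n(self):
        x = [1.0, 2.0, 3.0, 4.0]
        y = [1.0, 2.0, 3.0, 4.0]
        res = spearman(x, y)
        assert res.method == "exact"
        # 2 of 24 permutations reach |rho| = 1
        assert res.p_value == pytest.approx(2 / 24)

    def test_t_approximation_for_large_n(self, rng):
        x = rng.normal(size=30)
        res = spearman(x, x + rng.normal(scale=0.4, size=30))
        assert res.method == "t-approx"
        assert 0 <= res.p_value <= 1

    def test_constant_margin_undefined(self):
        res = spearman([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])
        assert res.method == "undefined"
        assert np.isnan(res.rho)

    def test_minimum_pair_count(self):
        with pytest.raises(ValueError):
            spearman([1.0, 2.0], [2.0, 1.0])

    def test_paired_outcomes_drop_incomplete_pairs(self):
        pairs = PairedOutcomes(
            np.array(["a", "b", "c", "d"]),
            np.array([1.0, 2.0, np.nan, 4.0]),
            np.array([1.0, 2.0, 3.0, 4.0]),
        )
        assert pairs.n == 3
        assert spearman(pairs).rho == pytest.approx(1.0)


def _make_table(values_by_cell):
    rows = []
    i = 0
    for (g, a), vals in values_by_cell.items():
        for v in vals:
            rows.append((f"m{i}", g, a, float(v)))
            i += 1
    return pd.DataFrame(rows, columns=["animal_id", "genotype", "age_months", "value"])


def _anova_oracle_balanced_2x2(table):
    """Textbook sums-of-squares on ranks for a balanced 2x2 design."""
    from scipy.stats import rankdata

    df = table.copy()
    df["r"] = rankdata(df["value"])
    grand = df["r"].mean()
    n = len(df)
    cell = df.groupby(["genotype", "age_months"])["r"].mean()
    gmean = df.groupby("genotype")["r"].mean()
    amean = df.groupby("age_months")["r"].mean()
    n_per_cell = n / 4
    ss_g = 2 * n_per_cell * sum((m - grand) ** 2 for m in gmean)
    ss_a = 2 * n_per_cell * sum((m - grand) ** 2 for m in amean)
    ss_cells = n_per_cell * sum((m - grand) ** 2 for m in cell)
    ss_int = ss_cells - ss_g - ss_a
    ss_err = sum(
        (row.r - cell[(row.genotype, row.age_months)]) ** 2 for row in df.itertuples()
    )
    dfe = n - 4
    return {
        "genotype": (ss_g / 1) / (ss_err / dfe),
        "age_months": (ss_a / 1) / (ss_err / dfe),
        "genotype:age_months": (ss_int / 1) / (ss_err / dfe),
    }


class TestTwoWayAnova:
    def test_constant_response_gives_zero_f(self):
        table = _make_table({("WT", 3.0): [5, 5, 5], ("WT", 12.0): [5, 5, 5],
                             ("TNF-Tg", 3.0): [5, 5, 5], ("TNF-Tg", 12.0): [5, 5, 5]})
        res = two_way_anova_ranked(table)
        for effect in ("genotype", "age_months", "genotype:age_months"):
            assert res.f_value(effect) == 0.0

    def test_balanced_2x2_matches_hand_computed_f(self, rng):
        table = _make_table({
            ("WT", 3.0): rng.normal(0, 1, 3),
            ("WT", 12.0): rng.normal(1, 1, 3),
            ("TNF-Tg", 3.0): rng.normal(2, 1, 3),
            ("TNF-Tg", 12.0): rng.normal(3, 1, 3),
        })
        res = two_way_anova_ranked(table)
        oracle = _anova_oracle_balanced_2x2(table)
        for effect, f_expected in oracle.items():
            assert res.f_value(effect) == pytest.approx(f_expected, rel=1e-6)

    def test_genotype_shift_detected_with_high_power(self):
        detected = 0
        n_sim = 40
        for rep in range(n_sim):
            rng = np.random.default_rng(5000 + rep)
            table = _make_table({
                (g, a): rng.normal(2.0 * (g == "TNF-Tg"), 1.0, 6)
                for g in ("WT", "TNF-Tg") for a in (3.0, 4.0, 5.5, 12.0)
            })
            if two_way_anova_ranked(table).p_value("genotype") < 0.05:
                detected += 1
        assert detected / n_sim >= 0.9

    def test_empty_cell_named_in_error(self):
        table = _make_table({("WT", 3.0): [1, 2], ("WT", 12.0): [3, 4],
                             ("TNF-Tg", 3.0): [5, 6]})
        with pytest.raises(ValueError, match="12"):
            two_way_anova_ranked(table)

    def test_tukey_table_produced(self, rng):
        table = _make_table({
            (g, a): rng.normal(0, 1, 4)
            for g in ("WT", "TNF-Tg") for a in (3.0, 12.0)
        })
        res = two_way_anova_ranked(table)
        assert len(res.tukey) == 6  # C(4 cells, 2) comparisons

    def test_type_iii_available(self, rng):
        table = _make_table({
            (g, a): rng.normal(0, 1, 3 + (g == "WT"))
            for g in ("WT", "TNF-Tg") for a in (3.0, 12.0)
        })
        res2 = two_way_anova_ranked(table, ss_type=2)
        res3 = two_way_anova_ranked(table, ss_type=3)
        assert set(res3.table.index) >= {"genotype", "age_months"}
        assert res2.ss_type == 2 and res3.ss_type == 3


class TestBonferroniTimepoints:
    def test_corrected_alpha_is_alpha_over_k(self, rng):
        table = _make_table({
            (g, a): rng.normal(0, 1, 4)
            for g in ("WT", "TNF-Tg") for a in (3.0, 4.0, 5.5, 12.0)
        })
        results = bonferroni_timepoint_tests(table, alpha=0.05, k=4)
        assert all(r.corrected_alpha == pytest.approx(0.0125) for r in results)
        assert len(results) == 4

    def test_identical_groups_not_significant(self):
        table = _make_table({("WT", 3.0): [1, 2, 3], ("TNF-Tg", 3.0): [1, 2, 3]})
        (res,) = bonferroni_timepoint_tests(table, k=1)
        assert res.p_value > 0.9
        assert not res.significant

    def test_small_group_flagged_not_computable(self):
        table = _make_table({("WT", 3.0): [1.0], ("TNF-Tg", 3.0): [2.0, 3.0]})
        (res,) = bonferroni_timepoint_tests(table)
        assert not res.computable
        assert np.isnan(res.p_value)

    def test_strong_shift_detected(self, rng):
        table = _make_table({("WT", 3.0): rng.normal(0, 1, 6),
                             ("TNF-Tg", 3.0): rng.normal(5, 1, 6)})
        (res,) = bonferroni_timepoint_tests(table)
        assert res.significant


class TestShapiroGate:
    def test_skewed_samples_flagged_non_normal(self):
        flagged = 0
        n_sim = 200
        for rep in range(n_sim):
            rng = np.random.default_rng(9000 + rep)
            res = shapiro_wilk_gate(rng.exponential(size=20))
            flagged += res.rank_transform_recommended
        assert flagged / n_sim >= 0.8

    def test_normal_samples_pass_at_nominal_rate(self):
        passed = 0
        n_sim = 300
        for rep in range(n_sim):
            rng = np.random.default_rng(20000 + rep)
            passed += shapiro_wilk_gate(rng.standard_normal(20)).normal
        assert passed / n_sim == pytest.approx(0.95, abs=0.04)

    def test_out_of_range_n_rejected(self):
        with pytest.raises(ValueError):
            shapiro_wilk_gate([1.0, 2.0])


class TestGeneratedCohortStatistics:
    def test_default_cohort_shows_genotype_effect(self):
        table, _ = generate_cohort(n_per_cell=6, rng_seed=42)
        sub = table[table.outcome == "ct_tissue_mm3"]
        res = two_way_anova_ranked(sub)
        assert res.p_value("genotype") < 0.001

    def test_perfect_latent_correlation(self):
        _, pairs = generate_cohort(rho_true=1.0, n_total=20, rng_seed=3)
        assert spearman(pairs).rho == pytest.approx(1.0)
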