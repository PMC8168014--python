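"""Normalizations and the statistical battery against hand-computed oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lhamap.stats import (
    atrophy_compensate,
    normalize_50k,
    one_way_anova_tukey,
    pooled_t_from_summary,
    sidak_adjust,
    two_way_anova_sidak,
    unpaired_t,
)


class TestNormalize50k:
    def test_simple_split(self):
        out = normalize_50k({"A": 10.0, "B": 40.0})
        assert out == {"A": 10_000.0, "B": 40_000.0}

    def test_single_region(self):
        assert normalize_50k({"A": 123.0}) == {"A": 50_000.0}

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            normalize_50k({"A": 0.0})

    @given(
        st.lists(st.floats(min_value=0.01, max_value=1e6), min_size=1, max_size=40)
    )
    @settings(deadline=None, max_examples=50)
    def test_sum_is_always_50k(self, counts):
        out = normalize_50k({f"r{i}": c for i, c in enumerate(counts)})
        assert sum(out.values()) == pytest.approx(50_000.0, abs=1e-6)


class TestAtrophyCompensation:
    def test_reference_volume_is_identity(self):
        counts = {"A": 100.0, "B": 7.5}
        assert atrophy_compensate(counts, 2.75) == counts

    def test_half_volume_halves_counts(self):
        out = atrophy_compensate({"A": 100.0}, 1.375)
        assert out["A"] == pytest.approx(50.0)

    def test_density_mode_is_inverse(self):
        lit = atrophy_compensate({"A": 100.0}, 2.0, mode="literal")["A"]
        den = atrophy_compensate({"A": 100.0}, 2.0, mode="density")["A"]
        assert lit * den == pytest.approx(100.0**2)

    def test_compensation_cancels_under_50k(self):
        """50k normalization after compensation equals 50k normalization alone."""
        counts = {"A": 120.0, "B": 330.0, "C": 55.0}
        direct = normalize_50k(counts)
        composed = normalize_50k(atrophy_compensate(counts, 1.9))
        for r in counts:
            assert composed[r] == pytest.approx(direct[r])

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(ValueError):
            atrophy_compensate({"A": 1.0}, 0.0)


class TestSidak:
    def test_family_of_one_is_identity(self):
        assert sidak_adjust(0.03, 1) == pytest.approx(0.03)

    def test_monotone_and_bounded(self):
        ps = np.linspace(0.001, 0.5, 20)
        adj = sidak_adjust(ps, 28)
        assert (np.diff(adj) >= 0).all()
        assert ((0 <= adj) & (adj <= 1)).all()

    def test_never_exceeds_bonferroni(self):
        for p in (1e-4, 0.01, 0.03):
            for m in (2, 10, 28):
                assert sidak_adjust(p, m) <= min(1.0, m * p) + 1e-12


def _balanced_layout(n_geno=2, n_struct=28, n_rep=3, seed=0, effect=None):
    rng = np.random.default_rng(seed)
    rows = []
    for g in range(n_geno):
        for s in range(n_struct):
            mu = 100 + 10 * s + (effect or 0) * g * (s == 2)
            for _ in range(n_rep):
                rows.append((f"g{g}", f"s{s:02d}", mu + rng.normal(0, 5)))
    return pd.DataFrame(rows, columns=["genotype", "structure", "value"])


def _two_way_ss_oracle(df):
    """Textbook balanced two-way ANOVA sums-of-squares decomposition."""
    grand = df["value"].mean()
    n = len(df)
    cells = df.groupby(["genotype", "structure"])["value"]
    a_means = df.groupby("genotype")["value"].mean()
    b_means = df.groupby("structure")["value"].mean()
    cell_means = cells.mean()
    counts_a = df.groupby("genotype").size()
    counts_b = df.groupby("structure").size()
    counts_cell = cells.size()
    ss_a = float((counts_a * (a_means - grand) ** 2).sum())
    ss_b = float((counts_b * (b_means - grand) ** 2).sum())
    ss_cells = float((counts_cell * (cell_means - grand) ** 2).sum())
    ss_ab = ss_cells - ss_a - ss_b
    ss_res = float(
        sum(((v - v.mean()) ** 2).sum() for _, v in cells)
    )
    df_a = df["genotype"].nunique() - 1
    df_b = df["structure"].nunique() - 1
    df_ab = df_a * df_b
    df_res = n - df["genotype"].nunique() * df["structure"].nunique()
    ms_res = ss_res / df_res
    return {
        "genotype": (ss_a / df_a) / ms_res,
        "structure": (ss_b / df_b) / ms_res,
        "genotype:structure": (ss_ab / df_ab) / ms_res,
        "df_res": df_res,
    }


class TestTwoWayAnova:
    def test_residual_df_matches_balanced_layout(self):
        res, _ = two_way_anova_sidak(_balanced_layout())
        g = res.effect("genotype")
        assert (g["df1"], g["df2"]) == (1.0, 112.0)

    def test_matches_ss_oracle_small_layout(self):
        df = _balanced_layout(n_geno=2, n_struct=2, n_rep=2, seed=4)
        res, _ = two_way_anova_sidak(df)
        oracle = _two_way_ss_oracle(df)
        for effect in ("genotype", "structure", "genotype:structure"):
            assert res.effect(effect)["F"] == pytest.approx(
                oracle[effect], abs=1e-10, rel=1e-10
            )
        assert res.df_residual == oracle["df_res"]

    def test_identical_groups_no_effect(self):
        df = _balanced_layout(seed=9)
        dup = df.copy()
        dup["genotype"] = dup["genotype"].map({"g0": "g1", "g1": "g0"})
        sym = pd.concat([df, dup], ignore_index=True)  # genotypes identical
        res, post = two_way_anova_sidak(sym)
        assert res.effect("genotype")["F"] == pytest.approx(0.0, abs=1e-8)
        assert res.effect("genotype")["p"] == pytest.approx(1.0, abs=1e-6)

    def test_empty_cell_named_in_error(self):
        df = _balanced_layout(n_struct=3)
        df = df[~((df["genotype"] == "g1") & (df["structure"] == "s01"))]
        with pytest.raises(ValueError, match="s01"):
            two_way_anova_sidak(df)

    def test_posthoc_invariants(self):
        _, post = two_way_anova_sidak(_balanced_layout(effect=40, seed=2))
        assert (post["p_sidak"] >= post["p_unadjusted"] - 1e-12).all()
        assert post["p_sidak"].between(0, 1).all()
        assert post.loc[post["structure"] == "s02", "p_sidak"].iloc[0] < 0.05


class TestUnpairedT:
    def test_hand_computed_example(self):
        t, df, p = unpaired_t([1.0, 2.0], [3.0, 4.0])
        assert t == pytest.approx(-2.828, abs=1e-3)
        assert df == 2

    def test_identical_groups(self):
        t, df, p = unpaired_t([5.0, 5.0, 5.0], [5.0, 5.0])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_consistent_with_summary_form(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 8), rng.normal(0.5, 1.2, 11)
        t1, df1, p1 = unpaired_t(a, b)
        t2, df2, p2 = pooled_t_from_summary(
            a.mean(), a.std(ddof=1), len(a), b.mean(), b.std(ddof=1), len(b)
        )
        assert (t1, df1, p1) == pytest.approx((t2, df2, p2))


class TestPooledTSummary:
    def test_hypothalamic_volumetry_statistic(self):
        """ALS vs control hypothalamic volumes reproduce |t| = 8.9, df = 113."""
        t, df, p = pooled_t_from_summary(750.8, 74.3, 72, 886.9, 86.5, 43)
        assert round(abs(t), 1) == 8.9
        assert df == 113
        assert p < 1e-4

    def test_equal_means_zero(self):
        t, _, p = pooled_t_from_summary(5.0, 1.0, 10, 5.0, 2.0, 12)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_reduces_to_classic_equal_variance_form(self):
        m1, m2, sd, n = 10.0, 12.0, 2.0, 6
        t, df, _ = pooled_t_from_summary(m1, sd, n, m2, sd, n)
        classic = (m1 - m2) / (sd * np.sqrt(2.0 / n))
        assert t == pytest.approx(classic)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            pooled_t_from_summary(1.0, 1.0, 1, 2.0, 1.0, 5)


def _one_way_ss_oracle(groups):
    arrays = [np.asarray(v, float) for v in groups.values()]
    grand = np.concatenate(arrays).mean()
    k = len(arrays)
    n = sum(len(a) for a in arrays)
    ss_b = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays)
    ss_w = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    return (ss_b / (k - 1)) / (ss_w / (n - k))


class TestOneWayAnova:
    def test_df_for_four_groups_of_six(self):
        rng = np.random.default_rng(1)
        groups = {f"g{i}": rng.normal(i, 1, 6) for i in range(4)}
        res, _ = one_way_anova_tukey(groups)
        row = res.table.iloc[0]
        assert (row["df1"], row["df2"]) == (3.0, 20.0)

    def test_identical_groups(self):
        groups = {"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]}
        res, _ = one_way_anova_tukey(groups)
        assert res.table.iloc[0]["F"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_ss_oracle(self):
        rng = np.random.default_rng(5)
        groups = {"a": rng.normal(0, 1, 4), "b": rng.normal(1, 1, 5), "c": rng.normal(2, 1, 3)}
        res, _ = one_way_anova_tukey(groups)
        assert res.table.iloc[0]["F"] == pytest.approx(
            _one_way_ss_oracle(groups), rel=1e-10
        )

    def test_tukey_flags_extreme_pair(self):
        rng = np.random.default_rng(2)
        groups = {"lo": rng.normal(0, 1, 6), "mid": rng.normal(1, 1, 6), "hi": rng.normal(8, 1, 6)}
        _, post = one_way_anova_tukey(groups)
        row = post[post["pair"] == "hi vs lo"]
        assert row["p_tukey"].iloc[0] < 0.001
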