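"""Tests of the statistics engine against definitions and enumeration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from wmtstudy.stats import (
    bh_fdr, between_anova, chi_square_independence, extreme_outliers,
    hedges_g, mann_whitney_u, mixed_anova, oneway_anova,
    rm_power_sample_size, t_test,
)

from _oracles import bh_stepup, mixed_anova_cellmeans, mw_enumeration


def _balanced_frame(rng, n_per_cell=8, effects=None):
    """Balanced 2x2x2 long frame with optional programmed effects."""
    effects = effects or {}
    rows = []
    pid = 0
    for a in (-1, 1):
        for b in (-1, 1):
            for _ in range(n_per_cell):
                pid += 1
                base = rng.normal(0, 1)
                for w, wlab in ((-1, "a_pre"), (1, "b_post")):
                    mu = (effects.get("a", 0) * a + effects.get("b", 0) * b
                          + effects.get("w", 0) * w
                          + effects.get("aw", 0) * a * w)
                    rows.append({
                        "participant": f"S{pid}",
                        "A": "a1" if a < 0 else "a2",
                        "B": "b1" if b < 0 else "b2",
                        "w": wlab,
                        "y": base + mu + rng.normal(0, 0.3)})
    return pd.DataFrame(rows)


class TestMixedAnova:
    def test_matches_cell_means_closed_form(self):
        """Balanced designs: F equals the explicit cell-means oracle."""
        rng = np.random.default_rng(3)
        for rep in range(5):
            df = _balanced_frame(rng, effects={"a": 0.4, "w": 0.3,
                                               "aw": 0.25})
            table = mixed_anova(df, dv="y", within="w",
                                subject="participant", between=["A", "B"])
            wide = df.pivot_table(index=["participant", "A", "B"],
                                  columns="w", values="y").reset_index()
            y = wide[["a_pre", "b_post"]].to_numpy()
            a = np.where(wide["A"] == "a1", -1.0, 1.0)
            b = np.where(wide["B"] == "b1", -1.0, 1.0)
            oracle, dfe = mixed_anova_cellmeans(y, a, b)
            got = dict(zip(table["effect"], table["F"]))
            mapping = {"A": "a", "B": "b", "A:B": "a:b", "w": "w",
                       "A:w": "a:w", "B:w": "b:w", "A:B:w": "a:b:w"}
            for effect, key in mapping.items():
                assert got[effect] == pytest.approx(oracle[key], abs=1e-8)
            assert set(table["df2"]) == {dfe}

    def test_equal_cell_means_give_zero_F(self):
        # subject variation is balanced across cells, so every cell mean
        # (and every cell mean change) is identical: all F must be 0
        rows = []
        cells = [("a1", "b1"), ("a1", "b2"), ("a2", "b1"), ("a2", "b2")]
        for i in range(12):
            a, b = cells[i % 4]
            j = i // 4  # within-cell subject index, same in every cell
            avg_off = j * 0.3
            diff_off = (j - 1) * 0.2
            rows.append({"participant": f"S{i}", "A": a, "B": b,
                         "w": "a_pre", "y": 5.0 + avg_off - diff_off / 2})
            rows.append({"participant": f"S{i}", "A": a, "B": b,
                         "w": "b_post", "y": 5.0 + avg_off + diff_off / 2})
        df = pd.DataFrame(rows)
        table = mixed_anova(df, dv="y", within="w", subject="participant",
                            between=["A", "B"])
        assert np.allclose(table["F"], 0.0, atol=1e-12)
        assert np.allclose(table["eta_p_sq"], 0.0, atol=1e-12)

    def test_eta_selfconsistency(self):
        rng = np.random.default_rng(9)
        df = _balanced_frame(rng, effects={"aw": 0.5})
        table = mixed_anova(df, dv="y", within="w", subject="participant",
                            between=["A", "B"])
        recon = (table["F"] * table["df1"]
                 / (table["F"] * table["df1"] + table["df2"]))
        assert np.allclose(table["eta_p_sq"], recon, atol=1e-10)

    def test_drops_subjects_missing_a_level(self):
        rng = np.random.default_rng(4)
        df = _balanced_frame(rng)
        df = df.drop(df[(df["participant"] == "S1")
                        & (df["w"] == "b_post")].index)
        table = mixed_anova(df, dv="y", within="w", subject="participant",
                            between=["A", "B"])
        assert set(table["df2"]) == {4 * 8 - 1 - 4}

    def test_too_small_cell_rejected(self):
        rng = np.random.default_rng(4)
        df = _balanced_frame(rng, n_per_cell=1)
        with pytest.raises(ValueError):
            mixed_anova(df, dv="y", within="w", subject="participant",
                        between=["A", "B"])

    def test_one_between_factor(self):
        rng = np.random.default_rng(12)
        df = _balanced_frame(rng, effects={"a": 0.8})
        table = mixed_anova(df, dv="y", within="w", subject="participant",
                            between=["A"])
        assert list(table["effect"]) == ["A", "w", "A:w"]
        assert table.loc[table["effect"] == "A", "p"].iloc[0] < 0.01


class TestTTest:
    def test_identical_samples(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = t_test(x, x.copy())
        assert res.t == pytest.approx(0.0)
        assert res.g == pytest.approx(0.0)

    def test_matches_textbook_formula(self):
        x = np.array([4.1, 5.2, 6.3, 5.5, 4.9])
        y = np.array([3.2, 4.1, 3.9, 4.4])
        n1, n2 = len(x), len(y)
        sp2 = (((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1))
               / (n1 + n2 - 2))
        t_hand = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
        res = t_test(x, y)
        assert res.t == pytest.approx(t_hand)
        assert res.df == n1 + n2 - 2
        assert res.p == pytest.approx(
            2 * sps.t.sf(abs(t_hand), n1 + n2 - 2))

    def test_pooled_df_for_printed_group_sizes(self):
        rng = np.random.default_rng(0)
        res = t_test(rng.normal(size=32), rng.normal(size=34))
        assert res.df == 64

    def test_paired(self):
        x = np.array([3.0, 4.0, 5.0, 6.0])
        y = np.array([2.5, 3.0, 4.0, 6.5])
        res = t_test(x, y, paired=True)
        d = x - y
        assert res.t == pytest.approx(
            d.mean() / (d.std(ddof=1) / np.sqrt(len(d))))
        assert res.df == 3

    def test_hedges_correction_factor(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = x - 1.0
        d_raw = 1.0 / x.std(ddof=1)
        j = 1 - 3 / (4 * 8 - 1)
        assert hedges_g(x, y) == pytest.approx(j * d_raw)


class TestMannWhitney:
    def test_complete_separation(self):
        assert mann_whitney_u([1, 2, 3], [4, 5, 6])[0] == 0.0

    def test_identical_groups_give_half_max(self):
        x = [1.0, 2.0, 3.0, 4.0]
        U, p = mann_whitney_u(x, x)
        assert U == len(x) ** 2 / 2

    @pytest.mark.parametrize("n1", [2, 3, 4, 5, 6])
    @pytest.mark.parametrize("n2", [2, 3, 4, 5, 6])
    def test_exact_p_matches_enumeration(self, n1, n2):
        rng = np.random.default_rng(100 * n1 + n2)
        for _ in range(3):
            x = rng.normal(size=n1)
            y = rng.normal(0.5, size=n2)
            U, p = mann_whitney_u(x, y)
            U_ref, p_ref = mw_enumeration(x, y)
            assert U == U_ref
            assert p == pytest.approx(p_ref, abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestBHFDR:
    def test_constant_vector_unchanged(self):
        p = np.full(7, 0.02)
        assert np.allclose(bh_fdr(p), 0.02)

    def test_hand_worked_stepup(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]),
                           [0.04, 0.04, 0.04, 0.04])

    def test_singleton(self):
        assert bh_fdr([0.34])[0] == pytest.approx(0.34)

    def test_matches_stepup_definition_on_random_vectors(self):
        rng = np.random.default_rng(21)
        for _ in range(1000):
            p = rng.uniform(size=rng.integers(1, 40))
            assert np.allclose(bh_fdr(p), bh_stepup(p), atol=1e-12)

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(22)
        p = rng.uniform(size=25)
        assert np.all(bh_fdr(p) >= p - 1e-15)


class TestChiSquare:
    def test_proportional_table_is_zero(self):
        chi2, df, p = chi_square_independence([[10, 20], [30, 60]])
        assert chi2 == pytest.approx(0.0)
        assert df == 1
        assert p == pytest.approx(1.0)

    def test_matches_expected_count_formula(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            table = rng.integers(1, 40, size=(2, 4)).astype(float)
            chi2, df, p = chi_square_independence(table)
            row = table.sum(axis=1, keepdims=True)
            col = table.sum(axis=0, keepdims=True)
            expected = row @ col / table.sum()
            chi2_hand = float(((table - expected) ** 2 / expected).sum())
            assert chi2 == pytest.approx(chi2_hand)
            assert df == 3

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            chi_square_independence([[0, 0], [3, 4]])


class TestOutliers:
    def test_flags_only_the_extreme_point(self):
        values = list(range(1, 21)) + [1000]
        report = extreme_outliers(values)
        assert report.indices == (20,)

    def test_all_equal_flags_nothing(self):
        assert extreme_outliers([5.0] * 10).indices == ()

    def test_matches_independent_quartile_rule(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            v = rng.standard_cauchy(size=60)
            report = extreme_outliers(v)
            q1 = np.percentile(v, 25)
            q3 = np.percentile(v, 75)
            lo, hi = q1 - 3 * (q3 - q1), q3 + 3 * (q3 - q1)
            expected = tuple(np.nonzero((v < lo) | (v > hi))[0])
            assert report.indices == expected
            assert report.fences == pytest.approx((lo, hi))


class TestPower:
    def test_returned_N_is_minimal(self):
        """N achieves the power and N - groups does not (noncentral F)."""
        from scipy.stats import f as fdist, ncf

        for eta in (0.03, 0.06, 0.15):
            N = rm_power_sample_size(eta, alpha=0.05, power=0.80)
            f2 = eta / (1 - eta)

            def pwr(n):
                lam = f2 * n * 2 / 0.5
                crit = fdist.ppf(0.95, 1, n - 2)
                return ncf.sf(crit, 1, n - 2, lam)

            assert pwr(N) >= 0.80
            assert pwr(N - 2) < 0.80

    def test_medium_effect_lands_low_thirties(self):
        N = rm_power_sample_size(0.06, alpha=0.05, power=0.80)
        assert 28 <= N <= 36
        assert N % 2 == 0

    def test_tiny_power_gives_minimal_design(self):
        assert rm_power_sample_size(0.06, power=1e-9) == 4

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            rm_power_sample_size(0.0)
        with pytest.raises(ValueError):
            rm_power_sample_size(0.06, power=1.5)


class TestOneWayAndBetween:
    def test_oneway_matches_scipy(self):
        rng = np.random.default_rng(2)
        groups = [rng.normal(size=10), rng.normal(0.5, size=12),
                  rng.normal(size=9)]
        row = oneway_anova(groups)
        F, p = sps.f_oneway(*groups)
        assert row.F == pytest.approx(F)
        assert row.p == pytest.approx(p)
        assert (row.df1, row.df2) == (2, 28)

    def test_between_anova_detects_main_effect(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame({
            "t": ["x"] * 20 + ["y"] * 20,
            "s": (["u"] * 10 + ["v"] * 10) * 2,
            "score": np.r_[rng.normal(0, 1, 20), rng.normal(1.5, 1, 20)]})
        table = between_anova(df, dv="score", between=["t", "s"])
        assert table.loc[table["effect"] == "t", "p"].iloc[0] < 0.01
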