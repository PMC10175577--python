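"""Tests for smoothing, spline knot search and the Step-1/Step-2 stats."""

import numpy as np
import pandas as pd
import pytest

from wmtstudy.learning import (
    FlatSeriesError, LearningCurveModel, SmoothedSeries,
    compare_learning_parameters, fit_spline_at_knot, select_best_knot,
    sequential_session_anovas, smooth_series,
)

from _oracles import bh_stepup, mw_enumeration, spline_normal_equations


def _series(values):
    return SmoothedSeries(participant="P", values=tuple(values))


def _hinge(t, knot, intercept=1.0, s1=0.5, s2=0.0):
    t = np.asarray(t, dtype=float)
    return (intercept + s1 * np.minimum(t, knot)
            + s2 * np.maximum(0.0, t - knot))


class TestSmoothing:
    def test_constant_series(self):
        out = smooth_series([3.0] * 16)
        assert out.values == tuple([3.0] * 15)

    def test_ramp(self):
        out = smooth_series(list(range(1, 17)))
        assert out.values == tuple(np.arange(1.5, 16.0, 1.0))

    def test_matches_convolution_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            raw = rng.normal(size=16)
            got = np.array(smooth_series(raw).values)
            ref = np.convolve(raw, [0.5, 0.5], mode="valid")
            assert np.allclose(got, ref)

    def test_wrong_length_or_nan(self):
        with pytest.raises(ValueError):
            smooth_series([1.0] * 15)
        with pytest.raises(ValueError):
            smooth_series([np.nan] + [1.0] * 15)


class TestSplineFit:
    def test_exact_recovery_in_model_class(self):
        t = np.arange(1, 16)
        fit = fit_spline_at_knot(_series(_hinge(t, 8)), 8)
        assert fit.slope1 == pytest.approx(0.5)
        assert fit.slope2 == pytest.approx(0.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_pure_linear_any_knot(self):
        t = np.arange(1, 16)
        y = 2.0 + 0.3 * t
        for k in (2, 7, 14):
            fit = fit_spline_at_knot(_series(y), k)
            assert fit.slope1 == pytest.approx(0.3)
            assert fit.slope2 == pytest.approx(0.3)
            assert fit.r_squared == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(30):
            y = rng.normal(size=15)
            for k in range(2, 15):
                fit = fit_spline_at_knot(_series(y), k)
                ref = spline_normal_equations(y, k)
                assert fit.intercept == pytest.approx(ref["intercept"])
                assert fit.slope1 == pytest.approx(ref["slope1"])
                assert fit.slope2 == pytest.approx(ref["slope2"])
                assert fit.r_squared == pytest.approx(ref["r_squared"])

    def test_flat_series_r2_undefined_slopes_zero(self):
        fit = fit_spline_at_knot(_series([2.0] * 15), 5)
        assert fit.r_squared is None
        assert fit.slope1 == pytest.approx(0.0, abs=1e-12)
        assert fit.slope2 == pytest.approx(0.0, abs=1e-12)

    def test_knot_out_of_range(self):
        with pytest.raises(ValueError):
            fit_spline_at_knot(_series(np.arange(15.0)), 1)
        with pytest.raises(ValueError):
            fit_spline_at_knot(_series(np.arange(15.0)), 15)

    def test_continuity_at_knot(self):
        rng = np.random.default_rng(13)
        y = rng.normal(size=15)
        fit = fit_spline_at_knot(_series(y), 7)
        eps = 1e-9
        left = fit.predict(np.array([7.0 - eps]))[0]
        right = fit.predict(np.array([7.0 + eps]))[0]
        assert left == pytest.approx(right, abs=1e-6)


class TestKnotSelection:
    def test_programmed_knot_recovered_exactly(self):
        t = np.arange(1, 16)
        fit = select_best_knot(_series(_hinge(t, 8)))
        assert fit.knot_index == 8
        assert fit.r_squared == pytest.approx(1.0)

    def test_linear_data_ties_break_to_smallest_knot(self):
        t = np.arange(1, 16)
        fit = select_best_knot(_series(1.0 + 0.2 * t))
        assert fit.knot_index == 2

    def test_flat_series_raises(self):
        with pytest.raises(FlatSeriesError):
            select_best_knot(_series([4.0] * 15))

    def test_selection_matches_exhaustive_argmax(self):
        """Selected knot is the argmax of the 13 oracle fits, with the
        earliest knot winning ties, on noisy programmed-knot series."""
        rng = np.random.default_rng(31)
        t = np.arange(1, 16)
        for _ in range(1000):
            knot = rng.integers(3, 13)
            y = _hinge(t, knot, s1=rng.uniform(0.05, 0.4))
            y = y + rng.normal(0, 0.2, size=15)
            fit = select_best_knot(_series(y))
            r2s = [spline_normal_equations(y, k)["r_squared"]
                   for k in range(2, 15)]
            best_k = 2 + int(np.argmax(r2s))  # argmax takes first maximum
            assert fit.knot_index == best_k

    def test_affine_invariance(self):
        rng = np.random.default_rng(44)
        y = _hinge(np.arange(1, 16), 6) + rng.normal(0, 0.1, 15)
        base = select_best_knot(_series(y))
        scaled = select_best_knot(_series(3.0 * y - 7.0))
        assert scaled.knot_index == base.knot_index
        assert scaled.slope1 == pytest.approx(3.0 * base.slope1)
        assert scaled.r_squared == pytest.approx(base.r_squared)


class TestLearningCurveModel:
    def test_fit_from_raw_series(self):
        raw = _hinge(np.arange(1, 17), 8, s1=0.3)
        res = LearningCurveModel(raw).fit()
        # smoothing a session-8 plateau puts the spline knot at 7 or 8
        assert res.knot_index in (7, 8)
        assert res.slope1 == pytest.approx(0.3, abs=0.02)
        assert "knot location" in res.summary()

    def test_fixed_knot_fit(self):
        raw = _hinge(np.arange(1, 17), 8, s1=0.3)
        res = LearningCurveModel(raw).fit(knot=4)
        assert res.knot_index == 4
        assert len(res.fittedvalues()) == 15


class TestGroupComparison:
    def _fits(self, rng, n, slope_mu=0.1):
        fits = []
        for _ in range(n):
            y = _hinge(np.arange(1, 16), rng.integers(3, 13),
                       s1=max(0.01, rng.normal(slope_mu, 0.05)))
            y = y + rng.normal(0, 0.1, 15)
            fits.append(select_best_knot(_series(y)))
        return fits

    def test_identical_groups(self):
        rng = np.random.default_rng(5)
        fits = self._fits(rng, 8)
        table = compare_learning_parameters(fits, fits)
        assert np.allclose(table["U"], 8 * 8 / 2)
        assert np.all(table["p"] > 0.9)

    def test_table_shape(self):
        rng = np.random.default_rng(6)
        table = compare_learning_parameters(
            self._fits(rng, 6), self._fits(rng, 7),
            labels=("distributed", "intensive"))
        assert list(table["measure"]) == ["first_slope", "knot_location"]
        for col in ("distributed_mean", "distributed_sd",
                    "distributed_median", "intensive_mean", "U", "p", "g"):
            assert col in table.columns

    def test_U_matches_enumeration_for_small_groups(self):
        rng = np.random.default_rng(7)
        fits_a = self._fits(rng, 5, slope_mu=0.08)
        fits_b = self._fits(rng, 5, slope_mu=0.2)
        table = compare_learning_parameters(fits_a, fits_b)
        a = [f.slope1 for f in fits_a]
        b = [f.slope1 for f in fits_b]
        U_ref, p_ref = mw_enumeration(a, b)
        row = table[table["measure"] == "first_slope"].iloc[0]
        assert row["U"] == U_ref
        assert row["p"] == pytest.approx(p_ref)

    def test_empty_group_rejected(self):
        rng = np.random.default_rng(8)
        with pytest.raises(ValueError):
            compare_learning_parameters(self._fits(rng, 5), [])


def _wmt_sessions(rng, n_per_group, trajectory):
    """Long frame of WMT-only training outcomes for both schedules."""
    rows = []
    pid = 0
    for schedule in ("distributed", "intensive"):
        for _ in range(n_per_group):
            pid += 1
            base = rng.normal(2.0, 0.3)
            for t in range(1, 17):
                rows.append({"participant": f"P{pid}",
                             "schedule": schedule, "task": "verbal",
                             "session": t,
                             "mean_nback": base + trajectory(t)
                             + rng.normal(0, 0.15)})
    return pd.DataFrame(rows)


class TestSequentialAnovas:
    def test_null_data_has_no_discoveries(self):
        rng = np.random.default_rng(9)
        data = _wmt_sessions(rng, 12, lambda t: 0.0)
        out = sequential_session_anovas(data, "verbal")
        assert len(out) == 45
        assert set(out["effect"]) == {"group", "session", "group:session"}
        sess = out[out["effect"] == "session"]
        assert len(sess) == 15
        assert np.all(sess["p_fdr"] > 0.05)

    def test_gain_from_session_four_detected_from_four_onward(self):
        """A step improvement at session 4 yields FDR-significant session
        effects exactly for the S1-vs-S4 ... S1-vs-S16 contrasts."""
        rng = np.random.default_rng(10)
        data = _wmt_sessions(rng, 15, lambda t: 0.8 if t >= 4 else 0.0)
        out = sequential_session_anovas(data, "verbal")
        sess = out[out["effect"] == "session"].set_index("N")
        assert np.all(sess.loc[4:16, "p_fdr"] < 0.05)
        assert np.all(sess.loc[2:3, "p_fdr"] > 0.05)

    def test_fdr_matches_stepup_oracle_per_family(self):
        rng = np.random.default_rng(11)
        data = _wmt_sessions(rng, 10, lambda t: 0.05 * t)
        out = sequential_session_anovas(data, "verbal")
        for effect in ("group", "session", "group:session"):
            sub = out[out["effect"] == effect]
            assert np.allclose(sub["p_fdr"].to_numpy(),
                               bh_stepup(sub["p_raw"].to_numpy()))

    def test_joint_family_mode(self):
        rng = np.random.default_rng(12)
        data = _wmt_sessions(rng, 8, lambda t: 0.0)
        out = sequential_session_anovas(data, "verbal", fdr_family="joint")
        assert np.allclose(out["p_fdr"].to_numpy(),
                           bh_stepup(out["p_raw"].to_numpy()))

    def test_pfdr_never_below_praw(self):
        rng = np.random.default_rng(13)
        data = _wmt_sessions(rng, 8, lambda t: 0.02 * t)
        out = sequential_session_anovas(data, "verbal")
        assert np.all(out["p_fdr"] >= out["p_raw"] - 1e-15)
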