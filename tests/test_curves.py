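import numpy as np
import pandas as pd
import pytest

from thermocycle.curves import (
    DailyCurve,
    agreement_categories,
    daily_difference,
    estimate_daily_curve,
    phase_summary,
    rmcorr,
)
from thermocycle.core import Modality
from thermocycle.shifts import ShiftResult

from conftest import make_cycle


def biphasic(*days):
    return ShiftResult(tuple(days), "biphasic")


MONO = ShiftResult((), "monophasic")


class TestPhaseSummary:
    def test_constant_series_has_zero_change(self):
        cyc = make_cycle(np.full(29, 36.0), positive_day=14)
        s = phase_summary(cyc, "wrist")
        assert s.follicular_mean == s.luteal_mean == 36.0
        assert s.between_phase_change == 0.0

    def test_step_after_ovulation_gives_step_change(self):
        vals = np.full(29, 36.0)
        vals[15:] = 36.3  # luteal days 16..29 (ovulation day 15)
        s = phase_summary(make_cycle(vals, positive_day=14), "wrist")
        assert s.between_phase_change == pytest.approx(0.30)

    def test_phase_entirely_missing_returns_absent(self):
        vals = np.full(29, 36.0)
        vals[15:] = np.nan
        assert phase_summary(make_cycle(vals, positive_day=14), "wrist") is None

    def test_anovulatory_cycle_rejected(self):
        cyc = make_cycle(np.full(28, 36.0))
        with pytest.raises(ValueError):
            phase_summary(cyc, "wrist")

    def test_change_is_antisymmetric(self):
        vals = 36.0 + 0.1 * np.sin(np.arange(29))
        up = phase_summary(make_cycle(vals, positive_day=14), "wrist")
        down = phase_summary(
            make_cycle(72.0 - vals, positive_day=14), "wrist")
        assert up.between_phase_change == pytest.approx(-down.between_phase_change)


class TestRmcorr:
    def test_perfect_parallel_lines(self):
        pids, x, y = [], [], []
        for i, offset in enumerate([0.0, 1.0, 2.5]):
            for xi in range(4):
                pids.append(f"P{i}")
                x.append(float(xi))
                y.append(xi + offset)
        res = rmcorr(pids, x, y)
        assert res.r == pytest.approx(1.0)
        assert res.p < 1e-10
        assert res.df == 12 - 3 - 1

    def test_single_participant_equals_pearson(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=12)
        y = 0.4 * x + rng.normal(size=12)
        with pytest.warns(UserWarning, match="single participant"):
            res = rmcorr(["P1"] * 12, x, y)
        from scipy import stats

        r_p, p_p = stats.pearsonr(x, y)
        assert res.r == pytest.approx(r_p, abs=1e-12)
        assert res.p == pytest.approx(p_p, rel=1e-9)
        assert res.df == 10

    def test_hand_computed_two_participant_dataset(self):
        # P1: (0,1),(1,3),(2,4); P2: (0,4),(2,5),(4,9)
        pids = ["P1"] * 3 + ["P2"] * 3
        x = [0.0, 1.0, 2.0, 0.0, 2.0, 4.0]
        y = [1.0, 3.0, 4.0, 4.0, 5.0, 9.0]
        # centered within participant:
        # P1: xc = [-1,0,1],  yc = [-5/3, 1/3, 4/3]
        # P2: xc = [-2,0,2],  yc = [-2, -1, 3]
        # Sxx = 1+0+1+4+0+4 = 10;  Sxy = 5/3+4/3+4+6 = 13
        # slope = 13/10; SS_x = slope^2*Sxx = 16.9
        # SS_err = sum(yc - slope*xc)^2
        xc = np.array([-1, 0, 1, -2, 0, 2], float)
        yc = np.array([-5 / 3, 1 / 3, 4 / 3, -2, -1, 3])
        slope = 13 / 10
        ss_err = float(np.sum((yc - slope * xc) ** 2))
        expected_r = np.sqrt(16.9 / (16.9 + ss_err))
        res = rmcorr(pids, x, y)
        assert res.r == pytest.approx(expected_r, abs=1e-12)
        assert res.df == 6 - 2 - 1

    def test_matches_reference_implementation(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        rows = []
        for i in range(8):
            b = rng.normal(0, 1)
            for _ in range(6):
                x = rng.normal()
                rows.append({"pid": f"P{i}", "x": x,
                             "y": 0.5 * x + b + rng.normal(0, 0.7)})
        df = pd.DataFrame(rows)
        res = rmcorr(df["pid"], df["x"], df["y"])
        ref = pingouin.rm_corr(data=df, x="x", y="y", subject="pid")
        assert res.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)
        assert res.df == int(ref["dof"].iloc[0])
        assert res.p == pytest.approx(float(ref["pval"].iloc[0]), rel=1e-6)

    def test_invariant_to_participant_level_offsets(self):
        rng = np.random.default_rng(9)
        pids = np.repeat([f"P{i}" for i in range(5)], 7)
        x = rng.normal(size=35)
        y = 0.3 * x + rng.normal(size=35)
        base = rmcorr(pids, x, y)
        offsets = {f"P{i}": rng.normal(0, 10) for i in range(5)}
        y_shifted = y + np.array([offsets[p] for p in pids])
        shifted = rmcorr(pids, x, y_shifted)
        assert shifted.r == pytest.approx(base.r, abs=1e-12)

    def test_r_squared_equals_partial_eta_squared(self):
        # oracle: explicit ANCOVA SS decomposition via least squares
        rng = np.random.default_rng(11)
        pids = np.repeat(np.arange(6), 5)
        x = rng.normal(size=30)
        y = 0.6 * x + pids * 0.5 + rng.normal(size=30)
        res = rmcorr([f"P{p}" for p in pids], x, y)
        dummies = np.eye(6)[pids]
        full = np.column_stack([dummies, x])
        sse_full = np.sum((y - full @ np.linalg.lstsq(full, y, rcond=None)[0]) ** 2)
        sse_red = np.sum((y - dummies @ np.linalg.lstsq(dummies, y, rcond=None)[0]) ** 2)
        partial_eta_sq = (sse_red - sse_full) / sse_red
        assert res.r**2 == pytest.approx(partial_eta_sq, abs=1e-10)

    def test_small_participants_dropped_with_warning(self):
        pids = ["P1"] * 4 + ["P2"]
        x = [0, 1, 2, 3, 9]
        y = [0, 1, 2, 3, 9]
        with pytest.warns(UserWarning, match="fewer than 2"):
            res = rmcorr(pids, x, y)
        assert res.n_participants == 1


def _balanced_obs(n_participants=6, n_days=5, effect=None, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_participants):
        b = rng.normal(0, 0.2)
        for d in range(1, n_days + 1):
            mu = 36.0 + (effect(d) if effect else 0.0)
            rows.append({"participant": f"P{i}", "cycle": f"P{i}/c{d}",
                         "phase_day": d,
                         "temp": mu + b + rng.normal(0, noise)})
    return pd.DataFrame(rows)


class TestEstimateDailyCurve:
    def test_identical_temperatures_give_exact_flat_curve(self):
        obs = _balanced_obs()
        obs["temp"] = 36.0
        curve = estimate_daily_curve(obs, "preovulatory", "wrist")
        np.testing.assert_array_equal(curve.estimate, 36.0)
        np.testing.assert_array_equal(curve.ci_low, curve.ci_high)

    def test_balanced_single_observation_equals_raw_means(self):
        obs = _balanced_obs(noise=0.1, seed=3)
        curve = estimate_daily_curve(obs, "postovulatory", "wrist")
        raw = obs.groupby("phase_day")["temp"].mean().to_numpy()
        np.testing.assert_allclose(curve.estimate, raw, atol=1e-6)

    def test_linear_rise_recovered(self):
        obs = _balanced_obs(n_participants=50, n_days=10,
                            effect=lambda d: 0.05 * (d - 1), noise=0.1, seed=4)
        curve = estimate_daily_curve(obs, "postovulatory", "wrist")
        rise = curve.estimate[-1] - curve.estimate[0]
        assert rise == pytest.approx(0.45, abs=0.1)

    def test_ci_contains_estimate(self):
        obs = _balanced_obs(noise=0.15, seed=6)
        curve = estimate_daily_curve(obs, "menstrual", "bbt")
        assert np.all(curve.ci_low <= curve.estimate)
        assert np.all(curve.ci_high >= curve.estimate)

    def test_too_few_participants_rejected(self):
        obs = _balanced_obs(n_participants=3)
        with pytest.raises(ValueError, match="participants"):
            estimate_daily_curve(obs, "menstrual", "wrist")


class TestDailyDifference:
    def _curve(self, est, phase="postovulatory", modality=Modality.WRIST):
        est = np.asarray(est, float)
        days = np.arange(1, est.size + 1)
        return DailyCurve(phase, modality, days, est, est - 0.1, est + 0.1, "test")

    def test_identical_curves_zero(self):
        a = self._curve(np.full(5, 36.2))
        diff, mean = daily_difference(a, self._curve(np.full(5, 36.2), modality=Modality.BBT))
        assert np.all(diff["difference"] == 0.0) and mean == 0.0

    def test_constant_offset(self):
        a = self._curve(np.full(5, 36.5))
        b = self._curve(np.full(5, 36.0), modality=Modality.BBT)
        _, mean = daily_difference(a, b)
        assert mean == pytest.approx(0.5)

    def test_mismatched_days_rejected(self):
        a = self._curve(np.full(5, 36.0))
        b = self._curve(np.full(6, 36.0))
        with pytest.raises(ValueError):
            daily_difference(a, b)

    def test_mismatched_phase_rejected(self):
        a = self._curve(np.full(5, 36.0))
        b = self._curve(np.full(5, 36.0), phase="menstrual")
        with pytest.raises(ValueError):
            daily_difference(a, b)


class TestAgreement:
    def test_all_both_biphasic(self):
        res = [biphasic(20)] * 4
        cats = agreement_categories(res, res)
        assert cats.both_biphasic == 4 and cats.total == 4

    def test_mixed_patterns(self):
        wrist = [biphasic(20), biphasic(21), MONO]
        bbt = [biphasic(19), MONO, MONO]
        cats = agreement_categories(wrist, bbt)
        assert (cats.both_biphasic, cats.wrist_only_biphasic,
                cats.bbt_only_biphasic, cats.both_monophasic) == (1, 1, 0, 1)

    def test_marginals_match_per_modality_counts(self, rng):
        wrist = [biphasic(20) if rng.random() < 0.6 else MONO for _ in range(50)]
        bbt = [biphasic(18) if rng.random() < 0.25 else MONO for _ in range(50)]
        cats = agreement_categories(wrist, bbt)
        assert cats.total == 50
        assert cats.wrist_biphasic == sum(r.biphasic for r in wrist)
        assert cats.bbt_biphasic == sum(r.biphasic for r in bbt)
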