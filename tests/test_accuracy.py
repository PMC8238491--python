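import numpy as np
import pytest
from scipy import optimize, stats
from statsmodels.stats.contingency_tables import mcnemar

from thermocycle.accuracy import (
    ConfusionTable,
    accuracy_measures,
    build_confusion,
    cluster_bootstrap_ci,
    compare_paired,
    proportion_ci,
)

# the published two-modality confusion tables (193 cycles: 170 ovulatory, 23 not)
WRIST_TABLE = ConfusionTable(tp=106, fp=17, tn=6, fn=64)
BBT_TABLE = ConfusionTable(tp=39, fp=7, tn=16, fn=131)


def cp_oracle(k, n, alpha=0.05):
    """Clopper-Pearson by direct root-finding on the binomial tails."""
    lo = 0.0 if k == 0 else optimize.brentq(
        lambda p: stats.binom.sf(k - 1, n, p) - alpha / 2, 1e-12, 1 - 1e-12)
    hi = 1.0 if k == n else optimize.brentq(
        lambda p: stats.binom.cdf(k, n, p) - alpha / 2, 1e-12, 1 - 1e-12)
    return lo, hi


def wilson_oracle(k, n, alpha=0.05):
    """Wilson score interval from the score equation roots."""
    z = stats.norm.ppf(1 - alpha / 2)
    phat = k / n

    def score(p):
        return (phat - p) ** 2 - z**2 * p * (1 - p) / n

    lo = 0.0 if k == 0 else optimize.brentq(score, 1e-12, phat) if phat > 0 else 0.0
    hi = 1.0 if k == n else optimize.brentq(score, phat, 1 - 1e-12) if phat < 1 else 1.0
    return lo, hi


class TestBuildConfusion:
    def test_one_of_each(self):
        t = build_confusion([(True, True), (False, True), (True, False), (False, False)])
        assert (t.tp, t.fn, t.fp, t.tn) == (1, 1, 1, 1)

    def test_cohort_scale_counts(self):
        flags = ([(True, True)] * 106 + [(False, True)] * 64
                 + [(True, False)] * 17 + [(False, False)] * 6)
        t = build_confusion(flags)
        assert (t.tp, t.fn, t.fp, t.tn) == (106, 64, 17, 6)
        assert t.total == 193

    def test_all_true_positives(self):
        t = build_confusion([(True, True)] * 10)
        assert (t.fn, t.fp, t.tn) == (0, 0, 0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            build_confusion([])


class TestAccuracyMeasures:
    def test_wrist_cohort_ratios(self):
        m = accuracy_measures(WRIST_TABLE)
        assert m.sensitivity.value == pytest.approx(0.6235, abs=5e-5)
        assert m.specificity.value == pytest.approx(0.2609, abs=5e-5)
        assert m.ppv.value == pytest.approx(0.8618, abs=5e-5)
        assert m.npv.value == pytest.approx(0.0857, abs=5e-5)
        assert m.tp_rate == pytest.approx(106 / 193)
        assert m.fp_rate == pytest.approx(17 / 193)

    def test_bbt_cohort_ratios(self):
        m = accuracy_measures(BBT_TABLE)
        assert m.sensitivity.value == pytest.approx(0.2294, abs=5e-5)
        assert m.specificity.value == pytest.approx(0.6957, abs=5e-5)
        assert m.ppv.value == pytest.approx(0.8478, abs=5e-5)
        assert m.npv.value == pytest.approx(0.1088, abs=5e-5)

    def test_perfect_test(self):
        m = accuracy_measures(ConfusionTable(tp=10, fp=0, tn=10, fn=0))
        for meas in (m.sensitivity, m.specificity, m.ppv, m.npv):
            assert meas.value == 1.0

    def test_zero_denominator_measure_absent(self):
        m = accuracy_measures(ConfusionTable(tp=5, fp=0, tn=0, fn=5))
        assert m.specificity is None          # tn + fp = 0
        assert m.npv is not None and m.npv.value == 0.0   # 0/5, not coerced away
        m2 = accuracy_measures(ConfusionTable(tp=5, fp=2, tn=0, fn=0))
        assert m2.npv is None                 # tn + fn = 0
        assert m2.sensitivity is not None and m2.sensitivity.value == 1.0

    def test_matches_bruteforce_flag_enumeration(self, rng):
        for _ in range(200):
            n = rng.integers(2, 40)
            flags = [(bool(rng.integers(2)), bool(rng.integers(2)))
                     for _ in range(n)]
            t = build_confusion(flags)
            m = accuracy_measures(t)
            ov = [f for f in flags if f[1]]
            anov = [f for f in flags if not f[1]]
            if ov:
                assert m.sensitivity.value == pytest.approx(
                    sum(s for s, _ in ov) / len(ov))
                # complements partition exactly
                assert m.sensitivity.value + t.fn / (t.tp + t.fn) == pytest.approx(1.0)
            if anov:
                assert m.specificity.value == pytest.approx(
                    sum(not s for s, _ in anov) / len(anov))
                assert m.specificity.value + t.fp / (t.tn + t.fp) == pytest.approx(1.0)


class TestProportionCI:
    def test_boundaries(self):
        assert proportion_ci(0, 10, "clopper_pearson")[0] == 0.0
        assert proportion_ci(10, 10, "clopper_pearson")[1] == 1.0

    @pytest.mark.parametrize("k,n", [(106, 170), (6, 23), (39, 170), (16, 23), (1, 30)])
    def test_against_tail_rootfinding_oracles(self, k, n):
        lo, hi = proportion_ci(k, n, "clopper_pearson")
        olo, ohi = cp_oracle(k, n)
        assert lo == pytest.approx(olo, abs=1e-6)
        assert hi == pytest.approx(ohi, abs=1e-6)
        wlo, whi = proportion_ci(k, n, "wilson")
        owlo, owhi = wilson_oracle(k, n)
        assert wlo == pytest.approx(owlo, abs=1e-6)
        assert whi == pytest.approx(owhi, abs=1e-6)

    def test_cp_contains_point_estimate_and_wilson_is_narrower(self, rng):
        for _ in range(100):
            n = int(rng.integers(10, 200))
            k = int(rng.integers(0, n + 1))
            lo, hi = proportion_ci(k, n, "clopper_pearson")
            assert lo <= k / n <= hi
            if 0 < k < n:
                wlo, whi = proportion_ci(k, n, "wilson")
                assert (whi - wlo) < (hi - lo)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            proportion_ci(1, 0)
        with pytest.raises(ValueError):
            proportion_ci(5, 3)


class TestComparePaired:
    def test_identical_outcomes(self):
        a = [True, False, True] * 5
        cond = [True] * 15
        assert compare_paired(a, a, cond) == 1.0

    def test_one_sided_discordance(self):
        a = [True] * 10 + [False] * 5
        b = [False] * 10 + [False] * 5
        p = compare_paired(a, b, [True] * 15, "positives")
        assert p == pytest.approx(2 * 0.5**10)

    def test_balanced_discordance_capped_at_one(self):
        a = [True] * 5 + [False] * 5
        b = [False] * 5 + [True] * 5
        assert compare_paired(a, b, [True] * 10) == 1.0

    def test_stratum_selects_condition(self):
        # discordance only among anovulatory cycles
        cond = [True] * 6 + [False] * 6
        a = [True] * 6 + [True] * 6
        b = [True] * 6 + [False] * 6
        assert compare_paired(a, b, cond, "positives") == 1.0
        assert compare_paired(a, b, cond, "negatives") == pytest.approx(2 * 0.5**6)

    def test_matches_statsmodels_exact_mcnemar(self, rng):
        for _ in range(25):
            n = 40
            a = rng.integers(2, size=n).astype(bool)
            b = rng.integers(2, size=n).astype(bool)
            p = compare_paired(a, b, np.ones(n, bool), "positives")
            table = [[np.sum(a & b), np.sum(a & ~b)],
                     [np.sum(~a & b), np.sum(~a & ~b)]]
            ref = mcnemar(table, exact=True).pvalue
            assert p == pytest.approx(ref, abs=1e-12)


class TestClusterBootstrap:
    def test_no_variation_gives_degenerate_interval(self):
        pids = np.repeat([f"P{i}" for i in range(6)], 3)
        shift = np.ones(18, bool)
        ov = np.ones(18, bool)
        lo, hi, skipped = cluster_bootstrap_ci(pids, shift, ov, "sensitivity",
                                               B=300, seed=1)
        assert (lo, hi) == (1.0, 1.0)

    def test_single_cycle_per_participant_matches_flat_bootstrap(self):
        rng = np.random.default_rng(7)
        n = 80
        pids = [f"P{i}" for i in range(n)]
        ov = np.ones(n, bool)
        shift = rng.random(n) < 0.6
        lo, hi, _ = cluster_bootstrap_ci(pids, shift, ov, "sensitivity",
                                         B=2000, seed=11)
        # flat bootstrap of cycles: same resampling law when clusters are singletons
        flat_rng = np.random.default_rng(12)
        reps = [shift[flat_rng.integers(0, n, n)].mean() for _ in range(2000)]
        flo, fhi = np.percentile(reps, [2.5, 97.5])
        assert lo == pytest.approx(flo, abs=0.02)
        assert hi == pytest.approx(fhi, abs=0.02)

    def test_interval_contains_point_estimate(self):
        rng = np.random.default_rng(3)
        pids = np.repeat([f"P{i}" for i in range(20)], 4)
        ov = rng.random(80) < 0.85
        shift = np.where(ov, rng.random(80) < 0.6, rng.random(80) < 0.2)
        t = build_confusion(list(zip(shift, ov)))
        point = t.tp / (t.tp + t.fn)
        lo, hi, _ = cluster_bootstrap_ci(pids, shift, ov, "sensitivity",
                                         B=500, seed=5)
        assert lo <= point <= hi

    def test_requires_multiple_participants(self):
        with pytest.raises(ValueError):
            cluster_bootstrap_ci(["P1"] * 4, [True] * 4, [True] * 4, B=300)
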