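import numpy as np
import pytest
from scipy import stats

from digicms.survival import (
    cindex_delong,
    delong_test,
    fit_coxph,
    harrell_cindex,
    km_logrank,
    roc_auc,
    youden_cutoff,
)


def auc_pair_counting(scores, labels):
    """O(n^2) Mann-Whitney oracle: ties count 1/2."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def cindex_enumeration(times, events, risk):
    """Comparable-pair oracle for Harrell's C (higher risk -> earlier event)."""
    num = den = 0.0
    n = len(times)
    for i in range(n):
        for j in range(n):
            if i == j or not events[i]:
                continue
            if times[i] < times[j] or (times[i] == times[j] and not events[j]):
                den += 1
                if risk[i] > risk[j]:
                    num += 1
                elif risk[i] == risk[j]:
                    num += 0.5
    return num / den


class TestROC:
    def test_perfect_separation(self):
        r = roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert r.auc == 1.0

    def test_random_scores_near_half(self, rng):
        scores = rng.random(2000)
        labels = rng.integers(0, 2, 2000)
        assert roc_auc(scores, labels).auc == pytest.approx(0.5, abs=0.03)

    def test_ties_match_pair_counting_oracle(self, rng):
        scores = rng.integers(0, 5, 20).astype(float)  # heavy ties
        labels = rng.integers(0, 2, 20)
        while len(np.unique(labels)) < 2:
            labels = rng.integers(0, 2, 20)
        assert roc_auc(scores, labels).auc == pytest.approx(
            auc_pair_counting(scores, labels), abs=1e-12
        )

    def test_invariant_under_monotone_transforms(self, rng):
        scores = rng.standard_normal(100)
        labels = rng.integers(0, 2, 100)
        base = roc_auc(scores, labels).auc
        assert roc_auc(np.exp(scores), labels).auc == pytest.approx(base, abs=1e-12)
        assert roc_auc(3.0 * scores - 7.0, labels).auc == pytest.approx(base, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])


class TestYouden:
    def test_worked_example_midpoint(self):
        r = roc_auc([0.1, 0.4, 0.35, 0.8], [0, 1, 0, 1])
        assert youden_cutoff(r) == pytest.approx(0.375)

    def test_matches_exhaustive_scan_on_random_sets(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 30))
            scores = np.round(rng.random(n), 2)
            labels = rng.integers(0, 2, n)
            if len(np.unique(labels)) < 2 or len(np.unique(scores)) < 2:
                continue
            r = roc_auc(scores, labels)
            thr = youden_cutoff(r)

            def j_at(t):
                pred = scores >= t
                sens = (pred & (labels == 1)).sum() / (labels == 1).sum()
                spec = (~pred & (labels == 0)).sum() / (labels == 0).sum()
                return sens + spec - 1.0

            # oracle: scan every possible cut position
            uniq = np.unique(scores)
            candidates = np.concatenate(([-np.inf], (uniq[:-1] + uniq[1:]) / 2, [np.inf]))
            best = max(j_at(t) for t in candidates)
            assert j_at(thr) == pytest.approx(best, abs=1e-12)
            # tie rule: no lower candidate achieves the same J
            lower = [t for t in candidates if t < thr - 1e-12]
            assert all(j_at(t) < best - 1e-12 for t in lower)

    def test_uninformative_scores_give_zero_j(self):
        r = roc_auc([0.1, 0.2, 0.1, 0.2], [0, 0, 1, 1])
        thr = youden_cutoff(r)
        pred = r.scores >= thr
        sens = (pred & (r.labels == 1)).sum() / 2
        spec = (~pred & (r.labels == 0)).sum() / 2
        assert sens + spec - 1.0 == pytest.approx(0.0)

    def test_constant_scores_rejected(self):
        res = roc_auc([0.5, 0.5, 0.5, 0.5], [0, 1, 0, 1])
        with pytest.raises(ValueError, match="identical"):
            youden_cutoff(res)


class TestKMLogrank:
    def test_identical_groups_statistic_zero(self):
        times = np.array([2.0, 5.0, 7.0, 9.0])
        events = np.array([1, 0, 1, 1])
        res = km_logrank({"a": (times, events), "b": (times.copy(), events.copy())})
        assert res.statistic == pytest.approx(0.0, abs=1e-10)
        assert res.p_value == pytest.approx(1.0, abs=1e-10)

    def test_toy_data_matches_hand_computed_hypergeometric(self):
        # g1 events at 1,2,3; g2 events at 4,5,6 -> sum over the 6 event times
        # of (observed - expected) in g1 with hypergeometric variance
        res = km_logrank({
            "g1": (np.array([1.0, 2.0, 3.0]), np.array([1, 1, 1])),
            "g2": (np.array([4.0, 5.0, 6.0]), np.array([1, 1, 1])),
        })
        n1, n2 = 3, 3
        o_minus_e = 0.0
        var = 0.0
        at_risk_1, at_risk_2 = n1, n2
        for t, in_g1 in [(1, True), (2, True), (3, True), (4, False), (5, False), (6, False)]:
            n = at_risk_1 + at_risk_2
            e1 = at_risk_1 / n  # one event at each time
            o_minus_e += (1.0 if in_g1 else 0.0) - e1
            var += at_risk_1 * at_risk_2 / n**2 if n > 1 else 0.0
            if in_g1:
                at_risk_1 -= 1
            else:
                at_risk_2 -= 1
        expected_chi2 = o_minus_e**2 / var
        assert res.statistic == pytest.approx(expected_chi2, rel=1e-6)

    def test_km_equals_empirical_survivor_without_censoring(self, rng):
        times = rng.exponential(10.0, 40)
        res = km_logrank({
            "g": (times, np.ones(40, int)),
            "h": (rng.exponential(10.0, 40), np.ones(40, int)),
        })
        curve = res.curves["g"]
        for t, s in zip(curve["time"], curve["survival"]):
            assert s == pytest.approx((times > t).mean(), abs=1e-12)

    def test_km_curve_monotone_from_one(self, rng):
        times = rng.exponential(5.0, 30)
        events = rng.integers(0, 2, 30)
        events[0] = 1
        res = km_logrank({"g": (times, events), "h": (times + 1, events)})
        surv = res.curves["g"]["survival"].to_numpy()
        assert surv[0] == 1.0
        assert (np.diff(surv) <= 1e-12).all()

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="zero subjects"):
            km_logrank({"a": (np.array([1.0]), np.array([1])),
                        "b": (np.array([]), np.array([]))})

    def test_null_simulation_rejects_at_nominal_rate(self, rng):
        # hazard ratio 1, no censoring: empirical type-I error ~ 5%
        rejections = 0
        for _ in range(200):
            t1 = rng.exponential(1.0, 25)
            t2 = rng.exponential(1.0, 25)
            res = km_logrank({"a": (t1, np.ones(25, int)), "b": (t2, np.ones(25, int))})
            rejections += res.p_value < 0.05
        assert rejections / 200 == pytest.approx(0.05, abs=0.04)


class TestCox:
    def _frame(self, times, events, **covs):
        import pandas as pd

        return pd.DataFrame({"time": times, "event": events, **covs})

    def test_null_binary_covariate_hr_one(self, rng):
        times = rng.exponential(10.0, 200)
        df = self._frame(times, np.ones(200, int), group=rng.integers(0, 2, 200))
        fit = fit_coxph(df, "time", "event", ["group"])
        assert fit.loc[0, "hr"] == pytest.approx(1.0, abs=0.35)

    def test_recovers_true_hazard_ratio(self, rng):
        n = 500
        group = rng.integers(0, 2, n)
        lam = 0.01 * np.where(group == 1, 2.0, 1.0)
        times = rng.exponential(1.0 / lam)
        cens = rng.exponential(1.0 / (0.25 * lam))  # ~20% censoring
        obs = np.minimum(times, cens)
        events = (times <= cens).astype(int)
        df = self._frame(obs, events, group=group)
        fit = fit_coxph(df, "time", "event", ["group"])
        assert 1.6 <= fit.loc[0, "hr"] <= 2.5
        assert fit.loc[0, "hr_ci_low"] < fit.loc[0, "hr"] < fit.loc[0, "hr_ci_high"]

    def test_categorical_expansion_against_reference(self, rng):
        n = 120
        df = self._frame(
            rng.exponential(5.0, n), np.ones(n, int),
            stage=rng.choice(["I", "II", "III"], n), age=rng.normal(50, 8, n),
        )
        fit = fit_coxph(df, "time", "event", ["stage", "age"])
        assert set(fit["covariate"]) == {"stage[II]", "stage[III]", "age"}

    def test_zero_events_rejected(self, rng):
        df = self._frame(rng.exponential(5.0, 20), np.zeros(20, int),
                         group=rng.integers(0, 2, 20))
        with pytest.raises(ValueError, match="event"):
            fit_coxph(df, "time", "event", ["group"])

    def test_collinear_covariates_rejected(self, rng):
        g = rng.integers(0, 2, 50)
        df = self._frame(rng.exponential(5.0, 50), np.ones(50, int), g1=g, g2=1 - g)
        with pytest.raises(ValueError, match="collinear"):
            fit_coxph(df, "time", "event", ["g1", "g2"])


class TestCindexDelong:
    def test_perfectly_concordant_scores(self):
        times = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        risk = np.array([5.0, 4.0, 3.0, 2.0, 1.0])  # highest risk dies first
        assert harrell_cindex(times, np.ones(5, int), risk) == 1.0

    def test_matches_comparable_pair_enumeration(self, rng):
        times = rng.exponential(5.0, 30)
        events = rng.integers(0, 2, 30)
        events[:3] = 1
        risk = rng.standard_normal(30)
        assert harrell_cindex(times, events, risk) == pytest.approx(
            cindex_enumeration(times, events, risk), abs=1e-12
        )

    def test_identical_scores_give_p_one(self, rng):
        scores = rng.random(40)
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        a, b, p = delong_test(scores, scores.copy(), labels)
        assert a == b
        assert p == 1.0

    def test_delong_detects_clear_difference(self, rng):
        n = 300
        labels = rng.integers(0, 2, n)
        good = labels + 0.3 * rng.standard_normal(n)
        noise = rng.standard_normal(n)
        a, b, p = delong_test(good, noise, labels)
        assert a > b
        assert p < 0.01

    def test_combined_report(self, rng):
        n = 60
        labels = rng.integers(0, 2, n)
        labels[:2] = [0, 1]
        times = rng.exponential(5.0, n)
        events = np.ones(n, int)
        out = cindex_delong(rng.random(n), rng.random(n), times, events, labels)
        assert set(out) == {"c_index_a", "c_index_b", "auc_a", "auc_b", "delong_p"}
        assert 0.0 <= out["delong_p"] <= 1.0

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            harrell_cindex([1.0, 2.0], [0, 0], [0.5, 0.6])
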