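import numpy as np
import pandas as pd
import pytest

from isomirdisp.survival_signature import (
    NOT_TESTABLE,
    Signature,
    SurvivalRecord,
    check_eligibility,
    correlation_prune,
    cox_fit,
    cross_apply,
    km_curve,
    km_logrank,
    median_split,
    rfe_select,
    risk_scores,
    roc_auc,
    signature_search,
)
from isomirdisp.synthetic_data import SimConfig, simulate_survival


def _records(times, events):
    return [
        SurvivalRecord(f"p{i}", float(t), int(e))
        for i, (t, e) in enumerate(zip(times, events))
    ]


class TestEligibility:
    def test_nine_dead_fifty_alive_false(self):
        recs = _records(range(59), [1] * 9 + [0] * 50)
        assert not check_eligibility(recs)

    def test_boundary_true(self):
        recs = _records(range(20), [1] * 10 + [0] * 10)
        assert check_eligibility(recs)

    def test_empty_false(self):
        assert not check_eligibility([])


class TestCorrelationPrune:
    def test_identical_features_keep_one(self, rng):
        x = rng.normal(size=30)
        expr = pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=30)})
        kept = correlation_prune(expr, 0.9)
        assert len([f for f in kept if f in ("a", "b")]) == 1
        assert "c" in kept

    def test_all_below_threshold_all_kept(self, rng):
        expr = pd.DataFrame(rng.normal(size=(100, 5)), columns=list("abcde"))
        assert correlation_prune(expr, 0.9) == list("abcde")

    def test_greedy_removes_larger_mean_corr(self, rng):
        # r(a,b) ~ 0.9; c independent but slightly more correlated with a
        n = 2000
        z = rng.normal(size=n)
        a = z + 0.45 * rng.normal(size=n)
        b = z + 0.45 * rng.normal(size=n)
        c = 0.2 * a + rng.normal(size=n)
        expr = pd.DataFrame({"a": a, "b": b, "c": c})
        corr = expr.corr().abs()
        assert corr.loc["a", "b"] > 0.8
        # mean |r| of a exceeds b's because of the extra a-c correlation
        kept = correlation_prune(expr, 0.8)
        assert kept == ["b", "c"]

    def test_threshold_validated(self, rng):
        expr = pd.DataFrame(rng.normal(size=(10, 2)), columns=["a", "b"])
        with pytest.raises(ValueError):
            correlation_prune(expr, 0.0)

    def test_threshold_one_keeps_non_duplicates(self, rng):
        expr = pd.DataFrame(rng.normal(size=(10, 3)), columns=["a", "b", "c"])
        assert correlation_prune(expr, 1.0) == ["a", "b", "c"]


class TestCoxFit:
    def _cohort(self, seed=0, n=300, beta=0.7, cens=0.2, n_feats=1):
        cfg = SimConfig(seed=seed, n_patients=n, censoring_rate=cens)
        betas = {"feat-0001": beta} if beta else {}
        return simulate_survival(cfg, n_feats, betas)

    def test_null_feature_beta_near_zero(self):
        expr, recs, _ = self._cohort(seed=2, beta=0.0)
        res = cox_fit(expr, recs, mode="univariate-each")
        row = res.table.iloc[0]
        assert abs(row["beta"]) < 3 * row["se"]

    def test_matches_lifelines(self):
        from lifelines import CoxPHFitter

        expr, recs, _ = self._cohort(seed=3, n_feats=3)
        mine = cox_fit(expr, recs, mode="multivariate").table
        df = expr.copy()
        df["T"] = [r.time for r in recs]
        df["E"] = [r.event for r in recs]
        ll = CoxPHFitter().fit(df, "T", "E")
        assert np.allclose(mine["beta"].values, ll.params_.values, atol=1e-4)
        assert np.allclose(mine["se"].values, ll.standard_errors_.values, atol=1e-4)

    def test_score_equation_satisfied(self):
        expr, recs, _ = self._cohort(seed=4, n_feats=2)
        res = cox_fit(expr, recs, mode="multivariate")
        assert res.max_grad < 1e-6

    def test_univariate_fdr_column(self):
        expr, recs, _ = self._cohort(seed=5, n_feats=4)
        res = cox_fit(expr, recs, mode="univariate-each")
        ok = res.table["converged"]
        assert (res.table.loc[ok, "fdr"] >= res.table.loc[ok, "p"] - 1e-12).all()

    def test_constant_feature_raises(self):
        expr, recs, _ = self._cohort(seed=6)
        expr["const"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            cox_fit(expr, recs)

    def test_duplication_near_invariance(self):
        # exactly invariant under Breslow; Efron's staggered tie weights
        # make it approximate, so allow a small relative tolerance
        expr, recs, _ = self._cohort(seed=7, n=100)
        r1 = cox_fit(expr, recs, mode="multivariate").table["beta"].values
        expr2 = pd.concat([expr, expr.set_index(expr.index + "d")])
        recs2 = recs + [SurvivalRecord(r.sample_id + "d", r.time, r.event) for r in recs]
        r2 = cox_fit(expr2, recs2, mode="multivariate").table["beta"].values
        assert np.allclose(r1, r2, rtol=0.05, atol=0.02)

    def test_monotone_likelihood_flagged(self):
        # perfectly separating feature: event iff x > 0
        times = np.arange(1, 41, dtype=float)
        x = np.where(times <= 20, 1.0, -1.0)
        events = (x > 0).astype(int)
        recs = _records(times, events)
        expr = pd.DataFrame({"f": x}, index=[r.sample_id for r in recs])
        with pytest.warns(UserWarning, match="converge"):
            res = cox_fit(expr, recs, mode="univariate-each")
        assert not res.table["converged"].iloc[0]


class TestRfe:
    def test_identity_at_full_size(self, rng):
        expr = pd.DataFrame(rng.normal(size=(60, 4)), columns=list("abcd"))
        labels = rng.integers(0, 2, size=60)
        out = rfe_select(expr, labels, [4])
        assert out[4] == list("abcd")

    def test_oversized_target_capped(self, rng):
        expr = pd.DataFrame(rng.normal(size=(60, 3)), columns=list("abc"))
        labels = rng.integers(0, 2, size=60)
        with pytest.warns(UserWarning, match="capped"):
            out = rfe_select(expr, labels, [10])
        assert out[10] == list("abc")

    def test_informative_feature_survives(self, rng):
        hits = 0
        for rep in range(20):
            r = np.random.default_rng(rep)
            X = r.normal(size=(120, 10))
            labels = (X[:, 0] > 0).astype(int)  # feature 0 separates
            expr = pd.DataFrame(X, columns=[f"f{i}" for i in range(10)])
            out = rfe_select(expr, labels, [1, 3])
            if "f0" in out[1] and "f0" in out[3]:
                hits += 1
        assert hits >= 19

    def test_nested_subsets(self, rng):
        expr = pd.DataFrame(rng.normal(size=(80, 6)), columns=list("abcdef"))
        labels = rng.integers(0, 2, size=80)
        out = rfe_select(expr, labels, [2, 4, 6])
        assert set(out[2]) <= set(out[4]) <= set(out[6])


class TestRiskScores:
    def test_hand_arithmetic(self):
        expr = pd.DataFrame({"a": [2.0], "b": [3.0]}, index=["p1"])
        s = risk_scores(expr, {"a": 0.5, "b": -1.0})
        assert s["p1"] == pytest.approx(-2.0)

    def test_zero_betas(self, rng):
        expr = pd.DataFrame(rng.normal(size=(5, 2)), columns=["a", "b"])
        assert (risk_scores(expr, {"a": 0.0, "b": 0.0}) == 0).all()

    def test_linearity(self, rng):
        expr = pd.DataFrame(rng.normal(size=(5, 2)), columns=["a", "b"])
        betas = {"a": 0.3, "b": 0.7}
        assert np.allclose(
            risk_scores(2 * expr, betas).values, 2 * risk_scores(expr, betas).values
        )

    def test_feature_order_invariance(self, rng):
        expr = pd.DataFrame(rng.normal(size=(6, 3)), columns=["a", "b", "c"])
        betas = {"a": 0.1, "b": -0.2, "c": 0.3}
        rev = dict(reversed(list(betas.items())))
        assert np.allclose(risk_scores(expr, betas).values, risk_scores(expr, rev).values)

    def test_missing_feature_raises(self, rng):
        expr = pd.DataFrame(rng.normal(size=(5, 1)), columns=["a"])
        with pytest.raises(ValueError, match="missing"):
            risk_scores(expr, {"a": 1.0, "zz": 2.0})


class TestKmLogrank:
    def test_product_limit_four_deaths(self):
        curve = km_curve(np.array([1.0, 2.0, 3.0, 4.0]), np.array([1, 1, 1, 1]))
        assert np.allclose(curve["survival"].values, [0.75, 0.50, 0.25, 0.0])

    def test_censoring_shrinks_risk_set(self):
        curve = km_curve(np.array([1.0, 2.0, 3.0]), np.array([1, 0, 1]))
        assert np.allclose(curve["survival"].values, [2 / 3, 0.0])

    def test_identical_groups_chi2_zero(self):
        times = [1, 2, 3, 4, 5, 6]
        events = [1, 1, 0, 1, 1, 0]
        recs = _records(times + times, events + events)
        assign = {r.sample_id: ("high" if i < 6 else "low") for i, r in enumerate(recs)}
        _, chi2, p = km_logrank(recs, assign)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_lifelines(self, rng):
        from lifelines.statistics import logrank_test

        times = rng.exponential(10, size=50)
        events = rng.integers(0, 2, size=50)
        groups = rng.integers(0, 2, size=50)
        recs = _records(times, events)
        assign = {r.sample_id: ("high" if g else "low") for r, g in zip(recs, groups)}
        _, chi2, p = km_logrank(recs, assign)
        lt = logrank_test(
            times[groups == 1], times[groups == 0],
            events[groups == 1], events[groups == 0],
        )
        assert chi2 == pytest.approx(lt.test_statistic, rel=1e-9)
        assert p == pytest.approx(lt.p_value, rel=1e-9)

    def test_zero_event_group_warns(self):
        recs = _records([1, 2, 3, 4], [1, 1, 0, 0])
        assign = {"p0": "high", "p1": "high", "p2": "low", "p3": "low"}
        with pytest.warns(UserWarning, match="zero events"):
            km_logrank(recs, assign)


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([1, 2, 3, 10, 11], [0, 0, 0, 1, 1]) == 1.0

    def test_all_equal_half(self):
        assert roc_auc([5, 5, 5, 5], [0, 1, 0, 1]) == 0.5

    def test_matches_pair_counting(self, rng):
        scores = rng.normal(size=10)
        labels = rng.integers(0, 2, size=10)
        if labels.sum() in (0, 10):
            labels[0] = 1 - labels[0]
        num = den = 0.0
        for i in np.flatnonzero(labels == 1):
            for j in np.flatnonzero(labels == 0):
                den += 1
                num += 1.0 if scores[i] > scores[j] else (0.5 if scores[i] == scores[j] else 0.0)
        assert roc_auc(scores, labels) == pytest.approx(num / den, abs=1e-12)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, size=40)
        labels[0], labels[1] = 0, 1
        assert roc_auc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )

    def test_one_class_raises(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2], [1, 1])


class TestMedianSplit:
    def test_ties_go_low(self):
        s = pd.Series([1.0, 2.0, 2.0, 3.0], index=list("abcd"))
        assign, cutoff = median_split(s)
        assert cutoff == 2.0
        assert assign == {"a": "low", "b": "low", "c": "low", "d": "high"}


class TestSignatureSearch:
    def _cohort(self, seed, betas=None, n_feats=40, n=150, cens=0.5):
        cfg = SimConfig(seed=seed, n_patients=n, censoring_rate=cens)
        return simulate_survival(cfg, n_feats, betas or {})

    def test_recovers_planted_features(self):
        betas = {"feat-0001": 1.0, "feat-0002": -1.0}
        expr, recs, _ = self._cohort(21, betas)
        sig = signature_search(expr, recs)
        assert sig is not None
        assert set(betas) <= set(sig.features) or len(set(sig.features) & set(betas)) >= 1
        assert sig.auc > 0.6

    def test_deterministic(self):
        betas = {"feat-0001": 0.9}
        expr, recs, _ = self._cohort(22, betas)
        s1 = signature_search(expr, recs)
        s2 = signature_search(expr, recs)
        assert s1.features == s2.features
        assert s1.auc == s2.auc
        assert s1.corr_threshold == s2.corr_threshold

    def test_row_permutation_invariance(self):
        betas = {"feat-0001": 0.9}
        expr, recs, _ = self._cohort(23, betas)
        s1 = signature_search(expr, recs)
        perm = expr.sample(frac=1.0, random_state=0)
        s2 = signature_search(perm, recs)
        assert s1.features == s2.features
        assert s1.auc == pytest.approx(s2.auc)

    def test_ineligible_cohort_raises(self):
        expr, recs, _ = self._cohort(24, {"feat-0001": 0.5}, n=15)
        recs = [SurvivalRecord(r.sample_id, r.time, 0) for r in recs]
        with pytest.raises(ValueError, match="ineligible"):
            signature_search(expr, recs)

    def test_betas_are_univariate(self):
        betas = {"feat-0001": 1.2}
        expr, recs, _ = self._cohort(25, betas)
        sig = signature_search(expr, recs)
        for f in sig.features:
            uni = cox_fit(expr.loc[[r.sample_id for r in recs], [f]], recs,
                          mode="univariate-each")
            assert sig.betas[f] == pytest.approx(uni.table["beta"].iloc[0])

    def test_cutoff_is_median(self):
        betas = {"feat-0001": 1.0}
        expr, recs, _ = self._cohort(26, betas)
        sig = signature_search(expr, recs)
        assert sig.cutoff == pytest.approx(float(sig.risk_scores.median()))


class TestCrossApply:
    def _signature(self, seed=30):
        cfg = SimConfig(seed=seed, n_patients=150, censoring_rate=0.5)
        expr, recs, _ = simulate_survival(cfg, 30, {"feat-0001": 1.0})
        sig = signature_search(expr, recs)
        return sig, expr, recs

    def test_self_application_reproduces_auc(self):
        sig, expr, recs = self._signature()
        out = cross_apply(sig, expr, recs)
        assert out != NOT_TESTABLE
        auc, logrank_p = out
        assert auc == pytest.approx(sig.auc)
        assert logrank_p == pytest.approx(sig.logrank_p)

    def test_missing_feature_not_testable(self):
        sig, expr, recs = self._signature()
        reduced = expr.drop(columns=sig.features[:1])
        assert cross_apply(sig, reduced, recs) == NOT_TESTABLE

    def test_second_cohort_similar_auc(self):
        sig, _, _ = self._signature()
        cfg = SimConfig(seed=31, n_patients=400, censoring_rate=0.5)
        expr2, recs2, _ = simulate_survival(cfg, 30, {"feat-0001": 1.0})
        out = cross_apply(sig, expr2, recs2)
        assert out != NOT_TESTABLE
        auc, _ = out
        assert auc > 0.55

    def test_signature_json_round_trip(self, tmp_path):
        import json

        sig, _, _ = self._signature()
        p = tmp_path / "sig.json"
        sig.to_json(p)
        data = json.loads(p.read_text())
        assert data["features"] == sig.features
        assert data["auc"] == pytest.approx(sig.auc)
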