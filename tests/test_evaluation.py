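import numpy as np
import pandas as pd
import pytest

import oracles
from mojknet import evaluation as ev
from mojknet.datatypes import LatentEmbedding


class TestMacroMetrics:
    def test_perfect_predictions(self):
        y = np.array([0, 1, 2, 0, 1, 2])
        assert ev.macro_metrics(y, y, 3) == (1.0, 1.0, 1.0)

    def test_printed_confusion_matrix(self):
        # confusion [[8,2],[3,7]]: per-class precision (8/11, 7/9)
        y = np.array([0] * 10 + [1] * 10)
        p = np.array([0] * 8 + [1] * 2 + [0] * 3 + [1] * 7)
        prec, rec, f1 = ev.macro_metrics(y, p, 2)
        assert np.isclose(prec, (8 / 11 + 7 / 9) / 2)
        assert np.isclose(rec, (8 / 10 + 7 / 10) / 2)

    def test_all_one_class_half_recall(self):
        y = np.array([0, 0, 1, 1])
        p = np.zeros(4, dtype=int)
        _, rec, _ = ev.macro_metrics(y, p, 2)
        assert rec == 0.5

    def test_matches_bruteforce_on_random_fixtures(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            y = rng.integers(0, 4, size=30)
            p = rng.integers(0, 4, size=30)
            ours = ev.macro_metrics(y, p, 4)
            theirs = oracles.macro_from_labels(y, p, 4)
            assert np.allclose(ours, theirs, atol=1e-12)

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            ev.macro_metrics(np.array([0, 1]), np.array([0]), 2)


def survival_table(times, events, risk=None):
    n = len(times)
    risk = risk if risk is not None else np.arange(n, dtype=float)
    med = np.median(risk)
    group = np.where(risk > med, "high", "low")
    return ev.SurvivalTable(table=pd.DataFrame({
        "time": times, "event": events, "risk_score": risk, "risk_group": group,
    }))


class TestKaplanMeier:
    def test_all_censored_flat_one(self):
        t, s = ev.kaplan_meier(survival_table([1.0, 2, 3, 4], [0, 0, 0, 0]))
        assert np.allclose(s, 1.0)

    def test_all_events_steps(self):
        t, s = ev.kaplan_meier(survival_table([1.0, 2.0, 3.0], [1, 1, 1]))
        lookup = dict(zip(t, s))
        assert np.isclose(lookup[1.0], 2 / 3)
        assert np.isclose(lookup[2.0], 1 / 3)
        assert np.isclose(lookup[3.0], 0.0)

    def test_single_event_among_four(self):
        t, s = ev.kaplan_meier(survival_table([5.0, 6, 7, 8], [1, 0, 0, 0]))
        assert np.isclose(dict(zip(t, s))[5.0], 0.75)

    def test_matches_product_limit_oracle_with_censoring(self):
        rng = np.random.default_rng(1)
        times = rng.exponential(10, size=12).round(1) + 0.1
        events = rng.integers(0, 2, size=12)
        t, s = ev.kaplan_meier(survival_table(times, events))
        ot, os_ = oracles.km_curve(times, events)
        ours = dict(zip(t, s))
        for tt, ss in zip(ot, os_):
            assert np.isclose(ours.get(tt, ss), ss, atol=1e-10)

    def test_non_increasing_from_one(self):
        rng = np.random.default_rng(2)
        times = rng.exponential(5, size=20) + 0.1
        events = rng.integers(0, 2, size=20)
        t, s = ev.kaplan_meier(survival_table(times, events))
        assert s[0] == 1.0
        assert (np.diff(s) <= 1e-12).all()

    def test_nonpositive_time_errors(self):
        with pytest.raises(ValueError):
            survival_table([0.0, 1.0], [1, 1])


class TestLogRank:
    def test_symmetric_groups_chi2_zero(self):
        # two groups with identical event patterns
        times = [1.0, 2, 3, 1, 2, 3]
        events = [1, 1, 0, 1, 1, 0]
        risk = [1.0, 1, 1, 0, 0, 0]
        tab = survival_table(times, events, risk=np.array(risk, float))
        chi2, p = ev.logrank_test(tab)
        assert chi2 < 1e-10
        assert p > 0.99

    def test_textbook_toy_matches_enumeration_oracle(self):
        # group A events at 1,2,3; group B events at 4,5,6
        times = np.array([1.0, 2, 3, 4, 5, 6])
        events = np.ones(6, dtype=int)
        risk = np.array([2.0, 2, 2, 1, 1, 1])
        tab = survival_table(times, events, risk=risk)
        chi2, p = ev.logrank_test(tab)
        expected = oracles.logrank_chi2(times[:3], events[:3], times[3:], events[3:])
        assert np.isclose(chi2, expected, atol=1e-8)
        assert p < 0.05

    def test_chi2_nonnegative_and_label_swap_invariant(self):
        rng = np.random.default_rng(3)
        times = rng.exponential(10, size=16) + 0.1
        events = rng.integers(0, 2, size=16)
        risk = rng.normal(size=16)
        tab = survival_table(times, events, risk=risk)
        chi2, _ = ev.logrank_test(tab)
        flipped = tab.table.copy()
        flipped["risk_group"] = np.where(flipped["risk_group"] == "high",
                                         "low", "high")
        chi2_f, _ = ev.logrank_test(ev.SurvivalTable(table=flipped))
        assert chi2 >= 0
        assert np.isclose(chi2, chi2_f, atol=1e-10)

    def test_random_fixture_matches_oracle(self):
        rng = np.random.default_rng(4)
        times = (rng.exponential(10, size=14) + 0.1).round(2)
        events = rng.integers(0, 2, size=14)
        risk = rng.normal(size=14)
        tab = survival_table(times, events, risk=risk)
        chi2, _ = ev.logrank_test(tab)
        hi = tab.group("high")
        lo = tab.group("low")
        expected = oracles.logrank_chi2(hi["time"].to_numpy(), hi["event"].to_numpy(),
                                        lo["time"].to_numpy(), lo["event"].to_numpy())
        assert np.isclose(chi2, expected, atol=1e-8)


class TestConcordance:
    def test_perfectly_anti_ordered(self):
        # risk anti-ordered with time (short survival = high risk) -> 1.0;
        # risk equal to time -> 0.0
        times = np.array([1.0, 2, 3, 4])
        assert ev.concordance_index(-times, times, np.ones(4, int)) == 1.0
        assert ev.concordance_index(times, times, np.ones(4, int)) == 0.0

    def test_mixed_censoring_matches_pair_loop(self):
        times = np.array([2.0, 4, 4.5, 5, 7, 9])
        events = np.array([1, 0, 1, 1, 0, 1])
        risk = np.array([3.0, 1.0, 2.5, 2.5, 0.5, 0.1])
        ours = ev.concordance_index(risk, times, events)
        assert np.isclose(ours, oracles.cindex_pairs(risk, times, events), atol=1e-12)

    def test_complement_identity_without_ties(self):
        rng = np.random.default_rng(5)
        times = rng.exponential(10, size=10) + 0.1
        events = rng.integers(0, 2, size=10)
        events[0] = 1
        risk = rng.normal(size=10)
        c1 = ev.concordance_index(risk, times, events)
        c2 = ev.concordance_index(-risk, times, events)
        assert np.isclose(c1 + c2, 1.0, atol=1e-12)


class TestRiskGroups:
    def _embedding_with_hazard(self, n=80, seed=0):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, size=n)
        X = rng.normal(size=(n, 10))
        X[:, 0] += 3 * y            # embedding separates subtypes
        hazard = np.where(y == 1, 5.0, 1.0) / 50.0
        times = rng.exponential(1 / hazard) + 0.01
        censor = rng.exponential(80, size=n)
        events = (times <= censor).astype(int)
        obs = np.minimum(times, censor)
        emb = LatentEmbedding(sample_ids=[f"P{i}" for i in range(n)],
                              values=X, source="MOJKNET_FINAL")
        return emb, obs, events

    def test_hazard_recovery(self):
        emb, times, events = self._embedding_with_hazard()
        tab = ev.assign_risk_groups(emb, times, events, seed=0)
        chi2, p = ev.logrank_test(tab)
        cidx = ev.concordance_index(tab.table["risk_score"], times, events)
        assert p < 0.05
        assert cidx > 0.6

    def test_median_split_sizes(self):
        emb, times, events = self._embedding_with_hazard(seed=2)
        tab = ev.assign_risk_groups(emb, times, events, seed=0)
        n_high = (tab.table["risk_group"] == "high").sum()
        assert abs(n_high - len(times) / 2) <= 1

    def test_ties_go_low(self):
        # constant-ish scores are rejected instead of silently grouped
        emb = LatentEmbedding(sample_ids=["a", "b", "c", "d"],
                              values=np.zeros((4, 3)), source="MOJKNET_FINAL")
        with pytest.raises(ValueError, match="degenerate"):
            ev.assign_risk_groups(emb, np.array([1.0, 2, 3, 4]),
                                  np.array([1, 1, 0, 1]), seed=0)

    def test_permuted_survival_null(self):
        cs = []
        for seed in range(5):
            emb, times, events = self._embedding_with_hazard(seed=10 + seed)
            rng = np.random.default_rng(seed)
            perm = rng.permutation(len(times))
            tab = ev.assign_risk_groups(emb, times[perm], events[perm], seed=0)
            cs.append(ev.concordance_index(tab.table["risk_score"],
                                           times[perm], events[perm]))
        assert abs(np.mean(cs) - 0.5) <= 0.1

    def test_cox_head_against_established_fit(self):
        # cross-check the in-repo partial-likelihood head against lifelines
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(7)
        n = 60
        X = rng.normal(size=(n, 3))
        beta_true = np.array([1.0, -0.5, 0.0])
        times = rng.exponential(1.0 / np.exp(X @ beta_true)) + 0.01
        events = np.ones(n, int)
        risk = ev.cox_risk_scores(X, times, events, ridge=0.01, n_iter=2000)
        df = pd.DataFrame(X, columns=["x0", "x1", "x2"])
        df["T"], df["E"] = times, events
        cph = CoxPHFitter(penalizer=0.01 / n).fit(df, "T", "E")
        ll_risk = X @ cph.params_.to_numpy() - (X @ cph.params_.to_numpy()).mean()
        assert np.corrcoef(risk, ll_risk)[0, 1] > 0.99
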