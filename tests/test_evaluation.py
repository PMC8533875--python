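"""Metrics, leave-one-day-out folds, sweeps, and signed-rank statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from neuroauth.auth import AuthPolicy, AuthTask
from neuroauth.ensemble import EnsembleConfig
from neuroauth.evaluation import (ConfusionCounts, bagging_size_sweep,
                                  leave_one_day_out, metrics,
                                  pairwise_scheme_tests,
                                  training_fraction_sweep,
                                  wilcoxon_signed_rank)
from neuroauth.learner import LearnerConfig
from neuroauth.synth import ValidationError

PL = AuthTask("performed", "left")
PR = AuthTask("performed", "right")
FAST = LearnerConfig(hidden_units=8, epochs=15, batch_size=16,
                     learning_rate=1e-2, seed=0)
CFG = EnsembleConfig(M=1, base=FAST, seed=0)


class TestMetrics:
    def test_reference_counts(self):
        acc, far, frr = metrics(ConfusionCounts(TP=9, FN=1, TN=18, FP=2))
        assert (acc, far, frr) == (0.9, 0.1, 0.1)

    def test_perfect_classifier(self):
        assert metrics(ConfusionCounts(TP=5, FN=0, TN=5, FP=0)) == (1, 0, 0)

    def test_all_reject_classifier(self):
        acc, far, frr = metrics(ConfusionCounts(TP=0, FN=5, TN=5, FP=0))
        assert far == 0.0 and frr == 1.0

    def test_empty_attempt_sets_rejected(self):
        with pytest.raises(ValidationError):
            metrics(ConfusionCounts(TP=1, FN=0, TN=0, FP=0))
        with pytest.raises(ValidationError):
            metrics(ConfusionCounts(TP=0, FN=0, TN=1, FP=0))


@pytest.fixture(scope="module")
def report(small_pool):
    return leave_one_day_out(small_pool, [0, 1, 2],
                             AuthPolicy(tasks=(PL, PR)), CFG, n_days=2)


class TestLeaveOneDayOut:
    def test_one_row_per_subject_scheme_fold(self, report):
        df = report.to_frame()
        # 3 subjects x 2 folds x (combined + 2 components)
        assert len(df) == 3 * 2 * 3
        assert set(df["scheme"]) == {
            "performed-left+performed-right", "performed-left",
            "performed-right"}

    def test_attempt_counts_match_design(self, report):
        df = report.to_frame()
        # per fold: 1 genuine candidate x 2 paired trials, 2 imposters x 2
        assert np.all(df.TP + df.FN == 2)
        assert np.all(df.TN + df.FP == 4)

    def test_aggregate_equals_bruteforce_mean(self, report):
        df = report.to_frame()
        agg = report.aggregates().set_index("scheme")
        for scheme, grp in df.groupby("scheme"):
            assert agg.loc[scheme, "accuracy"] == pytest.approx(
                grp["accuracy"].mean())
            assert agg.loc[scheme, "FAR"] == pytest.approx(grp["FAR"].mean())

    def test_conjunction_bounds_hold_exactly(self, report):
        """AND-combination can only shrink FAR and grow FRR relative to
        its components, attempt for attempt."""
        df = report.to_frame()
        for (_, _), grp in df.groupby(["subject", "fold"]):
            comb = grp[grp.scheme == "performed-left+performed-right"]
            comps = grp[grp.scheme != "performed-left+performed-right"]
            assert comb.FAR.iloc[0] <= comps.FAR.min() + 1e-12
            assert comb.FRR.iloc[0] >= comps.FRR.max() - 1e-12

    def test_missing_day_names_subject_and_day(self, small_pool):
        truncated = [e for e in small_pool
                     if not (e.subject_id == 1 and e.day_index == 1)]
        with pytest.raises(ValidationError, match="subject 1.*day 1"):
            leave_one_day_out(truncated, [0, 1, 2],
                              AuthPolicy(tasks=(PL,)), CFG, n_days=2)

    def test_train_test_day_disjoint(self, small_pool, monkeypatch):
        """Provenance assertion: no training epoch may come from the fold's
        held-out day."""
        import neuroauth.evaluation as ev
        seen = []
        orig = ev.fit_subject_model

        def spy(pool, *args, **kwargs):
            seen.append({e.day_index for e in pool})
            return orig(pool, *args, **kwargs)

        monkeypatch.setattr(ev, "fit_subject_model", spy)
        leave_one_day_out(small_pool, [0], AuthPolicy(tasks=(PL,)), CFG,
                          n_days=2)
        assert seen == [{1}, {0}]  # fold 0 trains on day 1 and vice versa


class TestSweeps:
    def test_fraction_sweep_table_shape_and_shared_subsets(self, small_pool):
        table = training_fraction_sweep(
            small_pool, [0], PL, fractions=(0.5, 1.0), n_runs=2,
            cfg=EnsembleConfig(M=1, base=FAST, seed=0), n_days=2, seed=0)
        assert set(table["method"]) == {"single_lstm", "bagged_M1"}
        # both methods present for every (fraction, fold, run) cell
        counts = table.groupby(["fraction", "fold", "run"])["method"].nunique()
        assert (counts == 2).all()
        assert len(table) == 2 * 2 * 2 * 2  # fractions x folds x runs x methods

    def test_fraction_below_one_epoch_skipped(self, small_pool, caplog):
        with caplog.at_level("WARNING"):
            table = training_fraction_sweep(
                small_pool, [0], PL, fractions=(0.01,), n_runs=1,
                cfg=EnsembleConfig(M=1, base=FAST, seed=0), n_days=2, seed=0)
        assert table.empty
        assert "skipped" in caplog.text

    def test_bagging_sweep_one_row_per_m_subject_fold(self, small_pool):
        table = bagging_size_sweep(small_pool, [0, 1], AuthPolicy(tasks=(PL,)),
                                   sizes=(1, 3), cfg=CFG, n_days=2)
        assert set(table["M"]) == {1, 3}
        assert len(table) == 2 * 2 * 2  # M x subjects x folds

    def test_bagging_sweep_reproducible(self, small_pool):
        a = bagging_size_sweep(small_pool, [0], AuthPolicy(tasks=(PL,)),
                               sizes=(3,), cfg=CFG, n_days=2)
        b = bagging_size_sweep(small_pool, [0], AuthPolicy(tasks=(PL,)),
                               sizes=(3,), cfg=CFG, n_days=2)
        pd.testing.assert_frame_equal(a, b)


class TestWilcoxon:
    def test_constant_shift_exact_p(self):
        """All ten differences share a sign: statistic 0 and exact
        two-sided p = 2/2^10."""
        rng = np.random.default_rng(0)
        b = rng.normal(size=10)
        statistic, p = wilcoxon_signed_rank(b + 1.0, b)
        assert statistic == 0.0
        assert p == pytest.approx(2.0 / 2 ** 10)

    def test_null_pvalues_roughly_uniform(self):
        """Simulation oracle: under exchangeable symmetric differences the
        p-value distribution is approximately uniform."""
        rng = np.random.default_rng(1)
        ps = []
        for _ in range(300):
            d = rng.normal(size=12)
            _, p = wilcoxon_signed_rank(d, np.zeros(12))
            ps.append(p)
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 1e-3

    def test_large_n_uses_normal_approximation(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=30)
        _, p = wilcoxon_signed_rank(a + 0.5, a)
        ref = stats.wilcoxon(a + 0.5, a, zero_method="wilcox",
                             method="approx", correction=False)
        assert p == pytest.approx(ref.pvalue)

    def test_too_few_nonzero_differences_rejected(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        b = a.copy()
        b[:4] += 1.0  # only 4 nonzero differences remain
        with pytest.raises(ValidationError, match="nonzero"):
            wilcoxon_signed_rank(b, a)

    def test_all_zero_differences_rejected(self):
        a = np.ones(8)
        with pytest.raises(ValidationError, match="zero"):
            wilcoxon_signed_rank(a, a)

    def test_pairwise_table_contains_all_scheme_pairs(self, small_pool):
        report = leave_one_day_out(small_pool, [0, 1, 2],
                                   AuthPolicy(tasks=(PL, PR)), CFG, n_days=2)
        table = pairwise_scheme_tests(report)
        assert len(table) == 3  # 3 schemes -> 3 pairs
        assert {"scheme_a", "scheme_b", "p_value",
                "significant"} <= set(table.columns)
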