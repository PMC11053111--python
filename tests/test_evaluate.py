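"""Validation protocol: splits, oversampling, metrics, bootstrap, KM."""

import numpy as np
import pytest

from polarmace.errors import ValidationError
from polarmace.evaluate import (
    ExperimentConfig,
    SplitPlan,
    auc,
    bootstrap_summary,
    concordance_index,
    km_risk_groups,
    oversample_positives,
    run_experiment,
    selection_counts,
    stratified_split,
    youden_cutoff,
)


class TestStratifiedSplit:
    def test_reference_cohort_counts(self):
        labels = np.array([1] * 47 + [0] * 187)
        train, test = stratified_split(labels, 0.75, seed=0)
        assert len(train) == 175 and len(test) == 59
        assert labels[train].sum() == 35
        assert (labels[train] == 0).sum() == 140

    def test_disjoint_and_exhaustive(self):
        labels = (np.arange(100) % 3 == 0).astype(int)
        train, test = stratified_split(labels, 0.75, seed=5)
        assert len(np.intersect1d(train, test)) == 0
        assert len(np.union1d(train, test)) == 100

    def test_small_symmetric_case(self):
        labels = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        train, _ = stratified_split(labels, 0.5, seed=1)
        assert len(train) == 4 and labels[train].sum() == 2

    def test_same_seed_reproduces_partition(self):
        labels = np.array([0, 1] * 30)
        a = stratified_split(labels, 0.75, seed=9)
        b = stratified_split(labels, 0.75, seed=9)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            stratified_split(np.zeros(10, dtype=int), 0.75, seed=0)


class TestOversampling:
    def test_reference_counts_245_105_140(self):
        labels = np.array([1] * 47 + [0] * 187)
        train, _ = stratified_split(labels, 0.75, seed=0)
        over = oversample_positives(train, labels, seed=0)
        assert len(over) == 245
        assert labels[over].sum() == 105
        assert (labels[over] == 0).sum() == 140

    def test_each_positive_appears_exactly_three_times(self):
        labels = np.array([1, 0, 0, 1, 0])
        over = oversample_positives(np.arange(5), labels, seed=2)
        counts = dict(zip(*np.unique(over, return_counts=True)))
        assert counts == {0: 3, 1: 1, 2: 1, 3: 3, 4: 1}

    def test_no_positives_leaves_set_unchanged(self):
        labels = np.zeros(6, dtype=int)
        over = oversample_positives(np.arange(6), labels, seed=0)
        assert sorted(over) == list(range(6))


class TestAuc:
    def test_perfect_separation(self):
        assert auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_pairwise_oracle_with_ties(self, rng):
        for _ in range(10):
            scores = rng.integers(0, 5, size=20).astype(float)  # force ties
            labels = rng.integers(0, 2, size=20)
            if labels.sum() in (0, 20):
                continue
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            pairs = sum(
                1.0 if p > n else (0.5 if p == n else 0.0) for p in pos for n in neg
            )
            assert auc(scores, labels) == pytest.approx(pairs / (len(pos) * len(neg)))

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.uniform(size=50)
        labels = rng.integers(0, 2, size=50)
        assert auc(scores, labels) == pytest.approx(roc_auc_score(labels, scores))

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.uniform(size=40)
        labels = rng.integers(0, 2, size=40)
        assert auc(scores, labels) == pytest.approx(auc(np.exp(3 * scores), labels))

    def test_null_scores_near_half(self, rng):
        scores = rng.uniform(size=4000)
        labels = rng.integers(0, 2, size=4000)
        assert abs(auc(scores, labels) - 0.5) < 0.05

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            auc([0.5, 0.6], [1, 1])


class TestYoudenCutoff:
    def test_separable_example(self):
        cut, sens, spec = youden_cutoff([0.1, 0.2, 0.7, 0.9], [0, 0, 1, 1])
        assert sens == 1.0 and spec == 1.0
        assert 0.2 < cut <= 0.7

    def test_degenerate_equal_scores(self):
        cut, sens, spec = youden_cutoff([0.4] * 6, [0, 1, 0, 1, 0, 1])
        assert sens + spec - 1.0 == pytest.approx(0.0)

    def test_matches_exhaustive_threshold_scan(self, rng):
        for _ in range(10):
            scores = rng.uniform(size=30)
            labels = rng.integers(0, 2, size=30)
            if labels.sum() in (0, 30):
                continue
            best_j = max(
                ((scores >= t) & (labels == 1)).sum() / labels.sum()
                + ((scores < t) & (labels == 0)).sum() / (labels == 0).sum()
                - 1.0
                for t in scores
            )
            cut, sens, spec = youden_cutoff(scores, labels)
            assert sens + spec - 1.0 == pytest.approx(best_j)
            assert scores.min() <= cut <= scores.max()


class TestConcordance:
    def test_perfect_risk_ordering(self):
        times = np.array([10.0, 50.0, 200.0, 400.0])
        assert concordance_index(-times, np.ones(4, dtype=int), times) == 1.0

    def test_null_risks_near_half(self, rng):
        risks = rng.uniform(size=600)
        events = (rng.uniform(size=600) < 0.5).astype(int)
        times = rng.uniform(10, 900, size=600)
        assert abs(concordance_index(risks, events, times) - 0.5) < 0.05

    def test_hand_enumerated_censored_fixture(self):
        # patient 0: event day 100; patient 1: censored day 50; patient 2:
        # event day 200; patient 3: censored day 300.
        # comparable: (0,2) (0,3) (2,3); pair (1,*) never comparable as no
        # event before; (0,1) not comparable (censored earlier).
        risks = np.array([3.0, 9.9, 2.0, 1.0])
        events = np.array([1, 0, 1, 0])
        times = np.array([100.0, 50.0, 200.0, 300.0])
        assert concordance_index(risks, events, times) == 1.0
        # flip one pair: risk of patient 2 below patient 3
        risks = np.array([3.0, 9.9, 0.5, 1.0])
        assert concordance_index(risks, events, times) == pytest.approx(2.0 / 3.0)

    def test_matches_lifelines(self, rng):
        from lifelines.utils import concordance_index as ll_ci

        risks = rng.uniform(size=80)
        events = (rng.uniform(size=80) < 0.6).astype(int)
        times = rng.uniform(10, 900, size=80)
        mine = concordance_index(risks, events, times)
        assert mine == pytest.approx(ll_ci(times, -risks, events))

    def test_no_comparable_pairs_rejected(self):
        with pytest.raises(ValidationError):
            concordance_index([1.0, 2.0], [0, 0], [10.0, 20.0])


class TestBootstrapSummary:
    def test_degenerate_distribution(self):
        report = bootstrap_summary({"a": [0.7] * 100, "b": [0.7] * 100})
        row = report.means.loc["a"]
        assert row["mean"] == pytest.approx(0.7)
        assert row["ci_lo"] == pytest.approx(row["mean"])
        assert row["ci_hi"] == pytest.approx(row["mean"])
        assert report.comparisons.iloc[0]["p_value"] == 1.0

    def test_planted_margin_gives_small_p(self, rng):
        base = rng.normal(0.70, 0.02, size=100)
        report = bootstrap_summary({"good": list(base + 0.05), "bad": list(base)})
        assert report.comparisons.iloc[0]["p_value"] <= 0.01

    def test_ci_brackets_the_mean(self, rng):
        values = list(rng.uniform(0.6, 0.8, size=100))
        report = bootstrap_summary({"m": values})
        row = report.means.loc["m"]
        assert row["ci_lo"] <= row["mean"] <= row["ci_hi"]

    def test_mismatched_repeat_counts_rejected(self):
        with pytest.raises(ValidationError):
            bootstrap_summary({"a": [0.5] * 10, "b": [0.5] * 9})


class TestKmRiskGroups:
    def test_no_events_gives_flat_curves(self, rng):
        scores = rng.uniform(size=40)
        out = km_risk_groups(scores, np.zeros(40, dtype=int), rng.uniform(100, 900, size=40))
        assert out["low"].survival_function_.iloc[-1, 0] == 1.0
        assert out["high"].survival_function_.iloc[-1, 0] == 1.0

    def test_identical_groups_give_zero_statistic(self):
        times = np.tile([100.0, 200.0, 300.0, 400.0], 2)
        events = np.tile([1, 0, 1, 0], 2)
        scores = np.array([0.0] * 4 + [1.0] * 4)
        out = km_risk_groups(scores, events, times)
        assert out["chi2"] == pytest.approx(0.0, abs=1e-9)

    def test_median_ties_go_to_low_risk_group(self):
        scores = np.array([0.2, 0.5, 0.5, 0.9])
        out = km_risk_groups(scores, np.array([0, 0, 1, 1]), np.array([100.0, 200, 300, 400]))
        assert out["low_mask"].sum() == 3  # both 0.5 scores are at the median

    def test_planted_hazard_separation_detected(self, rng):
        # high-risk half has ~3x hazard; expect log-rank p < 0.05 in most runs
        detected = 0
        n_rep = 10
        for rep in range(n_rep):
            r = np.random.default_rng(rep)
            scores = np.concatenate([np.zeros(117), np.ones(117)])
            lam = np.where(scores > 0, 3.0, 1.0) / 900.0
            t_event = r.exponential(1.0 / lam)
            censor = r.uniform(400, 900, size=234)
            times = np.minimum(t_event, censor)
            events = (t_event <= censor).astype(int)
            out = km_risk_groups(scores, events, times)
            detected += out["p_value"] < 0.05
        assert detected >= 0.9 * n_rep


class TestSelectionCounts:
    class _Stub:
        def __init__(self, idx):
            self.selected_features_ = np.array(idx, dtype=int)

    def test_counts_bounded_by_repeats_and_zero_for_never_selected(self):
        models = [self._Stub([0, 2]) for _ in range(100)]
        counts = selection_counts(models, ["a", "b", "c"])
        assert counts["a"] == 100 and counts["b"] == 0 and counts["c"] == 100
        assert counts.max() <= 100

    def test_planted_informative_feature_has_highest_count(self, rng):
        from polarmace.models import fit_lr_elasticnet

        y = np.tile([0, 1], 40)
        X = np.column_stack([y + 0.2 * rng.normal(size=80), rng.normal(size=(80, 4))])
        models = [fit_lr_elasticnet(X, y, seed=s) for s in range(3)]
        counts = selection_counts(models, [f"f{i}" for i in range(5)])
        assert counts["f0"] == counts.max() == 3


class TestRunExperiment:
    def test_end_to_end_determinism_and_no_leakage(self, small_cohort):
        records, _ = small_cohort
        plan = SplitPlan(n_repeats=3)
        cfg = ExperimentConfig(signal="smbf")
        res_a, sum_a, _ = run_experiment(records, "global", plan, cfg)
        res_b, sum_b, _ = run_experiment(records, "global", plan, cfg)
        assert [r.auc for r in res_a] == [r.auc for r in res_b]
        assert sum_a.means.equals(sum_b.means)
        labels = np.array([r.outcome.event for r in records])
        for r in res_a:
            train, test = stratified_split(labels, plan.train_fraction, plan.seeds[r.repeat])
            assert len(np.intersect1d(train, r.test_indices)) == 0
            np.testing.assert_array_equal(np.sort(r.test_indices), test)

    def test_survival_task_reports_c_index(self, small_cohort):
        records, _ = small_cohort
        plan = SplitPlan(n_repeats=2)
        cfg = ExperimentConfig(signal="smbf", task="survival")
        results, summary, _ = run_experiment(records, "global", plan, cfg)
        for r in results:
            assert 0.0 <= r.c_index <= 1.0
            assert np.isnan(r.auc)
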