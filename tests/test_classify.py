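import numpy as np
import pytest

import uropep as u
from conftest import separable_cohort
from uropep.classify import _kernel_decision, class_weights, clopper_pearson, delong_paired_test
from uropep.types import SampleRecord


def auc_concordance_oracle(scores, labels):
    """Pairwise concordance: mean over (pos, neg) pairs of 1/0.5/0."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, bool)
    pos, neg = s[y], s[~y]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


class TestTraining:
    def test_separable_clouds_fit_perfectly(self):
        peaks, records = separable_cohort()
        model = u.train_svm(peaks, records, peaks.peptide_ids)
        calls = model.classify(peaks)
        labels = np.array([r.is_case for r in records])
        scores = model.decision_values(peaks).to_numpy()
        assert np.array_equal(scores > 0, labels)

    def test_rbf_kernel_self_similarity_is_one(self):
        # K(u, u) = exp(0) = 1 regardless of gamma
        u_vec = np.array([[1.0, -2.0, 3.0]])
        d2 = ((u_vec[:, None, :] - u_vec[None, :, :]) ** 2).sum(axis=2)
        assert np.exp(-0.0764 * d2)[0, 0] == 1.0

    def test_class_weight_ratio(self):
        labels = np.array([1] * 2 + [0] * 10)
        w = class_weights(labels)
        assert w[1] / w[0] == pytest.approx(5.0)

    def test_single_class_rejected(self):
        peaks, records = separable_cohort()
        cases = [r for r in records if r.is_case]
        with pytest.raises(ValueError):
            u.train_svm(peaks.subset_samples([r.sample_id for r in cases]), cases,
                        peaks.peptide_ids)

    def test_case_control_flip_negates_scores(self):
        peaks, records = separable_cohort(seed=9)
        flipped = [
            SampleRecord(sample_id=r.sample_id, group="LC" if r.is_case else "HCC",
                         age=r.age, sex=r.sex)
            for r in records
        ]
        m1 = u.train_svm(peaks, records, peaks.peptide_ids)
        m2 = u.train_svm(peaks, flipped, peaks.peptide_ids)
        np.testing.assert_allclose(
            m1.decision_values(peaks).to_numpy(),
            -m2.decision_values(peaks).to_numpy(),
            atol=1e-6,
        )


class TestMembershipScores:
    def test_duplicated_sample_scores_identically(self):
        peaks, records = separable_cohort()
        model = u.train_svm(peaks, records, peaks.peptide_ids)
        dup = peaks.subset_samples([peaks.sample_ids[0], peaks.sample_ids[0]][:1])
        s1 = u.membership_scores(model, peaks).iloc[0]
        s2 = u.membership_scores(model, dup).iloc[0]
        assert s1 == pytest.approx(s2, rel=1e-12)

    def test_missing_panel_peptide_rejected(self):
        peaks, records = separable_cohort()
        model = u.train_svm(peaks, records, peaks.peptide_ids)
        with pytest.raises(KeyError):
            u.membership_scores(model, peaks.subset_peptides(peaks.peptide_ids[:2]))

    def test_decision_values_match_manual_kernel_sum(self):
        # oracle: recompute f(x) = sum_i alpha_i exp(-g ||sv_i - x||^2) + b
        peaks, records = separable_cohort(seed=2)
        model = u.train_svm(peaks, records, peaks.peptide_ids)
        X = model._features(peaks)
        manual = _kernel_decision(model.artifact(), X)
        np.testing.assert_allclose(
            manual, model.svc.decision_function(X), rtol=1e-9, atol=1e-9
        )

    def test_json_round_trip_preserves_scores(self, tmp_path):
        peaks, records = separable_cohort(seed=3)
        model = u.train_svm(peaks, records, peaks.peptide_ids)
        path = tmp_path / "model.json"
        model.save(path)
        loaded = u.ClassifierModel.load(path)
        np.testing.assert_allclose(
            loaded.decision_values(peaks).to_numpy(),
            model.decision_values(peaks).to_numpy(),
            rtol=1e-8,
        )
        assert loaded.threshold == model.threshold


class TestLeaveOneOut:
    def test_separable_toy_has_perfect_loo_auc(self):
        peaks, records = separable_cohort(n_per_class=10)
        scores = u.loo_cross_validate(peaks, records, peaks.peptide_ids)
        labels = np.array([r.is_case for r in records])
        assert u.auc_mann_whitney(scores.to_numpy(), labels) == 1.0

    def test_permuted_labels_give_chance_auc(self):
        peaks, records = separable_cohort(n_per_class=20, seed=21)
        rng = np.random.default_rng(5)
        perm = rng.permutation(len(records))
        shuffled = [
            SampleRecord(sample_id=records[i].sample_id,
                         group=records[perm[i]].group, age=60.0)
            for i in range(len(records))
        ]
        scores = u.loo_cross_validate(peaks, shuffled, peaks.peptide_ids)
        labels = np.array([r.is_case for r in shuffled])
        auc = u.auc_mann_whitney(scores.to_numpy(), labels)
        assert abs(auc - 0.5) < 0.2

    def test_tiny_classes_rejected(self):
        peaks, records = separable_cohort(n_per_class=2)
        with pytest.raises(ValueError):
            u.loo_cross_validate(peaks, records, peaks.peptide_ids)


class TestROC:
    def test_small_worked_example(self):
        # cases {3, 1}, controls {2, 0}: 3 of 4 pairs concordant
        res = u.roc_analysis([3, 1, 2, 0], [True, True, False, False], threshold=1.5)
        assert res.auc == pytest.approx(0.75)

    def test_perfect_separation(self):
        res = u.roc_analysis([5, 6, 1, 2], [True, True, False, False], threshold=3.5)
        assert res.auc == 1.0
        assert res.sensitivity == 1.0 and res.specificity == 1.0

    def test_clopper_pearson_worked_example(self):
        lo, hi = clopper_pearson(7, 10)
        assert lo == pytest.approx(0.348, abs=5e-4)
        assert hi == pytest.approx(0.933, abs=5e-4)

    def test_auc_matches_concordance_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(6, 60))
            scores = np.round(rng.normal(size=n), 1)  # induce ties
            labels = rng.random(n) < 0.4
            if labels.all() or not labels.any():
                continue
            assert u.auc_mann_whitney(scores, labels) == pytest.approx(
                auc_concordance_oracle(scores, labels), abs=1e-12
            )

    def test_delong_ci_contains_point_estimate(self, rng):
        scores = rng.normal(size=80) + np.repeat([0.0, 1.0], 40)
        labels = np.repeat([False, True], 40)
        res = u.roc_analysis(scores, labels, threshold=0.5)
        lo, hi = res.auc_ci_95
        assert lo <= res.auc <= hi
        assert 0.0 <= lo and hi <= 1.0

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            u.roc_analysis([1, 2], [True, True], 0.0)


class TestYouden:
    def test_worked_example(self):
        thr, j = u.youden_threshold(
            [0.9, 0.8, 0.1, 0.2, 0.85], [True, True, False, False, False]
        )
        assert 0.2 < thr <= 0.8
        assert j == pytest.approx(2 / 3, abs=1e-9)

    def test_perfect_separation_takes_gap_midpoint(self):
        thr, j = u.youden_threshold([5, 6, 1, 2], [True, True, False, False])
        assert thr == pytest.approx(3.5)
        assert j == 1.0

    def test_degenerate_constant_scores(self):
        thr, j = u.youden_threshold([2.0, 2.0, 2.0], [True, False, False])
        assert thr == 2.0 and j == 0.0


class TestCovariateAdjustment:
    def make_records(self, labels, ages, sexes=None):
        return [
            SampleRecord(
                sample_id=f"S{i}",
                group="HCC" if labels[i] else "LC",
                age=float(ages[i]),
                sex=(sexes[i] if sexes is not None else "M"),
            )
            for i in range(len(labels))
        ]

    def test_uninformative_covariates_leave_auc_unchanged(self, rng):
        labels = np.repeat([True, False], 40)
        scores = rng.normal(size=80) + labels * 2.0
        records = self.make_records(labels, rng.uniform(40, 80, 80),
                                    np.where(rng.random(80) < 0.5, "F", "M"))
        adj = u.adjust_covariates(scores, records)
        assert abs(adj.auc_adjusted - adj.auc_unadjusted) < 0.05

    def test_label_determined_by_age_gives_perfect_adjusted_auc(self, rng):
        labels = np.repeat([True, False], 30)
        ages = np.where(labels, 75.0, 45.0) + rng.normal(0, 1, 60)
        scores = rng.normal(size=60)  # useless score
        adj = u.adjust_covariates(scores, self.make_records(labels, ages))
        assert adj.auc_adjusted > 0.99

    def test_constant_score_reduces_to_covariate_model(self, rng):
        labels = np.repeat([True, False], 25)
        ages = np.where(labels, 70.0, 50.0) + rng.normal(0, 5, 50)
        adj = u.adjust_covariates(np.zeros(50), self.make_records(labels, ages))
        assert adj.auc_adjusted > 0.8

    def test_paired_delong_identical_scores_p_one(self, rng):
        labels = np.repeat([True, False], 20)
        scores = rng.normal(size=40) + labels
        a1, a2, p = delong_paired_test(scores, scores, labels)
        assert a1 == a2 and p == 1.0
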