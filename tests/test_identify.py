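"""Pair construction, empirical ROC curves, and subject group splits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from connectoprint import build_pairs, roc_from_pairs, roc_from_scores, split_groups
from connectoprint.core import ScanRecord
from connectoprint.identify import auc_mann_whitney


def _scan(sub, visit, session, age=20.0, sex="F", vec=None, rng=None):
    if vec is None:
        vec = (rng or np.random.default_rng(abs(hash((sub, visit, session))) % 2**31)
               ).uniform(-1, 1, 20)
    return ScanRecord(sub, visit, session, age, sex, vec)


class TestBuildPairs:
    def test_two_subject_enumeration(self):
        scans = [_scan(s, 1, ses) for s in ("a", "b") for ses in ("pre", "post")]
        pairs = build_pairs(scans, ["V1_pre_post"])
        assert len(pairs) == 4
        assert pairs["is_same_subject"].sum() == 2

    def test_subject_without_v2_contributes_no_cross_visit_rows(self):
        scans = [_scan("a", v, s) for v in (1, 2) for s in ("pre", "post")]
        scans += [_scan("b", 1, s) for s in ("pre", "post")]
        pairs = build_pairs(scans, ["X_pre_pre"])
        assert set(pairs["subject_b"]) == {"a"}
        assert len(pairs) == 2  # a_V1pre x a_V2pre, b_V1pre x a_V2pre

    def test_positive_count_matches_manifest(self, small_cohort):
        # oracle: count subjects holding both scans of the type
        pairs = build_pairs(small_cohort.scans, ["V2_pre_post"])
        n_v2 = len({s.subject_id for s in small_cohort.scans if s.visit == 2})
        assert pairs["is_same_subject"].sum() == n_v2
        assert len(pairs) == n_v2 * n_v2

    def test_scores_are_similarities(self, small_cohort):
        from connectoprint import similarity
        pairs = build_pairs(small_cohort.scans, ["V1_pre_post"]).iloc[:5]
        vecs = {s.scan_id: s.norm_vector for s in small_cohort.scans}
        for _, row in pairs.iterrows():
            assert row["score"] == pytest.approx(
                similarity(vecs[row["scan_a"]], vecs[row["scan_b"]]))

    def test_missing_pool_raises(self):
        scans = [_scan("a", 1, "pre"), _scan("b", 1, "pre")]
        with pytest.raises(ValueError, match="no eligible scans"):
            build_pairs(scans, ["V1_pre_post"])


class TestROC:
    def test_perfect_separation(self):
        roc = roc_from_scores(np.array([0.8, 0.9]), np.array([0.1, 0.2]))
        assert roc.auc == 1.0
        assert roc.sensitivity == 1.0 and roc.specificity == 1.0

    def test_worked_four_score_example(self):
        # Mann-Whitney enumeration over the 4 pairings: 3 concordant of 4
        roc = roc_from_scores(np.array([0.9, 0.4]), np.array([0.8, 0.1]))
        assert roc.auc == pytest.approx(0.75)

    def test_shuffled_labels_give_chance_auc(self, rng):
        scores = rng.standard_normal(2000)
        labels = rng.random(2000) < 0.3
        roc = roc_from_scores(scores[labels], scores[~labels])
        assert abs(roc.auc - 0.5) < 0.04

    def test_auc_equals_brute_force_concordance(self, rng):
        # exact oracle: count concordant pairs, ties count half
        for _ in range(20):
            n_pos = rng.integers(2, 60)
            n_neg = rng.integers(2, 120)
            pos = rng.integers(0, 8, n_pos) / 4.0  # force ties
            neg = rng.integers(0, 8, n_neg) / 4.0
            brute = np.mean((pos[:, None] > neg[None, :])
                            + 0.5 * (pos[:, None] == neg[None, :]))
            roc = roc_from_scores(pos, neg)
            assert roc.auc == pytest.approx(brute, abs=1e-12)
            # curve area cross-check (trapezoid over the full sweep)
            area = np.trapezoid(roc.tpr, roc.fpr)
            assert area == pytest.approx(roc.auc, abs=1e-12)

    def test_auc_agrees_with_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score
        scores = rng.standard_normal(500)
        labels = rng.random(500) < 0.4
        roc = roc_from_scores(scores[labels], scores[~labels])
        assert roc.auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_operating_point_reproduced_by_confusion_counting(self, rng):
        pos = rng.normal(1, 1, 80)
        neg = rng.normal(0, 1, 200)
        roc = roc_from_scores(pos, neg)
        t = roc.optimal_t
        assert roc.sensitivity == pytest.approx((pos >= t).mean())
        assert roc.specificity == pytest.approx((neg < t).mean())
        # Youden: no other observed threshold does better
        all_t = np.concatenate([pos, neg])
        youden = [(pos >= x).mean() - (neg >= x).mean() for x in all_t]
        assert roc.sensitivity - (1 - roc.specificity) == pytest.approx(max(youden))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_from_scores(np.array([1.0]), np.array([]))

    def test_tpr_fpr_monotone_in_threshold(self, rng):
        roc = roc_from_scores(rng.normal(1, 1, 50), rng.normal(0, 1, 50))
        assert (np.diff(roc.tpr) >= 0).all()  # thresholds sweep downward
        assert (np.diff(roc.fpr) >= 0).all()


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 10_000))
def test_auc_invariant_under_monotone_transform(seed):
    rng = np.random.default_rng(seed)
    pos = rng.normal(0.5, 1, 30)
    neg = rng.normal(0.0, 1, 50)
    base = auc_mann_whitney(pos, neg)
    for f in (lambda x: 3 * x + 2, np.tanh, lambda x: np.exp(x / 4)):
        assert auc_mann_whitney(f(pos), f(neg)) == pytest.approx(base, abs=1e-12)


class TestSplitGroups:
    def test_median_split_halves_balanced_ages(self):
        ages = list(range(12, 20)) + list(range(21, 29))
        scans = [_scan(f"s{i}", 1, "pre", age=a) for i, a in enumerate(ages)]
        young, old = split_groups(scans, by="median_age")
        assert len(young) == len(old) == 8

    def test_age18_rule(self):
        scans = [_scan(f"s{i}", 1, "pre", age=a)
                 for i, a in enumerate([12, 17, 18, 30])]
        young, old = split_groups(scans, by="age18")
        assert {s.age_years for s in young} == {12, 17}
        assert {s.age_years for s in old} == {18, 30}

    def test_median_vs_mean_membership_changes_only_between_cutpoints(self, small_cohort):
        scans = small_cohort.scans
        med_y, _ = split_groups(scans, by="median_age")
        mean_y, _ = split_groups(scans, by="mean_age")
        ages = {s.subject_id: s.age_years for s in scans if s.visit == 1}
        med = np.median(list(ages.values()))
        mean = np.mean(list(ages.values()))
        lo, hi = sorted([med, mean])
        moved = ({s.subject_id for s in med_y} ^ {s.subject_id for s in mean_y})
        for sid in moved:
            assert lo <= ages[sid] < hi

    def test_subject_stays_in_one_group_across_visits(self, small_cohort):
        young, old = split_groups(small_cohort.scans, by="median_age")
        assert {s.subject_id for s in young}.isdisjoint(
            {s.subject_id for s in old})

    def test_sex_split(self):
        scans = [_scan(f"s{i}", 1, "pre", sex=("F" if i % 2 else "M"))
                 for i in range(6)]
        f, m = split_groups(scans, by="sex")
        assert all(s.sex == "F" for s in f) and all(s.sex == "M" for s in m)

    def test_tiny_group_rejected(self):
        scans = [_scan("a", 1, "pre", age=10), _scan("b", 1, "pre", age=11),
                 _scan("c", 1, "pre", age=12)]
        with pytest.raises(ValueError, match="fewer than 2"):
            split_groups(scans, by="age18")
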