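"""Edge selection: rebalancing, splits, differential power, penalized fits."""

import numpy as np
import pandas as pd
import pytest

from connectoprint import (
    apply_model,
    build_pairs,
    default_spec,
    finn_rank,
    fit_penalized,
    generate_cohort,
    pair_features,
    rebalance,
    roc_from_pairs,
    split_train_test,
)
from connectoprint.core import ScanRecord
from connectoprint.edges import EdgeModel, PairFeatureSet, differential_power, score_pairs


def _feature_set(x, y, subjects=None):
    n = len(y)
    pairs = pd.DataFrame({
        "scan_a": [f"a{i}" for i in range(n)],
        "scan_b": [f"b{i}" for i in range(n)],
        "subject_a": subjects if subjects is not None else [f"s{i}" for i in range(n)],
        "subject_b": [f"t{i}" for i in range(n)],
        "comparison_type": "V1_pre_post",
        "is_same_subject": y,
        "score": x.sum(axis=1) / x.shape[1],
    })
    return PairFeatureSet(np.asarray(x, float), np.asarray(y, bool), pairs)


class TestPairFeatures:
    def test_row_sums_recover_similarity(self, small_cohort):
        pairs = build_pairs(small_cohort.scans, ["V1_pre_post"])
        fs = pair_features(pairs, small_cohort.scans)
        np.testing.assert_allclose(fs.X.sum(axis=1) / fs.n_edges,
                                   pairs["score"].to_numpy(), atol=1e-10)


class TestRebalance:
    def test_study_scale_bookkeeping(self, rng):
        # 532 pairs -> exactly 3x = 1,596 retained nonpairs
        x = rng.standard_normal((3000, 5))
        y = np.zeros(3000, bool)
        y[:532] = True
        out = rebalance(_feature_set(x, y), ratio=3)
        assert int(out.y.sum()) == 532
        assert int((~out.y).sum()) == 1_596

    def test_zero_distance_duplicates_selected(self, rng):
        xp = rng.standard_normal((5, 4))
        x = np.vstack([xp, xp, rng.standard_normal((20, 4)) + 10.0])
        y = np.array([True] * 5 + [False] * 25)
        out = rebalance(_feature_set(x, y), ratio=1)
        kept_neg = out.X[~out.y]
        np.testing.assert_allclose(np.sort(kept_neg, axis=0), np.sort(xp, axis=0))

    def test_matches_brute_force_distance_oracle(self, rng):
        x = rng.standard_normal((120, 6))
        y = rng.random(120) < 0.18
        y[:2] = True
        fs = _feature_set(x, y)
        out = rebalance(fs, ratio=3)
        # O(n^2) oracle over the full distance matrix
        pos, neg = x[y], x[~y]
        d = np.sqrt(((neg[:, None, :] - pos[None, :, :]) ** 2).sum(-1)).min(1)
        keep = np.argsort(d, kind="stable")[: 3 * y.sum()]
        expected = neg[np.sort(keep)]
        np.testing.assert_allclose(out.X[~out.y], expected)

    def test_too_few_nonpairs_rejected(self, rng):
        x = rng.standard_normal((10, 3))
        y = np.array([True] * 5 + [False] * 5)
        with pytest.raises(ValueError, match="nonpairs"):
            rebalance(_feature_set(x, y), ratio=3)


class TestSplit:
    @pytest.mark.parametrize("n_pos,n_neg,want", [
        (532, 1596, (355, 1064, 177, 532)),  # the study-scale bookkeeping
        (3, 9, (2, 6, 1, 3)),                # round-half-up on 2/3
    ])
    def test_stratified_counts(self, rng, n_pos, n_neg, want):
        x = rng.standard_normal((n_pos + n_neg, 3))
        y = np.array([True] * n_pos + [False] * n_neg)
        train, test = split_train_test(_feature_set(x, y), seed=0)
        assert (int(train.y.sum()), int((~train.y).sum()),
                int(test.y.sum()), int((~test.y).sum())) == want

    def test_disjoint_and_exhaustive(self, rng):
        x = rng.standard_normal((40, 3))
        y = np.array([True] * 10 + [False] * 30)
        fs = _feature_set(x, y)
        train, test = split_train_test(fs, seed=1)
        joined = np.vstack([train.X, test.X])
        assert joined.shape[0] == 40
        assert {tuple(r) for r in joined} == {tuple(r) for r in x}

    def test_empty_class_rejected(self, rng):
        x = rng.standard_normal((4, 3))
        y = np.array([True, False, False, False])
        with pytest.raises(ValueError, match="empty"):
            split_train_test(_feature_set(x, y), train_frac=0.9, seed=0)


class TestDifferentialPower:
    def test_uninformative_edge_scores_zero(self):
        z1 = np.ones((4, 3))
        z2 = np.ones((4, 3))
        dp = differential_power(z1, z2)
        np.testing.assert_allclose(dp, 0.0)

    def test_identifying_edge_floors_its_subject_and_dominates(self, rng):
        s = 5
        # subject 0's two scans share a large same-sign value on edge 0 while
        # everyone else sits near zero there: subject 0's cross products all
        # fall below its within product, so its P hits the floor
        z1 = rng.normal(0, 0.01, (s, 2))
        z2 = rng.normal(0, 0.01, (s, 2))
        z1[0, 0] = 3.0
        z2[0, 0] = 3.2
        dp = differential_power(z1, z2)
        floor_term = -np.log(1.0 / (2 * (s - 1) * 10))
        assert dp[0] >= floor_term          # at least subject 0 is floored
        assert dp[0] > dp[1] + floor_term / 2

    def test_matches_enumeration_oracle(self, rng):
        # brute force over all (s, j) products on a 5-subject, 20-edge set
        s, e = 5, 20
        z1 = rng.standard_normal((s, e))
        z2 = rng.standard_normal((s, e))
        floor = 1.0 / (2 * (s - 1) * 10)
        expected = np.zeros(e)
        for edge in range(e):
            for i in range(s):
                w = z1[i, edge] * z2[i, edge]
                cnt = sum(z1[i, edge] * z2[j, edge] >= w for j in range(s) if j != i)
                cnt += sum(z1[j, edge] * z2[i, edge] >= w for j in range(s) if j != i)
                p = max(cnt / (2 * (s - 1)), floor)
                expected[edge] += -np.log(p)
        np.testing.assert_allclose(differential_power(z1, z2), expected, atol=1e-12)

    def test_invariant_to_subject_order_and_scan_swap(self, rng):
        z1 = rng.standard_normal((6, 15))
        z2 = rng.standard_normal((6, 15))
        base = differential_power(z1, z2)
        perm = rng.permutation(6)
        np.testing.assert_allclose(differential_power(z1[perm], z2[perm]), base)
        np.testing.assert_allclose(differential_power(z2, z1), base)

    def test_group_consistency_option_selects_stable_edges(self, rng):
        from connectoprint.edges import group_consistency
        z1 = rng.standard_normal((6, 10)) * 0.1
        z2 = rng.standard_normal((6, 10)) * 0.1
        z1[:, 3] += 2.0  # edge 3 strong and stable in every subject
        z2[:, 3] += 2.0
        assert int(np.argmax(group_consistency(z1, z2))) == 3

    def test_finn_rank_excludes_single_scan_subjects(self, small_cohort):
        scans = list(small_cohort.scans)
        lone = ScanRecord("lonely", 1, "pre", 25.0, "M",
                          np.random.default_rng(0).uniform(-1, 1, scans[0].n_edges))
        with pytest.warns(UserWarning, match="lonely"):
            model = finn_rank(scans + [lone], top_frac=0.05)
        assert model.tuning["n_subjects"] == 12
        assert (model.scores >= 0).all()
        assert model.retained.size == round(0.05 * scans[0].n_edges)


class TestPenalized:
    def test_huge_lambda_shrinks_everything(self, rng):
        x = rng.standard_normal((60, 30))
        y = rng.random(60) < 0.5
        y[:5] = True; y[-5:] = False
        model = fit_penalized(_feature_set(x, y), method="elastic_net",
                              cv_folds=3, n_lambdas=3, lambda_min_ratio=0.99,
                              stratify_by_subject=False, seed=0)
        # at lambda_max the L1 part zeroes every weight
        from connectoprint.edges import _fit_path, _lambda_path
        lam = _lambda_path(x, y.astype(float), 0.1, 1, 1.0)
        coefs, _ = _fit_path(x, y, "elastic_net", 0.1, lam)
        assert np.abs(coefs).max() < 1e-5

    @pytest.mark.parametrize("method", ["elastic_net", "svm"])
    def test_planted_edges_recovered(self, method):
        # 10 planted edges differ strongly between classes; effect >> noise
        hits, false_rates = 0, []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n, e = 300, 120
            x = rng.standard_normal((n, e))
            y = rng.random(n) < 0.25
            planted = np.arange(10)
            x[np.ix_(y, planted)] += 3.0
            model = fit_penalized(_feature_set(x, y), method=method,
                                  cv_folds=5, n_lambdas=10,
                                  stratify_by_subject=False, seed=seed)
            got = set(model.retained.tolist())
            hits += len(got & set(planted.tolist())) >= 8
            false_rates.append(len(got - set(planted.tolist())) / (e - 10))
        assert hits >= 4
        assert np.mean(false_rates) <= 0.05

    def test_alpha_recorded_in_tuning(self, rng):
        x = rng.standard_normal((40, 10))
        y = np.array([True] * 15 + [False] * 25)
        model = fit_penalized(_feature_set(x, y), method="elastic_net",
                              cv_folds=3, n_lambdas=4,
                              stratify_by_subject=False, seed=0)
        assert model.tuning["alpha"] == 0.1
        assert model.method == "elastic_net"

    def test_single_class_rejected(self, rng):
        x = rng.standard_normal((10, 4))
        with pytest.raises(ValueError, match="both classes"):
            fit_penalized(_feature_set(x, np.ones(10, bool)))


class TestApplyModel:
    def test_finn_all_edges_equals_plain_similarity(self, small_cohort):
        pairs = build_pairs(small_cohort.scans, ["V1_pre_post"])
        fs = pair_features(pairs, small_cohort.scans)
        model = EdgeModel(method="finn", scores=np.ones(fs.n_edges),
                          retained=np.arange(fs.n_edges))
        scores = score_pairs(model, fs)
        np.testing.assert_allclose(scores, pairs["score"].to_numpy(), atol=1e-10)

    def test_fresh_threshold_on_new_cohort(self, small_cohort):
        pairs = build_pairs(small_cohort.scans, ["V1_pre_post"])
        fs = pair_features(pairs, small_cohort.scans)
        model = finn_rank(small_cohort.scans, top_frac=0.1)
        _, roc = apply_model(model, fs)
        assert 0.0 <= roc.auc <= 1.0
        assert roc.n_pos == int(fs.y.sum())

    def test_parcellation_mismatch_rejected(self, small_cohort, rng):
        pairs = build_pairs(small_cohort.scans, ["V1_pre_post"])
        fs = pair_features(pairs, small_cohort.scans)
        model = EdgeModel(method="finn", scores=np.ones(10),
                          retained=np.arange(10))
        with pytest.raises(ValueError, match="mismatch"):
            apply_model(model, fs)

    def test_no_leakage_shuffled_test_labels_drop_to_chance(self):
        spec = default_spec(n_subjects=24, n_nodes=30, seed=5)
        cohort = generate_cohort(spec)
        pairs = build_pairs(cohort.scans, ["V1_pre_post"])
        fs = pair_features(pairs, cohort.scans)
        balanced = rebalance(fs, ratio=3)
        train, test = split_train_test(balanced, seed=5)
        model = finn_rank(
            [s for s in cohort.scans
             if s.subject_id in set(train.pairs.loc[train.y, "subject_a"])])
        scores = score_pairs(model, test)
        rng = np.random.default_rng(0)
        chance = []
        for _ in range(50):
            y_shuf = rng.permutation(test.y)
            from connectoprint.identify import auc_mann_whitney
            chance.append(auc_mann_whitney(scores[y_shuf], scores[~y_shuf]))
        assert abs(np.mean(chance) - 0.5) < 0.05
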