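"""Rank AUROC, the sign test, table fitting, ablation and clustering."""

import numpy as np
import pandas as pd
import pytest

from tfdiff.model import (FeatureTable, ablate, cluster_importance_profiles,
                          fit_global, split_train_test, variable_importance)
from tfdiff.stats import auroc, binomial_sign_test, folded_auroc


class TestAuroc:
    def test_perfect_and_constant(self):
        assert auroc([3, 2, 1, 0], [1, 1, 0, 0]) == 1.0
        assert auroc([1, 1, 1, 1], [1, 0, 1, 0]) == 0.5

    def test_pairwise_oracle_on_random_instances(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 50))
            scores = rng.integers(0, 6, n).astype(float)  # many ties
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                labels[0] = 1 - labels[0]
            wins = ties = 0
            for s1 in scores[labels == 1]:
                for s2 in scores[labels == 0]:
                    wins += s1 > s2
                    ties += s1 == s2
            ref = (wins + 0.5 * ties) / (labels.sum() * (n - labels.sum()))
            assert auroc(scores, labels) == pytest.approx(ref)

    def test_tie_example(self):
        assert auroc([2, 1, 1, 0], [1, 1, 0, 0]) == pytest.approx(0.875)

    def test_folded(self):
        assert folded_auroc([0, 1, 2, 3], [1, 1, 0, 0]) == 1.0

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            auroc([1, 2], [1, 1])


class TestBinomialSignTest:
    def test_balanced_is_one(self):
        assert binomial_sign_test(10, 20) == 1.0

    def test_cofactor_expression_statistics(self):
        # 149 of 194 co-factors more expressed in the associated cell type
        p = binomial_sign_test(149, 194)
        assert 2.5e-14 <= p < 3.5e-14
        # 79 of 83 expressed/silent asymmetry
        assert binomial_sign_test(79, 83) < 2e-16

    def test_invalid(self):
        with pytest.raises(ValueError):
            binomial_sign_test(5, 0)


class TestSplit:
    def test_stratified_70_30(self):
        labels = np.r_[np.ones(1000), np.zeros(1000)]
        tr = split_train_test(labels, 0.70, seed=1)
        assert tr.sum() == 1400
        assert tr[labels == 1].sum() == 700

    def test_reproducible(self):
        labels = np.r_[np.ones(40), np.zeros(40)]
        assert (split_train_test(labels, seed=5) ==
                split_train_test(labels, seed=5)).all()

    def test_tiny_class_errors(self):
        with pytest.raises(ValueError):
            split_train_test(np.array([1, 0]), 0.7, 0)


def make_table(rng, n=300, p=8, signal_col=0, beta=2.5):
    X = rng.normal(size=(n, p))
    labels = (beta * X[:, signal_col] + rng.logistic(size=n) > 0).astype(int)
    groups = ["DM"] + ["NE"] * ((p - 1) // 2) + ["CF"] * (p - 1 - (p - 1) // 2)
    meta = pd.DataFrame({
        "name": [f"f{i}" for i in range(p)],
        "group": groups[:p],
        "identity": [f"f{i}" for i in range(p)],
        "region_start": 0, "region_end": 1,
    })
    values = pd.DataFrame(X, columns=meta["name"])
    split = split_train_test(labels, 0.7, seed=0)
    return FeatureTable(values, labels, split, meta)


class TestGlobalFit:
    def test_single_signal_feature_selected(self, rng):
        table = make_table(rng, beta=4.0)
        fit = fit_global(table, seed=0)
        assert fit.coef[0] > 0
        te = ~table.train
        assert auroc(fit.linear_scores(table.values)[te], table.labels[te]) > 0.85

    def test_all_noise_near_chance_and_sparse(self, rng):
        aurocs, frac_selected = [], []
        for rep in range(10):
            r = np.random.default_rng(rep)
            X = r.normal(size=(200, 10))
            labels = np.r_[np.ones(100), np.zeros(100)].astype(int)
            meta = pd.DataFrame({"name": [f"f{i}" for i in range(10)],
                                 "group": ["NE"] * 10,
                                 "identity": [f"f{i}" for i in range(10)],
                                 "region_start": 0, "region_end": 1})
            table = FeatureTable(pd.DataFrame(X, columns=meta["name"]),
                                 labels, split_train_test(labels, 0.7, rep), meta)
            fit = fit_global(table, seed=rep)
            te = ~table.train
            aurocs.append(auroc(fit.linear_scores(table.values)[te],
                                table.labels[te]))
            frac_selected.append(fit.nonzero / 10)
        assert abs(np.mean(aurocs) - 0.5) < 0.06
        assert np.mean(frac_selected) < 0.1

    def test_constant_column_dropped_with_warning(self, rng):
        table = make_table(rng)
        table.values["f3"] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            fit = fit_global(table, seed=0)
        assert fit.coef[3] == 0


class TestAblate:
    def test_zero_group_unchanged_exactly(self, rng):
        table = make_table(rng, beta=4.0)
        fit = fit_global(table, seed=0)
        zero_groups = [g for g in ("DM", "NE", "CF")
                       if (fit.coef[fit.groups == g] == 0).all()]
        te = ~table.train
        full = auroc(fit.linear_scores(table.values)[te], table.labels[te])
        for g in zero_groups:
            assert ablate(fit, table, g) == full

    def test_ablating_everything_is_chance(self, rng):
        table = make_table(rng)
        fit = fit_global(table, seed=0)
        coef = fit.coef.copy()
        fit.coef[:] = 0
        te = ~table.train
        assert auroc(fit.linear_scores(table.values)[te], table.labels[te]) == 0.5
        fit.coef[:] = coef

    def test_unknown_group(self, rng):
        table = make_table(rng)
        fit = fit_global(table, seed=0)
        with pytest.raises(ValueError):
            ablate(fit, table, "XX")


class TestImportance:
    def test_dominant_variable_ranks_first(self, rng):
        table = make_table(rng, beta=4.0)
        fit = fit_global(table, seed=0)
        imp = variable_importance(fit, table, n_keep=5)
        assert imp.iloc[0]["name"] == "f0"
        assert imp.iloc[0]["delta_auroc"] > 0.1
        assert imp.iloc[0]["associated_class"] == 1

    def test_duplicated_column_importance_understated(self, rng):
        # perfectly correlated twins: zeroing one barely moves the test
        # AUROC (the other compensates), while removing both loses the
        # signal — the correlation caveat of per-variable importances
        table = make_table(rng, beta=4.0)
        table.values["f7"] = table.values["f0"]
        fit = fit_global(table, seed=0)
        te = ~table.train
        full = auroc(fit.linear_scores(table.values)[te], table.labels[te])
        one = fit.coef.copy()
        one[7] = 0.0
        a_one = auroc(fit.linear_scores(table.values, one)[te], table.labels[te])
        both = fit.coef.copy()
        both[[0, 7]] = 0.0
        a_both = auroc(fit.linear_scores(table.values, both)[te], table.labels[te])
        assert abs(full - a_one) < 0.05
        assert full - a_both > 0.15


class TestClustering:
    def test_well_separated_centroids_recovered(self):
        from tfdiff.synth import importance_profile_fixtures

        profiles, truth = importance_profile_fixtures(k=3, n=60, noise=0.005,
                                                      seed=3)
        labels, centroids, elbow = cluster_importance_profiles(profiles, k=3,
                                                               seed=0)
        from sklearn.metrics import adjusted_rand_score
        assert adjusted_rand_score(truth, labels) == 1.0
        assert elbow[0][1] >= elbow[-1][1]

    def test_identical_profiles_coincide(self):
        profiles = np.tile([0.1, 0.2, 0.3], (9, 1))
        labels, centroids, _ = cluster_importance_profiles(profiles, k=3, seed=0)
        assert np.allclose(centroids, [0.1, 0.2, 0.3])

    def test_order_invariance(self):
        from tfdiff.synth import importance_profile_fixtures
        from sklearn.metrics import adjusted_rand_score

        profiles, _ = importance_profile_fixtures(k=3, n=30, noise=0.01, seed=1)
        l1, _, _ = cluster_importance_profiles(profiles, k=3, seed=0)
        perm = np.random.default_rng(0).permutation(len(profiles))
        l2, _, _ = cluster_importance_profiles(profiles[perm], k=3, seed=0)
        assert adjusted_rand_score(l1, l2[np.argsort(perm)]) == 1.0

    def test_too_few_profiles(self):
        with pytest.raises(ValueError):
            cluster_importance_profiles(np.zeros((2, 3)), k=3)
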