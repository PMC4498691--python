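"""ROC-AUC, cross-validation protocol, feature t-tests and the AUC ANOVA."""

import numpy as np
import pytest
from scipy import stats

from ehgemd.entropy_features import FeatureMatrix
from ehgemd.evaluation import (
    LearnerSpec,
    auc_anova,
    cross_validate,
    feature_ttests,
    roc_auc,
    summarize_auc,
)
from ehgemd.imbalance import SmoteConfig

# Published AUC table: rows SVM, RF, MLP, AB, BN, SLR; columns EMD / non-EMD
AUC_TABLE = np.array([
    [0.847, 0.540],
    [0.957, 0.914],
    [0.764, 0.627],
    [0.986, 0.913],
    [0.912, 0.842],
    [0.874, 0.503],
])


def exhaustive_auc(scores, labels):
    """Brute-force pair-count oracle: wins + half-ties over all pos-neg pairs."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_ties_give_half(self):
        assert roc_auc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_four_point_example(self):
        # exhaustive pair count: pairs (0.35,0.1)+, (0.35,0.4)-, (0.8,0.1)+,
        # (0.8,0.4)+ -> 3/4
        scores, labels = [0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]
        assert roc_auc(scores, labels) == 0.75
        assert exhaustive_auc(scores, labels) == 0.75

    def test_matches_exhaustive_pair_count_on_random_instances(self):
        rng = np.random.default_rng(0)
        for trial in range(20):
            n1, n0 = rng.integers(2, 51, size=2)
            scores = np.round(rng.normal(size=n1 + n0), 1)  # force ties
            labels = np.array([1] * n1 + [0] * n0)
            perm = rng.permutation(n1 + n0)
            scores, labels = scores[perm], labels[perm]
            assert roc_auc(scores, labels) == pytest.approx(
                exhaustive_auc(scores, labels), abs=1e-12
            )

    def test_complement_under_score_negation(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=30)  # continuous, tie-free
        labels = rng.integers(0, 2, size=30)
        labels[:2] = [0, 1]
        assert roc_auc(scores, labels) + roc_auc(-scores, labels) == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])


def toy_matrix(n_per_class=20, separation=3.0, seed=0, n_features=6):
    rng = np.random.default_rng(seed)
    data = np.vstack([
        rng.normal(0, 1, (n_per_class, n_features)),
        rng.normal(separation, 1, (n_per_class, n_features)),
    ])
    labels = ["term"] * n_per_class + ["preterm"] * n_per_class
    return FeatureMatrix(
        data=data, labels=labels,
        feature_names=[f"f{i}" for i in range(n_features)],
        record_ids=[f"r{i}" for i in range(2 * n_per_class)],
    )


class TestCrossValidate:
    def test_separable_data_scores_high(self):
        fm = toy_matrix(separation=4.0)
        res = cross_validate(fm, LearnerSpec("simple-logistic"), folds=10, seed=0)
        assert res.pooled_auc > 0.9
        assert len(res.fold_aucs) == 10

    def test_seeded_determinism(self):
        fm = toy_matrix()
        a = cross_validate(fm, LearnerSpec("random-forest", seed=1), folds=5, seed=3)
        b = cross_validate(fm, LearnerSpec("random-forest", seed=1), folds=5, seed=3)
        assert a.fold_aucs == b.fold_aucs
        for ia, ib in zip(a.test_indices, b.test_indices):
            np.testing.assert_array_equal(ia, ib)

    def test_fold_safe_never_tests_on_synthetic_rows(self):
        fm = toy_matrix(n_per_class=15)
        # imbalance it: drop 10 preterm rows
        keep = list(range(15)) + list(range(15, 20))
        fm2 = FeatureMatrix(
            data=fm.data[keep], labels=[fm.labels[i] for i in keep],
            feature_names=fm.feature_names,
            record_ids=[fm.record_ids[i] for i in keep],
        )
        res = cross_validate(fm2, LearnerSpec("bayes-net"), folds=5, seed=0,
                             leakage_mode="fold-safe")
        for idx in res.test_indices:
            assert all(fm2.origin[i] == "original" for i in idx)

    def test_paper_mode_balances_before_split(self):
        fm = toy_matrix(n_per_class=15)
        keep = list(range(15)) + list(range(15, 20))
        fm2 = FeatureMatrix(
            data=fm.data[keep], labels=[fm.labels[i] for i in keep],
            feature_names=fm.feature_names,
            record_ids=[fm.record_ids[i] for i in keep],
        )
        res = cross_validate(fm2, LearnerSpec("bayes-net"), folds=5, seed=0,
                             leakage_mode="paper", smote=SmoteConfig(seed=0))
        # all 30 balanced rows (15+15) get tested exactly once
        assert sum(len(i) for i in res.test_indices) == 30

    def test_too_many_folds_rejected(self):
        with pytest.raises(ValueError, match="fold count"):
            cross_validate(toy_matrix(n_per_class=5), LearnerSpec(), folds=10)


class TestFeatureTTests:
    def test_identical_groups_give_p_one(self):
        rng = np.random.default_rng(2)
        block = rng.normal(size=(5, 180))
        fm = FeatureMatrix(
            data=np.vstack([block, block]),
            labels=["term"] * 5 + ["preterm"] * 5,
            feature_names=[f"x{i}" for i in range(180)],
            record_ids=[f"r{i}" for i in range(10)],
        )
        pm_a, pm_f = feature_ttests(fm)
        off = ~np.eye(10, dtype=bool)
        assert np.allclose(pm_a.values[off], 1.0)
        assert pm_a.n_defined == 90 and pm_f.n_defined == 90

    def test_matches_pooled_variance_closed_form(self):
        # hand evaluation of the pooled-variance t for {1..5} vs {3..7}
        g0, g1 = np.arange(1.0, 6.0), np.arange(3.0, 8.0)
        sp2 = (4 * g0.var(ddof=1) + 4 * g1.var(ddof=1)) / 8
        t_expected = (g0.mean() - g1.mean()) / np.sqrt(sp2 * (1 / 5 + 1 / 5))
        p_expected = 2 * stats.t.sf(abs(t_expected), df=8)

        rng = np.random.default_rng(3)
        data = rng.normal(size=(10, 180))
        data[:5, 0], data[5:, 0] = g0, g1  # column 0 is feature A_1_2
        fm = FeatureMatrix(
            data=data, labels=["term"] * 5 + ["preterm"] * 5,
            feature_names=[f"x{i}" for i in range(180)],
            record_ids=[f"r{i}" for i in range(10)],
        )
        pm_a, _ = feature_ttests(fm)
        assert pm_a.values[0, 1] == pytest.approx(p_expected, rel=1e-10)

    def test_synthetic_rows_excluded(self):
        rng = np.random.default_rng(4)
        data = rng.normal(size=(12, 180))
        fm = FeatureMatrix(
            data=data,
            labels=["term"] * 5 + ["preterm"] * 5 + ["preterm"] * 2,
            feature_names=[f"x{i}" for i in range(180)],
            record_ids=[f"r{i}" for i in range(12)],
            origin=["original"] * 10 + ["synthetic"] * 2,
        )
        pm_with, _ = feature_ttests(fm)
        fm_orig = FeatureMatrix(
            data=data[:10], labels=fm.labels[:10],
            feature_names=fm.feature_names, record_ids=fm.record_ids[:10],
        )
        pm_only, _ = feature_ttests(fm_orig)
        np.testing.assert_allclose(
            pm_with.values, pm_only.values, rtol=1e-12, equal_nan=True
        )


class TestAucAnova:
    def test_published_auc_table_decomposition(self):
        table = auc_anova(AUC_TABLE)
        assert table.ss_method == pytest.approx(0.0835, abs=5e-5)
        assert table.f_method == pytest.approx(8.72, abs=5e-3)
        assert table.ss_classifier == pytest.approx(0.16215, abs=5e-6)
        assert table.f_classifier == pytest.approx(3.39, abs=5e-3)
        assert table.p_method == pytest.approx(0.0318, abs=5e-5)
        assert table.p_classifier == pytest.approx(0.1033, abs=5e-5)
        assert (table.df_method, table.df_classifier, table.df_error) == (1, 5, 5)

    def test_identical_columns_give_zero_method_effect(self):
        col = AUC_TABLE[:, :1]
        table = auc_anova(np.hstack([col, col]))
        assert table.ss_method == pytest.approx(0.0, abs=1e-15)
        assert table.f_method == pytest.approx(0.0, abs=1e-12)

    def test_ss_decomposition_is_exact_on_random_tables(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            A = rng.uniform(0.4, 1.0, size=(6, 2))
            table = auc_anova(A)
            # brute-force total-variance oracle
            ss_total = float(((A - A.mean()) ** 2).sum())
            assert table.ss_total == pytest.approx(ss_total, rel=1e-12)
            assert (
                table.ss_method + table.ss_classifier + table.ss_error
                == pytest.approx(ss_total, rel=1e-9)
            )

    def test_agrees_with_statsmodels_ols_anova(self):
        # independent route: OLS main-effects fit + anova_lm
        import pandas as pd
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        df = pd.DataFrame({
            "auc": AUC_TABLE.ravel(),
            "method": ["emd", "non_emd"] * 6,
            "clf": np.repeat([f"c{i}" for i in range(6)], 2),
        })
        fit = ols("auc ~ C(method) + C(clf)", data=df).fit()
        aov = sm.stats.anova_lm(fit, typ=2)
        table = auc_anova(AUC_TABLE)
        assert table.ss_method == pytest.approx(aov.loc["C(method)", "sum_sq"], rel=1e-9)
        assert table.ss_classifier == pytest.approx(aov.loc["C(clf)", "sum_sq"], rel=1e-9)
        assert table.f_method == pytest.approx(aov.loc["C(method)", "F"], rel=1e-9)
        assert table.p_method == pytest.approx(aov.loc["C(method)", "PR(>F)"], rel=1e-9)

    def test_incomplete_table_rejected(self):
        A = AUC_TABLE.copy()
        A[0, 0] = np.nan
        with pytest.raises(ValueError, match="complete"):
            auc_anova(A)


class TestSummarizeAuc:
    def test_published_emd_column(self):
        mean, mx = summarize_auc(AUC_TABLE[:, 0])
        assert round(mean, 2) == 0.89
        assert mx == 0.986

    def test_published_non_emd_column(self):
        mean, mx = summarize_auc(AUC_TABLE[:, 1])
        assert round(mean, 3) == 0.723
        assert mx == 0.914

    def test_singleton(self):
        assert summarize_auc([0.7]) == (0.7, 0.7)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_auc([])
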