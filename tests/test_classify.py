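"""Splitting, normalization, reduction, training, evaluation and fusion."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from epicon.classify import (ConfusionMatrix, CorrelationPruner, _scores,
                             accuracy, anova_kbest, confusion_counts,
                             correlation_prune, evaluate, fuse_with_clinician,
                             normalize, pca_reduce, sensitivity, specificity,
                             split_train_test, subgroup_tasks, train_model)

SMALL_GRID = {"clf__C": [1.0], "clf__kernel": ["linear"],
              "reduce__n_components": [5]}


def _toy_data(rng, n=100, n_feat=20, informative=0, shift=3.0):
    X = rng.standard_normal((n, n_feat))
    y = np.r_[np.zeros(n // 2), np.ones(n // 2)].astype(int)
    for j in range(informative):
        X[y == 1, j] += shift
    return X, y


# ---------------------------------------------------------------------------
# splitting

def test_split_stratified_exact():
    rng = np.random.default_rng(0)
    X, y = _toy_data(rng)
    tr, te = split_train_test(X, y, seed=1)
    assert tr.size == 80 and te.size == 20
    assert np.sum(y[tr] == 1) == 40 and np.sum(y[te] == 1) == 10


def test_split_deterministic_and_disjoint():
    rng = np.random.default_rng(0)
    X, y = _toy_data(rng)
    a = split_train_test(X, y, seed=5)
    b = split_train_test(X, y, seed=5)
    np.testing.assert_array_equal(a[0], b[0])
    for seed in range(500):
        tr, te = split_train_test(X, y, seed=seed)
        assert np.intersect1d(tr, te).size == 0
        assert np.union1d(tr, te).size == 100


def test_split_requires_both_classes():
    with pytest.raises(ValueError, match="both classes"):
        split_train_test(np.zeros((20, 3)), np.zeros(20))


# ---------------------------------------------------------------------------
# normalization

def test_normalize_hand_zscore():
    train = np.array([[2.0], [4.0], [6.0]])
    test = np.array([[4.0]])
    tr, te, kept = normalize(train, test)
    np.testing.assert_allclose(tr[:, 0], [-1.2247, 0.0, 1.2247], atol=1e-4)
    assert te[0, 0] == pytest.approx(0.0)  # test value equal to train mean
    assert kept.tolist() == [0]


def test_normalize_drops_constant_feature():
    train = np.column_stack([np.arange(5.0), np.full(5, 3.0)])
    test = np.column_stack([np.arange(2.0), np.full(2, 3.0)])
    tr, te, kept = normalize(train, test)
    assert kept.tolist() == [0]
    assert tr.shape == (5, 1) and te.shape == (2, 1)


# ---------------------------------------------------------------------------
# ANOVA K-best

def test_anova_identity_when_k_all(rng):
    X, y = _toy_data(rng, n=40, n_feat=6)
    assert anova_kbest(X, y, 6).tolist() == list(range(6))


def test_anova_textbook_f_oracle():
    """F values match the two-group one-way ANOVA formula on a toy table."""
    X = np.array([[1.0], [2.0], [3.0], [6.0], [7.0], [8.0]])
    y = np.array([0, 0, 0, 1, 1, 1])
    g0, g1 = X[y == 0, 0], X[y == 1, 0]
    grand = X[:, 0].mean()
    ss_between = 3 * ((g0.mean() - grand) ** 2 + (g1.mean() - grand) ** 2)
    ss_within = ((g0 - g0.mean()) ** 2).sum() + ((g1 - g1.mean()) ** 2).sum()
    f_manual = (ss_between / 1) / (ss_within / 4)
    from sklearn.feature_selection import f_classif
    F, _ = f_classif(X, y)
    assert F[0] == pytest.approx(f_manual)
    assert anova_kbest(X, y, 1).tolist() == [0]


def test_anova_separated_feature_ranked_first():
    hits = 0
    for seed in range(20):
        rng = np.random.default_rng(seed)
        X, y = _toy_data(rng, n=60, n_feat=30, informative=1, shift=3.0)
        hits += anova_kbest(X, y, 1)[0] == 0
    assert hits == 20


# ---------------------------------------------------------------------------
# PCA

def test_pca_exact_low_rank_roundtrip(rng):
    basis = rng.standard_normal((2, 10))
    coeffs = rng.standard_normal((30, 2))
    X = coeffs @ basis
    tr, te, comps = pca_reduce(X, X, 2)
    recon = tr @ comps + X.mean(axis=0)
    np.testing.assert_allclose(recon, X, atol=1e-8)


def test_pca_component_variances_non_increasing(rng):
    X = rng.standard_normal((40, 8)) * np.arange(1, 9)
    tr, _, _ = pca_reduce(X, X, 8)
    variances = tr.var(axis=0)
    assert np.all(np.diff(variances) <= 1e-9)


def test_pca_full_rank_roundtrip_identity(rng):
    X = rng.standard_normal((30, 6))
    tr, _, comps = pca_reduce(X, X, 6)
    recon = tr @ comps + X.mean(axis=0)
    np.testing.assert_allclose(recon, X, atol=1e-8)


# ---------------------------------------------------------------------------
# correlation pruning

def test_corr_prune_duplicate_column(rng):
    x = rng.standard_normal(50)
    X = np.column_stack([x, rng.standard_normal(50), x])
    kept = correlation_prune(X, 0.92)
    assert kept.tolist() == [0, 1]  # duplicate (index 2) removed


def test_corr_prune_orthogonal_kept(rng):
    X = rng.standard_normal((200, 6))
    assert correlation_prune(X, 0.92).size == 6


def test_corr_prune_boundary_strict():
    """|r| exactly at the threshold keeps both features."""
    x = np.array([1.0, 2.0, 3.0, 4.0])
    y = x.copy()
    X = np.column_stack([x, y])
    r = abs(np.corrcoef(X.T)[0, 1])
    kept = correlation_prune(X, threshold=r)  # threshold == correlation
    assert kept.tolist() == [0, 1]


def test_corr_pruner_transformer(rng):
    x = rng.standard_normal(50)
    X = np.column_stack([x, x, rng.standard_normal(50)])
    pruner = CorrelationPruner(0.92).fit(X)
    assert pruner.transform(X).shape == (50, 2)


# ---------------------------------------------------------------------------
# training

def test_train_separable_perfect_cv():
    rng = np.random.default_rng(3)
    X, y = _toy_data(rng, n=60, n_feat=10, informative=3, shift=6.0)
    model, report = train_model(X, y, "svm", "pca", grid=SMALL_GRID, seed=0)
    assert all(a == 1.0 for a in report.fold_auc)


def test_train_deterministic_hyperparameters():
    rng = np.random.default_rng(4)
    X, y = _toy_data(rng, n=60, n_feat=10, informative=2)
    grid = {"clf__C": [0.1, 1.0, 10.0], "clf__kernel": ["linear", "rbf"],
            "reduce__n_components": [3, 5]}
    _, r1 = train_model(X, y, "svm", "pca", grid=grid, seed=7)
    _, r2 = train_model(X, y, "svm", "pca", grid=grid, seed=7)
    assert r1.best_params == r2.best_params
    assert r1.fold_auc == r2.fold_auc


def test_train_rejects_single_class_fold():
    X = np.random.default_rng(0).standard_normal((12, 4))
    y = np.r_[np.zeros(10), np.ones(2)].astype(int)
    with pytest.raises(ValueError, match="stratification"):
        train_model(X, y, "svm", "none", grid={"clf__C": [1.0]}, seed=0)


def test_permuted_labels_fall_inside_surrogate_band():
    rng = np.random.default_rng(5)
    X, y = _toy_data(rng, n=100, n_feat=15, informative=3, shift=4.0)
    y_perm = rng.permutation(y)
    tr, te = split_train_test(X, y_perm, seed=0)
    model, _ = train_model(X[tr], y_perm[tr], "svm", "pca",
                           grid=SMALL_GRID, seed=0)
    report = evaluate(model, X[te], y_perm[te], seed=0)
    assert report.auc <= report.surrogate_auc_p95


def test_no_test_leakage():
    """Test-set labels never influence the fitted model's scores."""
    rng = np.random.default_rng(6)
    X, y = _toy_data(rng, n=80, n_feat=12, informative=2)
    tr, te = split_train_test(X, y, seed=1)
    model, _ = train_model(X[tr], y[tr], "svm", "pca", grid=SMALL_GRID, seed=1)
    s1 = _scores(model, X[te])
    _ = evaluate(model, X[te], rng.permutation(y[te]) | 0, seed=1)
    s2 = _scores(model, X[te])
    np.testing.assert_array_equal(s1, s2)


@pytest.mark.parametrize("model_kind,reduction", [
    ("logreg", "anova"), ("rfc", "none"), ("mlp", "corr+anova"),
])
def test_all_model_reduction_combinations_run(model_kind, reduction):
    rng = np.random.default_rng(8)
    X, y = _toy_data(rng, n=50, n_feat=12, informative=2, shift=4.0)
    grid = {"reduce__anova__k": [5]} if reduction == "corr+anova" else (
        {"reduce__k": [5]} if reduction == "anova" else {})
    model, report = train_model(X, y, model_kind, reduction, grid=grid, seed=0)
    assert report.mean_val_auc > 0.7


# ---------------------------------------------------------------------------
# evaluation metrics

def test_metrics_hand_confusion():
    c = ConfusionMatrix(TP=3, TN=2, FP=1, FN=2)
    assert accuracy(c) == pytest.approx(0.625)
    assert sensitivity(c) == pytest.approx(0.6)
    assert specificity(c) == pytest.approx(2 / 3)


def test_evaluate_perfect_scores():
    class Fake:
        def decision_function(self, X):
            return X[:, 0]
    y = np.array([0, 0, 1, 1, 0, 1])
    X = y[:, None].astype(float)
    report = evaluate(Fake(), X, y, seed=0)
    assert report.auc == 1.0
    assert report.confusion.FP == 0 and report.confusion.FN == 0


def test_evaluate_requires_two_classes():
    class Fake:
        def decision_function(self, X):
            return X[:, 0]
    with pytest.raises(ValueError, match="both classes"):
        evaluate(Fake(), np.zeros((4, 1)), np.zeros(4), seed=0)


def test_null_scores_calibration():
    """Random scores land inside the surrogate band in >= 90% of repetitions."""
    class Fake:
        def __init__(self, rng):
            self.rng = rng
        def decision_function(self, X):
            return self.rng.standard_normal(len(X))
    rng = np.random.default_rng(9)
    y = np.r_[np.zeros(50), np.ones(50)].astype(int)
    X = np.zeros((100, 1))
    inside = sum(
        evaluate(Fake(rng), X, y, seed=k).inside_surrogate_band
        for k in range(100))
    assert inside >= 90


# ---------------------------------------------------------------------------
# clinician fusion

def test_fusion_truth_table():
    out_and = fuse_with_clinician([1], [0], [1], "AND")
    out_or = fuse_with_clinician([1], [0], [1], "OR")
    assert out_and["prediction"] == [0]
    assert out_or["prediction"] == [1]


def test_fusion_identical_inputs_idempotent(rng):
    pred = rng.integers(0, 2, 30)
    y = rng.integers(0, 2, 30)
    for op in ("AND", "OR"):
        fused = fuse_with_clinician(pred, pred, y, op)
        base = confusion_counts(y, pred)
        assert fused["accuracy"] == pytest.approx(accuracy(base))


def test_fusion_monotonicity_exhaustive():
    """Over all 2x2x2 prediction patterns: OR boosts sensitivity, AND
    boosts specificity, relative to both inputs."""
    for bits in itertools.product([0, 1], repeat=6):
        y = np.array([0, 1])
        model = np.array(bits[0:2])
        clin = np.array(bits[2:4])
        sens = lambda p: sensitivity(confusion_counts(y, p))
        spec = lambda p: specificity(confusion_counts(y, p))
        fused_or = np.array(fuse_with_clinician(model, clin, y, "OR")["prediction"])
        fused_and = np.array(fuse_with_clinician(model, clin, y, "AND")["prediction"])
        assert sens(fused_or) >= max(sens(model), sens(clin))
        assert spec(fused_and) >= max(spec(model), spec(clin))


# ---------------------------------------------------------------------------
# subgroup tasks

def test_subgroup_tasks_partition_and_skip():
    rng = np.random.default_rng(10)
    n = 80
    X, y = _toy_data(rng, n=n, n_feat=10, informative=2, shift=4.0)
    order = rng.permutation(n)
    X, y = X[order], y[order]
    meta = pd.DataFrame({
        "sex": ["M"] * n,  # all male: female task must be skipped
        "age": rng.uniform(20, 80, n),
    })
    out = subgroup_tasks(X, y, meta, seed=0, grid={"reduce__k": [5],
                                                   "clf__C": [1.0]})
    assert out["female"]["skipped"] is True
    assert out["male"]["skipped"] is False
    young = (meta["age"] < 50).sum()
    old = (meta["age"] >= 50).sum()
    assert young + old == n


def test_subgroup_age_boundary_rule():
    rng = np.random.default_rng(11)
    n = 60
    X, y = _toy_data(rng, n=n, n_feat=8, informative=2, shift=4.0)
    meta = pd.DataFrame({"sex": ["M"] * n, "age": [50.0] * n})
    out = subgroup_tasks(X, y, meta, seed=0, grid={"reduce__k": [4],
                                                   "clf__C": [1.0]})
    assert out["age<50"]["skipped"] is True     # nobody below the cut
    assert out["age>=50"]["skipped"] is False   # exactly 50 counts as older
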