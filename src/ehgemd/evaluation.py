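"""Cross-validated classification, feature t-tests and the AUC ANOVA.

Discrimination of term vs preterm records is scored with ROC-AUC under
stratified 10-fold cross-validation, for six representative classifier
families (polynomial-kernel SVM, random forest, multilayer perceptron,
AdaBoost on decision trees, naive-Bayes network stand-in, and logistic
regression).  The classifiers are pluggable adapters over scikit-learn; the
scientific claim under test concerns the features, not classifier internals.

Two cross-validation protocols are provided, because SMOTE placement
matters.  ``leakage_mode="paper"`` balances the full cohort with SMOTE
*before* splitting (262/262 then 10 folds), which lets interpolated copies
of a test record appear in training folds and inflates AUC.
``"fold-safe"`` (the default) splits the original records first and applies
SMOTE inside each training fold only, so no synthetic row ever reaches a
test fold.

Per-feature screening uses two-sided two-sample Student t-tests (pooled
variance) on the original rows only, arranged as 10x10 p-value matrices
over IMF index pairs.  Feature-set and classifier effects on an AUC table
are compared with a two-way main-effects ANOVA without replication
(method df 1, classifier df 5, error df 5).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .entropy_features import FeatureMatrix, N_IMF_COMPONENTS, pair_order
from .imbalance import SmoteConfig, balance_dataset

__all__ = [
    "LearnerSpec",
    "CVResult",
    "AnovaTable",
    "PMatrix",
    "LEARNER_NAMES",
    "roc_auc",
    "cross_validate",
    "feature_ttests",
    "auc_anova",
    "summarize_auc",
]

LEARNER_NAMES = (
    "svm-poly",
    "random-forest",
    "mlp",
    "adaboost-tree",
    "bayes-net",
    "simple-logistic",
)

POSITIVE_LABEL = "preterm"


@dataclass(frozen=True)
class LearnerSpec:
    """A named classifier with hyperparameter overrides and a seed."""

    name: str = "adaboost-tree"
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in LEARNER_NAMES:
            raise ValueError(f"unknown learner {self.name!r}; choose from {LEARNER_NAMES}")

    def build(self):
        hp = dict(self.hyperparameters)
        if self.name == "svm-poly":
            return SVC(kernel="poly", degree=hp.pop("degree", 1),
                       C=hp.pop("C", 1.0), random_state=self.seed, **hp)
        if self.name == "random-forest":
            return RandomForestClassifier(
                n_estimators=hp.pop("n_estimators", 100), random_state=self.seed, **hp)
        if self.name == "mlp":
            return MLPClassifier(
                hidden_layer_sizes=hp.pop("hidden_layer_sizes", (20,)),
                max_iter=hp.pop("max_iter", 600), random_state=self.seed, **hp)
        if self.name == "adaboost-tree":
            return AdaBoostClassifier(
                estimator=DecisionTreeClassifier(max_depth=hp.pop("max_depth", 1)),
                n_estimators=hp.pop("n_estimators", 50), random_state=self.seed, **hp)
        if self.name == "bayes-net":
            return GaussianNB(**hp)
        return LogisticRegression(max_iter=hp.pop("max_iter", 2000), **hp)

    @property
    def needs_scaling(self) -> bool:
        # margin/gradient-based learners are scale-sensitive; trees are not
        return self.name in ("svm-poly", "mlp", "simple-logistic")


def _scores(model, X: np.ndarray) -> np.ndarray:
    """Continuous decision scores, larger = more preterm-like."""
    if hasattr(model, "predict_proba"):
        proba = model.predict_proba(X)
        pos = list(model.classes_).index(POSITIVE_LABEL)
        return proba[:, pos]
    s = model.decision_function(X)
    if list(model.classes_)[1] != POSITIVE_LABEL:
        s = -s
    return s


def roc_auc(scores: Sequence[float], labels: Sequence) -> float:
    """Rank (Mann-Whitney) AUC: P(score_pos > score_neg) + 0.5 P(tie)."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray([1 if lab in (1, "1", POSITIVE_LABEL, True) else 0 for lab in labels])
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc needs both classes present")
    ranks = stats.rankdata(scores)  # midranks handle ties
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


@dataclass
class CVResult:
    fold_aucs: list[float]
    pooled_auc: float
    test_indices: list[np.ndarray]
    learner: str
    seed: int
    leakage_mode: str


def cross_validate(
    matrix: FeatureMatrix,
    learner: LearnerSpec,
    folds: int = 10,
    seed: int = 0,
    leakage_mode: Literal["paper", "fold-safe"] = "fold-safe",
    smote: Optional[SmoteConfig] = None,
) -> CVResult:
    """Stratified k-fold CV with per-fold and pooled ROC-AUC.

    ``leakage_mode="paper"`` SMOTE-balances the whole matrix before
    splitting; ``"fold-safe"`` balances each training fold only and tests on
    original rows exclusively.  Pooled AUC is computed on the concatenated
    held-out scores.
    """
    if smote is None:
        smote = SmoteConfig(seed=seed)
    counts = matrix.class_counts()
    if len(counts) != 2:
        raise ValueError(f"need exactly 2 classes, got {sorted(counts)}")
    if min(counts.values()) < folds:
        raise ValueError(
            f"fold count {folds} exceeds smallest class size {min(counts.values())}"
        )

    if leakage_mode == "paper":
        work = balance_dataset(matrix, smote)
    elif leakage_mode == "fold-safe":
        work = matrix
    else:
        raise ValueError(f"unknown leakage_mode {leakage_mode!r}")

    X_all = work.data
    y_all = np.asarray(work.labels)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)

    fold_aucs: list[float] = []
    test_idx_list: list[np.ndarray] = []
    pooled_scores: list[np.ndarray] = []
    pooled_labels: list[np.ndarray] = []
    for fold, (train_idx, test_idx) in enumerate(skf.split(X_all, y_all)):
        if leakage_mode == "fold-safe":
            train = FeatureMatrix(
                data=X_all[train_idx],
                labels=[work.labels[i] for i in train_idx],
                feature_names=work.feature_names,
                record_ids=[work.record_ids[i] for i in train_idx],
                origin=[work.origin[i] for i in train_idx],
            )
            fold_smote = SmoteConfig(
                k_neighbors=smote.k_neighbors,
                target_count=smote.target_count,
                seed=(smote.seed * 1000 + fold) % (2**31),
                standardize=smote.standardize,
            )
            train = balance_dataset(train, fold_smote)
            X_tr, y_tr = train.data, np.asarray(train.labels)
        else:
            X_tr, y_tr = X_all[train_idx], y_all[train_idx]
        X_te, y_te = X_all[test_idx], y_all[test_idx]

        if learner.needs_scaling:
            scaler = StandardScaler().fit(X_tr)
            X_tr, X_te = scaler.transform(X_tr), scaler.transform(X_te)
        model = learner.build().fit(X_tr, y_tr)
        s = _scores(model, X_te)
        fold_aucs.append(roc_auc(s, y_te))
        test_idx_list.append(test_idx)
        pooled_scores.append(s)
        pooled_labels.append(y_te)

    pooled = roc_auc(np.concatenate(pooled_scores), np.concatenate(pooled_labels))
    return CVResult(
        fold_aucs=fold_aucs,
        pooled_auc=pooled,
        test_indices=test_idx_list,
        learner=learner.name,
        seed=seed,
        leakage_mode=leakage_mode,
    )


@dataclass
class PMatrix:
    """10x10 p-value table over IMF index pairs; diagonal is NaN-masked."""

    values: np.ndarray  # (10, 10) with NaN on the diagonal / undefined cells
    measure: str        # "amplitude" or "frequency"
    undefined: list[tuple[int, int]] = field(default_factory=list)

    @property
    def n_defined(self) -> int:
        off = ~np.eye(self.values.shape[0], dtype=bool)
        return int(np.isfinite(self.values[off]).sum())

    def n_significant(self, alpha: float = 0.05) -> int:
        off = ~np.eye(self.values.shape[0], dtype=bool)
        vals = self.values[off]
        return int(np.nansum(vals < alpha))


def feature_ttests(matrix: FeatureMatrix) -> tuple[PMatrix, PMatrix]:
    """Student t-tests (pooled variance, two-sided) per entropy-ratio feature.

    Synthetic rows are excluded: group comparisons are only meaningful on
    original records.  Returns the amplitude and frequency p-value matrices.
    A feature with zero variance in both groups and equal means has an
    undefined t; such cells are NaN and reported.
    """
    orig = np.array([o == "original" for o in matrix.origin])
    labels = np.asarray(matrix.labels)[orig]
    X = matrix.data[orig]
    classes = sorted(set(labels))
    if len(classes) != 2:
        raise ValueError("t-tests need exactly two classes among original rows")
    g0, g1 = X[labels == classes[0]], X[labels == classes[1]]
    if len(g0) < 2 or len(g1) < 2:
        raise ValueError("each class needs >= 2 original rows")

    pairs = pair_order()
    n = N_IMF_COMPONENTS
    out = []
    for block, measure in ((0, "amplitude"), (1, "frequency")):
        pm = np.full((n, n), np.nan)
        undef: list[tuple[int, int]] = []
        for k, (i, j) in enumerate(pairs):
            col = block * len(pairs) + k
            with np.errstate(invalid="ignore", divide="ignore"):
                _, p = stats.ttest_ind(g0[:, col], g1[:, col], equal_var=True)
            if np.isnan(p):
                undef.append((i, j))
            else:
                pm[i - 1, j - 1] = float(p)
        out.append(PMatrix(values=pm, measure=measure, undefined=undef))
    return out[0], out[1]


@dataclass
class AnovaTable:
    """Two-way main-effects ANOVA of an AUC table (no interaction term)."""

    ss_method: float
    ss_classifier: float
    ss_error: float
    ss_total: float
    df_method: int
    df_classifier: int
    df_error: int
    df_total: int
    f_method: float
    f_classifier: float
    p_method: float
    p_classifier: float

    @property
    def ms_method(self) -> float:
        return self.ss_method / self.df_method

    @property
    def ms_classifier(self) -> float:
        return self.ss_classifier / self.df_classifier

    @property
    def ms_error(self) -> float:
        return self.ss_error / self.df_error

    def rows(self) -> list[dict]:
        return [
            {"source": "method", "SS": self.ss_method, "df": self.df_method,
             "MS": self.ms_method, "F": self.f_method, "p": self.p_method},
            {"source": "classifier", "SS": self.ss_classifier,
             "df": self.df_classifier, "MS": self.ms_classifier,
             "F": self.f_classifier, "p": self.p_classifier},
            {"source": "error", "SS": self.ss_error, "df": self.df_error,
             "MS": self.ms_error, "F": None, "p": None},
            {"source": "total", "SS": self.ss_total, "df": self.df_total,
             "MS": None, "F": None, "p": None},
        ]


def auc_anova(auc_table: np.ndarray) -> AnovaTable:
    """Two-way ANOVA without replication on a classifiers x methods table.

    Rows are classifiers (blocks), columns are feature-set methods.  The
    standard main-effects decomposition applies:

        SS_method     = r * sum_c (colmean_c - grand)^2
        SS_classifier = c * sum_r (rowmean_r - grand)^2
        SS_error      = SS_total - SS_method - SS_classifier

    with df (c-1), (r-1) and (r-1)(c-1); F = MS_factor / MS_error and p from
    the F distribution.  For the 6x2 AUC table this is df 1 / 5 / 5.
    """
    A = np.asarray(auc_table, dtype=float)
    if A.ndim != 2 or A.shape[0] < 2 or A.shape[1] < 2:
        raise ValueError("auc_anova needs a complete table with >= 2 rows and columns")
    if not np.all(np.isfinite(A)):
        raise ValueError("auc_anova requires a complete table (no missing cells)")
    r, c = A.shape
    grand = A.mean()
    ss_total = float(((A - grand) ** 2).sum())
    ss_method = float(r * ((A.mean(axis=0) - grand) ** 2).sum())
    ss_classifier = float(c * ((A.mean(axis=1) - grand) ** 2).sum())
    ss_error = ss_total - ss_method - ss_classifier
    df_m, df_c = c - 1, r - 1
    df_e = df_m * df_c
    ms_e = ss_error / df_e

    zero_tol = 1e-12 * ss_total  # rounding floor for an exactly-null factor

    def _f(ss: float, df: int) -> float:
        if ms_e > zero_tol:
            return (ss / df) / ms_e
        return 0.0 if ss <= zero_tol else float("inf")  # zero-error table

    f_m = _f(ss_method, df_m)
    f_c = _f(ss_classifier, df_c)
    return AnovaTable(
        ss_method=ss_method, ss_classifier=ss_classifier,
        ss_error=ss_error, ss_total=ss_total,
        df_method=df_m, df_classifier=df_c, df_error=df_e,
        df_total=r * c - 1,
        f_method=f_m, f_classifier=f_c,
        p_method=float(stats.f.sf(f_m, df_m, df_e)),
        p_classifier=float(stats.f.sf(f_c, df_c, df_e)),
    )


def summarize_auc(values: Sequence[float]) -> tuple[float, float]:
    """Arithmetic mean and maximum of a set of AUC values."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("summarize_auc needs at least one value")
    return float(v.mean()), float(v.max())
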