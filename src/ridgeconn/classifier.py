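"""LASSO-selected linear-SVM classification with permutation validation.

Feature selection is L1-penalized logistic regression over a geometric
penalty path, with the penalty chosen by repeated stratified k-fold
cross-validated deviance (``lambda_rule='min'`` takes the minimizer,
``'one_se'`` the sparsest model within one standard error). The classifier
is a linear SVM at fixed C evaluated by repeated stratified k-fold
cross-validation; per training fold the features are min-max scaled to
[0, 1] and the learned parameters applied to the test fold. Performance is
summarized as accuracy / sensitivity / specificity / Cohen's kappa in
percent (mean +/- sd over all repeats x folds) and the area under the ROC
curve of the pooled decision values per repeat. Significance is assessed by
a one-tailed label-permutation test on mean cross-validated accuracy.

Two selection modes are provided. ``'nested'`` redoes the LASSO inside
every training fold (no selection leakage). ``'paper'`` performs selection
once on the full dataset before cross-validation — the common published
shortcut, kept for procedure replication; it leaks the test folds into the
selection and typically inflates accuracy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from ._glm import perm_pvalue

logger = logging.getLogger(__name__)

__all__ = [
    "ClassifierConfig",
    "FoldMetrics",
    "ClassifierReport",
    "lasso_select",
    "minmax_scale",
    "cross_validate_svm",
    "roc_area",
    "permutation_test_accuracy",
    "confusion_metrics",
]


@dataclass(frozen=True)
class ClassifierConfig:
    C: float = 1.0
    n_folds: int = 5
    n_repeats: int = 100
    lasso_repeats: int = 10
    lasso_folds: int = 5
    lasso_path_size: int = 30
    lambda_rule: str = "min"
    selection_mode: str = "nested"
    n_perm: int = 5000
    paper_convention: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.n_folds < 2 or self.lasso_folds < 2:
            raise ValueError("folds must be >= 2")
        if self.n_repeats < 1 or self.lasso_repeats < 1:
            raise ValueError("repeats must be >= 1")
        if self.lambda_rule not in ("min", "one_se"):
            raise ValueError("lambda_rule must be 'min' or 'one_se'")
        if self.selection_mode not in ("paper", "nested"):
            raise ValueError("selection_mode must be 'paper' or 'nested'")


@dataclass(frozen=True)
class FoldMetrics:
    repeat: int
    fold: int
    tp: int
    fn: int
    fp: int
    tn: int
    accuracy: float
    sensitivity: float
    specificity: float
    kappa: float


@dataclass(frozen=True)
class ClassifierReport:
    """Cross-validated performance summary; rates are percentages."""

    selected_features: tuple[str, ...]
    folds: tuple[FoldMetrics, ...]
    accuracy_mean: float
    accuracy_sd: float
    sensitivity_mean: float
    sensitivity_sd: float
    specificity_mean: float
    specificity_sd: float
    kappa_mean: float
    kappa_sd: float
    roc_auc_mean: float
    roc_auc_sd: float
    roc_points: tuple[tuple[float, float], ...] = field(default_factory=tuple)
    p_perm: float | None = None

    def summary(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy_mean,
            "accuracy_sd": self.accuracy_sd,
            "sensitivity": self.sensitivity_mean,
            "sensitivity_sd": self.sensitivity_sd,
            "specificity": self.specificity_mean,
            "specificity_sd": self.specificity_sd,
            "kappa": self.kappa_mean,
            "kappa_sd": self.kappa_sd,
            "roc_auc": self.roc_auc_mean,
            "roc_auc_sd": self.roc_auc_sd,
        }


def _as_binary(labels: np.ndarray, positive_label=None) -> np.ndarray:
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {list(classes)}")
    if positive_label is None:
        # prefer the patient class when labels are strings
        lowered = {str(c).lower(): c for c in classes}
        positive_label = lowered.get("patient", classes[-1])
    return (labels == positive_label).astype(int)


def _lambda_path(X: np.ndarray, y: np.ndarray, size: int) -> np.ndarray:
    n = len(y)
    lam_max = np.max(np.abs(X.T @ (y - y.mean()))) / n
    lam_max = max(lam_max, 1e-6)
    return np.geomspace(lam_max * 1.05, lam_max * 0.01, size)


def _fit_l1(X: np.ndarray, y: np.ndarray, lam: float) -> LogisticRegression:
    # sklearn's objective is sum(loss) + |w|_1 / C; glmnet-style lambda
    # (mean loss + lam * |w|_1) maps to C = 1 / (n * lam)
    model = LogisticRegression(
        l1_ratio=1.0, C=1.0 / (len(y) * lam), solver="liblinear", max_iter=200,
        random_state=0,
    )
    model.fit(X, y)
    return model


def lasso_select(
    features: pd.DataFrame,
    labels: np.ndarray,
    cfg: ClassifierConfig | None = None,
    seed: int | np.random.SeedSequence | None = None,
) -> tuple[str, ...]:
    """Select features by cross-validated L1-penalized logistic regression.

    Features are z-scored internally so the penalty treats them evenly;
    selection is reported as original column names with nonzero
    coefficients at the chosen penalty, refit on the full data.
    """
    cfg = cfg or ClassifierConfig()
    y = _as_binary(labels)
    if min((y == 0).sum(), (y == 1).sum()) < 2:
        raise ValueError("need at least 2 subjects per class")
    X = features.to_numpy(dtype=float)
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd
    path = _lambda_path(Xs, y, cfg.lasso_path_size)

    ss = np.random.SeedSequence(cfg.seed) if seed is None else (
        seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    )
    fold_seeds = ss.generate_state(cfg.lasso_repeats)
    dev = np.zeros((cfg.lasso_repeats * cfg.lasso_folds, len(path)))
    row = 0
    for r in range(cfg.lasso_repeats):
        skf = StratifiedKFold(cfg.lasso_folds, shuffle=True, random_state=int(fold_seeds[r] % 2**31))
        for train, test in skf.split(Xs, y):
            for li, lam in enumerate(path):
                model = _fit_l1(Xs[train], y[train], lam)
                prob = model.predict_proba(Xs[test])[:, 1]
                dev[row, li] = log_loss(y[test], prob, labels=[0, 1])
            row += 1
    mean_dev = dev.mean(axis=0)
    if cfg.lambda_rule == "min":
        choice = int(np.argmin(mean_dev))
    else:
        se = dev.std(axis=0, ddof=1) / np.sqrt(dev.shape[0])
        best = int(np.argmin(mean_dev))
        within = np.flatnonzero(mean_dev <= mean_dev[best] + se[best])
        choice = int(within[0])  # path is decreasing in lambda: first = sparsest
    final = _fit_l1(Xs, y, path[choice])
    nz = np.flatnonzero(np.abs(final.coef_.ravel()) > 1e-10)
    return tuple(features.columns[k] for k in nz)


def minmax_scale(
    train: np.ndarray, apply_to: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray | None]:
    """Scale features to [0, 1] by the training min/max; apply the learned
    parameters to a second block (which may land outside [0, 1]).
    Constant training columns map to 0."""
    train = np.asarray(train, dtype=float)
    if train.size == 0:
        raise ValueError("training block must be nonempty")
    lo = train.min(axis=0)
    span = train.max(axis=0) - lo
    safe = np.where(span == 0, 1.0, span)
    train_s = np.where(span == 0, 0.0, (train - lo) / safe)
    out = None
    if apply_to is not None:
        apply_to = np.asarray(apply_to, dtype=float)
        out = np.where(span == 0, 0.0, (apply_to - lo) / safe)
    return train_s, out


def confusion_metrics(tp: int, fn: int, fp: int, tn: int) -> dict[str, float]:
    """Accuracy, sensitivity, specificity and Cohen's kappa (percent)."""
    total = tp + fn + fp + tn
    acc = (tp + tn) / total
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    p_yes = ((tp + fp) / total) * ((tp + fn) / total)
    p_no = ((fn + tn) / total) * ((fp + tn) / total)
    pe = p_yes + p_no
    kappa = (acc - pe) / (1 - pe) if pe < 1 else 0.0
    return {
        "accuracy": 100 * acc,
        "sensitivity": 100 * sens,
        "specificity": 100 * spec,
        "kappa": 100 * kappa,
    }


def roc_area(decision_values: np.ndarray, labels: np.ndarray) -> float:
    """ROC area as the Mann-Whitney concordance probability (ties 0.5)."""
    y = np.asarray(labels).astype(int)
    scores = np.asarray(decision_values, dtype=float)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    return float(auc)


def _cv_once(
    X: np.ndarray,
    y: np.ndarray,
    features: pd.DataFrame,
    cfg: ClassifierConfig,
    selected_cols: np.ndarray | None,
    repeat: int,
    rng: np.random.Generator,
    collect: list[FoldMetrics] | None,
) -> tuple[float, float]:
    """One repeat of stratified k-fold CV; returns (mean fold accuracy
    fraction, pooled ROC area)."""
    for _ in range(20):
        state = int(rng.integers(2**31))
        skf = StratifiedKFold(cfg.n_folds, shuffle=True, random_state=state)
        splits = list(skf.split(X, y))
        if all(len(np.unique(y[tr])) == 2 for tr, _ in splits):
            break
        logger.info("re-drawing CV split with a single-class fold")
    accs = []
    pooled_scores = np.empty(len(y))
    for fold, (train, test) in enumerate(splits):
        if selected_cols is None:
            names = lasso_select(
                features.iloc[train], y[train], cfg, seed=int(rng.integers(2**31))
            )
            cols = np.array([features.columns.get_loc(nm) for nm in names], dtype=int)
            if len(cols) == 0:
                cols = np.arange(X.shape[1])
        else:
            cols = selected_cols
        Xtr, Xte = minmax_scale(X[np.ix_(train, cols)], X[np.ix_(test, cols)])
        model = SVC(kernel="linear", C=cfg.C)
        model.fit(Xtr, y[train])
        pred = model.predict(Xte)
        pooled_scores[test] = model.decision_function(Xte)
        tp = int(((pred == 1) & (y[test] == 1)).sum())
        fn = int(((pred == 0) & (y[test] == 1)).sum())
        fp = int(((pred == 1) & (y[test] == 0)).sum())
        tn = int(((pred == 0) & (y[test] == 0)).sum())
        m = confusion_metrics(tp, fn, fp, tn)
        accs.append(m["accuracy"] / 100)
        if collect is not None:
            collect.append(FoldMetrics(repeat=repeat, fold=fold, tp=tp, fn=fn,
                                       fp=fp, tn=tn, **m))
    return float(np.mean(accs)), roc_area(pooled_scores, y), pooled_scores


def _roc_points(scores: np.ndarray, y: np.ndarray) -> tuple[tuple[float, float], ...]:
    """(FPR, TPR) points of the empirical ROC curve, threshold descending."""
    order = np.argsort(-scores)
    ys = y[order]
    tpr = np.concatenate([[0.0], np.cumsum(ys == 1) / max((y == 1).sum(), 1)])
    fpr = np.concatenate([[0.0], np.cumsum(ys == 0) / max((y == 0).sum(), 1)])
    return tuple(zip(fpr.tolist(), tpr.tolist()))


def cross_validate_svm(
    features: pd.DataFrame,
    labels: np.ndarray,
    cfg: ClassifierConfig | None = None,
    positive_label=None,
) -> ClassifierReport:
    """Repeated stratified k-fold cross-validation of the linear SVM."""
    cfg = cfg or ClassifierConfig()
    y = _as_binary(labels, positive_label)
    X = features.to_numpy(dtype=float)
    ss = np.random.SeedSequence(cfg.seed)
    ss_sel, ss_cv = ss.spawn(2)

    selected_cols: np.ndarray | None = None
    selected_names: tuple[str, ...] = tuple(features.columns)
    if cfg.selection_mode == "paper":
        selected_names = lasso_select(features, y, cfg, seed=ss_sel)
        if not selected_names:
            logger.warning("LASSO selected no features; using all columns")
            selected_names = tuple(features.columns)
        selected_cols = np.array(
            [features.columns.get_loc(nm) for nm in selected_names], dtype=int
        )

    rng = np.random.default_rng(ss_cv)
    fold_metrics: list[FoldMetrics] = []
    aucs = []
    last_scores = np.zeros(len(y))
    for repeat in range(cfg.n_repeats):
        _, auc, last_scores = _cv_once(
            X, y, features, cfg, selected_cols, repeat, rng, fold_metrics
        )
        aucs.append(auc)

    def pct(values):
        arr = np.array(values)
        return float(arr.mean()), float(arr.std(ddof=1)) if len(arr) > 1 else 0.0

    acc = pct([m.accuracy for m in fold_metrics])
    sens = pct([m.sensitivity for m in fold_metrics])
    spec = pct([m.specificity for m in fold_metrics])
    kap = pct([m.kappa for m in fold_metrics])
    auc_mean, auc_sd = pct([100 * a for a in aucs])

    return ClassifierReport(
        selected_features=selected_names if cfg.selection_mode == "paper" else tuple(features.columns),
        folds=tuple(fold_metrics),
        accuracy_mean=acc[0], accuracy_sd=acc[1],
        sensitivity_mean=sens[0], sensitivity_sd=sens[1],
        specificity_mean=spec[0], specificity_sd=spec[1],
        kappa_mean=kap[0], kappa_sd=kap[1],
        roc_auc_mean=auc_mean, roc_auc_sd=auc_sd,
        roc_points=_roc_points(last_scores, y),
    )


def permutation_test_accuracy(
    features: pd.DataFrame,
    labels: np.ndarray,
    cfg: ClassifierConfig | None = None,
    positive_label=None,
) -> float:
    """One-tailed label-permutation p-value for the CV accuracy.

    Each permutation relabels the subjects and reruns one round of k-fold
    cross-validation (same selection mode); the p-value is the fraction of
    permutations whose mean accuracy reaches the real-label accuracy
    (+1-corrected unless ``paper_convention``).
    """
    cfg = cfg or ClassifierConfig()
    if cfg.n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    y = _as_binary(labels, positive_label)
    X = features.to_numpy(dtype=float)
    ss = np.random.SeedSequence(cfg.seed)
    ss_sel, ss_real, ss_perm = ss.spawn(3)

    selected_cols: np.ndarray | None = None
    if cfg.selection_mode == "paper":
        names = lasso_select(features, y, cfg, seed=ss_sel)
        if names:
            selected_cols = np.array(
                [features.columns.get_loc(nm) for nm in names], dtype=int
            )

    rng_real = np.random.default_rng(ss_real)
    real_accs = [
        _cv_once(X, y, features, cfg, selected_cols, r, rng_real, None)[0]
        for r in range(cfg.n_repeats)
    ]
    real = float(np.mean(real_accs))

    rng = np.random.default_rng(ss_perm)
    wins = 0
    feats = features.reset_index(drop=True)
    for _ in range(cfg.n_perm):
        yp = y[rng.permutation(len(y))]
        acc = _cv_once(X, yp, feats, cfg, selected_cols, 0, rng, None)[0]
        wins += acc >= real
    return perm_pvalue(wins, cfg.n_perm, cfg.paper_convention)
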