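"""Response classifiers and their repeated cross-validated evaluation.

Five classifiers are supported: LDA, DLDA (linear discriminant with pooled
*diagonal* covariance), QDA, Gaussian naive Bayes, and a linear SVM
(C = 1).  Evaluation follows the study protocol: 50 iterations of
stratified 3-fold cross-validation with per-repetition metric pooling
(mean +/- SD across repetitions), a single-shot holdout evaluation, and
sequential inclusion of the top-1..10 ranked features.  The positive class
(pCR) is label 1 throughout: sensitivity is computed on pCR, specificity on
non-pCR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC

from .features import FeatureTable

CLASSIFIER_KINDS = ("LDA", "DLDA", "QDA", "NaiveBayes", "SVM")


class DiagonalLDA(BaseEstimator, ClassifierMixin):
    """Linear discriminant with pooled diagonal covariance.

    Equivalent to Gaussian naive Bayes with variances pooled across classes
    (one shared diagonal covariance), and to full LDA when the pooled
    covariance happens to be diagonal.  Class priors are the empirical
    frequencies; a small variance floor guards degenerate features.
    """

    def __init__(self, var_floor: float = 1e-12):
        self.var_floor = var_floor

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError("DiagonalLDA supports two classes")
        self.means_ = np.stack([X[y == c].mean(axis=0) for c in self.classes_])
        pooled = np.zeros(X.shape[1])
        for c in self.classes_:
            Xi = X[y == c]
            pooled += ((Xi - Xi.mean(axis=0)) ** 2).sum(axis=0)
        self.var_ = np.maximum(pooled / (X.shape[0] - 2), self.var_floor)
        self.priors_ = np.array([(y == c).mean() for c in self.classes_])
        return self

    def _log_likelihood(self, X):
        X = np.asarray(X, dtype=float)
        ll = []
        for k in range(2):
            z = (X - self.means_[k]) ** 2 / self.var_
            ll.append(-0.5 * z.sum(axis=1) + np.log(self.priors_[k]))
        return np.stack(ll, axis=1)

    def predict_proba(self, X):
        ll = self._log_likelihood(X)
        ll -= ll.max(axis=1, keepdims=True)
        p = np.exp(ll)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, X):
        return self.classes_[np.argmax(self._log_likelihood(X), axis=1)]


def make_classifier(kind: str):
    """Instantiate one of the five study classifiers."""
    if kind == "LDA":
        return LinearDiscriminantAnalysis()
    if kind == "DLDA":
        return DiagonalLDA()
    if kind == "QDA":
        return QuadraticDiscriminantAnalysis(reg_param=1e-6)
    if kind == "NaiveBayes":
        return GaussianNB()
    if kind == "SVM":
        return SVC(kernel="linear", C=1.0, probability=False)
    raise ValueError(f"unknown classifier kind {kind!r}")


def train_classifier(kind: str, X: np.ndarray, y: np.ndarray):
    """Fit a classifier; the returned model exposes a continuous score via
    ``predict_proba`` (posterior) or ``decision_function`` (SVM margin).

    A singular class covariance (QDA with more features than per-class
    samples) triggers escalating ridge regularization with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    model = make_classifier(kind)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # collinearity warnings from LDA/QDA
        try:
            model.fit(X, y)
            return model
        except np.linalg.LinAlgError:
            pass
    warnings.warn("singular class covariance; refitting with ridge-regularized QDA")
    model = RidgeQDA()
    model.fit(X, y)
    return model


class RidgeQDA(BaseEstimator, ClassifierMixin):
    """Gaussian QDA with a ridge-stabilized per-class covariance.

    Fallback when a class has fewer samples than features: each class
    covariance is shrunk as (1 - alpha) S_c + alpha * tr(S_c)/p * I, which
    is always positive definite for alpha > 0.
    """

    def __init__(self, alpha: float = 0.1):
        self.alpha = alpha

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        p = X.shape[1]
        self.means_, self._prec, self._logdet, self.priors_ = [], [], [], []
        for c in self.classes_:
            Xi = X[y == c]
            mu = Xi.mean(axis=0)
            S = np.cov(Xi, rowvar=False).reshape(p, p) if Xi.shape[0] > 1 else np.eye(p)
            tr = np.trace(S) / p
            S = (1 - self.alpha) * S + self.alpha * max(tr, 1e-12) * np.eye(p)
            sign, logdet = np.linalg.slogdet(S)
            self.means_.append(mu)
            self._prec.append(np.linalg.inv(S))
            self._logdet.append(logdet)
            self.priors_.append((y == c).mean())
        return self

    def _log_likelihood(self, X):
        X = np.asarray(X, dtype=float)
        ll = []
        for mu, prec, logdet, prior in zip(self.means_, self._prec, self._logdet, self.priors_):
            d = X - mu
            maha = np.einsum("ij,jk,ik->i", d, prec, d)
            ll.append(-0.5 * (maha + logdet) + np.log(prior))
        return np.stack(ll, axis=1)

    def predict_proba(self, X):
        ll = self._log_likelihood(X)
        ll -= ll.max(axis=1, keepdims=True)
        pr = np.exp(ll)
        return pr / pr.sum(axis=1, keepdims=True)

    def predict(self, X):
        return self.classes_[np.argmax(self._log_likelihood(X), axis=1)]


def _scores_and_threshold(model, X) -> tuple[np.ndarray, float]:
    if hasattr(model, "predict_proba"):
        return model.predict_proba(np.asarray(X, dtype=float))[:, 1], 0.5
    return model.decision_function(np.asarray(X, dtype=float)), 0.0


def binary_metrics(scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5) -> dict:
    """AUC (rank statistic, ties get half credit), accuracy, sensitivity
    (positive = pCR = 1), specificity, at the given score threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if np.unique(labels).size < 2:
        raise ValueError("both classes must be present")
    auc = float(roc_auc_score(labels, scores))
    pred = (scores >= threshold).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    return {
        "auc": auc,
        "accuracy": float((pred == labels).mean()),
        "sensitivity": tp / int((labels == 1).sum()),
        "specificity": tn / int((labels == 0).sum()),
    }


@dataclass
class EvalReport:
    """Evaluation metrics: mean +/- SD across CV repetitions, or point
    values (SD 0) for a holdout evaluation."""

    classifier: str
    n_features_used: int
    auc: float
    auc_sd: float
    accuracy: float
    accuracy_sd: float
    sensitivity: float
    sensitivity_sd: float
    specificity: float
    specificity_sd: float
    mode: str = "cv"

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _as_xy(table, labels, feature_subset):
    if isinstance(table, FeatureTable):
        X = table.df[list(feature_subset)].to_numpy()
    else:
        X = np.asarray(table, dtype=float)[:, list(feature_subset)]
    return X, np.asarray(labels).astype(int)


def cross_validate(
    table,
    labels,
    feature_subset,
    kind: str,
    n_repeats: int = 50,
    n_folds: int = 3,
    seed: int = 0,
) -> EvalReport:
    """Repeated stratified k-fold evaluation with per-repetition pooling.

    Out-of-fold scores are pooled within each repetition, metrics computed
    once per repetition, and mean/SD taken across repetitions.
    """
    X, y = _as_xy(table, labels, feature_subset)
    rng = np.random.default_rng(seed)
    per_rep = {m: [] for m in ("auc", "accuracy", "sensitivity", "specificity")}
    for _ in range(n_repeats):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=int(rng.integers(2**31 - 1)))
        scores = np.empty(len(y))
        thr = 0.5
        for tr, te in skf.split(X, y):
            model = train_classifier(kind, X[tr], y[tr])
            scores[te], thr = _scores_and_threshold(model, X[te])
        m = binary_metrics(scores, y, threshold=thr)
        for k, v in m.items():
            per_rep[k].append(v)
    vals = {k: np.asarray(v) for k, v in per_rep.items()}
    return EvalReport(
        classifier=kind,
        n_features_used=X.shape[1],
        auc=float(vals["auc"].mean()),
        auc_sd=float(vals["auc"].std(ddof=1)),
        accuracy=float(vals["accuracy"].mean()),
        accuracy_sd=float(vals["accuracy"].std(ddof=1)),
        sensitivity=float(vals["sensitivity"].mean()),
        sensitivity_sd=float(vals["sensitivity"].std(ddof=1)),
        specificity=float(vals["specificity"].mean()),
        specificity_sd=float(vals["specificity"].std(ddof=1)),
        mode="cv",
    )


def evaluate_holdout(
    train_table,
    train_labels,
    test_table,
    test_labels,
    feature_subset,
    kind: str,
) -> EvalReport:
    """Train on the training table, evaluate once on the holdout."""
    Xtr, ytr = _as_xy(train_table, train_labels, feature_subset)
    Xte, yte = _as_xy(test_table, test_labels, feature_subset)
    model = train_classifier(kind, Xtr, ytr)
    scores, thr = _scores_and_threshold(model, Xte)
    m = binary_metrics(scores, yte, threshold=thr)
    return EvalReport(
        classifier=kind,
        n_features_used=Xtr.shape[1],
        auc=m["auc"],
        auc_sd=0.0,
        accuracy=m["accuracy"],
        accuracy_sd=0.0,
        sensitivity=m["sensitivity"],
        sensitivity_sd=0.0,
        specificity=m["specificity"],
        specificity_sd=0.0,
        mode="holdout",
    )


def sequential_feature_eval(
    table,
    labels,
    ranked_features,
    kind: str,
    mode: str = "cv",
    test_table=None,
    test_labels=None,
    n_repeats: int = 50,
    n_folds: int = 3,
    seed: int = 0,
    max_features: int = 10,
) -> list[EvalReport]:
    """One EvalReport per prefix of the ranked feature list (top-1..top-10)."""
    reports = []
    for k in range(1, min(max_features, len(ranked_features)) + 1):
        subset = list(ranked_features[:k])
        if mode == "cv":
            reports.append(
                cross_validate(table, labels, subset, kind, n_repeats, n_folds, seed)
            )
        elif mode == "holdout":
            reports.append(
                evaluate_holdout(table, labels, test_table, test_labels, subset, kind)
            )
        else:
            raise ValueError("mode must be 'cv' or 'holdout'")
    return reports
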