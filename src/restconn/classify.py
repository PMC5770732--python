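"""Connectivity-based classification under leave-one-out cross-validation.

Functional features (per-subject mean component z within each
group-difference cluster) and effective features (per-subject GCIs) are
concatenated into one table.  Inside every LOOCV fold, feature
standardization and two-sample-t feature selection are fit on the
training rows only and applied to the held-out subject — the guard
against selection bias.  Two classifiers are provided: maximum-
uncertainty LDA (MLDA), whose pooled-covariance eigenvalues below their
mean are raised to the mean so the discriminant stays defined when
features outnumber subjects, and a soft-margin SVM with Gaussian kernel
``k(u, v) = exp(-||u - v||^2 / (2 * width^2))``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import SVC

__all__ = [
    "FeatureTable",
    "ClassificationResult",
    "build_features",
    "select_features_ttest",
    "train_mlda",
    "train_ksvm",
    "loocv",
    "average_feature_weights",
    "classification_metrics",
]


@dataclass
class FeatureTable:
    """Subjects x features matrix with group labels and feature provenance."""

    subjects: list[str]
    groups: np.ndarray              # 0/1 per subject; 1 = positive (patient)
    features: np.ndarray            # (n, d)
    feature_names: list[str]

    def __post_init__(self):
        self.groups = np.asarray(self.groups, dtype=int)
        self.features = np.asarray(self.features, dtype=float)
        n, d = self.features.shape
        if d < 1:
            raise ValueError("feature table needs at least one feature")
        if len(self.feature_names) != d or len(set(self.feature_names)) != d:
            raise ValueError("feature_names must be unique and match width")
        if len(self.subjects) != n or len(self.groups) != n:
            raise ValueError("subjects/groups length must match row count")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("feature table contains non-finite values")


@dataclass
class ClassificationResult:
    """LOOCV outcome: per-fold predictions, metrics, averaged weights."""

    predictions: np.ndarray
    truth: np.ndarray
    accuracy: float
    sensitivity: float
    specificity: float
    mean_weights: np.ndarray
    selected_counts: np.ndarray
    feature_names: list[str]
    per_fold_selected: np.ndarray = field(default=None, repr=False)
    per_fold_weights: np.ndarray = field(default=None, repr=False)


def classification_metrics(y_true, y_pred, positive=1):
    """(accuracy, sensitivity, specificity) with the patient group positive."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    pos = y_true == positive
    tp = int(np.sum(pos & (y_pred == positive)))
    tn = int(np.sum(~pos & (y_pred != positive)))
    acc = (tp + tn) / len(y_true)
    sens = tp / int(pos.sum()) if pos.any() else np.nan
    spec = tn / int((~pos).sum()) if (~pos).any() else np.nan
    return acc, sens, spec


def build_features(component_scores: pd.DataFrame, gci_table: pd.DataFrame,
                   groups: dict[str, str], positive_group: str = "patient",
                   standardize: bool = True) -> FeatureTable:
    """Concatenate functional and effective connectivity features.

    ``component_scores`` is a subjects x regions frame (per-subject mean
    component z within each group-difference cluster); columns are
    prefixed ``FC:``.  ``gci_table`` is the tidy per-subject GCI frame
    from :func:`restconn.granger.compute_gci_table`; its connections are
    pivoted to columns prefixed ``GC:`` (``GC:a->b`` or ``GC:a->b|relay``).
    Constant columns are dropped with a warning; remaining columns are
    z-scored over subjects.
    """
    fc = component_scores.copy()
    fc.columns = [c if str(c).startswith("FC:") else f"FC:{c}" for c in fc.columns]
    gc = gci_table.copy()
    gc["name"] = ["GC:" + s + "->" + t + ("" if r in ("", None) else "|" + r)
                  for s, t, r in zip(gc["source"], gc["target"], gc["relay"])]
    ec = gc.pivot(index="subject_id", columns="name", values="gci")

    subjects = list(fc.index)
    missing = [s for s in subjects if s not in ec.index]
    missing += [s for s in ec.index if s not in subjects]
    if missing:
        raise ValueError("subject(s) missing from one feature source: "
                         + ", ".join(sorted(set(str(m) for m in missing))))
    table = pd.concat([fc, ec.loc[subjects]], axis=1)
    if table.isna().any().any():
        raise ValueError("missing values after feature assembly")

    X = table.to_numpy(dtype=float)
    names = [str(c) for c in table.columns]
    sd = X.std(axis=0)
    if (sd == 0).any():
        dropped = [n for n, flat in zip(names, sd == 0) if flat]
        warnings.warn("dropping constant feature(s): " + ", ".join(dropped))
        keep = sd > 0
        X, names, sd = X[:, keep], [n for n, k in zip(names, keep) if k], sd[keep]
        if X.shape[1] == 0:
            raise ValueError("all features constant")
    if standardize:
        X = (X - X.mean(axis=0)) / sd
    y = np.array([1 if groups[s] == positive_group else 0 for s in subjects])
    return FeatureTable(subjects=[str(s) for s in subjects], groups=y,
                        features=X, feature_names=names)


def select_features_ttest(X, y, alpha=0.05):
    """Two-sample-t feature selection on training rows only.

    Keeps columns with p < ``alpha`` (uncorrected).  If nothing passes,
    the single smallest-p column is kept so no fold trains on an empty
    feature set.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    labels = np.unique(y)
    if len(labels) < 2:
        raise ValueError("training set contains a single group")
    a, b = X[y == labels[0]], X[y == labels[1]]
    with np.errstate(divide="ignore", invalid="ignore"):
        _, p = stats.ttest_ind(a, b, axis=0, equal_var=True)
    p = np.where(np.isfinite(p), p, 1.0)
    selected = np.flatnonzero(p < alpha)
    if selected.size == 0:
        selected = np.array([int(np.argmin(p))])
    return selected


def train_mlda(X, y, positive=1):
    """Maximum-uncertainty LDA: ``w = S*^-1 (mu_pos - mu_neg)``.

    The pooled within-class covariance is eigendecomposed and every
    eigenvalue below the mean eigenvalue is replaced by the mean, which
    regularizes the inversion exactly when the spectrum is spread (and
    is a no-op on an equal-spectrum covariance).  The bias puts the
    decision boundary at the midpoint of the projected class means;
    predict positive when ``x @ w + b > 0``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    pos, neg = X[y == positive], X[y != positive]
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("each class needs >= 2 training rows for a covariance")
    mu_p, mu_n = pos.mean(axis=0), neg.mean(axis=0)
    scatter = ((pos - mu_p).T @ (pos - mu_p) + (neg - mu_n).T @ (neg - mu_n))
    sp = scatter / (len(pos) + len(neg) - 2)
    lam, V = np.linalg.eigh(sp)
    lam_bar = lam.mean()
    lam_star = np.maximum(lam, lam_bar)
    w = V @ ((V.T @ (mu_p - mu_n)) / lam_star)
    bias = -float(w @ (mu_p + mu_n) / 2.0)
    return w, bias


def train_ksvm(X, y, width=0.5, C=1.0):
    """Gaussian-kernel soft-margin SVM; ``width`` is the kernel sigma."""
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    gamma = 1.0 / (2.0 * width ** 2)
    svm = SVC(kernel="rbf", gamma=gamma, C=C)
    svm.fit(np.asarray(X, float), np.asarray(y))
    return svm


class FoldError(RuntimeError):
    """A LOOCV fold failed; carries the fold index for diagnostics."""


def loocv(table: FeatureTable, classifier: str = "mlda", alpha: float = 0.05,
          svm_width: float = 0.5, svm_c: float = 1.0,
          unsafe_global_selection: bool = False) -> ClassificationResult:
    """Leave-one-out cross-validation with per-fold selection and scaling.

    In each fold the feature means/SDs and the t-test selection are
    computed from the n-1 training rows only, then applied to the
    held-out row.  ``unsafe_global_selection=True`` deliberately selects
    on all rows instead — it exists only to demonstrate (and regression-
    test) the optimistic bias that per-fold selection avoids.
    """
    X, y = table.features, table.groups
    n, d = X.shape
    if n < 4 or (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValueError("LOOCV needs n >= 4 with >= 2 subjects per class")
    preds = np.empty(n, dtype=int)
    sel_mask = np.zeros((n, d), dtype=bool)
    weights = np.full((n, d), np.nan)
    global_sel = select_features_ttest(X, y, alpha) if unsafe_global_selection else None

    for i in range(n):
        train = np.ones(n, dtype=bool)
        train[i] = False
        Xtr, ytr = X[train], y[train]
        mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0)
        sd = np.where(sd == 0, 1.0, sd)
        Xtr = (Xtr - mu) / sd
        xte = (X[i] - mu) / sd
        sel = global_sel if unsafe_global_selection else \
            select_features_ttest(Xtr, ytr, alpha)
        sel_mask[i, sel] = True
        try:
            if classifier == "mlda":
                w, b = train_mlda(Xtr[:, sel], ytr)
                preds[i] = int(xte[sel] @ w + b > 0)
                weights[i, sel] = w
            elif classifier == "ksvm":
                svm = train_ksvm(Xtr[:, sel], ytr, width=svm_width, C=svm_c)
                preds[i] = int(svm.predict(xte[sel][None, :])[0])
            else:
                raise ValueError(f"unknown classifier {classifier!r}")
        except ValueError:
            raise
        except Exception as exc:
            raise FoldError(f"fold {i} (subject {table.subjects[i]}) failed: "
                            f"{exc}") from exc

    acc, sens, spec = classification_metrics(y, preds, positive=1)
    mean_w, counts = average_feature_weights(weights, sel_mask)
    return ClassificationResult(predictions=preds, truth=y.copy(),
                                accuracy=acc, sensitivity=sens,
                                specificity=spec, mean_weights=mean_w,
                                selected_counts=counts,
                                feature_names=list(table.feature_names),
                                per_fold_selected=sel_mask,
                                per_fold_weights=weights)


def average_feature_weights(per_fold_weights, per_fold_selected):
    """Average each feature's discriminant weight over folds that chose it.

    Features never selected get weight 0.  Also returns the per-feature
    selection count across folds.
    """
    W = np.asarray(per_fold_weights, dtype=float)
    S = np.asarray(per_fold_selected, dtype=bool)
    counts = S.sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_w = np.nanmean(np.where(S, W, np.nan), axis=0)
    mean_w = np.where(counts > 0, mean_w, 0.0)
    return mean_w, counts
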