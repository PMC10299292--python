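"""Two-gene diagnostic classifier and its evaluation.

A margin classifier (SVM; RBF kernel with a median-heuristic bandwidth by
default) is trained on the (anchor, candidate) expression pair.  Evaluation
offers a stratified 60/40 train/test split and stratified k-fold
cross-validated ROC AUC; the headline metric is the mean 10-fold CV AUC.
An empirical anchor threshold is extracted: the largest expression value
below which every sample is a case.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.svm import SVC

from coherence_screen.dataio import DataIOError

CASE, CONTROL = "case", "control"


def _binary_labels(labels: Sequence[str]) -> np.ndarray:
    y = np.asarray([str(l) for l in labels])
    unknown = set(y) - {CASE, CONTROL}
    if unknown:
        raise DataIOError(f"labels must be case/control, got extras: {sorted(unknown)}")
    return (y == CASE).astype(int)


def _check_features(features: np.ndarray) -> np.ndarray:
    x = np.asarray(features, dtype=float)
    if x.ndim != 2 or x.shape[1] != 2:
        raise DataIOError(f"features must be n x 2, got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise DataIOError("features contain non-finite values")
    return x


def median_heuristic_gamma(features: np.ndarray) -> float:
    """RBF gamma = 1 / median squared pairwise distance (falls back to 1)."""
    x = np.asarray(features, dtype=float)
    sq = (x * x).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (x @ x.T)
    d2 = d2[np.triu_indices_from(d2, k=1)]
    med = float(np.median(d2)) if d2.size else 0.0
    return 1.0 / med if med > 0 else 1.0


@dataclass
class DiagnosticModel:
    """Fitted two-feature classifier; higher decision score = more case-like."""

    feature_genes: tuple[str, str]
    kernel: str
    _svc: SVC
    n: int
    n_case: int
    n_control: int
    seed: int

    def decision_function(self, features: np.ndarray) -> np.ndarray:
        x = _check_features(np.atleast_2d(np.asarray(features, dtype=float)))
        return self._svc.decision_function(x)

    def predict(self, features: np.ndarray) -> np.ndarray:
        score = self.decision_function(features)
        return np.where(score > 0, CASE, CONTROL)


@dataclass(frozen=True)
class CVReport:
    """Per-fold ROC AUCs and their mean."""

    auc_values: tuple[float, ...]
    scheme: str
    seed: int
    mean_auc: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.auc_values:
            raise ValueError("CVReport needs at least one AUC value")
        for a in self.auc_values:
            if not (0.0 <= a <= 1.0):
                raise ValueError(f"AUC {a} outside [0, 1]")
        object.__setattr__(self, "mean_auc", float(np.mean(self.auc_values)))


def roc_auc(scores: Sequence[float], labels: Sequence[str]) -> float:
    """ROC AUC by the rank (Mann-Whitney) formulation with midrank ties.

    Equals the probability that a uniformly random case outscores a uniformly
    random control, counting ties as 1/2.
    """
    y = _binary_labels(labels)
    s = np.asarray(scores, dtype=float)
    n1 = int(y.sum())
    n0 = int(y.size - n1)
    if n1 == 0 or n0 == 0:
        raise DataIOError("AUC needs both classes present")
    from scipy.stats import rankdata

    ranks = rankdata(s)  # midranks handle ties -> AUC 0.5 for constant scores
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def fit_classifier(
    features: np.ndarray,
    labels: Sequence[str],
    feature_genes: tuple[str, str] = ("anchor", "candidate"),
    kernel: str = "rbf",
    c: float = 1.0,
    seed: int = 0,
) -> DiagnosticModel:
    """Train the two-feature SVM; features are used on the log2 scale as-is
    so decision geometry stays in expression units."""
    x = _check_features(features)
    y = _binary_labels(labels)
    if x.shape[0] != y.size:
        raise DataIOError("features and labels disagree in length")
    if x.shape[0] < 4:
        raise DataIOError("need >=4 samples to train")
    if y.min() == y.max():
        raise DataIOError("training data contains a single class")
    if kernel not in ("linear", "rbf"):
        raise DataIOError(f"unsupported kernel '{kernel}'")
    # exact duplicate (features, label) rows carry no margin information;
    # drop them so the decision function is invariant to replication
    uniq = np.unique(np.column_stack([x, y]), axis=0)
    x_fit, y_fit = uniq[:, :2], uniq[:, 2].astype(int)
    if y_fit.min() == y_fit.max():
        raise DataIOError("training data contains a single class")
    gamma = median_heuristic_gamma(x_fit) if kernel == "rbf" else "scale"
    svc = SVC(kernel=kernel, C=c, gamma=gamma, random_state=seed)
    svc.fit(x_fit, y_fit)
    return DiagnosticModel(
        feature_genes=tuple(feature_genes),
        kernel=kernel,
        _svc=svc,
        n=int(y.size),
        n_case=int(y.sum()),
        n_control=int(y.size - y.sum()),
        seed=seed,
    )


def split_train_test(
    sample_ids: Sequence[str],
    labels: Sequence[str],
    train_fraction: float = 0.6,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Stratified random split into disjoint, exhaustive train/test sets."""
    ids = [str(s) for s in sample_ids]
    y = _binary_labels(labels)
    if len(ids) != y.size:
        raise DataIOError("sample_ids and labels disagree in length")
    if len(ids) < 5:
        raise DataIOError("need >=5 samples to split")
    if min(int(y.sum()), int(y.size - y.sum())) < 2:
        raise DataIOError("each class needs >=2 samples to stratify")
    if not (0.0 < train_fraction < 1.0):
        raise DataIOError("train_fraction must lie in (0, 1)")
    train, test = train_test_split(
        ids, train_size=train_fraction, stratify=y, random_state=seed, shuffle=True
    )
    return list(train), list(test)


def cv_auc(
    features: np.ndarray,
    labels: Sequence[str],
    k: int = 10,
    kernel: str = "rbf",
    c: float = 1.0,
    seed: int = 0,
) -> CVReport:
    """Stratified k-fold cross-validated ROC AUC of the two-gene classifier."""
    x = _check_features(features)
    y = _binary_labels(labels)
    n_case, n_control = int(y.sum()), int(y.size - y.sum())
    if min(n_case, n_control) < k:
        raise DataIOError(
            f"smallest class has {min(n_case, n_control)} samples < k={k}; "
            f"use a smaller k"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    label_arr = np.asarray([str(l) for l in labels])
    aucs = []
    for train_idx, test_idx in skf.split(x, y):
        model = fit_classifier(
            x[train_idx], label_arr[train_idx], kernel=kernel, c=c, seed=seed
        )
        scores = model.decision_function(x[test_idx])
        aucs.append(roc_auc(scores, label_arr[test_idx]))
    return CVReport(
        auc_values=tuple(aucs),
        scheme=f"stratified {k}-fold CV, shuffled, kernel={kernel}",
        seed=seed,
    )


def holdout_auc(
    features: np.ndarray,
    labels: Sequence[str],
    train_fraction: float = 0.6,
    kernel: str = "rbf",
    c: float = 1.0,
    seed: int = 0,
) -> float:
    """AUC on a stratified held-out fraction (the 60/40 evaluation mode)."""
    x = _check_features(features)
    y = np.asarray([str(l) for l in labels])
    ids = [str(i) for i in range(x.shape[0])]
    train, test = split_train_test(ids, y, train_fraction=train_fraction, seed=seed)
    tr = np.array([int(i) for i in train])
    te = np.array([int(i) for i in test])
    model = fit_classifier(x[tr], y[tr], kernel=kernel, c=c, seed=seed)
    return roc_auc(model.decision_function(x[te]), y[te])


def anchor_threshold(
    features: np.ndarray, labels: Sequence[str], axis: int = 0
) -> float | None:
    """Largest value t on the anchor axis such that every sample strictly
    below t is a case: t = the controls' minimum anchor expression.  Returns
    ``None`` when the global minimum on the axis belongs to a control (no
    case-only region exists below the controls)."""
    x = _check_features(features)
    y = _binary_labels(labels)
    if y.min() == y.max():
        raise DataIOError("threshold needs both classes present")
    vals = x[:, axis]
    t = float(vals[y == 0].min())
    if not np.any(vals[y == 1] < t):
        return None
    return t
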