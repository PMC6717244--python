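"""Training and evaluating the interface classifiers.

Feature selection is F-score ranking followed by cross-validated SVM-RBF
evaluation of the top-k candidates; the selected features feed both the
SVM-RBF and random-forest models.  Cross-validation is stratified, with
feature selection and standardization re-fit inside every training fold so
no information leaks from test folds.  Performance is summarized by
sensitivity, specificity, accuracy, the Matthews correlation coefficient and
the ROC AUC (rank statistic with midranks for ties).
"""

from __future__ import annotations

import hashlib
import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "LabeledDataset",
    "TrainedModel",
    "PerfReport",
    "fscore_rank",
    "select_features",
    "train",
    "cross_validate",
    "metrics",
    "roc_auc",
    "save_model",
    "load_model",
    "predict",
    "reduce_redundancy",
]

POSITIVE = "biological"
NEGATIVE = "crystallographic"

DEFAULT_CANDIDATE_COUNTS = (1, 2, 4, 8, 16, 32, 64)
SVM_GRID = {"svc__C": [1.0, 10.0, 100.0], "svc__gamma": ["scale", 0.01, 0.1]}
RF_TREES = 500


@dataclass
class LabeledDataset:
    """Feature matrix with biological/crystallographic labels."""

    X: pd.DataFrame
    y: np.ndarray               # 1 = biological, 0 = crystallographic
    groups: Optional[np.ndarray] = None

    def __post_init__(self):
        self.y = np.asarray(self.y).astype(int)
        if self.X.isna().any().any():
            raise ValueError("feature matrix contains missing values; "
                             "impute or flag them before training")

    @property
    def n(self) -> int:
        return len(self.y)

    def subset_features(self, names: Sequence[str]) -> "LabeledDataset":
        return LabeledDataset(self.X[list(names)], self.y, self.groups)


@dataclass
class TrainedModel:
    kind: str                   # "rf" | "svm_rbf"
    selected_features: list
    pipeline: object            # fitted sklearn estimator
    metadata: dict = field(default_factory=dict)

    def decision_scores(self, X: pd.DataFrame) -> np.ndarray:
        Xs = X[self.selected_features].to_numpy()
        if hasattr(self.pipeline, "predict_proba"):
            return self.pipeline.predict_proba(Xs)[:, 1]
        return self.pipeline.decision_function(Xs)

    def predict_labels(self, X: pd.DataFrame,
                       threshold: float = 0.5) -> np.ndarray:
        if self.kind == "rf":
            return (self.decision_scores(X) >= threshold).astype(int)
        return self.pipeline.predict(X[self.selected_features].to_numpy())

    def fingerprint(self) -> str:
        payload = pickle.dumps((self.kind, self.selected_features,
                                self.pipeline))
        return hashlib.sha256(payload).hexdigest()


@dataclass
class PerfReport:
    tp: int
    fn: int
    tn: int
    fp: int
    sn: float
    sp: float
    ac: float
    mcc: float
    auc: Optional[float] = None

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("tp", "fn", "tn", "fp", "sn", "sp", "ac", "mcc", "auc")}


# ---------------------------------------------------------------------------
# Metrics


def metrics(tp: int, fn: int, tn: int, fp: int,
            auc: Optional[float] = None) -> PerfReport:
    """Sensitivity, specificity, accuracy and MCC from a confusion matrix.

    MCC uses the standard Matthews formula and is defined as 0 when any of
    the four marginal factors is zero.
    """
    total = tp + fn + tn + fp
    if total == 0:
        raise ValueError("empty confusion matrix")
    if min(tp, fn, tn, fp) < 0:
        raise ValueError("negative counts")
    sn = tp / (tp + fn) if tp + fn else 0.0
    sp = tn / (fp + tn) if fp + tn else 0.0
    ac = (tp + tn) / total
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = 0.0 if denom == 0 else \
        (tp * tn - fp * fn) / float(np.sqrt(denom))
    return PerfReport(tp, fn, tn, fp, sn, sp, ac, mcc, auc)


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """ROC AUC via the Mann-Whitney rank statistic with midranks for ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes")
    ranks = rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# Feature selection


def fscore_rank(d: LabeledDataset) -> pd.DataFrame:
    """Fisher-score ranking of every feature.

    ``F = [(mean+ - mean)^2 + (mean- - mean)^2] / (var+ + var-)`` with
    n-1 sample variances.  A zero denominator means a feature constant
    within each class: F is 0 when the class means also agree (the feature
    carries nothing) and infinite when they differ (perfect separation).
    Sorted descending, ties broken by feature name.
    """
    pos = d.X[d.y == 1]
    neg = d.X[d.y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("F-score ranking needs both classes")
    overall = d.X.mean()
    num = (pos.mean() - overall) ** 2 + (neg.mean() - overall) ** 2
    den = pos.var(ddof=1).fillna(0.0) + neg.var(ddof=1).fillna(0.0)
    f = pd.Series(
        np.where(den > 0, num / den.replace(0, np.nan),
                 np.where(num > 0, np.inf, 0.0)),
        index=d.X.columns).fillna(0.0)
    out = pd.DataFrame({"feature": f.index, "fscore": f.to_numpy()})
    return out.sort_values(["fscore", "feature"],
                           ascending=[False, True],
                           kind="stable").reset_index(drop=True)


def _svm_cv_accuracy(X: np.ndarray, y: np.ndarray, seed: int,
                     k_folds: int) -> float:
    k = min(k_folds, int(np.bincount(y).min()))
    if k < 2:
        return 0.0
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    correct = 0
    for tr, te in skf.split(X, y):
        pipe = Pipeline([("scale", StandardScaler()),
                         ("svc", SVC(kernel="rbf"))])
        pipe.fit(X[tr], y[tr])
        correct += int((pipe.predict(X[te]) == y[te]).sum())
    return correct / len(y)


def select_features(d: LabeledDataset,
                    candidate_counts: Sequence[int] = DEFAULT_CANDIDATE_COUNTS,
                    seed: int = 0, k_folds: int = 5,
                    restrict_to: Optional[Sequence[str]] = None) -> list:
    """Choose the F-score prefix maximizing cross-validated SVM accuracy.

    For each candidate count k the top-k features by F-score are evaluated
    with a stratified-CV SVM-RBF; the best mean accuracy wins, smaller k on
    ties.  ``restrict_to`` limits the candidate pool (e.g. to the known
    features only).
    """
    pool = d if restrict_to is None else d.subset_features(restrict_to)
    ranking = fscore_rank(pool)["feature"].tolist()
    best_k, best_acc = None, -1.0
    for k in sorted(set(min(k, len(ranking))
                        for k in candidate_counts)):
        feats = ranking[:k]
        acc = _svm_cv_accuracy(pool.X[feats].to_numpy(), pool.y, seed,
                               k_folds)
        if acc > best_acc:
            best_k, best_acc = k, acc
    return ranking[:best_k]


# ---------------------------------------------------------------------------
# Training


def train(d: LabeledDataset, kind: str = "rf",
          hyper: Optional[dict] = None, seed: int = 0,
          features: Optional[Sequence[str]] = None) -> TrainedModel:
    """Fit an RF or SVM-RBF model on (a feature subset of) the dataset.

    SVM features are standardized inside the pipeline (training statistics
    stored); the SVM's C/gamma are tuned on a small logarithmic grid by
    internal CV.  The RF uses 500 trees and the given seed.
    """
    if np.bincount(d.y, minlength=2).min() < 2:
        raise ValueError("need at least two samples per class")
    feats = list(features) if features is not None else list(d.X.columns)
    X = d.X[feats].to_numpy()
    if kind == "rf":
        hyper = {"n_estimators": RF_TREES, **(hyper or {})}
        model = RandomForestClassifier(random_state=seed, **hyper)
        model.fit(X, d.y)
    elif kind == "svm_rbf":
        pipe = Pipeline([("scale", StandardScaler()),
                         ("svc", SVC(kernel="rbf"))])
        k_inner = min(3, int(np.bincount(d.y).min()))
        grid = hyper if hyper is not None else SVM_GRID
        model = GridSearchCV(
            pipe, grid,
            cv=StratifiedKFold(k_inner, shuffle=True, random_state=seed),
            n_jobs=1)
        model.fit(X, d.y)
    else:
        raise ValueError(f"unknown model kind {kind!r}")
    return TrainedModel(kind, feats, model,
                        {"seed": seed, "n_train": d.n})


def _fit_fold(d: LabeledDataset, train_idx: np.ndarray, kind: str,
              seed: int, select: bool,
              candidate_counts: Sequence[int],
              restrict_selection_to: Optional[Sequence[str]]
              ) -> TrainedModel:
    """Fit one CV fold: feature selection and fitting see training rows only."""
    d_tr = LabeledDataset(d.X.iloc[train_idx], d.y[train_idx])
    if select:
        feats = select_features(d_tr, candidate_counts, seed=seed,
                                restrict_to=restrict_selection_to)
    else:
        feats = list(d_tr.X.columns)
    model = train(d_tr, kind, seed=seed, features=feats)
    model.metadata["selection_trace"] = feats
    return model


def cross_validate(d: LabeledDataset, kind: str = "rf", k_folds: int = 5,
                   seed: int = 0, select: bool = True,
                   candidate_counts: Sequence[int] = DEFAULT_CANDIDATE_COUNTS,
                   restrict_selection_to: Optional[Sequence[str]] = None,
                   feature_subset: Optional[Sequence[str]] = None,
                   folds: Optional[list] = None) -> tuple:
    """Stratified k-fold cross-validation with in-fold feature selection.

    Returns ``(pooled PerfReport, per-fold list)``; each per-fold entry is a
    dict with the fold report, selected features, model fingerprint and test
    scores.  Pooled AUC is computed on the concatenated test scores.
    ``folds`` overrides fold construction (list of (train, test) index
    arrays), which keeps folds fixed while labels are perturbed in
    leakage tests.
    """
    if feature_subset is not None:
        d = d.subset_features(feature_subset)
    if folds is None:
        if k_folds > int(np.bincount(d.y).min()):
            raise ValueError("k_folds exceeds the size of a class")
        skf = StratifiedKFold(n_splits=k_folds, shuffle=True,
                              random_state=seed)
        folds = list(skf.split(d.X, d.y))
    tp = fn = tn = fp = 0
    all_scores, all_labels = [], []
    per_fold = []
    for fold_id, (tr, te) in enumerate(folds):
        model = _fit_fold(d, np.asarray(tr), kind, seed, select,
                          candidate_counts, restrict_selection_to)
        X_te = d.X.iloc[te]
        y_te = d.y[np.asarray(te)]
        pred = model.predict_labels(X_te)
        scores = model.decision_scores(X_te)
        f_tp = int(((pred == 1) & (y_te == 1)).sum())
        f_fn = int(((pred == 0) & (y_te == 1)).sum())
        f_tn = int(((pred == 0) & (y_te == 0)).sum())
        f_fp = int(((pred == 1) & (y_te == 0)).sum())
        tp, fn, tn, fp = tp + f_tp, fn + f_fn, tn + f_tn, fp + f_fp
        all_scores.append(scores)
        all_labels.append(y_te)
        fold_auc = None
        if len(set(y_te)) == 2:
            fold_auc = roc_auc(scores, y_te)
        per_fold.append({
            "fold": fold_id,
            "report": metrics(f_tp, f_fn, f_tn, f_fp, fold_auc),
            "selected_features": model.selected_features,
            "fingerprint": model.fingerprint(),
            "test_index": np.asarray(te),
            "test_scores": scores,
        })
    pooled_auc = roc_auc(np.concatenate(all_scores),
                         np.concatenate(all_labels))
    return metrics(tp, fn, tn, fp, pooled_auc), per_fold


# ---------------------------------------------------------------------------
# Persistence and prediction


ARCHIVE_VERSION = 1


def save_model(model: TrainedModel, path) -> None:
    payload = {"version": ARCHIVE_VERSION, "kind": model.kind,
               "selected_features": model.selected_features,
               "pipeline": model.pipeline, "metadata": model.metadata}
    Path(path).write_bytes(pickle.dumps(payload))


def load_model(path) -> TrainedModel:
    payload = pickle.loads(Path(path).read_bytes())
    if payload.get("version") != ARCHIVE_VERSION:
        raise ValueError(f"unsupported model archive version "
                         f"{payload.get('version')!r}")
    return TrainedModel(payload["kind"], payload["selected_features"],
                        payload["pipeline"], payload["metadata"])


def predict(model: TrainedModel, X: pd.DataFrame,
            threshold: float = 0.5) -> pd.DataFrame:
    """Score new interfaces; errors name any missing feature column."""
    missing = [f for f in model.selected_features if f not in X.columns]
    if missing:
        raise KeyError(f"feature table is missing required feature(s): "
                       f"{', '.join(missing)}")
    scores = model.decision_scores(X)
    labels = model.predict_labels(X, threshold)
    return pd.DataFrame({
        "score": scores,
        "predicted_class": np.where(labels == 1, POSITIVE, NEGATIVE),
        "threshold": threshold,
    }, index=X.index)


# ---------------------------------------------------------------------------
# Dataset preparation


def reduce_redundancy(sequences: dict, identity_threshold: float = 30.0
                      ) -> list:
    """Single-linkage cluster sequences at the identity threshold (percent)
    and keep one representative (first id in sorted order) per cluster.

    Identity is matches over the shorter ungapped length after a simple
    position-wise comparison of equal-length sequences, or over a global
    pairwise alignment length for unequal ones (done with Biopython).
    """
    from Bio import Align

    ids = sorted(sequences)
    n = len(ids)
    aligner = Align.PairwiseAligner(scoring="blastp")
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        parent[find(i)] = find(j)

    for i in range(n):
        for j in range(i + 1, n):
            s1, s2 = sequences[ids[i]], sequences[ids[j]]
            if len(s1) == len(s2):
                matches = sum(a == b for a, b in zip(s1, s2))
                ident = matches / len(s1) if len(s1) else 0.0
            else:
                aln = aligner.align(s1, s2)[0]
                a, b = str(aln[0]), str(aln[1])
                matches = sum(x == y and x != "-" for x, y in zip(a, b))
                ident = matches / min(len(s1), len(s2))
            if ident >= identity_threshold / 100.0:
                union(i, j)
    clusters: dict = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(ids[i])
    return sorted(min(members) for members in clusters.values())
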