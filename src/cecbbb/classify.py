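"""Electropherogram preprocessing and the time-series classifier stack.

Whole electropherogram traces (amplitude vs migration time) are treated as
fixed-length 1-D time series and assigned one of three BBB-permeability
classes derived from log BB cut-offs: class 0 poor (log BB <= -1), class 1
moderate, class 2 good (log BB >= 0.3). Two complementary classifiers are
provided as scikit-learn estimators - a shape-based k-NN using band-
constrained DTW and a motif-based BOSSVS model over SFA words - together
with a convex probability-level blend P_ens = w * P_kNN + (1 - w) * P_BOSSVS.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.metrics import (
    accuracy_score,
    auc,
    balanced_accuracy_score,
    confusion_matrix,
    f1_score,
    precision_score,
    recall_score,
    roc_curve,
)
from sklearn.utils.validation import check_is_fitted

from ._dtw import cross_dtw, dtw_distance, pairwise_dtw
from ._sfa import learn_breakpoints, max_word_length, quantize, sfa_words, window_fourier_features
from .exceptions import ConfigError, InvalidInputError

__all__ = [
    "LabelScheme",
    "Electropherogram",
    "preprocess",
    "preprocess_dataset",
    "label_from_logbb",
    "dtw_distance",
    "DtwKnnClassifier",
    "BossVSClassifier",
    "BlendedEnsembleClassifier",
    "knn_predict_proba",
    "blend",
    "tune_weight",
    "classification_metrics",
]


@dataclass(frozen=True)
class LabelScheme:
    """log BB cut-offs separating poor / moderate / good CNS permeability."""

    low_cut: float = -1.0
    high_cut: float = 0.3

    def __post_init__(self) -> None:
        if not self.low_cut < self.high_cut:
            raise InvalidInputError("low_cut must be below high_cut")


@dataclass
class Electropherogram:
    """A preprocessed trace with provenance."""

    compound_id: str
    signal: np.ndarray
    label: int | None = None
    index: np.ndarray | None = None  # original sample indices of kept points


def label_from_logbb(logbb: float, scheme: LabelScheme = LabelScheme()) -> int:
    """Class index from a log BB value (boundaries: <= low is 0, >= high is 2)."""
    if logbb is None or not math.isfinite(logbb):
        raise InvalidInputError(f"logbb must be finite, got {logbb!r}")
    if logbb <= scheme.low_cut:
        return 0
    if logbb >= scheme.high_cut:
        return 2
    return 1


def preprocess(raw_trace, trim_n: int = 100) -> Electropherogram:
    """Clean and z-normalize one raw trace.

    Non-numeric entries are coerced to NaN and removed, the first ``trim_n``
    points are dropped to suppress injection/early-baseline artifacts, and
    the remainder is z-normalized per sample (mean 0, population SD 1). An
    all-constant trace yields all zeros with a warning. The original sample
    indices of the retained points are kept for reporting.
    """
    s = pd.to_numeric(pd.Series(list(raw_trace)), errors="coerce")
    if len(s) <= trim_n + 2:
        raise InvalidInputError(
            f"trace of length {len(s)} too short for trim_n={trim_n}"
        )
    s = s.iloc[trim_n:].dropna()
    if len(s) < 2:
        raise InvalidInputError("fewer than 2 numeric points remain after cleaning")
    x = s.to_numpy(dtype=float)
    sd = x.std()  # population SD
    if sd == 0:
        warnings.warn("all-constant trace after trimming; returning zeros")
        z = np.zeros_like(x)
    else:
        z = (x - x.mean()) / sd
    return Electropherogram(
        compound_id="", signal=z, index=s.index.to_numpy()
    )


def preprocess_dataset(
    raw_traces, trim_n: int = 100, length_policy: str = "truncate"
) -> np.ndarray:
    """Preprocess a collection of traces into an equal-length 2-D array.

    Unequal cleaned lengths are right-truncated to the dataset minimum
    (default) or linearly resampled to it (``length_policy="resample"``).
    """
    cleaned = [preprocess(t, trim_n=trim_n).signal for t in raw_traces]
    min_len = min(len(c) for c in cleaned)
    if length_policy == "truncate":
        return np.stack([c[:min_len] for c in cleaned])
    if length_policy == "resample":
        grid = np.linspace(0.0, 1.0, min_len)
        return np.stack(
            [np.interp(grid, np.linspace(0.0, 1.0, len(c)), c) for c in cleaned]
        )
    raise ConfigError(f"unknown length_policy {length_policy!r}")


# ---------------------------------------------------------------------------
# k-NN with DTW
# ---------------------------------------------------------------------------


def _proba_from_distances(
    dist: np.ndarray, y_train: np.ndarray, classes: np.ndarray,
    n_neighbors: int, weights: str,
) -> np.ndarray:
    """Vote-fraction probabilities from a (n_query, n_train) distance matrix.

    Ties in neighbor distance are broken by stable input order; non-finite
    distances mark excluded candidates.
    """
    n_query, n_train = dist.shape
    usable = np.isfinite(dist).sum(axis=1).min()
    if n_neighbors > usable:
        raise ConfigError(
            f"n_neighbors={n_neighbors} exceeds the {usable} usable neighbors"
        )
    proba = np.zeros((n_query, classes.size))
    class_pos = {c: i for i, c in enumerate(classes)}
    for i in range(n_query):
        order = np.argsort(dist[i], kind="stable")
        order = order[np.isfinite(dist[i][order])][:n_neighbors]
        d = dist[i][order]
        if weights == "uniform":
            w = np.ones_like(d)
        elif weights == "distance":
            if np.any(d == 0):
                w = (d == 0).astype(float)
            else:
                w = 1.0 / d
        else:
            raise ConfigError(f"unknown vote weighting {weights!r}")
        for j, idx in enumerate(order):
            proba[i, class_pos[y_train[idx]]] += w[j]
        proba[i] /= proba[i].sum()
    return proba


class DtwKnnClassifier(ClassifierMixin, BaseEstimator):
    """k-nearest-neighbor classifier under band-constrained DTW.

    Parameters
    ----------
    n_neighbors : int
    weights : {"uniform", "distance"}
        Vote weighting; "distance" uses inverse DTW distance (exact matches
        absorb all weight).
    band_radius : int
        Sakoe-Chiba band half-width in samples.
    metric : {"dtw", "precomputed"}
        With "precomputed", ``fit`` ignores X's content beyond its row count
        and ``predict*`` expects an (n_query, n_train) distance matrix.
    """

    def __init__(self, n_neighbors: int = 3, weights: str = "uniform",
                 band_radius: int = 10, metric: str = "dtw"):
        self.n_neighbors = n_neighbors
        self.weights = weights
        self.band_radius = band_radius
        self.metric = metric

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise InvalidInputError("X must be 2-D and aligned with y")
        if self.n_neighbors < 1:
            raise ConfigError("n_neighbors must be >= 1")
        self.X_ = X
        self.y_ = y
        self.classes_ = np.unique(y)
        self.n_features_in_ = X.shape[1]
        return self

    def _distances(self, X) -> np.ndarray:
        if self.metric == "precomputed":
            D = np.asarray(X, dtype=float)
            if D.shape[1] != self.y_.shape[0]:
                raise InvalidInputError(
                    "precomputed distance matrix must have one column per "
                    "training sample"
                )
            return D
        return cross_dtw(np.asarray(X, float), self.X_, self.band_radius)

    def predict_proba(self, X):
        check_is_fitted(self, "X_")
        return _proba_from_distances(
            self._distances(X), self.y_, self.classes_,
            self.n_neighbors, self.weights,
        )

    def loo_predict_proba(self):
        """Leave-one-out probabilities on the training set.

        Each training sample is excluded from its own neighbor set, the
        leakage guard used whenever the training set predicts itself.
        """
        check_is_fitted(self, "X_")
        if self.metric == "precomputed":
            D = np.asarray(self.X_, dtype=float).copy()
        else:
            D = pairwise_dtw(self.X_, self.band_radius)
        np.fill_diagonal(D, np.inf)
        return _proba_from_distances(
            D, self.y_, self.classes_, self.n_neighbors, self.weights
        )

    def predict(self, X):
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]


def knn_predict_proba(
    train_X, train_y, query, *, n_neighbors=3, weights="uniform",
    band_radius=10, exclude_self=False,
) -> np.ndarray:
    """Class probabilities for one query trace (functional wrapper).

    With ``exclude_self``, a stored training sample identical to the query is
    removed from the neighbor candidates (leave-one-out semantics for
    training-set evaluation).
    """
    est = DtwKnnClassifier(
        n_neighbors=n_neighbors, weights=weights, band_radius=band_radius
    ).fit(np.asarray(train_X, float), np.asarray(train_y))
    q = np.asarray(query, dtype=float)[None, :]
    D = est._distances(q)
    if exclude_self:
        for j in range(est.X_.shape[0]):
            if np.array_equal(est.X_[j], q[0]):
                D[0, j] = np.inf
                break
    return _proba_from_distances(
        D, est.y_, est.classes_, n_neighbors, weights
    )[0]


# ---------------------------------------------------------------------------
# BOSSVS
# ---------------------------------------------------------------------------


class BossVSClassifier(ClassifierMixin, BaseEstimator):
    """Bag-of-SFA-Symbols in Vector Space classifier.

    Sliding windows of each training series are Fourier-transformed,
    quantized into SFA words (breakpoints learned from training windows by
    quantile binning), and counted per class. Class vectors are tf-idf
    weighted (log(1 + tf) times log(1 + n_classes/df)). A query is scored by
    cosine similarity of its own log(1 + tf) vector against each class
    vector; similarities are clipped at zero and normalized into
    pseudo-probabilities (uniform when all are zero).
    """

    def __init__(self, window_size: int = 64, word_length: int = 4,
                 n_bins: int = 4):
        self.window_size = window_size
        self.word_length = word_length
        self.n_bins = n_bins

    def _check_cfg(self, series_len: int) -> None:
        if self.word_length > self.window_size:
            raise ConfigError("word_length must not exceed window_size")
        if self.word_length > max_word_length(self.window_size):
            raise ConfigError(
                f"word_length {self.word_length} exceeds available Fourier "
                f"components of window_size {self.window_size}"
            )
        if self.n_bins < 2:
            raise ConfigError("n_bins must be >= 2")
        if self.window_size > series_len:
            raise ConfigError(
                f"window_size {self.window_size} exceeds series length {series_len}"
            )

    def _counts(self, signal: np.ndarray) -> dict[tuple, int]:
        words = sfa_words(signal, self.window_size, self.word_length,
                          self.breakpoints_)
        counts: dict[tuple, int] = {}
        for w in words:
            counts[w] = counts.get(w, 0) + 1
        return counts

    def fit(self, X, y, classes=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise InvalidInputError("X must be 2-D and aligned with y")
        self._check_cfg(X.shape[1])
        present = np.unique(y)
        if classes is not None:
            classes = np.asarray(classes)
            missing = set(classes.tolist()) - set(present.tolist())
            if missing:
                raise InvalidInputError(
                    f"training data lacks class(es) {sorted(missing)}"
                )
            self.classes_ = classes
        else:
            self.classes_ = present
        self.n_features_in_ = X.shape[1]

        all_feats = np.concatenate(
            [window_fourier_features(x, self.window_size, self.word_length)
             for x in X]
        )
        self.breakpoints_ = learn_breakpoints(all_feats, self.n_bins)

        per_series = [self._counts(x) for x in X]
        vocab = sorted({w for c in per_series for w in c})
        self.vocabulary_ = {w: i for i, w in enumerate(vocab)}
        n_classes = self.classes_.size
        tf = np.zeros((n_classes, len(vocab)))
        for counts, label in zip(per_series, y):
            ci = int(np.searchsorted(self.classes_, label))
            for w, c in counts.items():
                tf[ci, self.vocabulary_[w]] += c
        df = (tf > 0).sum(axis=0)
        self.idf_ = np.log1p(n_classes / np.maximum(df, 1))
        self.tfidf_ = np.log1p(tf) * self.idf_
        return self

    def _query_vector(self, signal: np.ndarray) -> np.ndarray:
        vec = np.zeros(len(self.vocabulary_))
        for w, c in self._counts(signal).items():
            i = self.vocabulary_.get(w)
            if i is not None:
                vec[i] = math.log1p(c)
        return vec

    def decision_function(self, X):
        """Cosine similarity to each class tf-idf vector."""
        check_is_fitted(self, "tfidf_")
        X = np.asarray(X, dtype=float)
        self._check_cfg(X.shape[1])
        norms = np.linalg.norm(self.tfidf_, axis=1)
        sims = np.zeros((X.shape[0], self.classes_.size))
        for i, x in enumerate(X):
            q = self._query_vector(x)
            qn = np.linalg.norm(q)
            if qn == 0:
                continue
            denom = norms * qn
            with np.errstate(invalid="ignore", divide="ignore"):
                s = (self.tfidf_ @ q) / denom
            sims[i] = np.where(np.isfinite(s), s, 0.0)
        return sims

    def predict_proba(self, X):
        sims = np.clip(self.decision_function(X), 0.0, None)
        totals = sims.sum(axis=1, keepdims=True)
        uniform = np.full(self.classes_.size, 1.0 / self.classes_.size)
        out = np.where(totals > 0, sims / np.where(totals == 0, 1, totals), uniform)
        return out

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


# ---------------------------------------------------------------------------
# Ensemble
# ---------------------------------------------------------------------------


def blend(p_knn: np.ndarray, p_bossvs: np.ndarray, omega: float) -> np.ndarray:
    """Convex probability blend w * P_kNN + (1 - w) * P_BOSSVS."""
    p_knn = np.asarray(p_knn, dtype=float)
    p_bossvs = np.asarray(p_bossvs, dtype=float)
    if p_knn.shape != p_bossvs.shape:
        raise InvalidInputError(
            f"probability shapes differ: {p_knn.shape} vs {p_bossvs.shape} "
            "(mismatched label sets?)"
        )
    if not (0.0 <= omega <= 1.0):
        raise InvalidInputError("omega must lie in [0, 1]")
    return omega * p_knn + (1.0 - omega) * p_bossvs


def default_omega_grid(step: float = 0.05) -> np.ndarray:
    return np.round(np.arange(0.0, 1.0 + step / 2, step), 10)


def tune_weight(
    oof_knn: np.ndarray, oof_bossvs: np.ndarray, labels, classes=None,
    grid: np.ndarray | None = None,
) -> float:
    """Ensemble weight maximizing weighted F1 of argmax-blended predictions.

    Ties are broken toward the smaller omega (the BOSSVS-heavy solution).
    """
    labels = np.asarray(labels)
    if classes is None:
        classes = np.unique(labels)
    grid = default_omega_grid() if grid is None else np.asarray(grid, float)
    if grid.size == 0:
        raise ConfigError("omega grid must be non-empty")
    if oof_knn.shape[0] != labels.shape[0]:
        raise InvalidInputError("OOF probability matrices must align with labels")
    best_omega, best_score = None, -np.inf
    for omega in np.sort(grid):
        pred = classes[np.argmax(blend(oof_knn, oof_bossvs, omega), axis=1)]
        score = f1_score(labels, pred, average="weighted", zero_division=0)
        if score > best_score:
            best_omega, best_score = float(omega), score
    return best_omega


class BlendedEnsembleClassifier(ClassifierMixin, BaseEstimator):
    """Probability-level convex blend of a DTW k-NN and a BOSSVS classifier.

    With omega in {0, 1} the ensemble reproduces the corresponding base
    classifier exactly.
    """

    def __init__(self, knn: DtwKnnClassifier | None = None,
                 bossvs: BossVSClassifier | None = None, omega: float = 0.5):
        self.knn = knn
        self.bossvs = bossvs
        self.omega = omega

    def fit(self, X, y):
        if not (0.0 <= self.omega <= 1.0):
            raise InvalidInputError("omega must lie in [0, 1]")
        self.knn_ = clone(self.knn) if self.knn is not None else DtwKnnClassifier()
        self.bossvs_ = clone(self.bossvs) if self.bossvs is not None else BossVSClassifier()
        self.knn_.fit(X, y)
        self.bossvs_.fit(X, y)
        if not np.array_equal(self.knn_.classes_, self.bossvs_.classes_):
            raise InvalidInputError("base classifiers disagree on the label set")
        self.classes_ = self.knn_.classes_
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "classes_")
        return blend(
            self.knn_.predict_proba(X), self.bossvs_.predict_proba(X), self.omega
        )

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def classification_metrics(y_true, y_pred, y_proba=None, classes=None) -> dict:
    """Standard multi-class metric bundle.

    Returns accuracy, balanced accuracy, weighted precision/recall/F1, a
    confusion matrix (rows = true classes), and one-vs-rest ROC curves with
    AUC per class when probabilities are supplied. Classes without both
    positive and negative examples in y_true are skipped from ROC with a
    warning.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape[0] != y_pred.shape[0]:
        raise InvalidInputError("y_true and y_pred lengths differ")
    if classes is None:
        classes = np.unique(np.concatenate([y_true, y_pred]))
    classes = np.asarray(classes)
    out = {
        "accuracy": float(accuracy_score(y_true, y_pred)),
        "balanced_accuracy": float(balanced_accuracy_score(y_true, y_pred)),
        "precision_weighted": float(
            precision_score(y_true, y_pred, average="weighted", zero_division=0)
        ),
        "recall_weighted": float(
            recall_score(y_true, y_pred, average="weighted", zero_division=0)
        ),
        "f1_weighted": float(
            f1_score(y_true, y_pred, average="weighted", zero_division=0)
        ),
        "confusion_matrix": confusion_matrix(y_true, y_pred, labels=classes),
        "classes": classes,
    }
    if y_proba is not None:
        y_proba = np.asarray(y_proba, dtype=float)
        roc: dict = {}
        for i, c in enumerate(classes):
            pos = y_true == c
            if pos.all() or not pos.any():
                warnings.warn(
                    f"ROC undefined for class {c}: only one outcome present"
                )
                continue
            fpr, tpr, _ = roc_curve(pos.astype(int), y_proba[:, i])
            roc[int(c)] = {"fpr": fpr, "tpr": tpr, "auc": float(auc(fpr, tpr))}
        out["roc"] = roc
    return out
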