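"""Nested stratified cross-validation of the blended trace classifier.

The outer loop is a stratified K-fold (default 5 folds, always capped by the
smallest class size) giving an unbiased performance estimate; within each
outer training split a stratified inner K-fold (up to 3 folds) tunes the
k-NN and BOSSVS hyperparameters by weighted F1, out-of-fold (OOF)
probability matrices are produced by refitting the selected base models on
inner training splits only, and the ensemble weight omega is tuned on those
OOF matrices before the blended model is refit on the full outer training
split and evaluated on the held-out outer fold. Everything is deterministic
given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import f1_score
from sklearn.model_selection import ParameterGrid, StratifiedGroupKFold, StratifiedKFold

from ._dtw import pairwise_dtw
from .classify import (
    BossVSClassifier,
    _proba_from_distances,
    blend,
    classification_metrics,
    default_omega_grid,
    tune_weight,
)
from .exceptions import ConfigError, StratificationError

DEFAULT_KNN_GRID = {
    "n_neighbors": [1, 3, 5],
    "weights": ["uniform", "distance"],
    "band_radius": [5, 10, 25],
}

DEFAULT_BOSSVS_GRID = {
    "window_size": [32, 64, 128],
    "word_length": [4, 6, 8],
    "n_bins": [3, 4],
}


@dataclass
class CvReport:
    """Per-fold and pooled results of a nested cross-validation run."""

    fold_metrics: list[dict]
    pooled: dict
    confusion_matrix: np.ndarray
    roc: dict
    fold_params: list[dict]
    classes: np.ndarray
    seed: int
    outer_folds: int

    def to_dict(self) -> dict:
        def _clean(m: dict) -> dict:
            out = {}
            for k, v in m.items():
                if k == "roc":
                    out[k] = {
                        c: {"fpr": r["fpr"].tolist(), "tpr": r["tpr"].tolist(),
                            "auc": r["auc"]}
                        for c, r in v.items()
                    }
                elif isinstance(v, np.ndarray):
                    out[k] = v.tolist()
                else:
                    out[k] = v
            return out

        return {
            "fold_metrics": [_clean(m) for m in self.fold_metrics],
            "pooled": _clean(self.pooled),
            "confusion_matrix": self.confusion_matrix.tolist(),
            "roc": _clean({"roc": self.roc})["roc"],
            "fold_params": self.fold_params,
            "classes": self.classes.tolist(),
            "seed": self.seed,
            "outer_folds": self.outer_folds,
        }


def _filter_bossvs_grid(grid: dict, series_len: int) -> list[dict]:
    configs = []
    for cfg in ParameterGrid(grid):
        w, l = cfg["window_size"], cfg["word_length"]
        if w <= series_len and l <= w and l <= 2 * (w // 2):
            configs.append(cfg)
    if not configs:
        raise ConfigError("no feasible BOSSVS configuration for this series length")
    return configs


def _knn_inner_score(dist, y, tr, va, cfg, classes) -> float:
    D = dist[cfg["band_radius"]][np.ix_(va, tr)]
    proba = _proba_from_distances(
        D, y[tr], classes, cfg["n_neighbors"], cfg["weights"]
    )
    pred = classes[np.argmax(proba, axis=1)]
    return f1_score(y[va], pred, average="weighted", zero_division=0)


def tune_base_models(
    X: np.ndarray,
    y: np.ndarray,
    knn_configs: list[dict],
    bossvs_configs: list[dict],
    inner_folds: int,
    seed: int,
    dist: dict[int, np.ndarray] | None = None,
    classes: np.ndarray | None = None,
):
    """Inner-CV hyperparameter selection on a training split only.

    Returns (best_knn_cfg, best_bossvs_cfg, inner_splits). ``dist`` may carry
    precomputed per-radius DTW distance matrices over exactly these samples;
    it is computed here otherwise, so the selection is a pure function of the
    training split.
    """
    if classes is None:
        classes = np.unique(y)
    counts = np.bincount(np.searchsorted(classes, y))
    k_inner = min(inner_folds, counts.min())
    if k_inner < 2:
        raise StratificationError(
            f"smallest class has {counts.min()} member(s); cannot form "
            "stratified inner folds"
        )
    if dist is None:
        radii = sorted({c["band_radius"] for c in knn_configs})
        dist = {r: pairwise_dtw(X, r) for r in radii}
    splits = list(
        StratifiedKFold(n_splits=k_inner, shuffle=True, random_state=seed)
        .split(np.zeros(len(y)), y)
    )

    best_knn, best_knn_score = None, -np.inf
    for cfg in knn_configs:
        score = float(np.mean(
            [_knn_inner_score(dist, y, tr, va, cfg, classes) for tr, va in splits]
        ))
        if score > best_knn_score:
            best_knn, best_knn_score = cfg, score

    best_bossvs, best_bossvs_score = None, -np.inf
    for cfg in bossvs_configs:
        scores = []
        for tr, va in splits:
            est = BossVSClassifier(**cfg).fit(X[tr], y[tr])
            pred = est.predict(X[va])
            scores.append(f1_score(y[va], pred, average="weighted", zero_division=0))
        score = float(np.mean(scores))
        if score > best_bossvs_score:
            best_bossvs, best_bossvs_score = cfg, score

    return best_knn, best_bossvs, splits


def _oof_probabilities(X, y, splits, knn_cfg, bossvs_cfg, dist, classes):
    """OOF probability matrices on a training split from inner refits."""
    n = len(y)
    oof_knn = np.zeros((n, classes.size))
    oof_bossvs = np.zeros((n, classes.size))
    for tr, va in splits:
        D = dist[knn_cfg["band_radius"]][np.ix_(va, tr)]
        p = _proba_from_distances(
            D, y[tr], classes, min(knn_cfg["n_neighbors"], len(tr)),
            knn_cfg["weights"],
        )
        # align inner-train classes (guaranteed complete by stratification)
        oof_knn[va] = p
        est = BossVSClassifier(**bossvs_cfg).fit(X[tr], y[tr], classes=classes)
        oof_bossvs[va] = est.predict_proba(X[va])
    return oof_knn, oof_bossvs


def nested_cv(
    X,
    y,
    knn_grid: dict | None = None,
    bossvs_grid: dict | None = None,
    *,
    outer_folds: int = 5,
    inner_folds: int = 3,
    omega_step: float = 0.05,
    seed: int = 42,
    groups=None,
) -> CvReport:
    """Nested stratified CV of the DTW k-NN + BOSSVS probability ensemble.

    ``groups`` optionally keeps all replicates of a compound within one outer
    fold (group-aware mode); by default repeated measurements are treated as
    independent samples.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    counts = np.bincount(np.searchsorted(classes, y))
    k_outer = min(outer_folds, counts.min())
    if k_outer < 2:
        raise StratificationError(
            f"smallest class has {counts.min()} member(s), fewer than the "
            f"2 required for stratified outer folds"
        )

    knn_configs = list(ParameterGrid(DEFAULT_KNN_GRID if knn_grid is None else knn_grid))
    bossvs_configs = _filter_bossvs_grid(
        DEFAULT_BOSSVS_GRID if bossvs_grid is None else bossvs_grid, X.shape[1]
    )
    omega_grid = default_omega_grid(omega_step)

    radii = sorted({c["band_radius"] for c in knn_configs})
    dist_full = {r: pairwise_dtw(X, r) for r in radii}

    if groups is not None:
        splitter = StratifiedGroupKFold(
            n_splits=k_outer, shuffle=True, random_state=seed
        )
        outer_splits = splitter.split(X, y, groups=groups)
    else:
        splitter = StratifiedKFold(n_splits=k_outer, shuffle=True, random_state=seed)
        outer_splits = splitter.split(X, y)

    fold_metrics, fold_params = [], []
    oof_true, oof_pred, oof_proba = [], [], []
    for fold_id, (train, test) in enumerate(outer_splits):
        dist_sub = {r: dist_full[r][np.ix_(train, train)] for r in radii}
        knn_cfg, bossvs_cfg, inner_splits = tune_base_models(
            X[train], y[train], knn_configs, bossvs_configs,
            inner_folds, seed, dist=dist_sub, classes=classes,
        )
        oof_knn, oof_bossvs = _oof_probabilities(
            X[train], y[train], inner_splits, knn_cfg, bossvs_cfg,
            dist_sub, classes,
        )
        omega = tune_weight(oof_knn, oof_bossvs, y[train], classes=classes,
                            grid=omega_grid)

        # refit on the full outer-training split, evaluate on the outer fold
        D_test = dist_full[knn_cfg["band_radius"]][np.ix_(test, train)]
        p_knn = _proba_from_distances(
            D_test, y[train], classes, knn_cfg["n_neighbors"], knn_cfg["weights"]
        )
        boss = BossVSClassifier(**bossvs_cfg).fit(X[train], y[train], classes=classes)
        p_boss = boss.predict_proba(X[test])
        p_ens = blend(p_knn, p_boss, omega)
        pred = classes[np.argmax(p_ens, axis=1)]

        fold_metrics.append(
            classification_metrics(y[test], pred, y_proba=p_ens, classes=classes)
        )
        fold_params.append(
            {"fold": fold_id, "knn": knn_cfg, "bossvs": bossvs_cfg, "omega": omega}
        )
        oof_true.append(y[test])
        oof_pred.append(pred)
        oof_proba.append(p_ens)

    y_true = np.concatenate(oof_true)
    y_pred = np.concatenate(oof_pred)
    y_proba = np.vstack(oof_proba)
    pooled = classification_metrics(y_true, y_pred, y_proba=y_proba, classes=classes)
    return CvReport(
        fold_metrics=fold_metrics,
        pooled={k: v for k, v in pooled.items() if k not in ("confusion_matrix", "roc", "classes")},
        confusion_matrix=pooled["confusion_matrix"],
        roc=pooled.get("roc", {}),
        fold_params=fold_params,
        classes=classes,
        seed=seed,
        outer_folds=k_outer,
    )
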