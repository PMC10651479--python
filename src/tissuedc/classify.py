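"""Diagnostic classifier: min-max scaling → 2-component PCA → logistic regression.

The sample feature matrix (size-stratified summary statistics per biopsy) is
scaled feature-wise to [0, 1] on the training cohort, projected onto its
first two principal components (singular value decomposition of the
mean-centred scaled matrix), and a logistic regression on (PC1, PC2)
separates healthy from pathological samples. Blind samples are pushed
through the frozen scaler/PCA/regression without refitting.

Also implements the two robustness analyses built on top of the classifier:
the minimum-cell-number subsampling curve and the tumour-fraction mixture
titration.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression

from .exceptions import ParameterError, SchemaError
from .featurize import FeaturizationConfig, summarize_sample, assemble_matrix

__all__ = [
    "TrainedClassifier",
    "Prediction",
    "fit_pipeline",
    "predict_samples",
    "feature_importance",
    "min_cells_curve",
    "mixture_titration",
    "DISEASE_LABEL",
    "HEALTHY_LABEL",
]

DISEASE_LABEL = "disease"
HEALTHY_LABEL = "healthy"
PROBABILITY_CUTOFF = 0.5


@dataclass
class TrainedClassifier:
    """Frozen scaler + PCA + logistic-regression parameters, serializable."""

    feature_names: list[str]
    col_min: np.ndarray
    col_max: np.ndarray
    pca_mean: np.ndarray
    loadings: np.ndarray            # (2, n_features)
    explained_variance_ratio: np.ndarray
    lr_coef: np.ndarray             # (2,)
    lr_intercept: float
    classes: list[str]              # [negative, positive]; positive = disease
    seed: int = 0
    config_hash: str = ""

    # -- transformation -----------------------------------------------------
    def scale(self, matrix: np.ndarray) -> np.ndarray:
        """Training min-max scaling; blind values may leave [0, 1] (not clipped)."""
        span = self.col_max - self.col_min
        scaled = np.zeros_like(matrix, dtype=float)
        ok = span > 0
        scaled[:, ok] = (matrix[:, ok] - self.col_min[ok]) / span[ok]
        return scaled

    def project(self, matrix: np.ndarray) -> np.ndarray:
        return (self.scale(matrix) - self.pca_mean) @ self.loadings.T

    # -- persistence --------------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "feature_names": self.feature_names,
            "col_min": self.col_min.tolist(),
            "col_max": self.col_max.tolist(),
            "pca_mean": self.pca_mean.tolist(),
            "loadings": self.loadings.tolist(),
            "explained_variance_ratio": self.explained_variance_ratio.tolist(),
            "lr_coef": self.lr_coef.tolist(),
            "lr_intercept": self.lr_intercept,
            "classes": self.classes,
            "seed": self.seed,
            "config_hash": self.config_hash,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "TrainedClassifier":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        return cls(
            feature_names=d["feature_names"],
            col_min=np.asarray(d["col_min"], dtype=float),
            col_max=np.asarray(d["col_max"], dtype=float),
            pca_mean=np.asarray(d["pca_mean"], dtype=float),
            loadings=np.asarray(d["loadings"], dtype=float),
            explained_variance_ratio=np.asarray(d["explained_variance_ratio"], dtype=float),
            lr_coef=np.asarray(d["lr_coef"], dtype=float),
            lr_intercept=float(d["lr_intercept"]),
            classes=d["classes"],
            seed=int(d.get("seed", 0)),
            config_hash=d.get("config_hash", ""),
        )


@dataclass
class Prediction:
    """Classifier output for one sample."""

    sample_id: str
    pc1: float
    pc2: float
    probability: float              # probability of the disease class
    label: str = field(init=False)

    def __post_init__(self) -> None:
        self.label = DISEASE_LABEL if self.probability >= PROBABILITY_CUTOFF else HEALTHY_LABEL


def _as_matrix(matrix: pd.DataFrame | np.ndarray,
               feature_names: Sequence[str] | None = None
               ) -> tuple[np.ndarray, list[str], list[str]]:
    if isinstance(matrix, pd.DataFrame):
        return (matrix.to_numpy(dtype=float), list(matrix.columns),
                [str(i) for i in matrix.index])
    arr = np.asarray(matrix, dtype=float)
    names = list(feature_names) if feature_names else [f"p{i}" for i in range(arr.shape[1])]
    return arr, names, [f"sample{i}" for i in range(arr.shape[0])]


def fit_pipeline(matrix: pd.DataFrame | np.ndarray, labels: Sequence[str],
                 seed: int = 0) -> TrainedClassifier:
    """Fit scaler, PCA and logistic regression on a labelled training cohort.

    Labels are binarized as disease vs. everything else; at least two samples
    of each class are required. Constant columns scale to 0 with a warning in
    the model (they carry no information and are excluded from importance).
    """
    X, names, _ = _as_matrix(matrix)
    y = np.asarray([DISEASE_LABEL if lbl == DISEASE_LABEL else HEALTHY_LABEL
                    for lbl in labels])
    if X.ndim != 2 or X.shape[0] != len(y):
        raise ParameterError("matrix rows and labels must align")
    if np.isnan(X).any():
        raise ParameterError("matrix contains missing values; impute before fitting")
    counts = pd.Series(y).value_counts()
    if len(counts) < 2 or counts.min() < 2:
        raise ParameterError(
            f"need >= 2 samples per class, got {counts.to_dict()}")

    col_min = X.min(axis=0)
    col_max = X.max(axis=0)
    span = col_max - col_min
    scaled = np.zeros_like(X)
    ok = span > 0
    scaled[:, ok] = (X[:, ok] - col_min[ok]) / span[ok]

    pca = PCA(n_components=2, svd_solver="full", random_state=seed)
    scores = pca.fit_transform(scaled)
    loadings = pca.components_.copy()
    # sign convention: largest-magnitude loading of each component positive
    for k in range(2):
        j = int(np.argmax(np.abs(loadings[k])))
        if loadings[k, j] < 0:
            loadings[k] *= -1.0
            scores[:, k] *= -1.0

    # L2 penalty at fixed strength C=1 (sklearn default), deterministic lbfgs
    lr = LogisticRegression(C=1.0, solver="lbfgs",
                            max_iter=1000, random_state=seed)
    lr.fit(scores, (y == DISEASE_LABEL).astype(int))

    return TrainedClassifier(
        feature_names=names,
        col_min=col_min,
        col_max=col_max,
        pca_mean=pca.mean_.copy(),
        loadings=loadings,
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        lr_coef=lr.coef_.ravel().copy(),
        lr_intercept=float(lr.intercept_[0]),
        classes=[HEALTHY_LABEL, DISEASE_LABEL],
        seed=seed,
        config_hash=hashlib.sha256(
            json.dumps(names).encode()).hexdigest()[:16],
    )


def predict_samples(model: TrainedClassifier,
                    matrix: pd.DataFrame | np.ndarray) -> list[Prediction]:
    """Score blind samples through the frozen scaler/PCA/regression."""
    X, names, ids = _as_matrix(matrix, model.feature_names)
    if names != model.feature_names:
        raise SchemaError(
            "blind matrix columns do not match training features; "
            f"mismatch: {sorted(set(names) ^ set(model.feature_names))[:6]}")
    scores = model.project(X)
    logits = scores @ model.lr_coef + model.lr_intercept
    probs = 1.0 / (1.0 + np.exp(-logits))
    return [Prediction(sample_id=i, pc1=float(s[0]), pc2=float(s[1]),
                       probability=float(p))
            for i, s, p in zip(ids, scores, probs)]


def feature_importance(model: TrainedClassifier) -> pd.DataFrame:
    """Per-parameter |loading|, normalized to max 1 within each component.

    Constant training columns (zero scale span) get importance 0.
    """
    imp = np.abs(model.loadings.copy())
    span = model.col_max - model.col_min
    imp[:, span <= 0] = 0.0
    for k in range(imp.shape[0]):
        m = imp[k].max()
        if m > 0:
            imp[k] /= m
    return pd.DataFrame(imp.T, index=model.feature_names, columns=["PC1", "PC2"])


def _predict_events(model: TrainedClassifier, events: pd.DataFrame,
                    cfg: FeaturizationConfig, sample_id: str) -> Prediction:
    vec = summarize_sample(events, cfg, sample_id=sample_id)
    matrix, _ = assemble_matrix([vec])
    return predict_samples(model, matrix)[0]


def min_cells_curve(events_by_sample: dict[str, pd.DataFrame],
                    true_labels: dict[str, str],
                    model: TrainedClassifier, cfg: FeaturizationConfig,
                    n_grid: Sequence[int], reps: int = 20,
                    seed: int = 0) -> pd.DataFrame:
    """Classification accuracy versus number of analysed cells.

    For each n in ``n_grid``, subsample n events without replacement from
    every sample (``reps`` times), re-featurize, predict, and report the
    fraction of correct predictions. Grid points exceeding a sample's size
    are skipped for that sample.
    """
    if reps < 1:
        raise ParameterError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for n in n_grid:
        correct = total = 0
        for sid, events in events_by_sample.items():
            if n > len(events):
                continue
            for _ in range(reps):
                idx = rng.choice(len(events), size=n, replace=False)
                pred = _predict_events(model, events.iloc[idx], cfg, sid)
                correct += int(pred.label == true_labels[sid])
                total += 1
        if total:
            rows.append({"n_cells": int(n), "accuracy": correct / total,
                         "n_predictions": total})
    return pd.DataFrame(rows)


def mixture_titration(healthy_events: pd.DataFrame,
                      disease_events: pd.DataFrame,
                      fractions: Sequence[float],
                      model: TrainedClassifier, cfg: FeaturizationConfig,
                      seed: int = 0,
                      n_pool: int | None = None) -> pd.DataFrame:
    """Predict pooled samples mixing disease and healthy events.

    For each fraction f the pool holds f·n disease + (1−f)·n healthy events
    (n = ``n_pool`` or the smaller table's size), emulating a biopsy with
    partial tumour content.
    """
    if len(healthy_events) == 0 or len(disease_events) == 0:
        raise ParameterError("both event pools must be non-empty")
    for f in fractions:
        if not 0.0 <= f <= 1.0:
            raise ParameterError(f"fractions must lie in [0,1], got {f}")
    n = n_pool or min(len(healthy_events), len(disease_events))
    rng = np.random.default_rng(seed)
    rows = []
    for f in fractions:
        n_dis = int(round(f * n))
        n_hea = n - n_dis
        parts = []
        if n_dis:
            parts.append(disease_events.iloc[
                rng.choice(len(disease_events), size=n_dis, replace=False)])
        if n_hea:
            parts.append(healthy_events.iloc[
                rng.choice(len(healthy_events), size=n_hea, replace=False)])
        pooled = pd.concat(parts, ignore_index=True)
        pred = _predict_events(model, pooled, cfg, f"mix{f:.2f}")
        rows.append({"fraction": float(f), "probability": pred.probability,
                     "label": pred.label, "n_events": n})
    return pd.DataFrame(rows)
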