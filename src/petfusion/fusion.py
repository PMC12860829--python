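"""Feature fusion and the gradient-boosted multiclass classifier.

Selected radiomics columns and the top-ranked latent dimensions from the
two network channels are concatenated in specification order (radiomics,
then local, then global latents), with the latent blocks z-scored against
training-cohort statistics.  The classifier is an XGBoost ensemble with a
softmax multiclass objective (soft-probability variant so per-subject
confidences exist) at the configured hyperparameters: learning rate 0.025,
gamma 0.1, max depth 6, L2 lambda 2, with early stopping on a held-out
validation fold.  Metrics are macro-averaged one-vs-rest.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn import metrics as skm
from sklearn.model_selection import train_test_split

from .selection import FusedFeatureSpec

__all__ = ["ClassifierSpec", "FusedMatrix", "MetricsReport", "fuse_features",
           "train_classifier", "predict_proba", "evaluate", "FusionModel"]


@dataclass(frozen=True)
class ClassifierSpec:
    objective: str = "multi:softprob"
    learning_rate: float = 0.025
    gamma: float = 0.1
    max_depth: int = 6
    reg_lambda: float = 2.0
    n_estimators: int = 200
    early_stopping_rounds: int = 20
    validation_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.max_depth < 1:
            raise ValueError("max depth must be >= 1")


@dataclass
class FusedMatrix:
    data: pd.DataFrame
    labels: np.ndarray
    spec: FusedFeatureSpec
    latent_stats: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.data.isna().any().any():
            raise ValueError("fused matrix contains missing values")
        if list(self.data.columns) != self.spec.columns:
            raise ValueError("fused matrix columns do not match the specification")


@dataclass
class MetricsReport:
    confusion: np.ndarray
    classes: list[str]
    accuracy: float
    macro_auc: float
    per_class_auc: dict[str, float]
    macro_recall: float
    macro_precision: float
    macro_f1: float

    def to_dict(self) -> dict:
        return {
            "classes": self.classes,
            "confusion": np.asarray(self.confusion).tolist(),
            "accuracy": self.accuracy,
            "macro_auc": self.macro_auc,
            "per_class_auc": self.per_class_auc,
            "macro_recall": self.macro_recall,
            "macro_precision": self.macro_precision,
            "macro_f1": self.macro_f1,
        }


def fuse_features(selected_radiomics: pd.DataFrame,
                  local_latents: pd.DataFrame | None,
                  global_latents: pd.DataFrame | None,
                  spec: FusedFeatureSpec,
                  labels=None,
                  latent_stats: pd.DataFrame | None = None):
    """Column-wise concatenation in spec order; latents z-scored to training stats.

    When ``latent_stats`` is None the statistics are computed from the given
    blocks (training mode) and returned inside the :class:`FusedMatrix` for
    reuse on evaluation cohorts.
    """
    blocks = []
    missing = [c for c in spec.radiomics if c not in selected_radiomics.columns]
    if missing:
        raise KeyError(f"missing radiomics columns: {missing}")
    blocks.append(selected_radiomics[spec.radiomics])
    index = selected_radiomics.index

    latent_cols = list(spec.local) + list(spec.global_)
    lat_parts = []
    for cols, block in ((spec.local, local_latents), (spec.global_, global_latents)):
        if not cols:
            continue
        if block is None:
            raise KeyError(f"latent block missing for spec columns {list(cols)}")
        if not block.index.equals(index):
            raise ValueError("subject mismatch between feature blocks")
        miss = [c for c in cols if c not in block.columns]
        if miss:
            raise KeyError(f"missing latent columns: {miss}")
        lat_parts.append(block[list(cols)])
    if lat_parts:
        lat = pd.concat(lat_parts, axis=1)
        if latent_stats is None:
            mu = lat.mean(axis=0)
            sd = lat.std(axis=0, ddof=0).replace(0.0, 1.0)
            latent_stats = pd.DataFrame({"mean": mu, "sd": sd})
        z = (lat - latent_stats["mean"]) / latent_stats["sd"]
        blocks.append(z)
    data = pd.concat(blocks, axis=1)[spec.columns] if latent_cols else blocks[0]
    y = np.asarray(labels) if labels is not None else np.asarray([None] * len(index))
    return FusedMatrix(data=data, labels=y, spec=spec, latent_stats=latent_stats)


class FusionModel:
    """Trained XGBoost classifier plus its label encoding and feature spec."""

    def __init__(self, booster, classes: list[str], columns: list[str], spec: ClassifierSpec):
        self.booster = booster
        self.classes = classes
        self.columns = columns
        self.spec = spec

    def predict_proba(self, data) -> np.ndarray:
        if isinstance(data, pd.DataFrame):
            if list(data.columns) != self.columns:
                raise ValueError("feature columns do not match the training specification")
        elif np.asarray(data).shape[1] != len(self.columns):
            raise ValueError("feature count does not match the training specification")
        return self.booster.predict_proba(np.asarray(data, dtype=np.float32))

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        proba = self.predict_proba(data)
        return np.asarray([self.classes[i] for i in proba.argmax(axis=1)])


def train_classifier(matrix: FusedMatrix, labels=None,
                     spec: ClassifierSpec = ClassifierSpec()) -> FusionModel:
    import xgboost as xgb

    y = np.asarray(labels if labels is not None else matrix.labels)
    classes = [str(c) for c in sorted(set(y))]
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    if matrix.data.isna().any().any():
        raise ValueError("NaN features")
    lut = {c: i for i, c in enumerate(classes)}
    yi = np.asarray([lut[v] for v in y])
    X = np.asarray(matrix.data, dtype=np.float32)
    n = len(yi)
    use_es = spec.validation_fraction > 0 and n >= 30 and min(np.bincount(yi)) >= 5
    kwargs = dict(objective="multi:softprob", num_class=len(classes),
                  learning_rate=spec.learning_rate, gamma=spec.gamma,
                  max_depth=spec.max_depth, reg_lambda=spec.reg_lambda,
                  n_estimators=spec.n_estimators, random_state=spec.seed,
                  n_jobs=1, tree_method="hist", eval_metric="mlogloss")
    if use_es:
        xtr, xva, ytr, yva = train_test_split(X, yi, test_size=spec.validation_fraction,
                                              random_state=spec.seed, stratify=yi)
        model = xgb.XGBClassifier(early_stopping_rounds=spec.early_stopping_rounds, **kwargs)
        model.fit(xtr, ytr, eval_set=[(xva, yva)], verbose=False)
    else:
        model = xgb.XGBClassifier(**kwargs)
        model.fit(X, yi)
    return FusionModel(model, classes, list(matrix.data.columns), spec)


def predict_proba(model: FusionModel, matrix: FusedMatrix) -> np.ndarray:
    return model.predict_proba(matrix.data)


def evaluate(model: FusionModel, matrix: FusedMatrix, labels=None) -> MetricsReport:
    """Confusion matrix, accuracy and macro one-vs-rest AUC/recall/precision/F1."""
    y = np.asarray(labels if labels is not None else matrix.labels)
    unknown = set(y) - set(model.classes)
    if unknown:
        raise ValueError(f"unknown labels: {sorted(unknown)}")
    proba = model.predict_proba(matrix.data)
    pred = np.asarray([model.classes[i] for i in proba.argmax(axis=1)])
    cm = skm.confusion_matrix(y, pred, labels=model.classes)
    acc = float(np.trace(cm) / cm.sum())
    onehot = np.stack([(y == c).astype(int) for c in model.classes], axis=1)
    per_auc = {}
    aucs = []
    for i, c in enumerate(model.classes):
        if onehot[:, i].min() == onehot[:, i].max():
            continue
        a = float(skm.roc_auc_score(onehot[:, i], proba[:, i]))
        per_auc[c] = a
        aucs.append(a)
    macro_auc = float(np.mean(aucs)) if aucs else float("nan")
    return MetricsReport(
        confusion=cm, classes=list(model.classes), accuracy=acc, macro_auc=macro_auc,
        per_class_auc=per_auc,
        macro_recall=float(skm.recall_score(y, pred, average="macro", zero_division=0)),
        macro_precision=float(skm.precision_score(y, pred, average="macro", zero_division=0)),
        macro_f1=float(skm.f1_score(y, pred, average="macro", zero_division=0)),
    )
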