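"""The eleven classifier configurations and their training protocol.

Six multilayer perceptrons (two architectures x three activations),
four support-vector machines (one per kernel), and one random forest:

* ANN1-* : hidden layers (25, 25, 25); ANN2-* : (30, 20, 10, 5);
  activations logistic / tanh / relu; Adam optimizer, initial learning
  rate 0.001, up to 1000 epochs with early stopping (10% validation
  split, tolerance 1e-4).
* SVM-* : C = 1.0, kernels linear / polynomial (degree 3) / RBF /
  sigmoid, gamma "scale"; probability-like scores via Platt-style
  calibration fitted on training folds.
* RF : 100 trees, Gini split criterion, bootstrap sampling.

Continuous features are standardized (zero mean, unit variance) for the
ANN and SVM families, whose objectives are scale-sensitive; the forest
sees raw features. Standardization parameters are always fitted on the
training portion only.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Optional

import joblib
import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .metrics import EvalReport, mean_report, metric_suite
from .splits import make_cv_folds

_ANN_LAYERS = {"ANN1": (25, 25, 25), "ANN2": (30, 20, 10, 5)}
_ANN_ACTIVATIONS = {"Logistic": "logistic", "Tanh": "tanh", "ReLU": "relu"}
_SVM_KERNELS = {"Linear": "linear", "Polynomial": "poly", "Gaussian": "rbf", "Sigmoid": "sigmoid"}

MODEL_IDS = (
    "ANN1-Logistic",
    "ANN2-Logistic",
    "ANN1-Tanh",
    "ANN2-Tanh",
    "ANN1-ReLU",
    "ANN2-ReLU",
    "SVM-Linear",
    "SVM-Polynomial",
    "SVM-Gaussian",
    "SVM-Sigmoid",
    "RF",
)


@dataclass(frozen=True)
class ModelConfig:
    model_id: str
    family: str
    hyperparameters: dict = field(default_factory=dict)


def enumerate_model_configs() -> list:
    """The closed list of eleven configurations, in stable order."""
    configs = []
    for mid in MODEL_IDS:
        if mid.startswith("ANN"):
            arch, act = mid.split("-")
            configs.append(
                ModelConfig(
                    mid,
                    "ANN",
                    {
                        "hidden_layer_sizes": _ANN_LAYERS[arch],
                        "activation": _ANN_ACTIVATIONS[act],
                        "solver": "adam",
                        "learning_rate_init": 0.001,
                        "max_iter": 1000,
                        "early_stopping": True,
                        "validation_fraction": 0.1,
                        "tol": 1e-4,
                        # patience sized for small-sample training: the
                        # validation score is quantized in ~4-point steps on
                        # a 27-row split and plateaus for hundreds of epochs
                        # before the loss starts moving
                        "n_iter_no_change": 400,
                    },
                )
            )
        elif mid.startswith("SVM"):
            kernel = _SVM_KERNELS[mid.split("-")[1]]
            hp = {"kernel": kernel, "C": 1.0, "gamma": "scale"}
            if kernel == "poly":
                hp["degree"] = 3
            configs.append(ModelConfig(mid, "SVM", hp))
        else:
            configs.append(
                ModelConfig(
                    mid,
                    "RF",
                    {"n_estimators": 100, "criterion": "gini", "bootstrap": True},
                )
            )
    return configs


def get_config(model_id: str) -> ModelConfig:
    for c in enumerate_model_configs():
        if c.model_id == model_id:
            return c
    raise KeyError(f"unknown model_id {model_id!r}; known: {list(MODEL_IDS)}")


def _build_estimator(config: ModelConfig, seed: int) -> Pipeline:
    if config.family == "ANN":
        est = MLPClassifier(random_state=seed, **config.hyperparameters)
        return Pipeline([("scale", StandardScaler()), ("clf", est)])
    if config.family == "SVM":
        # Platt-style sigmoid calibration fitted on training folds maps
        # decision values to probability-like scores; AUC is invariant to
        # the monotone mapping.
        est = CalibratedClassifierCV(
            SVC(random_state=seed, **config.hyperparameters),
            method="sigmoid",
            cv=5,
            ensemble=False,
        )
        return Pipeline([("scale", StandardScaler()), ("clf", est)])
    if config.family == "RF":
        est = RandomForestClassifier(random_state=seed, **config.hyperparameters)
        return Pipeline([("clf", est)])
    raise ValueError(f"unknown family {config.family!r}")


@dataclass
class FittedModel:
    config: ModelConfig
    pipeline: Pipeline
    feature_names: list
    seed: int
    trained_at: float = 0.0

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "FittedModel":
        return joblib.load(path)


def train_model(config: ModelConfig, X, y, seed: int = 0) -> FittedModel:
    """Fit one configuration; preprocessing fitted on the training data only."""
    X = pd.DataFrame(X)
    y = np.asarray(y)
    if len(X) == 0:
        raise ValueError("empty training set")
    if len(np.unique(y)) < 2:
        raise ValueError("training set contains a single class")
    pipe = _build_estimator(config, seed)
    pipe.fit(X.values, y)
    return FittedModel(
        config=config,
        pipeline=pipe,
        feature_names=list(X.columns),
        seed=seed,
        trained_at=time.time(),
    )


def predict_scores(model: FittedModel, X) -> np.ndarray:
    """Positive-class score in [0, 1] per row."""
    X = pd.DataFrame(X)
    if len(X) == 0:
        raise ValueError("empty feature set")
    if list(X.columns) != model.feature_names:
        raise ValueError("feature columns do not match the model's training registry")
    proba = model.pipeline.predict_proba(X.values)
    classes = list(model.pipeline.classes_)
    return proba[:, classes.index(1)]


def cross_validate(
    config: ModelConfig,
    X,
    y,
    k: int = 5,
    seed: int = 0,
    threshold: float = 0.5,
) -> list:
    """k-fold CV; each fold's model (and its scaler) fit on that fold's train part.

    Returns one EvalReport per fold (surface "cv_fold_<i>").
    """
    X = pd.DataFrame(X)
    y = pd.Series(np.asarray(y), index=X.index)
    folds = make_cv_folds(list(X.index), k=k, seed=seed)
    reports = []
    for i, fold in enumerate(folds):
        val_idx = list(fold)
        train_idx = [ix for f in folds for ix in f if f is not fold]
        try:
            fitted = train_model(config, X.loc[train_idx], y.loc[train_idx], seed=seed)
            scores = predict_scores(fitted, X.loc[val_idx])
            reports.append(
                metric_suite(
                    y.loc[val_idx].values,
                    scores,
                    threshold=threshold,
                    model_id=config.model_id,
                    surface=f"cv_fold_{i}",
                    seed=seed,
                )
            )
        except ValueError as exc:
            raise ValueError(f"{config.model_id} fold {i}: {exc}") from exc
    return reports


def cv_mean(reports, model_id: str) -> EvalReport:
    return mean_report(reports, model_id=model_id, surface="cv_mean")


__all__ = [
    "MODEL_IDS",
    "ModelConfig",
    "FittedModel",
    "enumerate_model_configs",
    "get_config",
    "train_model",
    "predict_scores",
    "cross_validate",
    "cv_mean",
]
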