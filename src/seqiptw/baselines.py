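"""Feature-based propensity baselines: logistic regression and MLP.

Both operate on a standardized :class:`~seqiptw.features.FeatureMatrix`
(counts, counts+recurrence, or HDPS-selected) and are fit against the binary
treatment label.  scikit-learn provides the underlying estimators; this
module pins the seeding and output contracts (probabilities strictly inside
(0, 1), deterministic refits under a fixed seed).
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier

from .features import FeatureMatrix

__all__ = ["BaselineSpec", "BaselinePropensityModel", "fit_baseline", "predict_propensity"]

_EPS = 1e-7  # keep predictions strictly inside (0,1) for inverse weighting


@dataclass(frozen=True)
class BaselineSpec:
    kind: str = "logistic"  # logistic | mlp
    feature_mode: str = "counts"  # counts | counts+recurrence | hdps_selected
    hidden_sizes: tuple[int, ...] = (64, 32)
    l2: float = 1e-4
    learning_rate: float = 1e-3
    epochs: int = 200
    batch_size: int = 128
    patience: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("logistic", "mlp"):
            raise ValueError(f"unknown baseline kind {self.kind!r}")
        if self.kind == "mlp" and any(h < 1 for h in self.hidden_sizes):
            raise ValueError("hidden sizes must be positive")


@dataclass
class BaselinePropensityModel:
    spec: BaselineSpec
    estimator: object
    n_features: int
    feature_names: list[str] = field(default_factory=list)

    def predict(self, features: FeatureMatrix | np.ndarray) -> np.ndarray:
        return predict_propensity(self, features)

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @classmethod
    def load(cls, path) -> "BaselinePropensityModel":
        with open(path, "rb") as fh:
            return pickle.load(fh)


def fit_baseline(spec: BaselineSpec, features: FeatureMatrix, A) -> BaselinePropensityModel:
    A = np.asarray(A, dtype=np.int64)
    if set(np.unique(A)) != {0, 1}:
        raise ValueError("treatment must contain both classes (propensity undefined)")
    X = features.values
    if spec.kind == "logistic":
        est = LogisticRegression(
            C=1.0 / max(spec.l2, 1e-12) / X.shape[0],
            max_iter=2000,
            solver="lbfgs",
            random_state=spec.seed,
        )
    else:
        est = MLPClassifier(
            hidden_layer_sizes=spec.hidden_sizes,
            activation="relu",
            solver="adam",
            alpha=spec.l2,
            learning_rate_init=spec.learning_rate,
            batch_size=min(spec.batch_size, X.shape[0]),
            max_iter=spec.epochs,
            # loss-convergence stopping: accuracy-based validation stopping
            # halts as soon as the held-out split is perfectly classified,
            # leaving probabilities uncalibrated on separable data
            early_stopping=False,
            n_iter_no_change=max(spec.patience, 10),
            tol=1e-5,
            random_state=spec.seed,
        )
    est.fit(X, A)
    return BaselinePropensityModel(
        spec=spec, estimator=est, n_features=X.shape[1],
        feature_names=list(features.feature_names),
    )


def predict_propensity(model: BaselinePropensityModel, features) -> np.ndarray:
    X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError(
            f"feature dimension {X.shape} does not match fitted dimension {model.n_features}"
        )
    p = model.estimator.predict_proba(X)[:, 1]
    return np.clip(p, _EPS, 1.0 - _EPS)
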