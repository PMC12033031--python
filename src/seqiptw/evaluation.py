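"""Metrics and the cross-validation experiment harness.

Per held-out fold the harness reports five metrics: propensity-score MAE,
true-propensity-weighted PS MAE, and the absolute ATE error of the raw,
trimmed and clipped IPTW estimators.  Fold means are summarized with 95%
Student-t confidence intervals.

Feature construction for the baselines (count summation, recurrence
thresholds, standardization statistics) uses the entire dataset, mirroring
the convention of standardizing with whole-dataset moments; the label-using
Bross ranking step is fit on training folds only.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .baselines import BaselineSpec, fit_baseline
from .data import ClaimsDataset
from .features import (
    FeatureMatrix,
    HdpsConfig,
    bross_rank,
    count_features,
    recurrence_features,
    standardize,
)
from .iptw import estimate_ate, estimate_ate_clipped, estimate_ate_trimmed
from .models import SeqModelConfig, train_sequence_model

__all__ = [
    "mae_ps",
    "weighted_mae_ps",
    "ate_mae",
    "ConstantPropensity",
    "BaselinePipeline",
    "fit_propensity_model",
    "kfold_indices",
    "EvalReport",
    "run_cv_experiment",
]

METRICS = ("ps_mae", "ps_mae_weighted", "ate_mae", "ate_mae_trimmed", "ate_mae_clipped")


def mae_ps(e, e_hat) -> float:
    """Mean absolute error between true and estimated propensity scores."""
    e, e_hat = np.asarray(e, float), np.asarray(e_hat, float)
    if e.shape != e_hat.shape or e.size == 0:
        raise ValueError("e and e_hat must be equal-length nonempty vectors")
    return float(np.mean(np.abs(e - e_hat)))


def weighted_mae_ps(e, e_hat) -> float:
    """PS MAE weighted by the true propensity (divisor M, not the weight sum),
    emphasizing severely confounded samples."""
    e, e_hat = np.asarray(e, float), np.asarray(e_hat, float)
    if e.shape != e_hat.shape or e.size == 0:
        raise ValueError("e and e_hat must be equal-length nonempty vectors")
    return float(np.mean(e * np.abs(e - e_hat)))


def ate_mae(delta_hat: float, tau: float) -> float:
    return float(abs(delta_hat - tau))


class ConstantPropensity:
    """Predicts the treated fraction of its training data for everyone —
    the analytic floor baseline."""

    def __init__(self, rate: float):
        if not (0.0 < rate < 1.0):
            raise ValueError("rate must lie in (0,1)")
        self.rate = rate

    @classmethod
    def fit(cls, ds: ClaimsDataset) -> "ConstantPropensity":
        return cls(float(ds.treatment().mean()))

    def predict(self, ds: ClaimsDataset) -> np.ndarray:
        return np.full(len(ds), self.rate)


class BaselinePipeline:
    """Feature pipeline + estimator for the non-sequence baselines.

    ``feature_mode``: ``counts`` (standardized per-code counts),
    ``counts+recurrence`` (counts plus all HDPS recurrence indicators —
    HDPS without feature selection), or ``hdps_selected`` (counts plus the
    Bross-top-k recurrence indicators, ranking fit on the training fold).
    """

    def __init__(self, spec: BaselineSpec, hdps: HdpsConfig | None = None):
        self.spec = spec
        self.hdps = hdps or HdpsConfig()
        self._fitted = False

    # -- feature construction ---------------------------------------------

    def fit_features(self, stats_ds: ClaimsDataset) -> None:
        """Learn thresholds and standardization moments from ``stats_ds``."""
        counts = count_features(stats_ds)
        if self.spec.feature_mode == "counts":
            raw = counts
        else:
            rec = recurrence_features(counts)
            self._rec_thresholds = rec.thresholds
            raw = FeatureMatrix(
                np.hstack([counts.values, rec.values]),
                counts.feature_names + rec.feature_names,
            )
        std = standardize(raw)
        self._mu, self._sigma = std.mu, std.sigma
        self._feature_names = raw.feature_names
        self._n_counts = counts.values.shape[1]

    def transform(self, ds: ClaimsDataset) -> FeatureMatrix:
        counts = count_features(ds)
        if self.spec.feature_mode == "counts":
            raw = counts
        else:
            rec = recurrence_features(counts, thresholds=self._rec_thresholds)
            raw = FeatureMatrix(
                np.hstack([counts.values, rec.values]),
                counts.feature_names + rec.feature_names,
            )
        ref = FeatureMatrix(
            np.zeros((1, len(self._feature_names))), self._feature_names,
            standardized=True, mu=self._mu, sigma=self._sigma,
        )
        z = standardize(raw, fit_stats=ref)
        if self.spec.feature_mode == "hdps_selected":
            z = FeatureMatrix(
                z.values[:, self._keep],
                [self._feature_names[i] for i in self._keep],
                standardized=True,
            )
        return z

    # -- fit / predict ------------------------------------------------------

    def fit(self, train_ds: ClaimsDataset, stats_ds: ClaimsDataset | None = None):
        if not hasattr(self, "_mu"):
            self.fit_features(stats_ds or train_ds)
        A = train_ds.treatment()
        if self.spec.feature_mode == "hdps_selected":
            counts = count_features(train_ds)
            rec = recurrence_features(counts, thresholds=self._rec_thresholds)
            order = bross_rank(rec, A, train_ds.outcome(), self.hdps)
            sel = np.sort(order[: self.hdps.top_k]) + self._n_counts
            self._keep = np.concatenate([np.arange(self._n_counts), sel])
        self._model = fit_baseline(self.spec, self.transform(train_ds), A)
        self._fitted = True
        return self

    def predict(self, ds: ClaimsDataset) -> np.ndarray:
        if not self._fitted:
            raise RuntimeError("pipeline not fitted")
        return self._model.predict(self.transform(ds))


def fit_propensity_model(spec, train_ds: ClaimsDataset, seed: int = 0,
                         stats_ds: ClaimsDataset | None = None):
    """Dispatch on spec type; returns an object with ``predict(ds) -> e_hat``."""
    if isinstance(spec, SeqModelConfig):
        model, _ = train_sequence_model(replace(spec, seed=seed), train_ds)
        return model
    if isinstance(spec, BaselineSpec):
        return BaselinePipeline(replace(spec, seed=seed)).fit(train_ds, stats_ds=stats_ds)
    if callable(spec):  # factory: spec(train_ds, seed) -> fitted model
        return spec(train_ds, seed)
    raise TypeError(f"unknown model spec type {type(spec)!r}")


def kfold_indices(n: int, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    if k < 2 or k > n:
        raise ValueError("need 2 <= k <= n")
    return [np.sort(f) for f in np.array_split(rng.permutation(n), k)]


@dataclass
class EvalReport:
    model: str
    scenario: str
    k: int
    seed: int
    per_fold: pd.DataFrame  # one row per fold, columns METRICS

    def summary(self) -> pd.DataFrame:
        """Across-fold mean with 95% Student-t confidence half-widths."""
        mean = self.per_fold[list(METRICS)].mean()
        sd = self.per_fold[list(METRICS)].std(ddof=1)
        half = stats.t.ppf(0.975, self.k - 1) * sd / np.sqrt(self.k)
        return pd.DataFrame({"mean": mean, "ci95": half})

    def to_csv(self, path) -> None:
        self.per_fold.assign(model=self.model, scenario=self.scenario).to_csv(
            path, index_label="fold"
        )

    def format_table(self) -> str:
        s = self.summary()
        cells = [f"{s['mean'][m]:.3f} ± {s['ci95'][m]:.3f}" for m in METRICS]
        header = f"{'Model':<14}" + "".join(f"{c:>18}" for c in ("PS", "PS_W", "ATE", "ATE_T", "ATE_C"))
        row = f"{self.model:<14}" + "".join(f"{c:>18}" for c in cells)
        return header + "\n" + row


def fold_metrics(test_ds: ClaimsDataset, e_hat: np.ndarray, tau: float,
                 alpha: float = 0.05) -> dict[str, float]:
    e = test_ds.true_propensity()
    A, Y = test_ds.treatment(), test_ds.outcome()
    return {
        "ps_mae": mae_ps(e, e_hat),
        "ps_mae_weighted": weighted_mae_ps(e, e_hat),
        "ate_mae": ate_mae(estimate_ate(A, Y, e_hat).delta_hat, tau),
        "ate_mae_trimmed": ate_mae(
            estimate_ate_trimmed(A, Y, e_hat, alpha).delta_hat, tau
        ),
        "ate_mae_clipped": ate_mae(
            estimate_ate_clipped(A, Y, e_hat, alpha).delta_hat, tau
        ),
    }


def run_cv_experiment(
    ds: ClaimsDataset,
    model_spec,
    k: int = 10,
    seed: int = 0,
    alpha: float = 0.05,
    model_name: str | None = None,
) -> EvalReport:
    """Seeded patient-level k-fold CV; all metrics computed on held-out folds."""
    tau = ds.true_ate()
    A_all = ds.treatment()
    for attempt in range(2):
        rng = np.random.default_rng(seed + attempt)
        folds = kfold_indices(len(ds), k, rng)
        ok = all(
            len(np.unique(A_all[np.setdiff1d(np.arange(len(ds)), f)])) == 2
            and len(np.unique(A_all[f])) == 2
            for f in folds
        )
        if ok:
            break
    else:
        raise ValueError("could not form folds with both treatment classes")

    rows = []
    for i, fold in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(len(ds)), fold)
        model = fit_propensity_model(
            model_spec, ds.subset(train_idx), seed=seed + i, stats_ds=ds
        )
        e_hat = model.predict(ds.subset(fold))
        rows.append(fold_metrics(ds.subset(fold), e_hat, tau, alpha))
    name = model_name or getattr(model_spec, "kind", type(model_spec).__name__)
    return EvalReport(
        model=name,
        scenario=ds.metadata.get("scenario", "unknown"),
        k=k,
        seed=seed,
        per_fold=pd.DataFrame(rows),
    )
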