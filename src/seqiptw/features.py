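"""Count features, standardization, and HDPS-style recurrence features.

The baseline propensity models do not see sequences: each patient is reduced
to a vector of per-code occurrence counts (number of records containing the
code), optionally expanded into the three recurrence indicators of
high-dimensional propensity score adjustment (HDPS) — *once*, *sporadic*,
*frequent* — and ranked by the Bross bias multiplier for top-k selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import ClaimsDataset

__all__ = [
    "FeatureMatrix",
    "HdpsConfig",
    "count_features",
    "standardize",
    "recurrence_features",
    "bross_scores",
    "bross_rank",
    "select_top_k",
]

log = logging.getLogger(__name__)


@dataclass
class FeatureMatrix:
    values: np.ndarray  # (N, F) float
    feature_names: list[str]
    standardized: bool = False
    # fitted statistics, kept so held-out folds reuse them
    mu: np.ndarray | None = field(default=None, repr=False)
    sigma: np.ndarray | None = field(default=None, repr=False)
    thresholds: np.ndarray | None = field(default=None, repr=False)  # recurrence cutoffs

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.feature_names):
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.feature_names)} feature names"
            )

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, columns=self.feature_names).to_csv(path, index=False)


@dataclass(frozen=True)
class HdpsConfig:
    top_k: int = 100
    sporadic_q: float = 0.5   # median of carriers
    frequent_q: float = 0.75  # upper quartile of carriers
    outcome_dichotomization: str = "median"

    def __post_init__(self) -> None:
        if not (0.0 < self.sporadic_q < self.frequent_q <= 1.0):
            raise ValueError("need 0 < sporadic_q < frequent_q <= 1")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")


def count_features(ds: ClaimsDataset) -> FeatureMatrix:
    """Entry (i, k): number of records of patient i containing code k."""
    if len(ds) == 0:
        raise ValueError("empty dataset")
    dx = ds.vocabulary.size
    counts = np.zeros((len(ds), dx), dtype=np.float64)
    for i, p in enumerate(ds.patients):
        for r in p.records:
            for c in r.codes:
                counts[i, c] += 1.0
    return FeatureMatrix(counts, list(ds.vocabulary.codes))


def standardize(fm: FeatureMatrix, fit_stats: FeatureMatrix | None = None) -> FeatureMatrix:
    """Column-wise (x - mu) / sigma; population SD; sigma=0 columns map to 0.

    When ``fit_stats`` (a previously standardized matrix) is given, its fitted
    mean and SD are reused — this is how held-out folds are transformed with
    training-set statistics.
    """
    if fm.standardized:
        raise ValueError("matrix already standardized (single application contract)")
    if fit_stats is not None:
        if fit_stats.mu is None or fit_stats.sigma is None:
            raise ValueError("fit_stats carries no fitted statistics")
        if fit_stats.mu.shape[0] != fm.values.shape[1]:
            raise ValueError("fit_stats dimension mismatch")
        mu, sigma = fit_stats.mu, fit_stats.sigma
    else:
        mu = fm.values.mean(axis=0)
        sigma = fm.values.std(axis=0)  # population SD
    safe = np.where(sigma > 0, sigma, 1.0)
    z = (fm.values - mu) / safe
    z[:, sigma == 0] = 0.0
    return FeatureMatrix(z, list(fm.feature_names), standardized=True, mu=mu, sigma=sigma)


def recurrence_features(
    counts: FeatureMatrix,
    cfg: HdpsConfig | None = None,
    thresholds: np.ndarray | None = None,
) -> FeatureMatrix:
    """HDPS recurrence indicators per code: once / sporadic / frequent.

    Thresholds are quantiles (default median and upper quartile, linear
    interpolation) of the count distribution among *carriers* (patients with
    count >= 1).  A code that never occurs yields three all-zero columns
    (kept, logged as degenerate).  Pass a previously fitted ``thresholds``
    array (dx x 2, NaN rows for degenerate codes) to transform new patients
    with the fitting population's cutoffs.
    """
    if counts.standardized:
        raise ValueError("recurrence features need raw (unstandardized) counts")
    cfg = cfg or HdpsConfig()
    X = counts.values
    n, dx = X.shape
    if thresholds is None:
        thresholds = np.full((dx, 2), np.nan)
        for k in range(dx):
            carriers = X[:, k][X[:, k] >= 1]
            if carriers.size:
                thresholds[k, 0] = np.quantile(carriers, cfg.sporadic_q)
                thresholds[k, 1] = np.quantile(carriers, cfg.frequent_q)
    elif thresholds.shape != (dx, 2):
        raise ValueError(f"thresholds must have shape ({dx}, 2)")
    out = np.zeros((n, 3 * dx), dtype=np.float64)
    names: list[str] = []
    degenerate = 0
    for k, code in enumerate(counts.feature_names):
        names += [f"{code}_once", f"{code}_sporadic", f"{code}_frequent"]
        if np.isnan(thresholds[k]).any():
            degenerate += 1
            continue
        col = X[:, k]
        out[:, 3 * k] = col >= 1
        out[:, 3 * k + 1] = col >= thresholds[k, 0]
        out[:, 3 * k + 2] = col >= thresholds[k, 1]
    if degenerate:
        log.info("recurrence_features: %d codes never occur (all-zero columns kept)", degenerate)
    return FeatureMatrix(out, names, thresholds=thresholds)


def _dichotomize_outcome(Y: np.ndarray, rule: str) -> np.ndarray:
    if rule == "median":
        return (Y >= np.median(Y)).astype(np.float64)
    raise ValueError(f"unknown outcome dichotomization rule {rule!r}")


def bross_scores(
    features: FeatureMatrix, A, Y, cfg: HdpsConfig | None = None
) -> np.ndarray:
    """Per-feature |log BiasM| confounding scores (Bross bias multiplier).

    BiasM = (P_C1 (RR - 1) + 1) / (P_C0 (RR - 1) + 1) with P_C1 / P_C0 the
    feature prevalence among treated / untreated and RR the risk ratio of the
    dichotomized outcome given the feature, symmetrized as max(RR, 1/RR).
    Zero cells get a 0.1 continuity correction.
    """
    cfg = cfg or HdpsConfig()
    A = np.asarray(A, dtype=np.float64)
    Ybin = _dichotomize_outcome(np.asarray(Y, dtype=np.float64), cfg.outcome_dichotomization)
    X = features.values
    if set(np.unique(X)) - {0.0, 1.0}:
        raise ValueError("bross_rank needs binary feature columns")
    n_treated = A.sum()
    n_untreated = (1 - A).sum()
    if n_treated == 0 or n_untreated == 0:
        raise ValueError("both treatment groups must be present")

    scores = np.zeros(X.shape[1])
    corrected = 0
    for j in range(X.shape[1]):
        c = X[:, j]
        p_c1 = (c * A).sum() / n_treated
        p_c0 = (c * (1 - A)).sum() / n_untreated
        # risk ratio of outcome given feature
        n1, n0 = c.sum(), (1 - c).sum()
        e1, e0 = (Ybin * c).sum(), (Ybin * (1 - c)).sum()
        if min(n1, n0, e1, e0) == 0 or e1 == n1 or e0 == n0:
            n1, n0, e1, e0 = n1 + 0.2, n0 + 0.2, e1 + 0.1, e0 + 0.1
            corrected += 1
        rr = (e1 / n1) / (e0 / n0)
        rr = max(rr, 1.0 / rr)
        bias_m = (p_c1 * (rr - 1.0) + 1.0) / (p_c0 * (rr - 1.0) + 1.0)
        scores[j] = abs(np.log(bias_m))
    if corrected:
        log.info("bross_scores: continuity correction applied to %d features", corrected)
    return scores


def bross_rank(
    features: FeatureMatrix, A, Y, cfg: HdpsConfig | None = None
) -> np.ndarray:
    """Feature indices ordered by descending Bross score (ties by index)."""
    scores = bross_scores(features, A, Y, cfg)
    return np.lexsort((np.arange(scores.size), -scores))


def select_top_k(features: FeatureMatrix, order: np.ndarray, k: int) -> FeatureMatrix:
    keep = np.sort(order[:k])  # keep original column order for readability
    return FeatureMatrix(
        features.values[:, keep],
        [features.feature_names[i] for i in keep],
        standardized=features.standardized,
    )
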