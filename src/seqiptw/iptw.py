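"""IPTW average-treatment-effect estimation with trimming and clipping.

The Horvitz–Thompson form is used throughout:

    delta_hat = (1/N) * [ sum_i A_i Y_i / e_i  -  sum_i (1-A_i) Y_i / (1-e_i) ]

with divisor N (the sample count), not the weight sum.  Extreme estimated
propensities are handled either by symmetric trimming (drop patients with
e outside the closed interval [alpha, 1-alpha] and renormalize by the
retained count) or by symmetric clipping (bound e into [alpha, 1-alpha]).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AteEstimate",
    "estimate_ate",
    "trim",
    "estimate_ate_trimmed",
    "clip",
    "estimate_ate_clipped",
]


@dataclass(frozen=True)
class AteEstimate:
    delta_hat: float
    variant: str  # raw | trimmed | clipped
    alpha: float
    n_used: int
    n_excluded: int = 0


def _check(A, Y, e):
    A = np.asarray(A, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    e = np.asarray(e, dtype=np.float64)
    if not (A.shape == Y.shape == e.shape) or A.ndim != 1:
        raise ValueError("A, Y, e must be equal-length 1-D vectors")
    if A.size == 0:
        raise ValueError("empty input")
    if ((e <= 0.0) | (e >= 1.0)).any():
        raise ValueError(
            "estimated propensities must lie strictly in (0,1); "
            "clip extreme values first (see estimate_ate_clipped)"
        )
    return A, Y, e


def estimate_ate(A, Y, e) -> AteEstimate:
    A, Y, e = _check(A, Y, e)
    n = A.size
    delta = (np.sum(A * Y / e) - np.sum((1.0 - A) * Y / (1.0 - e))) / n
    return AteEstimate(delta_hat=float(delta), variant="raw", alpha=0.0, n_used=n)


def trim(e, alpha: float) -> np.ndarray:
    """Inclusion mask: True iff alpha <= e <= 1 - alpha (closed interval)."""
    if not (0.0 <= alpha < 0.5):
        raise ValueError("alpha must lie in [0, 0.5)")
    e = np.asarray(e, dtype=np.float64)
    return (e >= alpha) & (e <= 1.0 - alpha)


def estimate_ate_trimmed(A, Y, e, alpha: float = 0.05) -> AteEstimate:
    A, Y, e = _check(A, Y, e)
    mask = trim(e, alpha)
    n_kept = int(mask.sum())
    if n_kept == 0:
        raise ValueError(f"all {A.size} patients trimmed at alpha={alpha}")
    est = estimate_ate(A[mask], Y[mask], e[mask])
    return AteEstimate(
        delta_hat=est.delta_hat,
        variant="trimmed",
        alpha=alpha,
        n_used=n_kept,
        n_excluded=A.size - n_kept,
    )


def clip(e, alpha: float) -> np.ndarray:
    """Bound propensities into [alpha, 1 - alpha]."""
    if not (0.0 < alpha < 0.5):
        raise ValueError("alpha must lie in (0, 0.5)")
    return np.clip(np.asarray(e, dtype=np.float64), alpha, 1.0 - alpha)


def estimate_ate_clipped(A, Y, e, alpha: float = 0.05) -> AteEstimate:
    A, Y, _ = _check(A, Y, np.clip(e, 1e-12, 1 - 1e-12))
    est = estimate_ate(A, Y, clip(e, alpha))
    return AteEstimate(
        delta_hat=est.delta_hat, variant="clipped", alpha=alpha, n_used=A.size
    )
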