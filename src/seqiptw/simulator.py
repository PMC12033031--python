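"""Synthetic confounded claims-data generator.

Each patient is generated independently:

1. a record count ``T ~ Poisson(lambda_T)`` truncated to ``T >= 1``;
2. a static parameter matrix ``B`` (one Uniform(b_low, b_high) draw per code,
   broadcast over time — intrinsic characteristics that do not change) and a
   dynamic matrix ``C`` (Uniform initial row, then a log-scale Gaussian random
   walk — factors such as immune state that drift over time);
3. per-entry occurrence probabilities ``P_tk ~ Beta(B_tk, C_tk)`` and the
   binary record matrix ``X_tk ~ Bernoulli(P_tk)``;
4. a scenario statistic ``s`` computed from the temporal pattern of one or two
   *target* codes (longest consecutive run / record-wise distance between two
   codes / occurrences inside the trailing lookup window);
5. the true propensity ``e = sigmoid(beta0 + beta1 * s)``, treatment
   ``A ~ Bernoulli(e)``, and potential outcomes ``y0 = mu0 + gamma*s + eps``,
   ``y1 = y0 + tau`` (homogeneous additive effect), so the dataset-level true
   ATE is exactly ``tau``.

Because both the propensity and the outcome increase with ``s``, the scenario
statistic is a genuine time-dependent confounder: naive difference-in-means is
biased upward, while IPTW with the true propensity is unbiased.

Target codes draw their dynamic-parameter initial range from
``(c_low_target, c_high_target)`` instead of ``(c_low, c_high)``: with the
background Beta calibration (mean occurrence probability ~0.035) the target
codes would almost never occur and every scenario statistic would collapse to
zero.  The elevated target rate (mean ~1/3 per record) lets runs, distances
and window counts span their range, which is what produces propensity spread
and therefore measurable confounding.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .data import ClaimsDataset, ClaimsRecord, PatientSequence, Vocabulary

__all__ = [
    "SCENARIOS",
    "SimulatorConfig",
    "ConfigError",
    "sample_record_count",
    "generate_parameters",
    "emit_records",
    "scenario_statistic",
    "true_propensity",
    "assign_treatment_and_outcome",
    "generate_arrays",
    "generate_dataset",
]

SCENARIOS = ("consecutive_occurrence", "occurrence_distance", "occurrence_window")

_CHUNK = 2048  # patients per vectorized block; bounds transient memory


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SimulatorConfig:
    N: int = 12_000
    dx: int = 100
    lambda_T: float = 10.0
    # Background Beta-parameter calibration: E[B/(B+C)] ~ 0.035, i.e. about
    # 35 expected code occurrences per patient at T ~ 10, dx = 100.
    b_low: float = 0.5
    b_high: float = 1.5
    c_low: float = 15.0
    c_high: float = 40.0
    c_sigma: float = 0.1
    # Target codes occur at an elevated rate so the scenario statistic varies.
    c_low_target: float = 1.0
    c_high_target: float = 3.0
    scenario: str = "occurrence_window"
    target_codes: tuple[int, ...] = (0,)
    window_w: int = 5
    d_cap: int = 5
    beta0: float = -1.5
    beta1: float = 0.7
    mu0: float = 0.0
    gamma: float = 5.0
    tau: float = 20.0
    sigma_eps: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ConfigError(f"unknown scenario {self.scenario!r}; one of {SCENARIOS}")
        if self.scenario == "occurrence_distance" and len(self.target_codes) != 2:
            raise ConfigError("occurrence_distance needs exactly 2 target codes")
        if self.scenario != "occurrence_distance" and len(self.target_codes) != 1:
            raise ConfigError(f"{self.scenario} needs exactly 1 target code")
        for name in ("b_low", "b_high", "c_low", "c_high", "c_low_target", "c_high_target"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive (Beta parameters)")
        if self.b_high < self.b_low or self.c_high < self.c_low:
            raise ConfigError("parameter ranges must be non-degenerate (high >= low)")
        if self.lambda_T <= 0:
            raise ConfigError("lambda_T must be positive")
        if self.N < 1 or self.dx < 1:
            raise ConfigError("N and dx must be >= 1")
        if any(not (0 <= k < self.dx) for k in self.target_codes):
            raise ConfigError(f"target_codes {self.target_codes} out of range for dx={self.dx}")
        if self.scenario == "occurrence_window" and self.window_w < 1:
            raise ConfigError("window_w must be >= 1")
        if not np.isfinite(self.tau):
            raise ConfigError("tau must be finite")

    @classmethod
    def for_scenario(cls, scenario: str, **overrides) -> "SimulatorConfig":
        """Per-scenario defaults: target codes and link slope."""
        base: dict = {"scenario": scenario}
        if scenario == "consecutive_occurrence":
            base.update(target_codes=(0,), beta1=0.7)
        elif scenario == "occurrence_distance":
            base.update(target_codes=(0, 1), beta1=0.6)
        elif scenario == "occurrence_window":
            base.update(target_codes=(0,), beta1=0.7)
        else:
            raise ConfigError(f"unknown scenario {scenario!r}")
        base.update(overrides)
        return cls(**base)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Elementary generative steps (vectorized over patients where arrays allow)
# ---------------------------------------------------------------------------


def sample_record_count(cfg: SimulatorConfig, rng: np.random.Generator, size=None):
    """Truncated-Poisson record count: draws of 0 are redrawn, so T >= 1."""
    T = rng.poisson(cfg.lambda_T, size=size)
    if size is None:
        while T == 0:
            T = rng.poisson(cfg.lambda_T)
        return int(T)
    zero = T == 0
    while zero.any():
        T[zero] = rng.poisson(cfg.lambda_T, size=int(zero.sum()))
        zero = T == 0
    return T


def generate_parameters(cfg: SimulatorConfig, T: int, rng: np.random.Generator):
    """Per-patient static matrix B (rows identical) and dynamic matrix C."""
    if T < 1:
        raise ConfigError("T must be >= 1")
    b = rng.uniform(cfg.b_low, cfg.b_high, size=cfg.dx)
    B = np.broadcast_to(b, (T, cfg.dx)).copy()
    c1 = rng.uniform(cfg.c_low, cfg.c_high, size=cfg.dx)
    c1[list(cfg.target_codes)] = rng.uniform(
        cfg.c_low_target, cfg.c_high_target, size=len(cfg.target_codes)
    )
    eta = np.zeros((T, cfg.dx))
    if T > 1:
        eta[1:] = rng.normal(0.0, cfg.c_sigma, size=(T - 1, cfg.dx))
    C = c1 * np.exp(np.cumsum(eta, axis=0))
    return B, C


def emit_records(B: np.ndarray, C: np.ndarray, rng: np.random.Generator):
    """Beta occurrence probabilities and Bernoulli code emission."""
    if B.shape != C.shape:
        raise ValueError(f"shape mismatch: B {B.shape} vs C {C.shape}")
    P = rng.beta(B, C)
    X = (rng.random(P.shape) < P).astype(np.int8)
    return P, X


# -- scenario statistics ----------------------------------------------------
# All three operate on a (n, Tmax) binary matrix of the target code's
# occurrences with a per-patient record count; the public single-matrix API
# wraps the batched kernels with n=1.


def _longest_run(Xk: np.ndarray, T: np.ndarray) -> np.ndarray:
    n, Tmax = Xk.shape
    valid = np.arange(Tmax) < T[:, None]
    x = Xk * valid
    run = np.zeros(n, dtype=np.int64)
    best = np.zeros(n, dtype=np.int64)
    for t in range(Tmax):
        run = (run + 1) * x[:, t]
        best = np.maximum(best, run)
    return best


def _window_count(Xk: np.ndarray, T: np.ndarray, w: int) -> np.ndarray:
    Tmax = Xk.shape[1]
    t_idx = np.arange(Tmax)
    in_window = (t_idx >= (T[:, None] - w)) & (t_idx < T[:, None])
    return (Xk * in_window).sum(axis=1)


def _min_distance(Xa: np.ndarray, Xb: np.ndarray, T: np.ndarray) -> np.ndarray:
    """Minimum |t_i - t_j| over occurrence pairs; -1 when either code absent."""
    n, Tmax = Xa.shape
    valid = np.arange(Tmax) < T[:, None]
    a = (Xa * valid).astype(bool)
    b = (Xb * valid).astype(bool)
    present = a.any(axis=1) & b.any(axis=1)
    dmin = np.full(n, -1, dtype=np.int64)
    found = ~present  # patients lacking a code are done (stay -1)
    for d in range(Tmax):
        if found.all():
            break
        if d == 0:
            hit = (a & b).any(axis=1)
        else:
            hit = (a[:, :-d] & b[:, d:]).any(axis=1) | (b[:, :-d] & a[:, d:]).any(axis=1)
        newly = hit & ~found
        dmin[newly] = d
        found |= newly
    return dmin


def _scenario_statistic_batch(
    X: np.ndarray, T: np.ndarray, cfg: SimulatorConfig, col_of=None
) -> np.ndarray:
    col_of = col_of or (lambda k: k)
    if cfg.scenario == "consecutive_occurrence":
        return _longest_run(X[:, :, col_of(cfg.target_codes[0])], T).astype(np.float64)
    if cfg.scenario == "occurrence_window":
        return _window_count(
            X[:, :, col_of(cfg.target_codes[0])], T, cfg.window_w
        ).astype(np.float64)
    k1, k2 = cfg.target_codes
    dmin = _min_distance(X[:, :, col_of(k1)], X[:, :, col_of(k2)], T)
    s = np.maximum(0, cfg.d_cap - dmin).astype(np.float64)
    s[dmin < 0] = 0.0  # either code absent -> baseline
    return s


def scenario_statistic(X: np.ndarray, cfg: SimulatorConfig) -> float:
    """Scenario statistic of one patient's T x dx binary record matrix."""
    X = np.asarray(X)
    if X.ndim != 2:
        raise ValueError("X must be a T x dx matrix")
    T = np.array([X.shape[0]])
    return float(_scenario_statistic_batch(X[None, :, :], T, cfg)[0])


def true_propensity(s, cfg: SimulatorConfig):
    """Logistic link: e = sigmoid(beta0 + beta1 * s); increasing in s for beta1>0."""
    z = cfg.beta0 + cfg.beta1 * np.asarray(s, dtype=np.float64)
    return 1.0 / (1.0 + np.exp(-z))


def assign_treatment_and_outcome(e, s, cfg: SimulatorConfig, rng: np.random.Generator):
    """Bernoulli treatment and homogeneous additive potential outcomes."""
    e = np.asarray(e, dtype=np.float64)
    s = np.asarray(s, dtype=np.float64)
    A = (rng.random(e.shape) < e).astype(np.int64)
    eps = rng.normal(0.0, cfg.sigma_eps, size=e.shape)
    y0 = cfg.mu0 + cfg.gamma * s + eps
    y1 = y0 + cfg.tau
    Y = np.where(A == 1, y1, y0)
    return A, Y, y0, y1


# ---------------------------------------------------------------------------
# Whole-dataset generation
# ---------------------------------------------------------------------------


def generate_arrays(
    cfg: SimulatorConfig,
    rng: np.random.Generator | None = None,
    targets_only: bool = False,
):
    """Array-level generator (fast path for replicate studies).

    Returns a dict with per-patient ``T``, the padded record tensor ``X``
    (N x Tmax x dx, rows past T_i zero), and vectors ``s``, ``e``, ``A``,
    ``Y``, ``y0``, ``y1``.

    With ``targets_only=True`` only the target-code columns are simulated
    (``X`` has one column per target code, in ``cfg.target_codes`` order).
    Background codes are independent of the scenario statistic, the
    propensity, the treatment and the outcome, so the joint law of
    (T, s, e, A, Y, y0, y1) is unchanged — this marginalization is what
    replicate studies of the estimator need.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    out: dict[str, list[np.ndarray]] = {k: [] for k in ("T", "X", "s", "e", "A", "Y", "y0", "y1")}
    target = list(cfg.target_codes)
    if targets_only:
        columns = target
        col_of = {k: j for j, k in enumerate(target)}.__getitem__
        target_pos = list(range(len(target)))
    else:
        columns = list(range(cfg.dx))
        col_of = None
        target_pos = target
    dx_eff = len(columns)
    for start in range(0, cfg.N, _CHUNK):
        n = min(_CHUNK, cfg.N - start)
        T = sample_record_count(cfg, rng, size=n)
        Tmax = int(T.max())
        # static parameters: one draw per code, broadcast over time
        b = rng.uniform(cfg.b_low, cfg.b_high, size=(n, 1, dx_eff))
        # dynamic parameters: uniform start, log-scale Gaussian random walk
        c1 = rng.uniform(cfg.c_low, cfg.c_high, size=(n, 1, dx_eff))
        c1[:, :, target_pos] = rng.uniform(
            cfg.c_low_target, cfg.c_high_target, size=(n, 1, len(target))
        )
        eta = rng.normal(0.0, cfg.c_sigma, size=(n, Tmax, dx_eff))
        eta[:, 0, :] = 0.0
        C = c1 * np.exp(np.cumsum(eta, axis=1))
        B = np.broadcast_to(b, (n, Tmax, dx_eff))
        P = rng.beta(B, C)
        X = (rng.random(P.shape) < P).astype(np.int8)
        X *= (np.arange(Tmax) < T[:, None])[:, :, None]  # zero padded rows
        s = _scenario_statistic_batch(X, T, cfg, col_of=col_of)
        e = true_propensity(s, cfg)
        A, Y, y0, y1 = assign_treatment_and_outcome(e, s, cfg, rng)
        for k, v in (("T", T), ("X", X), ("s", s), ("e", e), ("A", A), ("Y", Y), ("y0", y0), ("y1", y1)):
            out[k].append(v)
    res = {k: np.concatenate(v) if k != "X" else v for k, v in out.items()}
    return res


def generate_dataset(cfg: SimulatorConfig) -> ClaimsDataset:
    """Generate the full synthetic dataset with ground truth attached."""
    arrays = generate_arrays(cfg)
    vocab = Vocabulary.of_size(cfg.dx)
    patients: list[PatientSequence] = []
    i = 0
    offset = 0
    for chunk in arrays["X"]:
        for j in range(chunk.shape[0]):
            T = int(arrays["T"][offset + j])
            records = [
                ClaimsRecord(t=t + 1, codes=frozenset(np.flatnonzero(chunk[j, t]).tolist()))
                for t in range(T)
            ]
            patients.append(
                PatientSequence(
                    id=f"p{offset + j:06d}",
                    records=records,
                    A=int(arrays["A"][offset + j]),
                    Y=float(arrays["Y"][offset + j]),
                    e_true=float(arrays["e"][offset + j]),
                    s_true=float(arrays["s"][offset + j]),
                    y0=float(arrays["y0"][offset + j]),
                    y1=float(arrays["y1"][offset + j]),
                )
            )
            i += 1
        offset += chunk.shape[0]
    metadata = {
        "generator": "seqiptw.simulator",
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "scenario": cfg.scenario,
        "tau": cfg.tau,
        "target_codes": list(cfg.target_codes),
    }
    return ClaimsDataset(vocabulary=vocab, patients=patients, metadata=metadata)
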