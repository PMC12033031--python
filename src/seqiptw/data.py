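"""Core data model for longitudinal claims sequences.

A patient is an ordered sequence of *records*; each record is a bag of
medical codes drawn from a fixed vocabulary of size ``dx``.  A binary
treatment ``A`` and a continuous outcome ``Y`` are observed at the end of
the observation period.  Simulated datasets additionally carry the true
propensity score ``e_true``, the scenario statistic ``s_true`` that drives
the confounding, and both potential outcomes ``y0``/``y1``.

Datasets are exchanged as JSON-lines: line 1 is a header object with the
vocabulary and provenance metadata, every following line is one patient.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Vocabulary",
    "ClaimsRecord",
    "PatientSequence",
    "ClaimsDataset",
    "ValidationError",
    "SchemaError",
    "encode_multi_hot",
    "decode_multi_hot",
    "write_jsonl",
    "read_jsonl",
]


class ValidationError(ValueError):
    """A sequence violates a structural invariant (e.g. code index >= dx)."""


class SchemaError(ValueError):
    """A serialized dataset is malformed (missing field, bad header, ...)."""


@dataclass(frozen=True)
class Vocabulary:
    """Ordered code vocabulary; index of a code is its position in ``codes``."""

    codes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.codes)) != len(self.codes):
            raise ValidationError("vocabulary contains duplicate codes")

    @classmethod
    def of_size(cls, dx: int, prefix: str = "code") -> "Vocabulary":
        """A generic vocabulary ``code_0 .. code_{dx-1}``."""
        return cls(tuple(f"{prefix}_{k}" for k in range(dx)))

    @property
    def size(self) -> int:
        return len(self.codes)

    def index(self, code: str) -> int:
        try:
            return self.codes.index(code)
        except ValueError:
            raise KeyError(f"code {code!r} not in vocabulary") from None


@dataclass(frozen=True)
class ClaimsRecord:
    """One time point: a set of vocabulary indices (possibly empty).

    ``t`` is 1-based and purely ordinal — calendar time is out of scope.
    """

    t: int
    codes: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        if self.t < 1:
            raise ValidationError(f"record time index must be >= 1, got {self.t}")
        object.__setattr__(self, "codes", frozenset(int(c) for c in self.codes))


@dataclass
class PatientSequence:
    id: str
    records: list[ClaimsRecord]
    A: int
    Y: float
    e_true: float | None = None
    s_true: float | None = None
    y0: float | None = None
    y1: float | None = None

    def __post_init__(self) -> None:
        if len(self.records) < 1:
            raise ValidationError(f"patient {self.id}: needs at least one record")
        ts = [r.t for r in self.records]
        if ts != list(range(1, len(ts) + 1)):
            raise ValidationError(
                f"patient {self.id}: record time indices must be 1..T consecutive, got {ts}"
            )
        if self.A not in (0, 1):
            raise ValidationError(f"patient {self.id}: treatment must be 0 or 1")
        if self.e_true is not None and not (0.0 < self.e_true < 1.0):
            raise ValidationError(f"patient {self.id}: e_true must lie in (0,1)")
        if self.y0 is not None and self.y1 is not None:
            expected = self.y1 if self.A == 1 else self.y0
            if not np.isclose(self.Y, expected, rtol=0, atol=1e-9):
                raise ValidationError(
                    f"patient {self.id}: Y={self.Y} inconsistent with potential outcome {expected}"
                )

    @property
    def T(self) -> int:
        return len(self.records)


@dataclass
class ClaimsDataset:
    vocabulary: Vocabulary
    patients: list[PatientSequence]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [p.id for p in self.patients]
        if len(set(ids)) != len(ids):
            raise ValidationError("patient ids are not unique")
        dx = self.vocabulary.size
        for p in self.patients:
            for r in p.records:
                bad = [c for c in r.codes if not (0 <= c < dx)]
                if bad:
                    raise ValidationError(
                        f"patient {p.id}, record t={r.t}: code indices {bad} out of range for dx={dx}"
                    )

    def __len__(self) -> int:
        return len(self.patients)

    # Convenience column extractors used throughout the estimation code.
    def treatment(self) -> np.ndarray:
        return np.array([p.A for p in self.patients], dtype=np.int64)

    def outcome(self) -> np.ndarray:
        return np.array([p.Y for p in self.patients], dtype=np.float64)

    def true_propensity(self) -> np.ndarray:
        e = [p.e_true for p in self.patients]
        if any(v is None for v in e):
            raise ValidationError("dataset has patients without e_true")
        return np.array(e, dtype=np.float64)

    def true_ate(self) -> float:
        tau = self.metadata.get("tau")
        if tau is None:
            raise ValidationError("dataset metadata carries no true ATE")
        return float(tau)

    def subset(self, indices) -> "ClaimsDataset":
        return ClaimsDataset(
            vocabulary=self.vocabulary,
            patients=[self.patients[i] for i in np.asarray(indices)],
            metadata=dict(self.metadata),
        )


def encode_multi_hot(seq: PatientSequence, vocab: Vocabulary) -> np.ndarray:
    """Multi-hot encode a patient: binary matrix of shape (T, dx).

    Entry (t-1, k) is 1 iff code k is present in the record at time t.
    """
    dx = vocab.size
    X = np.zeros((seq.T, dx), dtype=np.int8)
    for r in seq.records:
        for c in r.codes:
            if not (0 <= c < dx):
                raise ValidationError(
                    f"patient {seq.id}, record t={r.t}: code index {c} >= dx={dx}"
                )
            X[r.t - 1, c] = 1
    return X


def decode_multi_hot(X: np.ndarray) -> list[frozenset[int]]:
    """Inverse of :func:`encode_multi_hot` on its image: per-row code sets."""
    return [frozenset(np.flatnonzero(row).tolist()) for row in np.asarray(X)]


# ---------------------------------------------------------------------------
# JSONL I/O
# ---------------------------------------------------------------------------

_OPTIONAL = ("e_true", "s_true", "y0", "y1")


def _patient_to_obj(p: PatientSequence) -> dict:
    obj = {
        "id": p.id,
        "records": [sorted(r.codes) for r in p.records],
        "A": int(p.A),
        "Y": float(p.Y),
    }
    for k in _OPTIONAL:
        v = getattr(p, k)
        if v is not None:
            obj[k] = float(v)
    return obj


def _patient_from_obj(obj: dict, lineno: int) -> PatientSequence:
    for req in ("id", "records", "A", "Y"):
        if req not in obj:
            raise SchemaError(f"line {lineno}: patient object missing field {req!r}")
    records = [
        ClaimsRecord(t=t + 1, codes=frozenset(codes))
        for t, codes in enumerate(obj["records"])
    ]
    return PatientSequence(
        id=str(obj["id"]),
        records=records,
        A=int(obj["A"]),
        Y=float(obj["Y"]),
        **{k: (float(obj[k]) if k in obj else None) for k in _OPTIONAL},
    )


def write_jsonl(ds: ClaimsDataset, path) -> None:
    """One patient per line; header (vocabulary + metadata) on line 1."""
    with open(path, "w") as fh:
        header = {
            "dx": ds.vocabulary.size,
            "codes": list(ds.vocabulary.codes),
            "metadata": ds.metadata,
        }
        fh.write(json.dumps(header, sort_keys=True) + "\n")
        for p in ds.patients:
            fh.write(json.dumps(_patient_to_obj(p), sort_keys=True) + "\n")


def read_jsonl(path) -> ClaimsDataset:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise SchemaError("empty file: no header line")
    try:
        header = json.loads(lines[0])
    except json.JSONDecodeError as exc:
        raise SchemaError(f"line 1: malformed header: {exc}") from exc
    if "dx" not in header or "codes" not in header:
        raise SchemaError("line 1: header must carry 'dx' and 'codes'")
    if len(header["codes"]) != header["dx"]:
        raise SchemaError("line 1: header dx disagrees with code list length")
    vocab = Vocabulary(tuple(header["codes"]))
    patients = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        try:
            obj = json.loads(line)
        except json.JSONDecodeError as exc:
            raise SchemaError(f"line {lineno}: malformed patient line: {exc}") from exc
        patients.append(_patient_from_obj(obj, lineno))
    return ClaimsDataset(
        vocabulary=vocab, patients=patients, metadata=header.get("metadata", {})
    )
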