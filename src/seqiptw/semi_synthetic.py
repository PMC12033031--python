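"""Semi-synthetic confounding injection into Synthea-style condition records.

The hypothetical study estimates the effect of a treatment for *viral
sinusitis* while *chronic sinusitis* — similar symptoms, different therapy —
creates time-dependent confounding: patients whose chronic- and
viral-sinusitis diagnoses fall close together (in record-wise distance) get
both a higher treatment probability and a higher baseline outcome.

The loader reads the ``conditions.csv`` dialect of a Synthea export
(columns PATIENT, START, CODE, DESCRIPTION; extra columns ignored), grouping
same-date events of a patient into one ordinal record.  Because tests and
examples must run without any download, :func:`generate_synthea_fixture`
emits a *synthetic* conditions table with the same shape: background
condition codes plus a controllable fraction of patients carrying both
sinusitis codes at controllable record-wise distances.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import ClaimsDataset, ClaimsRecord, PatientSequence, Vocabulary
from .simulator import _min_distance, assign_treatment_and_outcome, true_propensity

__all__ = [
    "ConditionEvent",
    "InjectionConfig",
    "load_synthea_conditions",
    "resolve_code",
    "inject_confounding",
    "generate_synthea_fixture",
]

_REQUIRED = ("PATIENT", "START", "CODE", "DESCRIPTION")


@dataclass(frozen=True)
class ConditionEvent:
    patient_id: str
    date: str  # ISO
    code: str
    description: str


@dataclass(frozen=True)
class InjectionConfig:
    """Occurrence-distance confounding parameters (shared with the simulator's
    logistic link and additive-outcome model)."""

    d_cap: int = 5
    beta0: float = -1.5
    beta1: float = 0.6
    mu0: float = 0.0
    gamma: float = 5.0
    tau: float = 20.0
    sigma_eps: float = 1.0
    seed: int = 0


def _vocab_entry(code: str, description: str) -> str:
    return f"{code}:{description}"


def load_synthea_conditions(path) -> ClaimsDataset:
    """Read a conditions CSV into a labeled-free dataset (A=0, Y=0 stubs).

    Events of one patient sharing a calendar date form one record; records
    are ordered by date and re-indexed ordinally (t = visit order), so the
    result is insensitive to row order in the file.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"conditions file missing required columns: {missing}")
    dates = pd.to_datetime(df["START"], errors="coerce", format="mixed")
    n_bad = int(dates.isna().sum())
    if n_bad:
        raise ValueError(f"{n_bad} rows with unparseable START dates")
    df = df.assign(_date=dates)

    entries = sorted(
        {_vocab_entry(c, d) for c, d in zip(df["CODE"], df["DESCRIPTION"])}
    )
    vocab = Vocabulary(tuple(entries))
    lookup = {e: i for i, e in enumerate(entries)}

    patients: list[PatientSequence] = []
    for pid, grp in df.sort_values(["PATIENT", "_date"]).groupby("PATIENT", sort=True):
        records = []
        for t, (_, day) in enumerate(grp.groupby("_date", sort=True), start=1):
            codes = frozenset(
                lookup[_vocab_entry(c, d)] for c, d in zip(day["CODE"], day["DESCRIPTION"])
            )
            records.append(ClaimsRecord(t=t, codes=codes))
        patients.append(PatientSequence(id=str(pid), records=records, A=0, Y=0.0))
    return ClaimsDataset(
        vocabulary=vocab,
        patients=patients,
        metadata={"source": "synthea_conditions", "labeled": False},
    )


def resolve_code(vocab: Vocabulary, description: str) -> int:
    """Vocabulary index whose description contains ``description``
    (case-insensitive substring); errors list the nearest descriptions."""
    target = description.lower()
    hits = [i for i, e in enumerate(vocab.codes) if target in e.split(":", 1)[-1].lower()]
    if not hits:
        near = difflib.get_close_matches(
            description, [e.split(":", 1)[-1] for e in vocab.codes], n=5, cutoff=0.0
        )
        raise KeyError(
            f"no vocabulary description matches {description!r}; nearest: {near}"
        )
    if len(hits) > 1:
        raise KeyError(
            f"{description!r} matches multiple codes: "
            f"{[vocab.codes[i] for i in hits]}; be more specific"
        )
    return hits[0]


def inject_confounding(
    ds: ClaimsDataset,
    code_a: str = "chronic sinusitis",
    code_b: str = "viral sinusitis",
    cfg: InjectionConfig | None = None,
) -> ClaimsDataset:
    """Assign e_true, A, Y, y0, y1 from the record-wise distance between two
    named condition codes: s = max(0, d_cap - d_min), s = 0 when either code
    is absent (baseline propensity sigmoid(beta0))."""
    cfg = cfg or InjectionConfig()
    rng = np.random.default_rng(cfg.seed)
    ka, kb = resolve_code(ds.vocabulary, code_a), resolve_code(ds.vocabulary, code_b)

    n = len(ds)
    Tmax = max(p.T for p in ds.patients)
    Xa = np.zeros((n, Tmax), dtype=np.int8)
    Xb = np.zeros((n, Tmax), dtype=np.int8)
    T = np.zeros(n, dtype=np.int64)
    for i, p in enumerate(ds.patients):
        T[i] = p.T
        for r in p.records:
            if ka in r.codes:
                Xa[i, r.t - 1] = 1
            if kb in r.codes:
                Xb[i, r.t - 1] = 1
    dmin = _min_distance(Xa, Xb, T)
    s = np.maximum(0, cfg.d_cap - dmin).astype(np.float64)
    s[dmin < 0] = 0.0
    e = true_propensity(s, cfg)
    A, Y, y0, y1 = assign_treatment_and_outcome(e, s, cfg, rng)

    patients = [
        PatientSequence(
            id=p.id, records=p.records, A=int(A[i]), Y=float(Y[i]),
            e_true=float(e[i]), s_true=float(s[i]), y0=float(y0[i]), y1=float(y1[i]),
        )
        for i, p in enumerate(ds.patients)
    ]
    metadata = dict(ds.metadata)
    metadata.update(
        labeled=True,
        scenario="semi_synthetic_occurrence_distance",
        confounder_code_a=ds.vocabulary.codes[ka],
        confounder_code_b=ds.vocabulary.codes[kb],
        target_codes=[int(ka), int(kb)],
        tau=cfg.tau,
        seed=cfg.seed,
        d_cap=cfg.d_cap,
    )
    return ClaimsDataset(vocabulary=ds.vocabulary, patients=patients, metadata=metadata)


# ---------------------------------------------------------------------------
# Fixture generator (synthetic stand-in for a Synthea export)
# ---------------------------------------------------------------------------

_BACKGROUND = [
    ("44054006", "Diabetes"),
    ("38341003", "Hypertension"),
    ("195967001", "Asthma"),
    ("10509002", "Acute bronchitis (disorder)"),
    ("444814009", "Viral pharyngitis (disorder)"),
    ("162864005", "Body mass index 30+ - obesity (finding)"),
    ("271737000", "Anemia (disorder)"),
    ("40055000", "Chronic pharyngitis"),
    ("698754002", "Chronic paralysis due to lesion of spinal cord"),
    ("124171000119105", "Chronic intractable migraine without aura"),
]
_CHRONIC = ("40055000X", "Chronic sinusitis (disorder)")
_VIRAL = ("444814009X", "Viral sinusitis (disorder)")


def generate_synthea_fixture(
    n_patients: int,
    rng: np.random.Generator,
    path=None,
    fraction_both: float = 0.5,
    fraction_one: float = 0.2,
    forced_distance: int | None = None,
    mean_visits: float = 10.0,
) -> pd.DataFrame:
    """Emit a *synthetic* conditions table mimicking a Synthea export.

    ``fraction_both`` of patients carry chronic + viral sinusitis separated
    by ``forced_distance`` visits (or Uniform{1..4}); ``fraction_one`` carry
    only one of the two; the rest carry background codes only.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    rows = []
    base = np.datetime64("2015-01-01")
    for i in range(n_patients):
        pid = f"synthea-{i:05d}"
        u = rng.random()
        carrier_both = u < fraction_both
        carrier_one = fraction_both <= u < fraction_both + fraction_one
        dist = (
            forced_distance if forced_distance is not None else int(rng.integers(1, 5))
        )
        V = max(2, int(rng.poisson(mean_visits)))
        if carrier_both:
            V = max(V, dist + 1)  # both codes must fit at the forced distance
        # distinct, sorted visit dates
        offsets = np.sort(rng.choice(3650, size=V, replace=False))
        dates = [str(base + int(o)) for o in offsets]
        for d in dates:
            for _ in range(1 + rng.poisson(0.8)):
                code, desc = _BACKGROUND[rng.integers(len(_BACKGROUND))]
                rows.append((pid, d, code, desc))
        if carrier_both:
            t1 = int(rng.integers(0, V - dist))
            rows.append((pid, dates[t1], *_CHRONIC))
            rows.append((pid, dates[t1 + dist], *_VIRAL))
        elif carrier_one:
            code = _CHRONIC if rng.random() < 0.5 else _VIRAL
            rows.append((pid, dates[int(rng.integers(V))], *code))
    df = pd.DataFrame(rows, columns=list(_REQUIRED))
    if path is not None:
        df.to_csv(path, index=False)
    return df
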