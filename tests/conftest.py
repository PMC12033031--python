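import numpy as np
import pytest

from seqiptw.data import ClaimsDataset, ClaimsRecord, PatientSequence, Vocabulary
from seqiptw.simulator import SimulatorConfig, generate_dataset


def make_patient(pid, record_codes, A=0, Y=0.0, **kw):
    """Patient from a list of per-record code collections."""
    records = [ClaimsRecord(t=t + 1, codes=frozenset(c)) for t, c in enumerate(record_codes)]
    return PatientSequence(id=pid, records=records, A=A, Y=Y, **kw)


def random_dataset(rng, max_patients=4, dx_max=6, with_truth=False):
    """A small random valid dataset (used by round-trip property tests)."""
    dx = int(rng.integers(2, dx_max + 1))
    vocab = Vocabulary.of_size(dx)
    patients = []
    for i in range(int(rng.integers(1, max_patients + 1))):
        T = int(rng.integers(1, 5))
        codes = [
            frozenset(int(c) for c in rng.choice(dx, size=rng.integers(0, dx), replace=False))
            for _ in range(T)
        ]
        kw = {}
        A = int(rng.integers(2))
        if with_truth and rng.random() < 0.7:
            y0 = float(rng.normal())
            tau = 2.5
            kw = dict(
                e_true=float(rng.uniform(0.05, 0.95)),
                s_true=float(rng.integers(0, 5)),
                y0=y0,
                y1=y0 + tau,
            )
            Y = kw["y1"] if A else kw["y0"]
        else:
            Y = float(rng.normal())
        patients.append(make_patient(f"p{i}", codes, A=A, Y=Y, **kw))
    return ClaimsDataset(vocab, patients, metadata={"tag": "random"})


@pytest.fixture(scope="session")
def window_ds():
    """Small occurrence-window dataset shared across tests."""
    cfg = SimulatorConfig.for_scenario("occurrence_window", N=600, seed=42)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def distance_ds():
    cfg = SimulatorConfig.for_scenario("occurrence_distance", N=600, seed=43)
    return generate_dataset(cfg)
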