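"""Synthea-style loading, fixture generation and confounding injection."""

import numpy as np
import pandas as pd
import pytest

from seqiptw.data import ClaimsDataset, ClaimsRecord, PatientSequence, Vocabulary
from seqiptw.iptw import estimate_ate
from seqiptw.semi_synthetic import (
    InjectionConfig,
    generate_synthea_fixture,
    inject_confounding,
    load_synthea_conditions,
    resolve_code,
)


def _write(tmp_path, rows):
    df = pd.DataFrame(rows, columns=["PATIENT", "START", "CODE", "DESCRIPTION"])
    path = tmp_path / "conditions.csv"
    df.to_csv(path, index=False)
    return path


class TestLoader:
    def test_distinct_dates_become_ordinal_records(self, tmp_path):
        path = _write(tmp_path, [
            ("p1", "2019-01-01", "1", "Diabetes"),
            ("p1", "2019-05-02", "2", "Asthma"),
            ("p1", "2020-03-03", "1", "Diabetes"),
        ])
        ds = load_synthea_conditions(path)
        assert len(ds) == 1 and ds.patients[0].T == 3

    def test_same_date_events_share_one_record(self, tmp_path):
        path = _write(tmp_path, [
            ("p1", "2019-01-01", "1", "Diabetes"),
            ("p1", "2019-01-01", "2", "Asthma"),
        ])
        ds = load_synthea_conditions(path)
        assert ds.patients[0].T == 1
        assert len(ds.patients[0].records[0].codes) == 2

    def test_row_order_does_not_matter(self, tmp_path):
        rows = [
            ("p2", "2019-03-01", "2", "Asthma"),
            ("p1", "2019-01-01", "1", "Diabetes"),
            ("p1", "2018-05-01", "2", "Asthma"),
            ("p2", "2019-01-01", "1", "Diabetes"),
        ]
        a = load_synthea_conditions(_write(tmp_path, rows))
        rng = np.random.default_rng(0)
        shuffled = [rows[i] for i in rng.permutation(len(rows))]
        b = load_synthea_conditions(_write(tmp_path, shuffled))
        assert [p.records for p in a.patients] == [p.records for p in b.patients]

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"PATIENT": ["p"], "START": ["2019-01-01"]}).to_csv(path, index=False)
        with pytest.raises(ValueError, match="missing required columns"):
            load_synthea_conditions(path)

    def test_unparseable_dates_counted_in_error(self, tmp_path):
        path = _write(tmp_path, [
            ("p1", "2019-01-01", "1", "Diabetes"),
            ("p1", "not-a-date", "2", "Asthma"),
        ])
        with pytest.raises(ValueError, match="1 rows"):
            load_synthea_conditions(path)

    def test_fixture_roundtrips_through_loader(self, tmp_path):
        path = tmp_path / "fix.csv"
        generate_synthea_fixture(40, np.random.default_rng(1), path=path)
        ds = load_synthea_conditions(path)
        assert len(ds) <= 40 and len(ds) > 30  # all patients have >= 2 visits
        assert all(p.T >= 1 for p in ds.patients)


class TestResolution:
    def test_substring_match_is_case_insensitive(self, tmp_path):
        path = _write(tmp_path, [
            ("p1", "2019-01-01", "11", "Chronic sinusitis (disorder)"),
            ("p1", "2019-02-01", "22", "Viral sinusitis (disorder)"),
        ])
        ds = load_synthea_conditions(path)
        ka = resolve_code(ds.vocabulary, "chronic sinusitis")
        assert "Chronic sinusitis" in ds.vocabulary.codes[ka]

    def test_unresolvable_description_lists_nearest(self, tmp_path):
        path = _write(tmp_path, [("p1", "2019-01-01", "1", "Diabetes")])
        ds = load_synthea_conditions(path)
        with pytest.raises(KeyError, match="nearest"):
            resolve_code(ds.vocabulary, "chronic sinusitis")


def _manual_ds(hits_a=(4,), hits_b=(6,), T=7):
    """One patient with sinusitis codes at chosen record indices."""
    vocab = Vocabulary(("1:Chronic sinusitis (disorder)", "2:Viral sinusitis (disorder)", "3:Diabetes"))
    records = []
    for t in range(1, T + 1):
        codes = set()
        if t in hits_a:
            codes.add(0)
        if t in hits_b:
            codes.add(1)
        records.append(ClaimsRecord(t=t, codes=frozenset(codes)))
    return ClaimsDataset(vocab, [PatientSequence(id="p", records=records, A=0, Y=0.0)])


class TestInjection:
    def test_distance_statistic_from_named_codes(self):
        ds = _manual_ds(hits_a=(4,), hits_b=(6,))
        out = inject_confounding(ds, cfg=InjectionConfig(d_cap=5, seed=0))
        assert out.patients[0].s_true == 3.0  # d_min = 2 -> 5 - 2

    def test_patient_without_codes_gets_baseline_propensity(self):
        ds = _manual_ds(hits_a=(), hits_b=())
        cfg = InjectionConfig(beta0=-1.5, seed=0)
        out = inject_confounding(ds, cfg=cfg)
        assert out.patients[0].s_true == 0.0
        assert out.patients[0].e_true == pytest.approx(1 / (1 + np.exp(1.5)))

    def test_zero_effect_injection_has_zero_true_ate(self, tmp_path):
        path = tmp_path / "fix.csv"
        generate_synthea_fixture(200, np.random.default_rng(2), path=path)
        ds = load_synthea_conditions(path)
        out = inject_confounding(ds, cfg=InjectionConfig(tau=0.0, seed=1))
        assert out.true_ate() == 0.0
        for p in out.patients:
            assert p.y1 == p.y0

    def test_metadata_records_resolved_codes(self, tmp_path):
        path = tmp_path / "fix.csv"
        generate_synthea_fixture(100, np.random.default_rng(3), path=path)
        out = inject_confounding(load_synthea_conditions(path), cfg=InjectionConfig(seed=2))
        assert "Chronic sinusitis" in out.metadata["confounder_code_a"]
        assert "Viral sinusitis" in out.metadata["confounder_code_b"]


class TestFixture:
    def test_no_carriers_when_fraction_zero(self):
        df = generate_synthea_fixture(
            100, np.random.default_rng(4), fraction_both=0.0, fraction_one=0.0
        )
        assert not df["DESCRIPTION"].str.contains("sinusitis", case=False).any()

    def test_forced_distance_controls_the_statistic(self, tmp_path):
        path = tmp_path / "fix.csv"
        generate_synthea_fixture(
            150, np.random.default_rng(5), path=path,
            fraction_both=1.0, fraction_one=0.0, forced_distance=2,
        )
        out = inject_confounding(load_synthea_conditions(path), cfg=InjectionConfig(d_cap=5, seed=3))
        s = np.array([p.s_true for p in out.patients])
        assert (s == 3.0).all()  # every carrier at distance 2 -> 5 - 2

    def test_fixed_seed_reproduces_csv(self, tmp_path):
        a, b = tmp_path / "a.csv", tmp_path / "b.csv"
        generate_synthea_fixture(60, np.random.default_rng(6), path=a)
        generate_synthea_fixture(60, np.random.default_rng(6), path=b)
        assert a.read_bytes() == b.read_bytes()


def test_iptw_with_true_propensity_recovers_injected_effect(tmp_path):
    """End-to-end: fixture -> loader -> injection -> oracle IPTW ~ tau."""
    path = tmp_path / "big.csv"
    generate_synthea_fixture(5000, np.random.default_rng(7), path=path)
    out = inject_confounding(load_synthea_conditions(path), cfg=InjectionConfig(seed=4))
    est = estimate_ate(out.treatment(), out.outcome(), out.true_propensity())
    e = out.true_propensity()
    Y = out.outcome()
    # conservative SE bound for the weighted difference
    se = np.sqrt(np.var(Y / np.minimum(e, 1 - e)) / len(out))
    assert abs(est.delta_hat - out.true_ate()) <= 3 * se
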