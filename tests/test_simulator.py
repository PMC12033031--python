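"""Generator: record counts, parameter matrices, emission, scenario
statistics, propensity link, treatment/outcome assignment, determinism."""

import numpy as np
import pytest

from seqiptw.data import write_jsonl
from seqiptw.iptw import estimate_ate
from seqiptw.simulator import (
    ConfigError,
    SimulatorConfig,
    assign_treatment_and_outcome,
    emit_records,
    generate_arrays,
    generate_dataset,
    generate_parameters,
    sample_record_count,
    scenario_statistic,
    true_propensity,
)


class TestRecordCount:
    def test_poisson_mean_recovered(self):
        cfg = SimulatorConfig()
        T = sample_record_count(cfg, np.random.default_rng(0), size=100_000)
        assert 9.9 <= T.mean() <= 10.1

    def test_truncation_guarantees_at_least_one_record(self):
        cfg = SimulatorConfig(lambda_T=0.1)  # Poisson(0.1) is almost always 0
        T = sample_record_count(cfg, np.random.default_rng(1), size=5000)
        assert T.min() >= 1

    def test_fixed_seed_reproduces_sequence(self):
        cfg = SimulatorConfig()
        a = sample_record_count(cfg, np.random.default_rng(5), size=100)
        b = sample_record_count(cfg, np.random.default_rng(5), size=100)
        assert np.array_equal(a, b)


class TestParameters:
    def test_static_matrix_rows_identical_and_positive(self):
        cfg = SimulatorConfig(dx=20)
        B, C = generate_parameters(cfg, 6, np.random.default_rng(2))
        assert B.shape == C.shape == (6, 20)
        assert (B == B[0]).all()
        assert B.min() > 0 and C.min() > 0

    def test_zero_walk_sd_freezes_dynamic_matrix(self):
        cfg = SimulatorConfig(dx=10, c_sigma=0.0)
        _, C = generate_parameters(cfg, 8, np.random.default_rng(3))
        assert np.allclose(C, C[0])

    def test_nonpositive_range_rejected(self):
        with pytest.raises(ConfigError):
            SimulatorConfig(b_low=-0.5)

    def test_background_occurrence_rate_near_calibration(self):
        # E[B/(B+C)] under b~U(0.5,1.5), c~U(15,40) is about 0.035 -> with
        # T ~ 10 and dx = 100 background codes, ~35 occurrences per patient
        rng = np.random.default_rng(4)
        b = rng.uniform(0.5, 1.5, 200_000)
        c = rng.uniform(15, 40, 200_000)
        assert 0.03 < np.mean(b / (b + c)) < 0.045


class TestEmission:
    def test_beta_1_1_is_uniform(self):
        B = np.ones((1000, 100))
        P, X = emit_records(B, B, np.random.default_rng(5))
        assert abs(P.mean() - 0.5) < 0.005
        assert set(np.unique(X)) <= {0, 1}

    def test_occurrence_rate_matches_beta_mean(self):
        B = np.full((500, 200), 2.0)
        C = np.full((500, 200), 6.0)
        _, X = emit_records(B, C, np.random.default_rng(6))
        assert abs(X.mean() - 0.25) < 0.005  # 2/(2+6)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            emit_records(np.ones((2, 3)), np.ones((3, 2)), np.random.default_rng(0))


class TestScenarioStatistics:
    def _matrix(self, T, dx, hits):
        X = np.zeros((T, dx), dtype=np.int8)
        for t, k in hits:
            X[t - 1, k] = 1
        return X

    def test_longest_run_of_target_code(self):
        cfg = SimulatorConfig.for_scenario("consecutive_occurrence", dx=5, target_codes=(2,))
        X = self._matrix(5, 5, [(1, 2), (2, 2), (4, 2)])
        assert scenario_statistic(X, cfg) == 2.0

    def test_distance_saturating_transform(self):
        cfg = SimulatorConfig.for_scenario("occurrence_distance", dx=5, target_codes=(0, 1), d_cap=5)
        X = self._matrix(6, 5, [(2, 0), (5, 1)])
        assert scenario_statistic(X, cfg) == 2.0  # d_min=3 -> 5-3

    def test_distance_zero_when_code_absent(self):
        cfg = SimulatorConfig.for_scenario("occurrence_distance", dx=5, target_codes=(0, 1), d_cap=5)
        X = self._matrix(6, 5, [(2, 0)])
        assert scenario_statistic(X, cfg) == 0.0

    def test_trailing_window_count(self):
        cfg = SimulatorConfig.for_scenario("occurrence_window", dx=5, target_codes=(1,), window_w=3)
        X = self._matrix(5, 5, [(1, 1), (4, 1), (5, 1)])
        assert scenario_statistic(X, cfg) == 2.0

    def test_distance_scenario_needs_two_target_codes(self):
        with pytest.raises(ConfigError):
            SimulatorConfig(scenario="occurrence_distance", target_codes=(0,))


class TestPropensityLink:
    def test_sigmoid_at_zero(self):
        cfg = SimulatorConfig(beta0=0.0)
        assert true_propensity(0.0, cfg) == 0.5

    def test_monotone_increasing_in_statistic(self):
        cfg = SimulatorConfig(beta0=-1.5, beta1=0.7)
        e = true_propensity(np.arange(6), cfg)
        assert (np.diff(e) > 0).all()

    def test_default_link_value(self):
        cfg = SimulatorConfig(beta0=-1.5, beta1=0.7)
        assert true_propensity(3.0, cfg) == pytest.approx(1 / (1 + np.exp(-0.6)))
        assert true_propensity(3.0, cfg) == pytest.approx(0.6457, abs=1e-4)


class TestTreatmentAndOutcome:
    def test_zero_effect_makes_potential_outcomes_equal(self):
        cfg = SimulatorConfig(tau=0.0)
        _, _, y0, y1 = assign_treatment_and_outcome(
            np.full(500, 0.5), np.zeros(500), cfg, np.random.default_rng(8)
        )
        assert np.array_equal(y0, y1)

    def test_noiseless_outcome_plug_in(self):
        cfg = SimulatorConfig(sigma_eps=0.0, gamma=5.0, mu0=0.0, tau=20.0)
        rng = np.random.default_rng(9)
        _, _, y0, y1 = assign_treatment_and_outcome(np.array([0.999]), np.array([2.0]), cfg, rng)
        assert y0[0] == pytest.approx(10.0) and y1[0] == pytest.approx(30.0)

    def test_treated_fraction_matches_mean_propensity(self):
        cfg = SimulatorConfig()
        rng = np.random.default_rng(10)
        e = rng.uniform(0.2, 0.9, 12_000)
        A, *_ = assign_treatment_and_outcome(e, np.zeros_like(e), cfg, rng)
        se = np.sqrt(e.mean() * (1 - e.mean()) / e.size)
        assert abs(A.mean() - e.mean()) < 3 * se


class TestWholeDataset:
    def test_same_seed_gives_byte_identical_jsonl(self, tmp_path):
        cfg = SimulatorConfig.for_scenario("occurrence_window", N=150, seed=17)
        p1, p2 = tmp_path / "a.jsonl", tmp_path / "b.jsonl"
        write_jsonl(generate_dataset(cfg), p1)
        write_jsonl(generate_dataset(cfg), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_size_mean_record_count_and_ground_truth_invariants(self, window_ds):
        assert len(window_ds) == 600
        T = np.array([p.T for p in window_ds.patients])
        assert abs(T.mean() - 10.0) < 0.5
        e = window_ds.true_propensity()
        assert ((e > 0) & (e < 1)).all()
        for p in window_ds.patients:
            assert p.y1 - p.y0 == pytest.approx(window_ds.true_ate())

    def test_confounding_present_naive_estimator_biased(self, window_ds):
        A, Y = window_ds.treatment(), window_ds.outcome()
        naive = Y[A == 1].mean() - Y[A == 0].mean()
        se = np.sqrt(Y[A == 1].var() / (A == 1).sum() + Y[A == 0].var() / (A == 0).sum())
        assert naive - window_ds.true_ate() > 3 * se

    def test_iptw_with_true_propensity_recovers_effect(self, window_ds):
        A, Y, e = window_ds.treatment(), window_ds.outcome(), window_ds.true_propensity()
        est = estimate_ate(A, Y, e)
        # plug-in SE of the Horvitz-Thompson per-patient terms
        terms = A * Y / e - (1 - A) * Y / (1 - e)
        se = terms.std(ddof=1) / np.sqrt(len(terms))
        assert abs(est.delta_hat - window_ds.true_ate()) < 3 * se

    def test_targets_only_marginal_agrees_with_full_generation(self):
        cfg = SimulatorConfig.for_scenario("occurrence_window", N=4000, seed=23)
        full = generate_arrays(cfg)
        marg = generate_arrays(cfg, rng=np.random.default_rng(99), targets_only=True)
        assert marg["X"][0].shape[2] == 1
        # same law for the scenario statistic and propensity
        assert abs(full["s"].mean() - marg["s"].mean()) < 0.12
        assert abs(full["e"].mean() - marg["e"].mean()) < 0.02
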