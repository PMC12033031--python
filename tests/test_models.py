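"""Sequence propensity models: input construction, positional encodings,
forward contracts, training behavior."""

import numpy as np
import pytest

from seqiptw.data import ClaimsDataset, Vocabulary
from seqiptw.models import (
    SeqModelConfig,
    build_bert_code_input,
    build_bert_record_input,
    forward_propensity,
    load_checkpoint,
    make_model,
    positional_encoding,
    record_representation,
    save_checkpoint,
    train_sequence_model,
)

from conftest import make_patient


class TestPositionalEncoding:
    def test_position_zero_alternates_zero_one(self):
        pe = positional_encoding(0, 8)
        assert pe.tolist() == [0, 1, 0, 1, 0, 1, 0, 1]

    def test_values_bounded(self):
        for pos in (1, 17, 300):
            assert (np.abs(positional_encoding(pos, 32)) <= 1.0).all()

    def test_small_dimension_values(self):
        pe = positional_encoding(1, 4)
        assert pe == pytest.approx([np.sin(1), np.cos(1), np.sin(0.01), np.cos(0.01)])

    def test_odd_dimension_rejected(self):
        with pytest.raises(ValueError):
            positional_encoding(0, 5)


class TestRecordRepresentation:
    def test_single_code_is_its_embedding(self):
        emb = np.random.default_rng(0).normal(size=(6, 4))
        assert np.array_equal(record_representation({3}, emb), emb[3])

    def test_opposite_embeddings_cancel(self):
        emb = np.zeros((2, 4))
        emb[0] = [1, -2, 3, -4]
        emb[1] = -emb[0]
        assert np.allclose(record_representation({0, 1}, emb), 0.0)

    def test_empty_record_gives_zero_vector(self):
        emb = np.random.default_rng(1).normal(size=(3, 5))
        assert np.array_equal(record_representation(set(), emb), np.zeros(5))


class TestInputConstruction:
    def test_code_scheme_tokens_and_shared_positions(self):
        p = make_patient("p", [{0, 1}, {2}])
        inp = build_bert_code_input(p, dx=4)
        assert inp.length == 4  # CLS + 3 codes
        assert inp.positions.tolist() == [0, 1, 1, 2]
        assert inp.token_features[1].tolist() == [1, 0, 0, 0]
        assert inp.token_features[0].tolist() == [0, 0, 0, 0]  # CLS row

    def test_empty_record_advances_position_without_tokens(self):
        p = make_patient("p", [{1}, set(), {2}])
        inp = build_bert_code_input(p, dx=4)
        assert inp.length == 3
        assert inp.positions.tolist() == [0, 1, 3]

    def test_record_scheme_one_token_per_record(self):
        p = make_patient("p", [{0, 2}, set(), {1}])
        inp = build_bert_record_input(p, dx=4)
        assert inp.length == 4
        assert inp.positions.tolist() == [0, 1, 2, 3]
        assert inp.token_features[1].tolist() == [0.5, 0, 0.5, 0]
        assert inp.token_features[2].tolist() == [0, 0, 0, 0]  # empty record

    def test_schemes_coincide_for_singleton_records(self):
        p = make_patient("p", [{3}, {0}, {2}])
        a = build_bert_code_input(p, dx=5)
        b = build_bert_record_input(p, dx=5)
        assert np.array_equal(a.token_features, b.token_features)
        assert np.array_equal(a.positions, b.positions)

    def test_overflow_names_the_patient(self):
        p = make_patient("big", [{0, 1, 2}] * 3)
        with pytest.raises(ValueError, match="big"):
            build_bert_code_input(p, dx=4, max_seq_len=5)


def _tiny_ds(rng, n=60, dx=6, label_code=2):
    """Treatment = presence of one code anywhere (easy separable task)."""
    patients = []
    for i in range(n):
        T = int(rng.integers(1, 5))
        codes = [
            frozenset(int(c) for c in rng.choice(dx, rng.integers(0, 3), replace=False))
            for _ in range(T)
        ]
        A = int(any(label_code in c for c in codes))
        patients.append(make_patient(f"p{i}", codes, A=A, Y=float(A)))
    return ClaimsDataset(Vocabulary.of_size(dx), patients, metadata={"tau": 0.0})


class TestForward:
    @pytest.mark.parametrize("kind", ["lstm", "bert_code", "bert_record"])
    def test_fresh_head_outputs_half(self, kind):
        rng = np.random.default_rng(0)
        ds = _tiny_ds(rng)
        cfg = SeqModelConfig(kind=kind, embed_dim=8, hidden_dim=8, n_layers=1,
                             n_heads=2, ff_dim=16, seed=0)
        model = make_model(cfg, 6)
        model.head.W.data[:] = 0.0
        model.head.b.data[:] = 0.0
        e = model.predict(ds)
        assert e == pytest.approx(0.5)

    def test_attention_rows_stochastic_and_padding_ignored(self):
        rng = np.random.default_rng(1)
        ds = _tiny_ds(rng, n=8)
        cfg = SeqModelConfig(kind="bert_code", embed_dim=8, n_layers=2, n_heads=2,
                             ff_dim=16, seed=0)
        model = make_model(cfg, 6)
        e, maps = forward_propensity(model, ds.patients, return_attention=True)
        assert ((e > 0) & (e < 1)).all()
        lengths = [model.build_input(p).length for p in ds.patients]
        L = max(lengths)
        for layer_map in maps:
            assert np.allclose(layer_map.sum(axis=-1), 1.0, atol=1e-5)
            for i, n in enumerate(lengths):
                if n < L:
                    assert (layer_map[i, :, :, n:] < 1e-6).all()

    def test_attention_request_on_lstm_rejected(self):
        rng = np.random.default_rng(2)
        ds = _tiny_ds(rng, n=4)
        model = make_model(SeqModelConfig(kind="lstm", embed_dim=8, hidden_dim=8), 6)
        with pytest.raises(TypeError):
            forward_propensity(model, ds.patients, return_attention=True)

    def test_within_record_code_order_irrelevant(self):
        # records are bags: the model input is invariant to code enumeration order
        p1 = make_patient("p", [frozenset({4, 1, 3})])
        p2 = make_patient("p", [frozenset({3, 4, 1})])
        a = build_bert_code_input(p1, dx=5)
        b = build_bert_code_input(p2, dx=5)
        assert np.array_equal(a.token_features, b.token_features)


class TestTraining:
    @pytest.mark.parametrize("kind", ["lstm", "bert_record"])
    def test_learns_presence_task_below_base_rate_entropy(self, kind):
        rng = np.random.default_rng(3)
        ds = _tiny_ds(rng, n=400)
        cfg = SeqModelConfig(kind=kind, embed_dim=8, hidden_dim=8, n_layers=1,
                             n_heads=2, ff_dim=16, learning_rate=5e-3, epochs=10,
                             patience=10, batch_size=64, seed=1)
        model, log = train_sequence_model(cfg, ds)
        A = ds.treatment()
        p = A.mean()
        base_entropy = -(p * np.log(p) + (1 - p) * np.log(1 - p))
        assert min(row["val_ce"] for row in log) < base_entropy

    def test_same_seed_identical_weights(self):
        rng = np.random.default_rng(4)
        ds = _tiny_ds(rng, n=80)
        cfg = SeqModelConfig(kind="lstm", embed_dim=8, hidden_dim=8, epochs=2,
                             batch_size=32, seed=5)
        m1, _ = train_sequence_model(cfg, ds)
        m2, _ = train_sequence_model(cfg, ds)
        for a, b in zip(m1.state_dict(), m2.state_dict()):
            assert np.array_equal(a, b)

    def test_checkpoint_roundtrip_preserves_predictions(self, tmp_path):
        rng = np.random.default_rng(5)
        ds = _tiny_ds(rng, n=50)
        cfg = SeqModelConfig(kind="bert_record", embed_dim=8, n_layers=1, n_heads=2,
                             ff_dim=16, epochs=1, batch_size=32, seed=6)
        model, log = train_sequence_model(cfg, ds)
        path = tmp_path / "ckpt.pkl"
        save_checkpoint(model, path, log)
        back, back_log = load_checkpoint(path)
        assert np.array_equal(back.predict(ds), model.predict(ds))
        assert back_log == log

    def test_single_class_training_data_rejected(self):
        patients = [make_patient(f"p{i}", [{0}], A=1, Y=1.0) for i in range(20)]
        ds = ClaimsDataset(Vocabulary.of_size(2), patients)
        cfg = SeqModelConfig(kind="lstm", embed_dim=4, hidden_dim=4, epochs=1, seed=0)
        with pytest.raises(ValueError, match="both treatment classes"):
            train_sequence_model(cfg, ds)
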