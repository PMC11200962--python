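"""Gated transformer forward-pass tests against independent oracles."""

from __future__ import annotations

import numpy as np
import pytest

from gatedtab.autodiff import Tensor
from gatedtab.model import (BlockConfig, GatedTabTransformer,
                            SchemaMismatchError, gate_coefficients,
                            gated_attention, gated_ffn, scaled_dot_attention)

from _reference import (attention_oracle, block_forward_oracle,
                        model_forward_oracle, sigmoid)

CARDS = [3, 4, 2]
N_CONT = 3


def tiny_model(gate_enabled=True, seed=0, **kw) -> GatedTabTransformer:
    cfg = BlockConfig(n_blocks=2, n_heads=2, embed_dim=8, dropout=0.0,
                      attention_dropout=0.0, addnorm_dropout=0.0,
                      gate_enabled=gate_enabled, **kw)
    return GatedTabTransformer(CARDS, N_CONT, cfg, n_events=1, seed=seed)


def tiny_batch(rng, n=4):
    codes = np.column_stack([rng.integers(0, c, size=n) for c in CARDS])
    cont = rng.random((n, N_CONT))
    return codes, cont


# -- attention ----------------------------------------------------------

def test_sequence_length_one_returns_values_verbatim(rng):
    Q = Tensor(rng.normal(size=(1, 3)))
    V = Tensor(rng.normal(size=(1, 3)))
    A, weights = scaled_dot_attention(Q, Q, V, d_k=3)
    assert np.allclose(A.data, V.data)
    assert np.allclose(weights.data, 1.0)


def test_identical_keys_average_the_values(rng):
    K = Tensor(np.tile(rng.normal(size=(1, 2)), (4, 1)))
    Q = Tensor(rng.normal(size=(4, 2)))
    V = Tensor(rng.normal(size=(4, 2)))
    A, _ = scaled_dot_attention(Q, K, V, d_k=2)
    assert np.allclose(A.data, V.data.mean(axis=0), atol=1e-12)


def test_two_position_attention_matches_scalar_oracle(rng):
    X = rng.normal(size=(2, 2))
    A, weights = scaled_dot_attention(Tensor(X), Tensor(X), Tensor(X), d_k=2)
    assert np.allclose(A.data, attention_oracle(X, X, X, 2), atol=1e-12)
    assert np.allclose(weights.data.sum(axis=-1), 1.0, atol=1e-6)


def test_nonpositive_key_dimension_is_an_error(rng):
    X = Tensor(rng.normal(size=(2, 2)))
    with pytest.raises(ValueError):
        scaled_dot_attention(X, X, X, d_k=0)


# -- gates --------------------------------------------------------------

def test_zero_gate_parameters_give_half_open_gates(rng):
    src = Tensor(rng.normal(size=(3, 4)))
    G = gate_coefficients(src, Tensor(np.zeros((4, 4))), Tensor(np.zeros(4)))
    assert np.allclose(G.data, 0.5)


def test_large_bias_saturates_the_gate_open(rng):
    src = Tensor(rng.normal(size=(3, 4)))
    G = gate_coefficients(src, Tensor(np.zeros((4, 4))),
                          Tensor(np.full(4, 20.0)))
    assert (G.data > 0.999).all()


def test_scalar_gate_value_matches_direct_sigmoid():
    G = gate_coefficients(Tensor([[1.0]]), Tensor([[2.0]]), Tensor([0.0]))
    assert np.isclose(G.data[0, 0], 0.8807970779778823, atol=1e-10)


def test_gate_coefficients_strictly_inside_unit_interval(rng):
    src = Tensor(rng.normal(size=(5, 6)) * 3)
    G = gate_coefficients(src, Tensor(rng.normal(size=(6, 6))),
                          Tensor(rng.normal(size=6)))
    assert (G.data > 0).all() and (G.data < 1).all()


def test_gated_attention_is_elementwise_modulation(rng):
    A = Tensor(rng.normal(size=(2, 2)))
    assert np.allclose(gated_attention(A, Tensor(np.ones((2, 2)))).data, A.data)
    assert np.all(gated_attention(A, Tensor(np.zeros((2, 2)))).data == 0)
    G = Tensor(rng.random((2, 2)))
    assert np.allclose(gated_attention(A, G).data, A.data * G.data)
    with pytest.raises(ValueError):
        gated_attention(A, Tensor(np.ones((3, 2))))


# -- gated FFN ----------------------------------------------------------

def test_all_negative_preactivations_annihilate_the_ffn(rng):
    X1 = Tensor(np.ones((2, 2)))
    out, _ = gated_ffn(X1, Tensor(-np.eye(2)), Tensor(np.full(2, -1.0)),
                       Tensor(rng.normal(size=(2, 2))), Tensor(np.zeros(2)),
                       Tensor(rng.normal(size=(2, 2))), Tensor(np.array([0.3, -0.2])))
    assert np.allclose(out.data, [0.3, -0.2])  # only the output bias survives


def test_saturated_gate_recovers_the_ungated_ffn(rng):
    X1 = Tensor(rng.normal(size=(3, 2)))
    F1, b1 = Tensor(rng.normal(size=(2, 4))), Tensor(rng.normal(size=4))
    F2, b2 = Tensor(rng.normal(size=(4, 2))), Tensor(rng.normal(size=2))
    open_gate, _ = gated_ffn(X1, F1, b1, Tensor(np.zeros((2, 4))),
                             Tensor(np.full(4, 50.0)), F2, b2)
    bypassed, gate = gated_ffn(X1, F1, b1, Tensor(np.zeros((2, 4))),
                               Tensor(np.zeros(4)), F2, b2, gate_enabled=False)
    assert gate is None
    assert np.allclose(open_gate.data, bypassed.data, atol=1e-10)


def test_gated_ffn_matches_scalar_chain_oracle():
    X1 = np.array([[1.0, -0.5]])
    F1 = np.array([[0.6, -0.3], [0.2, 0.8]])
    b1 = np.array([0.1, -0.1])
    Fg = np.array([[0.5, 0.4], [-0.2, 0.3]])
    bgF = np.array([0.0, 0.2])
    F2, b2 = np.eye(2), np.zeros(2)
    out, gate = gated_ffn(Tensor(X1), Tensor(F1), Tensor(b1), Tensor(Fg),
                          Tensor(bgF), Tensor(F2), Tensor(b2))
    f = np.maximum(X1 @ F1 + b1, 0.0)
    g = sigmoid(X1 @ Fg + bgF)
    assert np.allclose(out.data, f * g, atol=1e-12)
    assert np.allclose(gate.data, g, atol=1e-12)


# -- block and model ----------------------------------------------------

def _block_weights(model: GatedTabTransformer, b: int) -> dict:
    return {k.split(".", 1)[1]: t.data
            for k, t in model.params.items() if k.startswith(f"block{b}.")}


def test_bypassed_gates_reproduce_an_independent_ungated_block(rng):
    model = tiny_model(gate_enabled=False)
    X = rng.normal(size=(3, len(CARDS), 8))
    out = model._block(Tensor(X), 0, train=False, rng=None, gates_out=None)
    expected = block_forward_oracle(X, _block_weights(model, 0), n_heads=2,
                                    gated=False)
    assert np.abs(out.data - expected).max() < 1e-6


def test_gated_block_matches_the_gated_oracle(rng):
    model = tiny_model(gate_enabled=True)
    X = rng.normal(size=(3, len(CARDS), 8))
    out = model._block(Tensor(X), 0, train=False, rng=None, gates_out=None)
    expected = block_forward_oracle(X, _block_weights(model, 0), n_heads=2,
                                    gated=True)
    assert np.abs(out.data - expected).max() < 1e-6


def test_block_preserves_shape_and_is_deterministic_without_dropout(rng):
    model = tiny_model()
    X = rng.normal(size=(5, len(CARDS), 8))
    out1 = model._block(Tensor(X), 1, train=False, rng=None, gates_out=None)
    out2 = model._block(Tensor(X), 1, train=False, rng=None, gates_out=None)
    assert out1.data.shape == X.shape
    assert np.array_equal(out1.data, out2.data)


def test_full_forward_matches_layerwise_oracle(rng):
    """The end-to-end forward pass (embedding lookup, gated blocks, MLP
    head) agrees with an independent layer-by-layer reconstruction from
    the checkpoint arrays, for both gate settings."""
    codes, cont = tiny_batch(rng, n=2)
    for gated in (True, False):
        model = tiny_model(gate_enabled=gated)
        logits, _ = model.forward(codes, cont)
        expected = model_forward_oracle(model, codes, cont)
        assert np.abs(logits.data - expected).max() < 1e-6


def test_probabilities_strictly_inside_unit_interval(rng):
    model = tiny_model()
    codes, cont = tiny_batch(rng, n=6)
    probs = model.predict_proba(codes, cont)
    assert (probs > 0).all() and (probs < 1).all()


def test_records_are_scored_independently(rng):
    model = tiny_model()
    codes, cont = tiny_batch(rng, n=5)
    probs = model.predict_proba(codes, cont)
    perm = rng.permutation(5)
    assert np.allclose(model.predict_proba(codes[perm], cont[perm]),
                       probs[perm], atol=1e-12)


def test_schema_mismatch_error_reports_the_problem(rng):
    model = tiny_model()
    codes, cont = tiny_batch(rng)
    with pytest.raises(SchemaMismatchError, match="categorical"):
        model.forward(codes[:, :2], cont)
    bad = codes.copy()
    bad[0, 0] = CARDS[0]        # out-of-range code
    with pytest.raises(SchemaMismatchError, match="codes outside"):
        model.forward(bad, cont)


def test_gate_tensors_are_collected_per_block(rng):
    model = tiny_model()
    codes, cont = tiny_batch(rng)
    _, gates = model.forward(codes, cont, collect_gates=True)
    assert len(gates) == model.config.n_blocks
    for record in gates:
        assert ((record["attention_gate"] > 0)
                & (record["attention_gate"] < 1)).all()
        assert np.allclose(record["attention_map"].sum(axis=-1), 1.0,
                           atol=1e-6)


def test_near_closed_gates_suppress_the_attention_branch(rng):
    """With the attention gate bias at -20 the attention branch contributes
    a <= 1e-6 fraction of what it contributes with the gate wide open."""
    codes, cont = tiny_batch(rng, n=3)

    def branch_contribution(bias: float) -> float:
        model = tiny_model(gate_enabled=True)
        for b in range(model.config.n_blocks):
            model.params[f"block{b}.bg"].data[:] = bias
        with_attn, _ = model.forward(codes, cont)
        for b in range(model.config.n_blocks):        # kill the branch
            model.params[f"block{b}.Wv"].data[:] = 0.0
            model.params[f"block{b}.bv"].data[:] = 0.0
            model.params[f"block{b}.Wo"].data[:] = 0.0
            model.params[f"block{b}.bo"].data[:] = 0.0
        without_attn, _ = model.forward(codes, cont)
        return float(np.linalg.norm(with_attn.data - without_attn.data))

    assert branch_contribution(-20.0) <= 1e-6 * branch_contribution(20.0)


def test_checkpoint_round_trip_is_bit_stable(rng, tmp_path):
    model = tiny_model(seed=9)
    codes, cont = tiny_batch(rng)
    before = model.predict_proba(codes, cont)
    model.save(tmp_path / "ckpt.npz")
    reloaded = GatedTabTransformer.load(tmp_path / "ckpt.npz")
    assert np.array_equal(reloaded.predict_proba(codes, cont), before)
    assert reloaded.checksum() == model.checksum()


def test_gate_input_source_switch_changes_the_gate_argument(rng):
    """Formula-style gating reads the block input; the algorithmic variant
    reads the attention output — with a non-trivial gate weight matrix the
    two disagree."""
    codes, cont = tiny_batch(rng)
    gate_weights = rng.normal(size=(2, 8, 8))
    outputs = []
    for source in ("layer_input", "attention_output"):
        model = tiny_model(gate_input_source=source)
        for b in range(model.config.n_blocks):
            model.params[f"block{b}.Wg"].data[:] = gate_weights[b]
        outputs.append(model.forward(codes, cont)[0].data)
    assert not np.allclose(outputs[0], outputs[1])
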