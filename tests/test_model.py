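import math

import numpy as np
import pytest

from mcwnet import (AttentionGateWeights, LSTMCellWeights, LSTMState,
                    attention_gate, build_acl, forward, lstm_cell_step,
                    load_model, make_network_spec, save_model, softmax)
from oracles import attention_gate_scalar, lstm_step_scalar


class TestSoftmax:
    def test_uniform_on_equal_scores(self):
        np.testing.assert_allclose(softmax([0.0, 0.0, 0.0]), [1 / 3] * 3)

    def test_shift_invariance(self):
        x = np.array([1.3, -0.2, 4.1, 0.0])
        np.testing.assert_allclose(softmax(x + 100.0), softmax(x),
                                   atol=1e-12)

    def test_direct_evaluation(self):
        got = softmax([1.0, 2.0, 3.0])
        e = np.exp([1.0, 2.0, 3.0])
        np.testing.assert_allclose(got, e / e.sum(), atol=1e-12)
        np.testing.assert_allclose(got, [0.0900, 0.2447, 0.6652], atol=1e-4)

    def test_sum_one_and_positive(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 50, size=(20, 5))
        p = softmax(x)
        assert (p > 0).all()
        np.testing.assert_allclose(p.sum(axis=-1), 1.0, atol=1e-12)

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            softmax([np.inf, 0.0])


class TestAttentionGate:
    def test_zero_features_give_zero_output(self):
        rng = np.random.default_rng(1)
        w = AttentionGateWeights.random(2, 3, 4, rng)
        out = attention_gate(np.zeros((4, 4, 2)), rng.random((4, 4, 3)), w)
        np.testing.assert_allclose(out, 0.0)

    def test_zero_weights_halve_features(self):
        w = AttentionGateWeights(np.zeros((2, 3)), np.zeros((2, 3)),
                                 np.zeros(3), np.zeros((3, 1)), 0.0)
        x = np.random.default_rng(2).random((5, 5, 2))
        out, alpha = attention_gate(x, x, w, return_alpha=True)
        np.testing.assert_allclose(alpha, 0.5)
        np.testing.assert_allclose(out, 0.5 * x)

    def test_matches_scalar_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            w = AttentionGateWeights.random(2, 2, 3, rng)
            x = rng.standard_normal((4, 4, 2))
            g = rng.standard_normal((4, 4, 2))
            out, alpha = attention_gate(x, g, w, return_alpha=True)
            want, want_alpha = attention_gate_scalar(
                x, g, w.w_x, w.w_g, w.b_g, w.phi, w.b_phi)
            np.testing.assert_allclose(out, want, atol=1e-6)
            np.testing.assert_allclose(alpha, want_alpha, atol=1e-6)
            assert (alpha > 0).all() and (alpha < 1).all()

    def test_rejects_spatial_mismatch(self):
        w = AttentionGateWeights.random(1, 1, 2, np.random.default_rng(0))
        with pytest.raises(ValueError, match="aligned"):
            attention_gate(np.zeros((4, 4, 1)), np.zeros((5, 5, 1)), w)


class TestLSTMCell:
    def test_zero_everything_gives_zero_state(self):
        w = LSTMCellWeights(*(np.zeros((3, 10)) for _ in range(4)),
                            *(np.zeros(3) for _ in range(4)), hidden=3)
        state = lstm_cell_step(np.zeros(4), LSTMState.zeros(3), w)
        np.testing.assert_allclose(state.h, 0.0)
        np.testing.assert_allclose(state.C, 0.0)

    def test_saturated_gates_preserve_memory(self):
        # forget bias +20 (gate ~ 1), input bias -20 (gate ~ 0): C_t = C_prev
        h = 3
        w = LSTMCellWeights(*(np.zeros((h, 2 + 2 * h)) for _ in range(4)),
                            np.full(h, 20.0), np.full(h, -20.0),
                            np.zeros(h), np.zeros(h), hidden=h)
        prev = LSTMState(np.zeros(h), np.array([0.3, -0.7, 1.2]))
        state = lstm_cell_step(np.array([0.5, -0.5]), prev, w)
        np.testing.assert_allclose(state.C, prev.C, atol=1e-6)

    def test_scalar_hand_evaluation(self):
        # hidden 1, x=1, zero state, unit weights, zero biases
        w = LSTMCellWeights(*(np.ones((1, 3)) for _ in range(4)),
                            *(np.zeros(1) for _ in range(4)), hidden=1)
        state = lstm_cell_step(np.array([1.0]), LSTMState.zeros(1), w)
        sig1 = 1.0 / (1.0 + math.exp(-1.0))
        c_expected = sig1 * math.tanh(1.0)
        h_expected = sig1 * math.tanh(c_expected)
        assert abs(state.C[0] - c_expected) < 1e-9
        assert abs(state.h[0] - h_expected) < 1e-9

    def test_matches_scalar_oracle_with_nonzero_state(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            hidden, d_in = 3, 4
            w = LSTMCellWeights.random(d_in, hidden, rng)
            x = rng.standard_normal(d_in)
            prev = LSTMState(rng.standard_normal(hidden),
                             rng.standard_normal(hidden))
            got = lstm_cell_step(x, prev, w)
            want_h, want_c = lstm_step_scalar(
                x, prev.h, prev.C, w.W_f, w.W_i, w.W_c, w.W_o,
                w.b_f, w.b_i, w.b_c, w.b_o)
            np.testing.assert_allclose(got.h, want_h, atol=1e-6)
            np.testing.assert_allclose(got.C, want_c, atol=1e-6)


class TestBuildAcl:
    def test_full_structure_layer_facts(self):
        model = build_acl("full")
        spec = model.spec
        kinds = spec.kinds()
        assert spec.layer_count == 28
        assert kinds.count("conv") == 6
        assert kinds.count("bn") == 2
        assert kinds.count("maxpool") == 3
        lstm_rows = [l for l in spec.layers if l.kind == "lstm"]
        assert len(lstm_rows) == 1 and lstm_rows[0].info["hidden"] == 100
        mul_rows = [l for l in spec.layers if l.kind == "mul"]
        assert len(mul_rows) == 1 and len(mul_rows[0].inputs) == 2
        drop = next(l for l in spec.layers if l.kind == "dropout")
        assert drop.info["rate"] == pytest.approx(0.40)

    def test_case1_lacks_gating_and_lstm(self):
        spec = build_acl("case1").spec
        kinds = spec.kinds()
        assert "sigmoid" not in kinds and "mul" not in kinds
        assert "lstm" not in kinds

    @pytest.mark.parametrize("variant,has_gate,has_lstm", [
        ("case2", False, True), ("case3", True, False),
    ])
    def test_partial_variants(self, variant, has_gate, has_lstm):
        kinds = build_acl(variant).spec.kinds()
        assert ("mul" in kinds) == has_gate
        assert ("lstm" in kinds) == has_lstm

    def test_parameter_count_ordering(self):
        counts = {v: build_acl(v).param_count()
                  for v in ("full", "case1", "case2", "case3")}
        assert counts["case1"] < counts["case2"] < counts["full"]
        assert counts["case1"] < counts["case3"] < counts["full"]
        # deterministic function of the spec
        assert counts["full"] == build_acl("full", seed=123).param_count()

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="variant"):
            build_acl("case9")

    def test_additive_mode_has_additive_gate(self):
        spec = build_acl("full", attention_mode="additive").spec
        assert "attention_gate" in spec.kinds()
        assert "sigmoid" not in spec.kinds()


class TestForward:
    @pytest.mark.parametrize("variant", ["full", "case1"])
    def test_rows_are_probabilities(self, variant):
        model = build_acl(variant, input_dims=(32, 32, 3), seed=0)
        x = np.random.default_rng(0).random((4, 32, 32, 3)).astype(np.float32)
        p = forward(model, x)
        assert p.shape == (4, 3)
        assert (p >= 0).all()
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_batch_permutation_permutes_outputs(self):
        model = build_acl("full", input_dims=(32, 32, 3), seed=1)
        x = np.random.default_rng(1).random((6, 32, 32, 3)).astype(np.float32)
        perm = np.array([3, 1, 5, 0, 2, 4])
        p = forward(model, x)
        pp = forward(model, x[perm])
        np.testing.assert_allclose(pp, p[perm], atol=2e-5)

    def test_fixed_seed_reproducible(self):
        x = np.random.default_rng(2).random((2, 32, 32, 3)).astype(np.float32)
        a = forward(build_acl("full", input_dims=(32, 32, 3), seed=7), x)
        b = forward(build_acl("full", input_dims=(32, 32, 3), seed=7), x)
        np.testing.assert_array_equal(a, b)

    def test_wrong_input_size_names_expected_dims(self):
        model = build_acl("full")
        with pytest.raises(ValueError, match="100, 100, 3"):
            forward(model, np.zeros((1, 50, 50, 3), np.float32))


class TestSerialization:
    def test_save_load_reproduces_outputs(self, tmp_path):
        model = build_acl("case3", input_dims=(32, 32, 3), seed=5)
        x = np.random.default_rng(5).random((3, 32, 32, 3)).astype(np.float32)
        before = forward(model, x)
        save_model(model, tmp_path / "m")
        again = load_model(tmp_path / "m")
        np.testing.assert_array_equal(forward(again, x), before)
        assert again.spec.variant == "case3"


class TestSpecConsistency:
    def test_shapes_propagate_without_runtime_fixes(self):
        for variant in ("full", "case1", "case2", "case3"):
            for mode in ("sequential", "additive"):
                spec = make_network_spec(variant, (100, 100, 3), 3, mode)
                model = build_acl(variant, (100, 100, 3), 3, 0, mode)
                x = np.zeros((1, 100, 100, 3), np.float32)
                assert model.forward(x).shape == (1, 3)
                assert spec.layers[-1].out_shape == (3,)
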