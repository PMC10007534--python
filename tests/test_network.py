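import numpy as np
import pytest

from strokegcn import autodiff as ad
from strokegcn.autodiff import Tensor
from strokegcn.graph import SkeletonGraph
from strokegcn.network import (ModelConfig, ModelParams, attention_energies,
                               attention_weights, birnn_encode,
                               context_vector, gated_cell, gcn_layer,
                               gcn_stack, head_forward, model_forward,
                               sparse_cce_loss)


@pytest.fixture
def tiny_params(path3, tiny_model_cfg):
    return ModelParams.init(np.random.default_rng(0), path3.n_nodes,
                            tiny_model_cfg)


class TestGCNLayer:
    def test_identity_graph_identity_weights(self):
        X = np.random.default_rng(0).normal(size=(4, 3))
        out = gcn_layer(X, np.eye(4), np.eye(3), "none")
        np.testing.assert_allclose(out.data, X)

    def test_matches_neighbour_sum_oracle(self):
        """Naive double loop: out[i] = sum_j O_hat[i,j] * (X[j] @ W)."""
        rng = np.random.default_rng(3)
        O = np.triu(rng.integers(0, 2, (5, 5)), 1)
        O = (O + O.T).astype(float)
        g = SkeletonGraph.from_adjacency("abcde", O)
        X = rng.normal(size=(5, 3))
        W = rng.normal(size=(3, 2))
        expected = np.zeros((5, 2))
        for i in range(5):
            for j in range(5):
                expected[i] += g.O_hat[i, j] * (X[j] @ W)
        got = gcn_layer(X, g.O_hat, W, "none").data
        np.testing.assert_allclose(got, expected, atol=1e-10)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(5)
        O = np.triu(rng.integers(0, 2, (6, 6)), 1)
        O = (O + O.T).astype(float)
        g = SkeletonGraph.from_adjacency("abcdef", O)
        X = rng.normal(size=(6, 3))
        W = rng.normal(size=(3, 3))
        perm = rng.permutation(6)
        P = np.eye(6)[perm]
        direct = gcn_layer(P @ X, P @ g.O_hat @ P.T, W, "relu").data
        permuted = P @ gcn_layer(X, g.O_hat, W, "relu").data
        np.testing.assert_allclose(direct, permuted, atol=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="node axes"):
            gcn_layer(np.zeros((4, 3)), np.eye(5), np.eye(3))

    def test_unknown_activation_rejected(self):
        with pytest.raises(ValueError, match="activation"):
            gcn_layer(np.zeros((2, 3)), np.eye(2), np.eye(3), "gelu")


class TestGCNStack:
    def test_zero_frame_gives_half_everywhere(self, path3, tiny_params):
        out = gcn_stack(Tensor(np.zeros((3, 3))), Tensor(path3.O_hat),
                        tiny_params)
        np.testing.assert_allclose(out.data, 0.5)

    def test_matches_hand_unrolled_three_stage_oracle(self, path3, tiny_params):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(3, 3))
        O = path3.O_hat
        p0 = tiny_params["gcn.psi0"].data
        p1 = tiny_params["gcn.psi1"].data
        p2 = tiny_params["gcn.psi2"].data
        h1 = O @ X @ p0
        h2 = np.maximum(O @ h1 @ p1, 0.0)
        expected = 1.0 / (1.0 + np.exp(-(O @ h2 @ p2)))
        got = gcn_stack(Tensor(X), Tensor(O), tiny_params).data
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_output_bounded_in_unit_interval(self, path3, tiny_params):
        X = np.random.default_rng(2).normal(size=(10, 3, 3))
        out = gcn_stack(Tensor(X), Tensor(path3.O_hat), tiny_params).data
        assert np.all(out > 0.0) and np.all(out < 1.0)


class TestGatedCell:
    def _zero_weights(self, d, h):
        z = lambda: Tensor(np.zeros((d + h, h)))
        return z(), z(), z()

    def test_zero_weights_zero_state(self):
        Wu, Wr, Wc = self._zero_weights(4, 3)
        out = gated_cell(np.zeros((1, 4)), np.zeros((1, 3)), Wu, Wr, Wc)
        np.testing.assert_allclose(out["ugc"].data, 0.5)
        np.testing.assert_allclose(out["rgc"].data, 0.5)
        np.testing.assert_allclose(out["mc"].data, 0.0)
        np.testing.assert_allclose(out["h"].data, 0.0)

    def test_zero_weights_halve_previous_state(self):
        """With all weights zero the update gate is 1/2 and the candidate
        is 0, so the published state update gives h = v/2."""
        Wu, Wr, Wc = self._zero_weights(4, 3)
        v = np.array([[1.0, -2.0, 0.5]])
        out = gated_cell(np.zeros((1, 4)), v, Wu, Wr, Wc)
        np.testing.assert_allclose(out["h"].data, 0.5 * v)

    def test_gates_strictly_inside_unit_interval(self):
        rng = np.random.default_rng(0)
        Wu, Wr, Wc = (Tensor(rng.normal(size=(7, 3))) for _ in range(3))
        out = gated_cell(rng.normal(size=(5, 4)),
                         rng.normal(size=(5, 3)), Wu, Wr, Wc)
        for gate in ("ugc", "rgc"):
            assert np.all(out[gate].data > 0.0)
            assert np.all(out[gate].data < 1.0)


class TestBiRNN:
    def test_matches_stepwise_unroll_oracle(self, tiny_params, tiny_model_cfg):
        rng = np.random.default_rng(4)
        D = 3 * tiny_model_cfg.gcn_out  # flattened 3-node frame vector
        seq = rng.normal(size=(2, 3, D))
        H = birnn_encode(Tensor(seq), tiny_params).data
        h_dim = tiny_model_cfg.rnn_hidden
        # manual forward direction
        h = np.zeros((2, h_dim))
        for t in range(3):
            step = gated_cell(Tensor(seq[:, t]), Tensor(h),
                              tiny_params["rnn.fwd.Wu"],
                              tiny_params["rnn.fwd.Wr"],
                              tiny_params["rnn.fwd.Wc"])
            h = step["h"].data
            np.testing.assert_allclose(H[:, t, :h_dim], h, atol=1e-12)
        # manual backward direction
        h = np.zeros((2, h_dim))
        for t in reversed(range(3)):
            step = gated_cell(Tensor(seq[:, t]), Tensor(h),
                              tiny_params["rnn.bwd.Wu"],
                              tiny_params["rnn.bwd.Wr"],
                              tiny_params["rnn.bwd.Wc"])
            h = step["h"].data
            np.testing.assert_allclose(H[:, t, h_dim:], h, atol=1e-12)

    def test_time_reversal_with_swapped_directions(self, tiny_model_cfg):
        rng = np.random.default_rng(8)
        params = ModelParams.init(rng, 3, tiny_model_cfg)
        swapped = ModelParams.init(rng, 3, tiny_model_cfg)
        for gate in ("Wu", "Wr", "Wc"):
            swapped.weights[f"rnn.fwd.{gate}"].data[...] = \
                params[f"rnn.bwd.{gate}"].data
            swapped.weights[f"rnn.bwd.{gate}"].data[...] = \
                params[f"rnn.fwd.{gate}"].data
        seq = rng.normal(size=(1, 4, 3 * tiny_model_cfg.gcn_out))
        H = birnn_encode(Tensor(seq), params).data
        H_rev = birnn_encode(Tensor(seq[:, ::-1].copy()), swapped).data
        h = tiny_model_cfg.rnn_hidden
        np.testing.assert_allclose(H_rev[:, ::-1, h:], H[:, :, :h], atol=1e-12)
        np.testing.assert_allclose(H_rev[:, ::-1, :h], H[:, :, h:], atol=1e-12)

    def test_single_frame_both_directions_see_it(self, tiny_params,
                                                 tiny_model_cfg):
        seq = np.random.default_rng(1).normal(size=(1, 1, 3 * 2))
        H = birnn_encode(Tensor(seq), tiny_params).data
        assert H.shape == (1, 1, 2 * tiny_model_cfg.rnn_hidden)

    def test_empty_sequence_rejected(self, tiny_params):
        with pytest.raises(ValueError, match="empty"):
            birnn_encode([], tiny_params)


class TestAttention:
    def test_zero_weights_energies_equal_second_bias(self, tiny_params):
        for k in ("att.psi1", "att.psi2", "att.b1"):
            tiny_params.weights[k].data[...] = 0.0
        tiny_params.weights["att.b2"].data[...] = 3.25
        H = np.random.default_rng(0).normal(size=(2, 5, 6))
        e = attention_energies(Tensor(H), tiny_params).data
        np.testing.assert_allclose(e, 3.25)

    def test_matches_per_timestep_two_layer_oracle(self, tiny_params):
        rng = np.random.default_rng(2)
        H = rng.normal(size=(1, 3, 6))
        got = attention_energies(Tensor(H), tiny_params).data
        for t in range(3):
            hidden = H[0, t] @ tiny_params["att.psi1"].data \
                + tiny_params["att.b1"].data
            expected = hidden @ tiny_params["att.psi2"].data \
                + tiny_params["att.b2"].data
            np.testing.assert_allclose(got[0, t], expected[0], atol=1e-12)

    def test_softmax_closed_forms(self):
        np.testing.assert_allclose(
            attention_weights(Tensor(np.array([[0.0, 0.0]]))).data,
            [[0.5, 0.5]])
        np.testing.assert_allclose(
            attention_weights(Tensor(np.array([[np.log(2.0), 0.0]]))).data,
            [[2 / 3, 1 / 3]], atol=1e-12)

    def test_shift_invariance_and_normalization(self):
        rng = np.random.default_rng(3)
        e = rng.normal(size=(4, 7)) * 50
        a1 = attention_weights(Tensor(e)).data
        a2 = attention_weights(Tensor(e + 123.456)).data
        np.testing.assert_allclose(a1, a2, atol=1e-12)
        np.testing.assert_allclose(a1.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(a1 >= 0)

    def test_context_vector_convexity_and_selection(self):
        rng = np.random.default_rng(4)
        h = rng.normal(size=6)
        H = np.tile(h, (1, 5, 1))
        alpha = attention_weights(Tensor(rng.normal(size=(1, 5)))).data
        cv = context_vector(Tensor(H), Tensor(alpha)).data
        np.testing.assert_allclose(cv[0], h, atol=1e-12)  # identical states
        one_hot = np.zeros((1, 5))
        one_hot[0, 3] = 1.0
        H2 = rng.normal(size=(1, 5, 6))
        cv2 = context_vector(Tensor(H2), Tensor(one_hot)).data
        np.testing.assert_allclose(cv2[0], H2[0, 3], atol=1e-12)

    def test_context_vector_matches_loop_sum_oracle(self):
        rng = np.random.default_rng(5)
        H = rng.normal(size=(2, 4, 3))
        alpha = attention_weights(Tensor(rng.normal(size=(2, 4)))).data
        got = context_vector(Tensor(H), Tensor(alpha)).data
        expected = np.zeros((2, 3))
        for b in range(2):
            for t in range(4):
                expected[b] += alpha[b, t] * H[b, t]
        np.testing.assert_allclose(got, expected, atol=1e-12)


class TestHeadAndLoss:
    def test_probabilities_form_a_simplex(self, tiny_params):
        Cv = np.random.default_rng(0).normal(size=(8, 6)) * 10
        p = head_forward(Tensor(Cv), tiny_params).data
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(p >= 0)

    def test_zero_weights_give_uniform_prediction(self, tiny_params):
        for k in ("head.W1", "head.b1", "head.W2", "head.b2"):
            tiny_params.weights[k].data[...] = 0.0
        p = head_forward(Tensor(np.random.default_rng(1).normal(size=(3, 6))),
                         tiny_params).data
        np.testing.assert_allclose(p, 0.25, atol=1e-12)

    def test_faithful_mode_hidden_is_constant_one(self, path3):
        cfg = ModelConfig(gcn_hidden=2, gcn_out=2, rnn_hidden=3,
                          faithful_head=True, center=False)
        params = ModelParams.init(np.random.default_rng(0), 3, cfg)
        assert params["head.W1"].data.shape[1] == 1
        # softmax over a single unit is identically 1, so the prediction
        # cannot depend on the context vector
        Cv = np.random.default_rng(2).normal(size=(4, 6))
        p1 = head_forward(Tensor(Cv), params).data
        p2 = head_forward(Tensor(Cv * 5), params).data
        np.testing.assert_allclose(p1, p2, atol=1e-12)

    def test_loss_zero_when_true_class_certain(self):
        p = np.zeros((2, 4))
        p[0, 1] = p[1, 3] = 1.0
        loss = sparse_cce_loss(Tensor(p), [1, 3])
        assert float(loss.data) == pytest.approx(0.0, abs=1e-10)

    def test_uniform_prediction_loss_is_ln4(self):
        p = np.full((6, 4), 0.25)
        loss = sparse_cce_loss(Tensor(p), [0, 1, 2, 3, 0, 1])
        assert float(loss.data) == pytest.approx(np.log(4.0), abs=1e-9)

    def test_loss_nonnegative_and_label_validated(self):
        rng = np.random.default_rng(0)
        p = ad.softmax(Tensor(rng.normal(size=(5, 4))), axis=-1)
        assert float(sparse_cce_loss(p, [0, 1, 2, 3, 0]).data) >= 0.0
        with pytest.raises(ValueError, match="label"):
            sparse_cce_loss(p, [0, 1, 2, 3, 4])


class TestModelForward:
    def test_output_is_simplex_and_deterministic(self, path3, tiny_params):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(3, 2, 3, 3))
        p1 = model_forward(X, path3, tiny_params).data
        p2 = model_forward(X, path3, tiny_params).data
        np.testing.assert_array_equal(p1, p2)
        np.testing.assert_allclose(p1.sum(axis=1), 1.0, atol=1e-12)

    def test_batch_of_identical_trials_identical_outputs(self, path3,
                                                         tiny_params):
        x = np.random.default_rng(7).normal(size=(2, 3, 3))
        X = np.stack([x, x, x])
        p = model_forward(X, path3, tiny_params).data
        np.testing.assert_allclose(p[1:] - p[0], 0.0, atol=1e-14)

    def test_marker_count_mismatch_rejected(self, path3, tiny_params):
        with pytest.raises(ValueError, match="markers"):
            model_forward(np.zeros((1, 2, 4, 3)), path3, tiny_params)

    def test_equals_stagewise_composition_oracle(self, path3, tiny_params):
        """model_forward is exactly the composition of the stage functions."""
        rng = np.random.default_rng(8)
        X = rng.normal(size=(2, 2, 3, 3))
        emb = gcn_stack(Tensor(X), Tensor(path3.O_hat), tiny_params)
        frames = emb.data.reshape(2, 2, -1)
        H = birnn_encode(Tensor(frames), tiny_params)
        alpha = attention_weights(attention_energies(H, tiny_params))
        Cv = context_vector(H, alpha)
        expected = head_forward(Cv, tiny_params).data
        got = model_forward(X, path3, tiny_params).data
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_checkpoint_round_trip(self, path3, tiny_params, tmp_path):
        X = np.random.default_rng(9).normal(size=(1, 2, 3, 3))
        before = model_forward(X, path3, tiny_params).data
        path = tmp_path / "ckpt.npz"
        tiny_params.save(path)
        restored = ModelParams.load(path)
        after = model_forward(X, path3, restored).data
        np.testing.assert_array_equal(before, after)
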