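"""Recurrence-level tests, including an independent scalar oracle.

The oracle below evaluates the gate equations with plain Python floats and
``math`` calls, entirely separate from the vectorized NumPy path it
checks.
"""

import math

import numpy as np
import pytest

from mhclstm.network import (
    BiLSTMNetwork,
    LSTMParameters,
    LSTMState,
    NetworkConfig,
    bilstm_encode,
    lstm_forward,
    lstm_step,
    predict_head,
)
from mhclstm.substitution import load_substitution_matrix


def scalar_lstm_run(seq, Wx, Uh, b, hidden):
    """Pure-Python step-by-step evaluation of the gate equations."""

    def sig(z):
        return 1.0 / (1.0 + math.exp(-z))

    H = hidden
    h = [0.0] * H
    C = [0.0] * H
    states = []
    for x in seq:
        a = []
        for row in range(4 * H):
            acc = b[row]
            for j, xj in enumerate(x):
                acc += Wx[row][j] * xj
            for j in range(H):
                acc += Uh[row][j] * h[j]
            a.append(acc)
        f = [sig(a[0 * H + u]) for u in range(H)]
        i = [sig(a[1 * H + u]) for u in range(H)]
        o = [sig(a[2 * H + u]) for u in range(H)]
        g = [math.tanh(a[3 * H + u]) for u in range(H)]
        C = [i[u] * g[u] + f[u] * C[u] for u in range(H)]
        h = [o[u] * math.tanh(C[u]) for u in range(H)]
        states.append((list(h), list(C)))
    return states


def small_params(rng, input_size=3, hidden=2, scale=0.5):
    return LSTMParameters(
        Wx=scale * rng.normal(size=(4 * hidden, input_size)),
        Uh=scale * rng.normal(size=(4 * hidden, hidden)),
        b=scale * rng.normal(size=4 * hidden),
    )


class TestLSTMStep:
    def test_all_zero_parameters_give_zero_state(self):
        params = LSTMParameters.zeros(4, 3)
        state = LSTMState.zeros(3)
        for _ in range(5):
            state = lstm_step(np.ones(4), state, params)
            assert np.all(state.h == 0.0) and np.all(state.C == 0.0)

    def test_saturated_gates_preserve_cell(self):
        # huge f/i/o biases force the gates to ~1; zero candidate weights
        # then make C_t = tanh(0)*1 + C_{t-1} = C_{t-1}, h_t = tanh(C_t)
        H = 1
        b = np.array([50.0, 50.0, 50.0, 0.0])
        params = LSTMParameters(np.zeros((4, 2)), np.zeros((4, 1)), b)
        prev = LSTMState(h=np.zeros(1), C=np.array([0.7]))
        state = lstm_step(np.array([0.3, -0.2]), prev, params)
        assert state.C[0] == pytest.approx(0.7, abs=1e-10)
        assert state.h[0] == pytest.approx(math.tanh(0.7), abs=1e-10)

    def test_matches_scalar_oracle(self, rng):
        params = small_params(rng)
        xs = [rng.normal(size=3) for _ in range(3)]
        expected = scalar_lstm_run([x.tolist() for x in xs],
                                   params.Wx.tolist(), params.Uh.tolist(),
                                   params.b.tolist(), hidden=2)
        state = LSTMState.zeros(2)
        for x, (h_exp, C_exp) in zip(xs, expected):
            state = lstm_step(x, state, params)
            assert np.max(np.abs(state.h - np.array(h_exp))) < 1e-10
            assert np.max(np.abs(state.C - np.array(C_exp))) < 1e-10

    def test_gate_ranges(self, rng):
        params = small_params(rng, scale=2.0)
        state = lstm_step(rng.normal(size=3), LSTMState.zeros(2), params)
        assert np.all(np.abs(state.h) < 1.0)

    def test_dimension_mismatch(self, rng):
        with pytest.raises(ValueError):
            lstm_step(np.ones(5), LSTMState.zeros(2), small_params(rng))


class TestLSTMForward:
    def test_length_one(self, rng):
        params = small_params(rng)
        x = rng.normal(size=(1, 3))
        final, hs = lstm_forward(x, params)
        step = lstm_step(x[0], LSTMState.zeros(2), params)
        assert np.array_equal(final.h, step.h) and hs.shape == (1, 2)

    def test_backward_equals_forward_on_reversed(self, rng):
        params = small_params(rng)
        seq = rng.normal(size=(5, 3))
        fin_b, hs_b = lstm_forward(seq, params, "backward")
        fin_f, hs_f = lstm_forward(seq[::-1], params, "forward")
        assert np.array_equal(fin_b.h, fin_f.h)
        assert np.array_equal(hs_b, hs_f)

    def test_matches_scalar_oracle_per_step(self, rng):
        params = small_params(rng)
        seq = rng.normal(size=(3, 3))
        expected = scalar_lstm_run(seq.tolist(), params.Wx.tolist(),
                                   params.Uh.tolist(), params.b.tolist(), 2)
        _, hs = lstm_forward(seq, params)
        for t, (h_exp, _) in enumerate(expected):
            assert np.max(np.abs(hs[t] - np.array(h_exp))) < 1e-10

    def test_empty_sequence_rejected(self, rng):
        with pytest.raises(ValueError):
            lstm_forward(np.zeros((0, 3)), small_params(rng))


class TestBiLSTMEncode:
    def test_zero_network_gives_zero_vector(self):
        fwd = LSTMParameters.zeros(20, 64)
        bwd = LSTMParameters.zeros(20, 64)
        v = bilstm_encode(np.random.default_rng(0).normal(size=(9, 20)), fwd, bwd)
        assert v.shape == (128,) and np.all(v == 0.0)

    def test_palindrome_with_shared_parameters(self, rng):
        params = small_params(rng, input_size=4, hidden=3)
        half = rng.normal(size=(3, 4))
        seq = np.vstack([half, half[::-1]])
        v = bilstm_encode(seq, params, params)
        assert np.allclose(v[:3], v[3:])

    def test_output_size_independent_of_length(self, rng):
        fwd = small_params(rng, input_size=20, hidden=64)
        bwd = small_params(rng, input_size=20, hidden=64)
        for L in (9, 15):
            assert bilstm_encode(rng.normal(size=(L, 20)), fwd, bwd).shape == (128,)


class TestPredictHead:
    def test_zero_head_outputs_half(self):
        p = predict_head(np.ones(8), np.zeros((4, 8)), np.zeros(4),
                         np.zeros((1, 4)), np.zeros(1))
        assert p == 0.5

    def test_output_in_unit_interval(self, rng):
        for _ in range(20):
            p = predict_head(
                rng.normal(size=6),
                rng.normal(size=(3, 6)), rng.normal(size=3),
                rng.normal(size=(1, 3)), rng.normal(size=1),
            )
            assert 0.0 < p < 1.0

    def test_matches_hand_computation(self):
        W1 = np.array([[1.0, -1.0], [0.5, 0.5]])
        b1 = np.array([0.1, -0.2])
        W2 = np.array([[2.0, -1.0]])
        b2 = np.array([0.3])
        enc = np.array([0.4, 0.9])
        z1 = [0.4 - 0.9 + 0.1, 0.2 + 0.45 - 0.2]
        a1 = [max(z, 0.0) for z in z1]
        z2 = 2.0 * a1[0] - 1.0 * a1[1] + 0.3
        expected = 1.0 / (1.0 + math.exp(-z2))
        assert predict_head(enc, W1, b1, W2, b2) == pytest.approx(expected, abs=1e-12)


class TestFullNetwork:
    def test_zero_model_scores_half_for_any_peptide(self):
        net = BiLSTMNetwork.zeros()
        for pep in ("SIINFEKL", "A", "ACDEFGHIKLMNPQRSTVWY" + "ACDEF"):
            assert net.forward(pep) == 0.5

    def test_batched_matches_standalone_path(self, rng, blosum62):
        """The padded/masked batch path must equal the simple per-peptide
        composition of evo_transform -> bilstm_encode -> predict_head."""
        from mhclstm.encoding import EvoKernelBank, evo_transform, one_hot_encode

        cfg = NetworkConfig(hidden_size=6, fc_hidden=4)
        net = BiLSTMNetwork.initialize(cfg, blosum62, rng)
        peptides = ["SIINFEKL", "GILGFVFTLW", "ACD"]
        batch = net.predict_proba(peptides)
        for pep, p_batch in zip(peptides, batch):
            E = evo_transform(one_hot_encode(pep), net.evo)
            v = bilstm_encode(E, net.fwd, net.bwd)
            p_single = predict_head(v, net.W1, net.b1, net.W2, net.b2)
            assert p_batch == pytest.approx(p_single, abs=1e-10)

    def test_padding_invariance(self, rng, blosum62):
        cfg = NetworkConfig()
        net = BiLSTMNetwork.initialize(cfg, blosum62, rng)
        peptides = ["SIINFEKL", "GILGFVFTL", "KLGGALQAKV", "LPEPLPQGQLTAY",
                    "A" * 25, "WY"]
        singleton = np.array([net.forward(p) for p in peptides])
        batched = net.predict_proba(peptides)
        shuffled = net.predict_proba(peptides[::-1])[::-1]
        assert np.max(np.abs(batched - singleton)) <= 1e-5
        assert np.max(np.abs(shuffled - singleton)) <= 1e-5

    def test_inference_deterministic(self, rng, blosum62):
        net = BiLSTMNetwork.initialize(NetworkConfig(), blosum62, rng)
        a = net.predict_proba(["SIINFEKL", "GILGFVFTL"])
        b = net.predict_proba(["SIINFEKL", "GILGFVFTL"])
        assert np.array_equal(a, b)

    def test_gradients_match_numerical(self, rng, blosum62):
        cfg = NetworkConfig(hidden_size=3, fc_hidden=2, dropout_rate=1.0)
        net = BiLSTMNetwork.initialize(cfg, blosum62, rng)
        net.evo.weights *= 0.3
        seqs = ["ACDEF", "KLMNPQR"]
        targets = np.array([1.0, 0.3])
        _, grads = net.loss_and_gradients(seqs, targets, train=False)
        params = net.parameters()
        eps = 1e-6
        for name, arr in params.items():
            idx = tuple(rng.integers(0, s) for s in arr.shape)
            old = arr[idx]
            arr[idx] = old + eps
            lp, _ = net.loss_and_gradients(seqs, targets, train=False)
            arr[idx] = old - eps
            lm, _ = net.loss_and_gradients(seqs, targets, train=False)
            arr[idx] = old
            num = (lp - lm) / (2 * eps)
            assert grads[name][idx] == pytest.approx(num, abs=1e-6, rel=1e-4)
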