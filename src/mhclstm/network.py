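"""Bidirectional LSTM binding network, implemented in NumPy (float64).

The architecture, front to back:

* evolutionary feature layer (:mod:`mhclstm.encoding`): one-hot 20xL →
  Lx20 features through the learnable BLOSUM-initialized kernel bank;
* two LSTM chains reading the feature matrix left-to-right and
  right-to-left; each maintains gated hidden/cell states

  .. code-block:: text

      f_t = sigmoid(W_f x_t + U_f h_{t-1} + b_f)     (forget gate)
      i_t = sigmoid(W_i x_t + U_i h_{t-1} + b_i)     (input gate)
      o_t = sigmoid(W_o x_t + U_o h_{t-1} + b_o)     (output gate)
      C_t = i_t * tanh(W_c x_t + U_c h_{t-1} + b_c) + f_t * C_{t-1}
      h_t = o_t * tanh(C_t)

* the two final hidden states are concatenated into one fixed-size vector
  (64 units per direction → 128 by default) — this is what makes the
  predictor independent of peptide length;
* dropout, then two fully-connected layers (ReLU bottleneck, default
  128→32→1) and a sigmoid yielding the binding probability.

Variable-length batches are padded and masked: at padded positions the
recurrent state is carried through unchanged, so each peptide's output is
identical whether scored alone or inside any batch.  Training gradients
(binary cross-entropy, backpropagation through time) are computed in
closed form by :meth:`BiLSTMNetwork.loss_and_gradients`.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np

from .alphabet import AA_INDEX, N_AMINO_ACIDS, validate_sequence
from .encoding import EvoKernelBank
from .substitution import SubstitutionMatrix

GATES = "fioc"  # stacked gate order: forget, input, output, cell candidate


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclasses.dataclass
class LSTMState:
    """Hidden and cell state vectors for one direction."""

    h: np.ndarray
    C: np.ndarray

    @classmethod
    def zeros(cls, hidden_size: int) -> "LSTMState":
        return cls(h=np.zeros(hidden_size), C=np.zeros(hidden_size))


class LSTMParameters:
    """Gate weights for one LSTM direction.

    Stored stacked (``Wx``: 4H x D input weights, ``Uh``: 4H x H recurrent
    weights, ``b``: 4H biases, gate order f, i, o, c); the per-gate
    matrices ``W_f`` ... ``b_c`` are exposed as views.
    """

    def __init__(self, Wx: np.ndarray, Uh: np.ndarray, b: np.ndarray):
        Wx = np.asarray(Wx, dtype=float)
        Uh = np.asarray(Uh, dtype=float)
        b = np.asarray(b, dtype=float)
        if Wx.shape[0] % 4 or Wx.shape[0] != Uh.shape[0] or Uh.shape[0] != b.shape[0]:
            raise ValueError("stacked gate arrays must share a 4H leading dim")
        H = Wx.shape[0] // 4
        if Uh.shape[1] != H:
            raise ValueError(f"recurrent weights must be 4Hx{H}, got {Uh.shape}")
        self.Wx, self.Uh, self.b = Wx, Uh, b
        self.hidden_size = H
        self.input_size = Wx.shape[1]

    def _gate(self, which: str):
        g = GATES.index(which)
        H = self.hidden_size
        return slice(g * H, (g + 1) * H)

    def __getattr__(self, name: str):
        # W_f / U_f / b_f ... as views into the stacked arrays
        if len(name) == 3 and name[1] == "_" and name[2] in GATES:
            sl = self._gate(name[2])
            if name[0] == "W":
                return self.Wx[sl]
            if name[0] == "U":
                return self.Uh[sl]
            if name[0] == "b":
                return self.b[sl]
        raise AttributeError(name)

    @classmethod
    def initialize(
        cls, input_size: int, hidden_size: int, rng: np.random.Generator
    ) -> "LSTMParameters":
        """Uniform(-1/sqrt(H), 1/sqrt(H)) weights; forget-gate bias +1."""
        bound = 1.0 / np.sqrt(hidden_size)
        Wx = rng.uniform(-bound, bound, size=(4 * hidden_size, input_size))
        Uh = rng.uniform(-bound, bound, size=(4 * hidden_size, hidden_size))
        b = np.zeros(4 * hidden_size)
        b[:hidden_size] = 1.0  # forget-gate bias: remember by default
        return cls(Wx, Uh, b)

    @classmethod
    def zeros(cls, input_size: int, hidden_size: int) -> "LSTMParameters":
        return cls(
            np.zeros((4 * hidden_size, input_size)),
            np.zeros((4 * hidden_size, hidden_size)),
            np.zeros(4 * hidden_size),
        )


@dataclasses.dataclass
class NetworkConfig:
    """Architecture hyperparameters.

    ``dropout_rate`` follows the convention selected by
    ``dropout_rate_is_keep_prob``: by default 0.8 means 80% of the units
    are *kept* (20% dropped).  Dropout acts only in training mode, between
    the biLSTM vector and the first fully-connected layer; inference is
    deterministic.
    """

    hidden_size: int = 64          # per direction; concatenated vector = 2x
    fc_hidden: int = 32
    dropout_rate: float = 0.8
    dropout_rate_is_keep_prob: bool = True
    substitution_matrix: str = "BLOSUM62"

    @property
    def keep_prob(self) -> float:
        p = self.dropout_rate if self.dropout_rate_is_keep_prob else 1.0 - self.dropout_rate
        if not 0.0 < p <= 1.0:
            raise ValueError(f"keep probability {p} outside (0, 1]")
        return p

    @property
    def encoding_size(self) -> int:
        return 2 * self.hidden_size

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def lstm_step(x_t: np.ndarray, prev: LSTMState, params: LSTMParameters) -> LSTMState:
    """One recurrence step for a single (unbatched) input vector."""
    x_t = np.asarray(x_t, dtype=float)
    if x_t.shape != (params.input_size,):
        raise ValueError(f"expected input of shape ({params.input_size},), got {x_t.shape}")
    a = params.Wx @ x_t + params.Uh @ prev.h + params.b
    H = params.hidden_size
    f = sigmoid(a[0 * H : 1 * H])
    i = sigmoid(a[1 * H : 2 * H])
    o = sigmoid(a[2 * H : 3 * H])
    g = np.tanh(a[3 * H : 4 * H])
    C = i * g + f * prev.C
    h = o * np.tanh(C)
    return LSTMState(h=h, C=C)


def lstm_forward(
    seq: np.ndarray, params: LSTMParameters, direction: str = "forward"
) -> tuple[LSTMState, np.ndarray]:
    """Run the LSTM over an Lx(input) feature matrix from a zero state.

    ``direction`` is ``"forward"`` (left-to-right) or ``"backward"``
    (right-to-left).  Returns the final state and the LxH per-step hidden
    vectors in processing order.
    """
    seq = np.asarray(seq, dtype=float)
    if seq.ndim != 2 or seq.shape[0] < 1:
        raise ValueError("sequence must be a non-empty Lx(input) matrix")
    if direction not in ("forward", "backward"):
        raise ValueError(f"unknown direction {direction!r}")
    steps = seq if direction == "forward" else seq[::-1]
    state = LSTMState.zeros(params.hidden_size)
    hs = np.empty((seq.shape[0], params.hidden_size))
    for t, x_t in enumerate(steps):
        state = lstm_step(x_t, state, params)
        hs[t] = state.h
    return state, hs


def bilstm_encode(
    seq: np.ndarray, fwd: LSTMParameters, bwd: LSTMParameters
) -> np.ndarray:
    """Fixed-size sequence encoding: concat of the two final hidden states."""
    if fwd.hidden_size != bwd.hidden_size:
        raise ValueError("both directions must share the hidden size")
    final_f, _ = lstm_forward(seq, fwd, "forward")
    final_b, _ = lstm_forward(seq, bwd, "backward")
    return np.concatenate([final_f.h, final_b.h])


def predict_head(
    encoding: np.ndarray,
    W1: np.ndarray,
    b1: np.ndarray,
    W2: np.ndarray,
    b2: np.ndarray,
) -> float:
    """Two fully-connected layers (ReLU bottleneck) and a sigmoid."""
    encoding = np.asarray(encoding, dtype=float)
    z1 = W1 @ encoding + b1
    a1 = np.maximum(z1, 0.0)
    z2 = float((W2 @ a1 + b2)[0])
    return float(sigmoid(np.array([z2]))[0])


def _one_hot_batch(sequences: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    """Pad a batch of peptides into (B, Lmax, 20) one-hots + (B,) lengths."""
    if len(sequences) == 0:
        raise ValueError("empty batch")
    for s in sequences:
        validate_sequence(s)
    lengths = np.array([len(s) for s in sequences])
    Lmax = int(lengths.max())
    X = np.zeros((len(sequences), Lmax, N_AMINO_ACIDS))
    for b, s in enumerate(sequences):
        for t, aa in enumerate(s):
            X[b, t, AA_INDEX[aa]] = 1.0
    return X, lengths


def _reverse_within_lengths(E: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """Reverse each sequence in place of its own length (padding stays)."""
    B = E.shape[0]
    out = np.zeros_like(E)
    for b in range(B):
        L = lengths[b]
        out[b, :L] = E[b, L - 1 :: -1]
    return out


class BiLSTMNetwork:
    """Full length-independent binding predictor with trainable parameters."""

    def __init__(
        self,
        evo: EvoKernelBank,
        fwd: LSTMParameters,
        bwd: LSTMParameters,
        W1: np.ndarray,
        b1: np.ndarray,
        W2: np.ndarray,
        b2: np.ndarray,
        config: NetworkConfig,
    ):
        self.evo = evo
        self.fwd = fwd
        self.bwd = bwd
        self.W1, self.b1 = np.asarray(W1, float), np.asarray(b1, float)
        self.W2, self.b2 = np.asarray(W2, float), np.asarray(b2, float)
        self.config = config

    @classmethod
    def initialize(
        cls,
        config: NetworkConfig,
        substitution: SubstitutionMatrix,
        rng: np.random.Generator,
    ) -> "BiLSTMNetwork":
        H, F = config.hidden_size, config.fc_hidden
        evo = EvoKernelBank.from_substitution_matrix(substitution)
        fwd = LSTMParameters.initialize(N_AMINO_ACIDS, H, rng)
        bwd = LSTMParameters.initialize(N_AMINO_ACIDS, H, rng)
        g1 = np.sqrt(6.0 / (2 * H + F))
        W1 = rng.uniform(-g1, g1, size=(F, 2 * H))
        g2 = np.sqrt(6.0 / (F + 1))
        W2 = rng.uniform(-g2, g2, size=(1, F))
        return cls(evo, fwd, bwd, W1, np.zeros(F), W2, np.zeros(1), config)

    @classmethod
    def zeros(cls, config: NetworkConfig | None = None) -> "BiLSTMNetwork":
        """All-zero network: every peptide scores exactly 0.5 (sanity anchor)."""
        config = config or NetworkConfig()
        H, F = config.hidden_size, config.fc_hidden
        evo = EvoKernelBank(np.zeros((20, 20)), init_name="zeros")
        return cls(
            evo,
            LSTMParameters.zeros(N_AMINO_ACIDS, H),
            LSTMParameters.zeros(N_AMINO_ACIDS, H),
            np.zeros((F, 2 * H)),
            np.zeros(F),
            np.zeros((1, F)),
            np.zeros(1),
            config,
        )

    # --- parameter registry (optimizer + persistence) -------------------

    def parameters(self) -> dict[str, np.ndarray]:
        return {
            "evo.weights": self.evo.weights,
            "fwd.Wx": self.fwd.Wx,
            "fwd.Uh": self.fwd.Uh,
            "fwd.b": self.fwd.b,
            "bwd.Wx": self.bwd.Wx,
            "bwd.Uh": self.bwd.Uh,
            "bwd.b": self.bwd.b,
            "head.W1": self.W1,
            "head.b1": self.b1,
            "head.W2": self.W2,
            "head.b2": self.b2,
        }

    def set_parameters(self, arrays: dict[str, np.ndarray]) -> None:
        self.evo.weights = np.asarray(arrays["evo.weights"], float)
        self.fwd = LSTMParameters(arrays["fwd.Wx"], arrays["fwd.Uh"], arrays["fwd.b"])
        self.bwd = LSTMParameters(arrays["bwd.Wx"], arrays["bwd.Uh"], arrays["bwd.b"])
        self.W1 = np.asarray(arrays["head.W1"], float)
        self.b1 = np.asarray(arrays["head.b1"], float)
        self.W2 = np.asarray(arrays["head.W2"], float)
        self.b2 = np.asarray(arrays["head.b2"], float)

    # --- inference ------------------------------------------------------

    def forward(self, peptide: str) -> float:
        """Binding probability for one peptide of any length >= 1."""
        return float(self.predict_proba([peptide])[0])

    def predict_proba(self, sequences: Sequence[str]) -> np.ndarray:
        """Deterministic batched inference (dropout off)."""
        X, lengths = _one_hot_batch(sequences)
        v = self._encode_batch(X, lengths)[0]
        z1 = v @ self.W1.T + self.b1
        a1 = np.maximum(z1, 0.0)
        z2 = a1 @ self.W2.T + self.b2
        return sigmoid(z2)[:, 0]

    # --- batched forward/backward --------------------------------------

    def _masked_lstm(self, E, mask, params):
        """Masked batched LSTM pass; returns final (h, C) and step caches."""
        B, Lmax, _ = E.shape
        H = params.hidden_size
        h = np.zeros((B, H))
        C = np.zeros((B, H))
        caches = []
        for t in range(Lmax):
            x_t = E[:, t, :]
            a = x_t @ params.Wx.T + h @ params.Uh.T + params.b
            f = sigmoid(a[:, 0 * H : 1 * H])
            i = sigmoid(a[:, 1 * H : 2 * H])
            o = sigmoid(a[:, 2 * H : 3 * H])
            g = np.tanh(a[:, 3 * H : 4 * H])
            C_new = i * g + f * C
            tanh_C = np.tanh(C_new)
            h_new = o * tanh_C
            m = mask[:, t : t + 1]
            C_next = m * C_new + (1.0 - m) * C
            h_next = m * h_new + (1.0 - m) * h
            caches.append((x_t, h, C, f, i, o, g, tanh_C, m))
            h, C = h_next, C_next
        return h, C, caches

    def _masked_lstm_backward(self, dh_final, params, caches, Lmax):
        """BPTT through :meth:`_masked_lstm`; returns grads and dE."""
        B, H = dh_final.shape
        dWx = np.zeros_like(params.Wx)
        dUh = np.zeros_like(params.Uh)
        db = np.zeros_like(params.b)
        dE = np.zeros((B, Lmax, params.input_size))
        dh = dh_final
        dC = np.zeros((B, H))
        for t in range(Lmax - 1, -1, -1):
            x_t, h_prev, C_prev, f, i, o, g, tanh_C, m = caches[t]
            dh_new = m * dh
            dh_carry = (1.0 - m) * dh
            dC_new = m * dC
            dC_carry = (1.0 - m) * dC
            do = dh_new * tanh_C
            dC_new = dC_new + dh_new * o * (1.0 - tanh_C ** 2)
            di = dC_new * g
            dg = dC_new * i
            df = dC_new * C_prev
            dC = dC_new * f + dC_carry
            dA = np.concatenate(
                [
                    df * f * (1.0 - f),
                    di * i * (1.0 - i),
                    do * o * (1.0 - o),
                    dg * (1.0 - g ** 2),
                ],
                axis=1,
            )
            dWx += dA.T @ x_t
            dUh += dA.T @ h_prev
            db += dA.sum(axis=0)
            dE[:, t, :] = dA @ params.Wx
            dh = dA @ params.Uh + dh_carry
        return {"Wx": dWx, "Uh": dUh, "b": db}, dE

    def _encode_batch(self, X, lengths):
        """Evo features + both LSTM passes; returns (encoding, cache)."""
        mask = (np.arange(X.shape[1])[None, :] < lengths[:, None]).astype(float)
        E = X @ self.evo.weights.T  # (B, Lmax, 20): Eq-style channel sum
        E_rev = _reverse_within_lengths(E, lengths)
        hF, CF, cachesF = self._masked_lstm(E, mask, self.fwd)
        hB, CB, cachesB = self._masked_lstm(E_rev, mask, self.bwd)
        v = np.concatenate([hF, hB], axis=1)
        cache = (X, lengths, mask, E, E_rev, cachesF, cachesB)
        return v, cache

    def loss_and_gradients(
        self,
        sequences: Sequence[str],
        targets: np.ndarray,
        rng: np.random.Generator | None = None,
        train: bool = True,
    ) -> tuple[float, dict[str, np.ndarray]]:
        """Mean binary cross-entropy and its gradient w.r.t. every parameter.

        Targets may be hard labels {0,1} or soft standardized affinities in
        [0,1].  ``rng`` drives the dropout mask when ``train`` is true.
        """
        targets = np.asarray(targets, dtype=float)
        X, lengths = _one_hot_batch(sequences)
        B, Lmax = X.shape[0], X.shape[1]
        v, cache = self._encode_batch(X, lengths)

        keep = self.config.keep_prob
        if train and keep < 1.0:
            if rng is None:
                raise ValueError("training-mode dropout requires an rng")
            drop_mask = (rng.random(v.shape) < keep) / keep
        else:
            drop_mask = np.ones_like(v)
        vd = v * drop_mask

        z1 = vd @ self.W1.T + self.b1
        a1 = np.maximum(z1, 0.0)
        z2 = a1 @ self.W2.T + self.b2
        p = sigmoid(z2)[:, 0]

        eps = 1e-12
        pc = np.clip(p, eps, 1.0 - eps)
        loss = float(np.mean(-(targets * np.log(pc) + (1 - targets) * np.log(1 - pc))))

        dz2 = ((p - targets) / B)[:, None]
        dW2 = dz2.T @ a1
        db2 = dz2.sum(axis=0)
        da1 = dz2 @ self.W2
        dz1 = da1 * (z1 > 0)
        dW1 = dz1.T @ vd
        db1 = dz1.sum(axis=0)
        dv = (dz1 @ self.W1) * drop_mask

        H = self.config.hidden_size
        X_, lengths_, mask, E, E_rev, cachesF, cachesB = cache
        gF, dE_f = self._masked_lstm_backward(dv[:, :H], self.fwd, cachesF, Lmax)
        gB, dE_rev = self._masked_lstm_backward(dv[:, H:], self.bwd, cachesB, Lmax)
        dE = dE_f + _reverse_within_lengths(dE_rev, lengths_)
        dWevo = np.einsum("btk,btn->kn", dE, X_)

        grads = {
            "evo.weights": dWevo,
            "fwd.Wx": gF["Wx"],
            "fwd.Uh": gF["Uh"],
            "fwd.b": gF["b"],
            "bwd.Wx": gB["Wx"],
            "bwd.Uh": gB["Uh"],
            "bwd.b": gB["b"],
            "head.W1": dW1,
            "head.b1": db1,
            "head.W2": dW2,
            "head.b2": db2,
        }
        return loss, grads
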