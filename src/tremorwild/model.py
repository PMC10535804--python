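"""A from-scratch numpy Bi-LSTM-with-attention binary classifier.

The network consumes each window's 33-feature vector as a length-33
sequence of scalars and produces the probability that the window comes
from a Parkinson's-disease subject:

    input (33, 1)
      -> bidirectional LSTM, 32 units/direction, sequences  (33, 64)
      -> dropout
      -> bidirectional LSTM, 64 units/direction, sequences  (33, 128)
      -> dropout
      -> bidirectional LSTM, 128 units/direction, sequences (33, 256)
      -> attention (parameter-free, shape-preserving)        (33, 256)
      -> dropout -> flatten (8448) -> dense 1, sigmoid

Each LSTM direction follows the standard gate equations

    i_t = sigmoid(W_xi x_t + W_hi h_{t-1} + b_i)
    f_t = sigmoid(W_xf x_t + W_hf h_{t-1} + b_f)
    o_t = sigmoid(W_xo x_t + W_ho h_{t-1} + b_o)
    g_t = tanh   (W_xc x_t + W_hc h_{t-1} + b_c)
    c_t = f_t * c_{t-1} + i_t * g_t
    h_t = o_t * tanh(c_t)

so a bidirectional layer with u units and input dimension d carries
2 * 4u(d + u + 1) trainable parameters. Everything runs in float64; with
dropout disabled the forward pass is bitwise deterministic given a seed.

Two documented variants exist beyond the default stack: an averaging
bidirectional merge (tanh read-outs of each direction, averaged) and a
learned attention that pools the sequence to a single context vector.
They are forward-only; gradient support covers the default configuration.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np

# gate column order inside the stacked weight matrices
_GATES = ("i", "f", "o", "g")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _orthogonal(rng: np.random.Generator, n: int) -> np.ndarray:
    a = rng.standard_normal((n, n))
    q, r = np.linalg.qr(a)
    return q * np.sign(np.diag(r))


# ---------------------------------------------------------------------------
# parameter containers


@dataclass
class LSTMDirectionParams:
    """One direction's weights: W_x (d, 4u), W_h (u, 4u), b (4u,).

    Columns are blocked [input | forget | output | candidate]. Initialisation:
    Glorot-uniform input weights, per-gate orthogonal recurrent weights,
    zero biases with the forget-gate bias at 1 (helps gradient flow early).
    """

    W_x: np.ndarray
    W_h: np.ndarray
    b: np.ndarray

    @property
    def units(self) -> int:
        return self.W_h.shape[0]

    @property
    def input_dim(self) -> int:
        return self.W_x.shape[0]

    @classmethod
    def init(cls, input_dim: int, units: int, rng: np.random.Generator
             ) -> "LSTMDirectionParams":
        limit = np.sqrt(6.0 / (input_dim + units))
        W_x = rng.uniform(-limit, limit, size=(input_dim, 4 * units))
        W_h = np.hstack([_orthogonal(rng, units) for _ in _GATES])
        b = np.zeros(4 * units)
        b[units : 2 * units] = 1.0  # forget-gate bias
        return cls(W_x, W_h, b)

    def gate_weights(self, gate: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(W_x, W_h, b) slices for one gate, by name in {'i','f','o','g'}."""
        j = _GATES.index(gate)
        u = self.units
        sl = slice(j * u, (j + 1) * u)
        return self.W_x[:, sl], self.W_h[:, sl], self.b[sl]

    def n_params(self) -> int:
        return self.W_x.size + self.W_h.size + self.b.size

    def arrays(self) -> list[np.ndarray]:
        return [self.W_x, self.W_h, self.b]


def lstm_step(
    x_t: np.ndarray,
    h_prev: np.ndarray,
    c_prev: np.ndarray,
    p: LSTMDirectionParams,
) -> tuple[np.ndarray, np.ndarray]:
    """One LSTM cell update (h_t, c_t) for input x_t and previous state.

    Accepts a single sample (vectors) or a batch (matrices, rows = samples).
    """
    x_t = np.atleast_2d(np.asarray(x_t, dtype=float))
    h_prev = np.atleast_2d(np.asarray(h_prev, dtype=float))
    c_prev = np.atleast_2d(np.asarray(c_prev, dtype=float))
    if x_t.shape[1] != p.input_dim or h_prev.shape[1] != p.units:
        raise ValueError(
            f"dimension mismatch: x {x_t.shape}, h {h_prev.shape}, "
            f"expected input_dim={p.input_dim}, units={p.units}"
        )
    u = p.units
    z = x_t @ p.W_x + h_prev @ p.W_h + p.b
    i = _sigmoid(z[:, :u])
    f = _sigmoid(z[:, u : 2 * u])
    o = _sigmoid(z[:, 2 * u : 3 * u])
    g = np.tanh(z[:, 3 * u :])
    c_t = f * c_prev + i * g
    h_t = o * np.tanh(c_t)
    if h_t.shape[0] == 1:
        return h_t[0], c_t[0]
    return h_t, c_t


def _lstm_forward(X: np.ndarray, p: LSTMDirectionParams, cache: bool
                  ) -> tuple[np.ndarray, dict | None]:
    """Run one direction over a (B, T, d) batch; returns (B, T, u) hidden states."""
    B, T, _ = X.shape
    u = p.units
    h = np.zeros((B, u))
    c = np.zeros((B, u))
    H = np.empty((B, T, u))
    cch = (
        {k: np.empty((B, T, u)) for k in ("i", "f", "o", "g", "c", "tanh_c", "h_prev", "c_prev")}
        if cache
        else None
    )
    for t in range(T):
        z = X[:, t] @ p.W_x + h @ p.W_h + p.b
        i = _sigmoid(z[:, :u])
        f = _sigmoid(z[:, u : 2 * u])
        o = _sigmoid(z[:, 2 * u : 3 * u])
        g = np.tanh(z[:, 3 * u :])
        c_new = f * c + i * g
        tc = np.tanh(c_new)
        h_new = o * tc
        if cache:
            cch["i"][:, t] = i
            cch["f"][:, t] = f
            cch["o"][:, t] = o
            cch["g"][:, t] = g
            cch["c"][:, t] = c_new
            cch["tanh_c"][:, t] = tc
            cch["h_prev"][:, t] = h
            cch["c_prev"][:, t] = c
        h, c = h_new, c_new
        H[:, t] = h
    return H, cch


def _lstm_backward(
    dH: np.ndarray, X: np.ndarray, p: LSTMDirectionParams, cch: dict
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """BPTT for one direction. dH: (B, T, u) upstream gradient on the hidden
    sequence. Returns (dX, grads for W_x/W_h/b)."""
    B, T, _ = X.shape
    u = p.units
    dW_x = np.zeros_like(p.W_x)
    dW_h = np.zeros_like(p.W_h)
    db = np.zeros_like(p.b)
    dX = np.empty_like(X)
    dh_next = np.zeros((B, u))
    dc_next = np.zeros((B, u))
    dZ = np.empty((B, 4 * u))
    for t in range(T - 1, -1, -1):
        i, f, o, g = (cch[k][:, t] for k in ("i", "f", "o", "g"))
        tc = cch["tanh_c"][:, t]
        dh = dH[:, t] + dh_next
        do = dh * tc
        dc = dc_next + dh * o * (1.0 - tc * tc)
        di = dc * g
        df = dc * cch["c_prev"][:, t]
        dg = dc * i
        dc_next = dc * f
        dZ[:, :u] = di * i * (1.0 - i)
        dZ[:, u : 2 * u] = df * f * (1.0 - f)
        dZ[:, 2 * u : 3 * u] = do * o * (1.0 - o)
        dZ[:, 3 * u :] = dg * (1.0 - g * g)
        dW_x += X[:, t].T @ dZ
        dW_h += cch["h_prev"][:, t].T @ dZ
        db += dZ.sum(axis=0)
        dX[:, t] = dZ @ p.W_x.T
        dh_next = dZ @ p.W_h.T
    return dX, {"W_x": dW_x, "W_h": dW_h, "b": db}


# ---------------------------------------------------------------------------
# layers


@dataclass
class BiCombineParams:
    """Read-out weights for the averaging bidirectional merge: each
    direction's hidden state passes through its own tanh read-out and the
    two are averaged, o_t = 0.5 (tanh(W4 h_t + b3) + tanh(W6 h'_t + b4))."""

    W4: np.ndarray
    W6: np.ndarray
    b3: np.ndarray
    b4: np.ndarray

    @classmethod
    def init(cls, units: int, rng: np.random.Generator) -> "BiCombineParams":
        limit = np.sqrt(6.0 / (2 * units))
        return cls(
            W4=rng.uniform(-limit, limit, size=(units, units)),
            W6=rng.uniform(-limit, limit, size=(units, units)),
            b3=np.zeros(units),
            b4=np.zeros(units),
        )


class BiLSTMLayer:
    """Bidirectional LSTM returning the full output sequence.

    merge_mode='concat' (default) concatenates the forward and time-aligned
    backward hidden states, output width 2u. merge_mode='mean' applies the
    averaging read-out (width u); it is forward-only.
    """

    def __init__(self, input_dim: int, units: int, rng: np.random.Generator,
                 merge_mode: str = "concat"):
        if merge_mode not in ("concat", "mean"):
            raise ValueError("merge_mode must be 'concat' or 'mean'")
        self.merge_mode = merge_mode
        self.units = units
        self.input_dim = input_dim
        self.fwd = LSTMDirectionParams.init(input_dim, units, rng)
        self.bwd = LSTMDirectionParams.init(input_dim, units, rng)
        self.combine = (
            BiCombineParams.init(units, rng) if merge_mode == "mean" else None
        )
        self._cache: dict | None = None

    @property
    def output_dim(self) -> int:
        return 2 * self.units if self.merge_mode == "concat" else self.units

    def forward(self, X: np.ndarray, cache: bool = False) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ValueError("expected (batch, time, features)")
        if X.shape[1] == 0:
            raise ValueError("empty sequence")
        Hf, cf = _lstm_forward(X, self.fwd, cache)
        Hb_rev, cb = _lstm_forward(X[:, ::-1], self.bwd, cache)
        Hb = Hb_rev[:, ::-1]
        if self.merge_mode == "concat":
            out = np.concatenate([Hf, Hb], axis=2)
        else:
            p = self.combine
            out = 0.5 * (np.tanh(Hf @ p.W4 + p.b3) + np.tanh(Hb @ p.W6 + p.b4))
        if cache:
            self._cache = {"X": X, "fwd": cf, "bwd": cb}
        return out

    def backward(self, dOut: np.ndarray) -> np.ndarray:
        if self.merge_mode != "concat":
            raise NotImplementedError("gradients implemented for concat merge only")
        cch = self._cache
        u = self.units
        dXf, gf = _lstm_backward(dOut[:, :, :u], cch["X"], self.fwd, cch["fwd"])
        dXb_rev, gb = _lstm_backward(
            dOut[:, ::-1, u:], cch["X"][:, ::-1], self.bwd, cch["bwd"]
        )
        self.grads = {"fwd": gf, "bwd": gb}
        return dXf + dXb_rev[:, ::-1]

    def params_and_grads(self):
        for name, p in (("fwd", self.fwd), ("bwd", self.bwd)):
            g = self.grads[name]
            yield p.W_x, g["W_x"]
            yield p.W_h, g["W_h"]
            yield p.b, g["b"]

    def n_params(self) -> int:
        n = self.fwd.n_params() + self.bwd.n_params()
        if self.combine is not None:
            n += sum(a.size for a in
                     (self.combine.W4, self.combine.W6, self.combine.b3, self.combine.b4))
        return n

    def arrays(self) -> list[np.ndarray]:
        out = self.fwd.arrays() + self.bwd.arrays()
        if self.combine is not None:
            out += [self.combine.W4, self.combine.W6, self.combine.b3, self.combine.b4]
        return out


@dataclass
class AttentionParams:
    """Weights for the learned attention variant: scores
    e_t = v_a . tanh(W_a h_t + b_a), alpha = softmax(e), c = sum_t alpha_t h_t."""

    W_a: np.ndarray
    v_a: np.ndarray
    b_a: np.ndarray

    @classmethod
    def init(cls, dim: int, attn_dim: int, rng: np.random.Generator
             ) -> "AttentionParams":
        limit = np.sqrt(6.0 / (dim + attn_dim))
        return cls(
            W_a=rng.uniform(-limit, limit, size=(dim, attn_dim)),
            v_a=rng.uniform(-limit, limit, size=attn_dim),
            b_a=np.zeros(attn_dim),
        )


def _softmax(e: np.ndarray) -> np.ndarray:
    m = e.max(axis=-1, keepdims=True)
    x = np.exp(e - m)
    return x / x.sum(axis=-1, keepdims=True)


class AttentionLayer:
    """Parameter-free, shape-preserving attention (the default).

    The query is the temporal mean of the sequence; scores are the dot
    product of each timestep with the query, weights the softmax over time,
    and each timestep is re-scaled by T * alpha_t so that uniform attention
    is the identity. Carries zero trainable parameters and preserves (T, D).
    """

    def __init__(self):
        self._cache = None

    def forward(self, X: np.ndarray, cache: bool = False) -> np.ndarray:
        B, T, D = X.shape
        q = X.mean(axis=1)                          # (B, D)
        e = np.einsum("btd,bd->bt", X, q)           # (B, T)
        alpha = _softmax(e)
        out = (T * alpha)[:, :, None] * X
        if cache:
            self._cache = {"X": X, "q": q, "alpha": alpha}
        self.last_alpha = alpha
        return out

    def backward(self, dOut: np.ndarray) -> np.ndarray:
        cch = self._cache
        X, q, alpha = cch["X"], cch["q"], cch["alpha"]
        B, T, D = X.shape
        dX = (T * alpha)[:, :, None] * dOut
        dalpha = T * np.einsum("btd,btd->bt", dOut, X)
        # softmax jacobian
        de = alpha * (dalpha - np.sum(alpha * dalpha, axis=1, keepdims=True))
        dX += de[:, :, None] * q[:, None, :]
        dq = np.einsum("bt,btd->bd", de, X)
        dX += dq[:, None, :] / T
        return dX

    def n_params(self) -> int:
        return 0


def attention_layer(
    seq: np.ndarray,
    params: AttentionParams | None = None,
    variant: str = "parameter_free",
) -> tuple[np.ndarray, np.ndarray]:
    """Functional attention over a single (T, D) sequence.

    parameter_free: shape-preserving re-weighting (see AttentionLayer);
    learned: pools to a context vector c = sum_t alpha_t seq_t with scores
    from the tanh read-out. Returns (output, alpha); alpha sums to 1.
    """
    seq = np.asarray(seq, dtype=float)
    if seq.ndim != 2 or seq.shape[0] < 1:
        raise ValueError("expected a (T>=1, D) sequence")
    if variant == "parameter_free":
        layer = AttentionLayer()
        out = layer.forward(seq[None])
        return out[0], layer.last_alpha[0]
    if variant == "learned":
        if params is None:
            raise ValueError("learned attention requires AttentionParams")
        e = np.tanh(seq @ params.W_a + params.b_a) @ params.v_a
        alpha = _softmax(e)
        return alpha @ seq, alpha
    raise ValueError(f"unknown attention variant {variant!r}")


def bidirectional_layer(
    seq: np.ndarray,
    fwd: LSTMDirectionParams,
    bwd: LSTMDirectionParams,
    merge_mode: str = "concat",
    combine: BiCombineParams | None = None,
) -> np.ndarray:
    """Functional bidirectional pass over a single (T, D_in) sequence."""
    seq = np.asarray(seq, dtype=float)
    if seq.ndim != 2 or seq.shape[0] == 0:
        raise ValueError("expected a non-empty (T, D) sequence")
    layer = BiLSTMLayer.__new__(BiLSTMLayer)
    layer.merge_mode = merge_mode
    layer.units = fwd.units
    layer.input_dim = fwd.input_dim
    layer.fwd = fwd
    layer.bwd = bwd
    layer.combine = combine
    layer._cache = None
    if merge_mode == "mean" and combine is None:
        raise ValueError("mean merge requires BiCombineParams")
    return layer.forward(seq[None])[0]


# ---------------------------------------------------------------------------
# the full network


@dataclass(frozen=True)
class ModelSpec:
    """Architecture hyperparameters of the classifier stack."""

    input_steps: int = 33
    input_channels: int = 1
    bilstm_units: tuple[int, ...] = (32, 64, 128)
    dropout_rates: tuple[float, ...] = (0.2, 0.2, 0.2)
    attention_variant: str = "parameter_free"
    merge_mode: str = "concat"
    dense_units: int = 1

    def __post_init__(self) -> None:
        if len(self.dropout_rates) != len(self.bilstm_units):
            raise ValueError("need one dropout rate per Bi-LSTM layer")
        if self.dense_units != 1:
            raise ValueError("binary classifier requires dense_units == 1")
        if self.attention_variant not in ("parameter_free", "learned"):
            raise ValueError("attention_variant must be parameter_free or learned")

    def to_json(self) -> str:
        return json.dumps(
            {
                "input_steps": self.input_steps,
                "input_channels": self.input_channels,
                "bilstm_units": list(self.bilstm_units),
                "dropout_rates": list(self.dropout_rates),
                "attention_variant": self.attention_variant,
                "merge_mode": self.merge_mode,
                "dense_units": self.dense_units,
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "ModelSpec":
        d = json.loads(s)
        d["bilstm_units"] = tuple(d["bilstm_units"])
        d["dropout_rates"] = tuple(d["dropout_rates"])
        return cls(**d)


class BiLSTMAttentionClassifier:
    """The full stack, trainable with plain BPTT + Adam (see train_eval).

    Forward passes are deterministic given the seed when ``train=False``
    (dropout off). ``predict_proba`` maps (n, 33) feature matrices to
    probabilities of the positive (PD) class.
    """

    def __init__(self, spec: ModelSpec | None = None, seed: int = 0):
        self.spec = spec or ModelSpec()
        self.seed = seed
        rng = np.random.default_rng(seed)
        spec = self.spec
        self.layers: list[BiLSTMLayer] = []
        d = spec.input_channels
        for u in spec.bilstm_units:
            layer = BiLSTMLayer(d, u, rng, merge_mode=spec.merge_mode)
            self.layers.append(layer)
            d = layer.output_dim
        self.attention = AttentionLayer()
        if spec.attention_variant == "learned":
            self.attn_params = AttentionParams.init(d, d, rng)
            flat_dim = d
        else:
            self.attn_params = None
            flat_dim = spec.input_steps * d
        self.flat_dim = flat_dim
        limit = np.sqrt(6.0 / (flat_dim + 1))
        self.W_out = rng.uniform(-limit, limit, size=(flat_dim, 1))
        self.b_out = np.zeros(1)
        self._dropout_rng = np.random.default_rng(rng.integers(2**31))

    # -- shape/parameter introspection ------------------------------------

    def layer_names(self) -> list[str]:
        names = []
        for k in range(len(self.layers)):
            names += [f"bilstm_{k + 1}", f"dropout_{k + 1}"]
        # attention sits before the final dropout in the stack
        names.insert(-1, "attention")
        names += ["flatten", "dense"]
        return names

    def count_parameters(self, layer_name: str | None = None) -> int:
        """Trainable parameter count, total or for one named layer.

        Matches the closed form 2*4*u*(d+u+1) per bidirectional layer with
        concat merge.
        """
        counts: dict[str, int] = {}
        for k, layer in enumerate(self.layers):
            counts[f"bilstm_{k + 1}"] = layer.n_params()
            counts[f"dropout_{k + 1}"] = 0
        counts["attention"] = (
            0 if self.attn_params is None
            else self.attn_params.W_a.size + self.attn_params.v_a.size
            + self.attn_params.b_a.size
        )
        counts["flatten"] = 0
        counts["dense"] = self.W_out.size + self.b_out.size
        if layer_name is None:
            return sum(counts.values())
        if layer_name not in counts:
            raise KeyError(
                f"unknown layer {layer_name!r}; layers: {', '.join(counts)}"
            )
        return counts[layer_name]

    def layer_output_shapes(self) -> list[tuple[str, tuple]]:
        """(layer, output shape) pairs mirroring the architecture table."""
        T = self.spec.input_steps
        shapes = [("input", (T, self.spec.input_channels))]
        for k, layer in enumerate(self.layers):
            shapes.append((f"bilstm_{k + 1}", (T, layer.output_dim)))
            shapes.append((f"dropout_{k + 1}", (T, layer.output_dim)))
        d = self.layers[-1].output_dim
        shapes.insert(-1, ("attention", (T, d)))
        shapes.append(("flatten", (self.flat_dim,)))
        shapes.append(("dense", (1,)))
        return shapes

    # -- forward / backward ------------------------------------------------

    def _dropout(self, X: np.ndarray, rate: float, train: bool
                 ) -> tuple[np.ndarray, np.ndarray | None]:
        if not train or rate <= 0.0:
            return X, None
        mask = (self._dropout_rng.random(X.shape) >= rate) / (1.0 - rate)
        return X * mask, mask

    def forward(self, X: np.ndarray, train: bool = False) -> np.ndarray:
        """Probabilities for a (n, input_steps) or (n, input_steps, channels)
        feature batch."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[:, :, None]
        if X.shape[1] != self.spec.input_steps or X.shape[2] != self.spec.input_channels:
            raise ValueError(
                f"expected input (*, {self.spec.input_steps}, "
                f"{self.spec.input_channels}), got {X.shape}"
            )
        self._masks = []
        h = X
        rates = self.spec.dropout_rates
        for k, layer in enumerate(self.layers):
            h = layer.forward(h, cache=train)
            if k < len(self.layers) - 1:
                h, m = self._dropout(h, rates[k], train)
                self._masks.append(m)
        if self.attn_params is not None:
            outs = [attention_layer(h[i], self.attn_params, "learned")[0]
                    for i in range(h.shape[0])]
            h = np.stack(outs)
            flat = h
        else:
            h = self.attention.forward(h, cache=train)
            flat = h.reshape(h.shape[0], -1)
        flat, m = self._dropout(flat, rates[-1], train)
        self._masks.append(m)
        self._flat = flat if train else None
        z = flat @ self.W_out + self.b_out
        return _sigmoid(z)[:, 0]

    def backward(self, dz: np.ndarray) -> None:
        """Accumulate gradients from d(loss)/d(logit), shape (n,).

        Requires a preceding ``forward(..., train=True)``; only the default
        (concat + parameter-free attention) configuration is trainable.
        """
        if self.attn_params is not None:
            raise NotImplementedError("training supports parameter-free attention")
        dz = np.asarray(dz, dtype=float)[:, None]
        flat = self._flat
        self.dW_out = flat.T @ dz
        self.db_out = dz.sum(axis=0)
        dflat = dz @ self.W_out.T
        if self._masks[-1] is not None:
            dflat = dflat * self._masks[-1]
        B = flat.shape[0]
        d = self.layers[-1].output_dim
        dh = dflat.reshape(B, self.spec.input_steps, d)
        dh = self.attention.backward(dh)
        for k in range(len(self.layers) - 1, -1, -1):
            dh = self.layers[k].backward(dh)
            if k > 0 and self._masks[k - 1] is not None:
                dh = dh * self._masks[k - 1]

    def params_and_grads(self):
        for layer in self.layers:
            yield from layer.params_and_grads()
        yield self.W_out, self.dW_out
        yield self.b_out, self.db_out

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X, train=False)

    # -- persistence --------------------------------------------------------

    def _all_arrays(self) -> list[np.ndarray]:
        arrays: list[np.ndarray] = []
        for layer in self.layers:
            arrays += layer.arrays()
        if self.attn_params is not None:
            arrays += [self.attn_params.W_a, self.attn_params.v_a, self.attn_params.b_a]
        arrays += [self.W_out, self.b_out]
        return arrays

    def save(self, path: str | Path) -> None:
        """Single-file checkpoint: JSON spec + raw float64 weight buffers."""
        path = Path(path)
        with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
            zf.writestr("spec.json", self.spec.to_json())
            zf.writestr("seed.json", json.dumps({"seed": self.seed}))
            for k, arr in enumerate(self._all_arrays()):
                buf = io.BytesIO()
                np.save(buf, arr)
                zf.writestr(f"w{k:03d}.npy", buf.getvalue())

    @classmethod
    def load(cls, path: str | Path) -> "BiLSTMAttentionClassifier":
        with zipfile.ZipFile(path) as zf:
            spec = ModelSpec.from_json(zf.read("spec.json").decode())
            seed = json.loads(zf.read("seed.json").decode())["seed"]
            model = cls(spec, seed=seed)
            for k, arr in enumerate(model._all_arrays()):
                loaded = np.load(io.BytesIO(zf.read(f"w{k:03d}.npy")))
                arr[...] = loaded
        return model


def build_model(spec: ModelSpec | None = None, seed: int = 0
                ) -> BiLSTMAttentionClassifier:
    """Construct the (untrained) classifier with deterministic initialisation."""
    return BiLSTMAttentionClassifier(spec, seed=seed)


def bidirectional_param_count(units: int, input_dim: int) -> int:
    """Closed form 2 * 4u(d + u + 1) for a concat-merge bidirectional layer."""
    return 2 * 4 * units * (input_dim + units + 1)
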