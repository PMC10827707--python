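"""Minimal NumPy neural-net engine for the recurrent backbone.

Implements exactly the layers the supervised feature extractor needs —
token embedding (or one-hot), GRU/LSTM cells with optional bidirectional
wrapping, dense relu layers with inverted dropout, a linear head trained
with sigmoid + binary cross-entropy — together with manual backpropagation
(BPTT through the recurrent layer) and an Adam optimizer.  Everything is
deterministic given the supplied ``numpy`` Generators.

Padded positions (token id 0 beyond a row's true length) are excluded via a
prefix mask: the hidden state is frozen across masked steps, so the final
state equals the state after the last real token and no gradient flows
through padding.
"""

from __future__ import annotations

import numpy as np


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, int], dtype) -> np.ndarray:
    limit = np.sqrt(6.0 / (shape[0] + shape[1]))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


def orthogonal(rng: np.random.Generator, shape: tuple[int, int], dtype) -> np.ndarray:
    a = rng.standard_normal(size=(max(shape), max(shape)))
    q, r = np.linalg.qr(a)
    q = q * np.sign(np.diag(r))  # fix sign ambiguity for determinism
    return q[: shape[0], : shape[1]].astype(dtype)


class Layer:
    """Base: subclasses hold parallel ``weights``/``grads`` array lists."""

    def __init__(self):
        self.weights: list[np.ndarray] = []
        self.grads: list[np.ndarray] = []

    def zero_grad(self) -> None:
        for g in self.grads:
            g[...] = 0.0

    def n_params(self) -> int:
        return int(sum(w.size for w in self.weights))


class Embedding(Layer):
    """Learned token embedding; row 0 doubles as the padding/unknown row."""

    def __init__(self, rng, n_tokens: int, dim: int, dtype=np.float32):
        super().__init__()
        self.dim = dim
        W = rng.uniform(-0.05, 0.05, size=(n_tokens, dim)).astype(dtype)
        self.weights = [W]
        self.grads = [np.zeros_like(W)]

    def forward(self, tokens: np.ndarray) -> np.ndarray:
        self._tokens = tokens
        return self.weights[0][tokens]

    def backward(self, dX: np.ndarray) -> None:
        dW = self.grads[0]
        flat = self._tokens.reshape(-1)
        np.add.at(dW, flat, dX.reshape(-1, self.dim))


class OneHot(Layer):
    """Fixed one-hot encoding of token ids (no parameters)."""

    def __init__(self, n_tokens: int, dtype=np.float32):
        super().__init__()
        self.dim = n_tokens
        self._eye = np.eye(n_tokens, dtype=dtype)

    def forward(self, tokens: np.ndarray) -> np.ndarray:
        return self._eye[tokens]

    def backward(self, dX: np.ndarray) -> None:
        pass


class GRU(Layer):
    """GRU over a padded batch; returns the final (masked) hidden state.

    Per step: z = sigma(x W_z + h V_z + b_z), r = sigma(x W_r + h V_r + b_r),
    c = tanh(x W_c + (r * h) V_c + b_c), h' = z * h + (1 - z) * c, with the
    update skipped (h' = h) on masked steps.
    """

    def __init__(self, rng, in_dim: int, units: int, dtype=np.float32):
        super().__init__()
        self.units = units
        self.dtype = dtype
        H = units
        W = glorot_uniform(rng, (in_dim, 3 * H), dtype)      # [z | r | c]
        V2 = orthogonal(rng, (H, 2 * H), dtype)              # [z | r]
        Vc = orthogonal(rng, (H, H), dtype)
        b = np.zeros(3 * H, dtype=dtype)
        # start in a state-retaining regime (update gate ~0.73) so evidence
        # integrates across long sequences; the GRU analogue of the LSTM
        # forget-gate bias initialization
        b[:H] = 1.0
        self.weights = [W, V2, Vc, b]
        self.grads = [np.zeros_like(w) for w in self.weights]

    def forward(self, X: np.ndarray, mask: np.ndarray, train: bool = False) -> np.ndarray:
        W, V2, Vc, b = self.weights
        B, T, D = X.shape
        H = self.units
        G = (X.reshape(B * T, D) @ W).reshape(B, T, 3 * H) + b
        h = np.zeros((B, H), dtype=self.dtype)
        cache = [] if train else None
        for t in range(T):
            u = h @ V2
            z = sigmoid(G[:, t, :H] + u[:, :H])
            r = sigmoid(G[:, t, H : 2 * H] + u[:, H:])
            rh = r * h
            c = np.tanh(G[:, t, 2 * H :] + rh @ Vc)
            hn = z * h + (1.0 - z) * c
            m = mask[:, t : t + 1]
            h_new = m * hn + (1.0 - m) * h
            if train:
                cache.append((h, z, r, c, rh))
            h = h_new
        if train:
            self._cache = (X, mask, cache)
        return h

    def backward(self, dh: np.ndarray) -> np.ndarray:
        X, mask, cache = self._cache
        W, V2, Vc, b = self.weights
        dW, dV2, dVc, db = self.grads
        B, T, D = X.shape
        H = self.units
        dG = np.zeros((B, T, 3 * H), dtype=self.dtype)
        dh = dh.astype(self.dtype, copy=True)
        for t in range(T - 1, -1, -1):
            h_prev, z, r, c, rh = cache[t]
            m = mask[:, t : t + 1]
            dhn = dh * m
            dh_prev = dh * (1.0 - m)
            dz = dhn * (h_prev - c)
            dc = dhn * (1.0 - z)
            dh_prev += dhn * z
            dc_pre = dc * (1.0 - c * c)
            dVc += rh.T @ dc_pre
            drh = dc_pre @ Vc.T
            dh_prev += drh * r
            dr = drh * h_prev
            dz_pre = dz * z * (1.0 - z)
            dr_pre = dr * r * (1.0 - r)
            dzr = np.concatenate([dz_pre, dr_pre], axis=1)
            dV2 += h_prev.T @ dzr
            dh_prev += dzr @ V2.T
            dG[:, t, : 2 * H] = dzr
            dG[:, t, 2 * H :] = dc_pre
            dh = dh_prev
        db += dG.sum(axis=(0, 1))
        dW += X.reshape(B * T, D).T @ dG.reshape(B * T, 3 * H)
        return (dG.reshape(B * T, 3 * H) @ W.T).reshape(B, T, D)


class LSTM(Layer):
    """LSTM over a padded batch; returns the final (masked) hidden state."""

    def __init__(self, rng, in_dim: int, units: int, dtype=np.float32):
        super().__init__()
        self.units = units
        self.dtype = dtype
        H = units
        W = glorot_uniform(rng, (in_dim, 4 * H), dtype)      # [i | f | o | g]
        V = orthogonal(rng, (H, 4 * H), dtype)
        b = np.zeros(4 * H, dtype=dtype)
        b[H : 2 * H] = 1.0  # forget-gate bias
        self.weights = [W, V, b]
        self.grads = [np.zeros_like(w) for w in self.weights]

    def forward(self, X: np.ndarray, mask: np.ndarray, train: bool = False) -> np.ndarray:
        W, V, b = self.weights
        B, T, D = X.shape
        H = self.units
        G = (X.reshape(B * T, D) @ W).reshape(B, T, 4 * H) + b
        h = np.zeros((B, H), dtype=self.dtype)
        c = np.zeros((B, H), dtype=self.dtype)
        cache = [] if train else None
        for t in range(T):
            a = G[:, t] + h @ V
            i = sigmoid(a[:, :H])
            f = sigmoid(a[:, H : 2 * H])
            o = sigmoid(a[:, 2 * H : 3 * H])
            g = np.tanh(a[:, 3 * H :])
            cn = f * c + i * g
            tc = np.tanh(cn)
            hn = o * tc
            m = mask[:, t : t + 1]
            if train:
                cache.append((h, c, i, f, o, g, tc))
            h = m * hn + (1.0 - m) * h
            c = m * cn + (1.0 - m) * c
        if train:
            self._cache = (X, mask, cache)
        return h

    def backward(self, dh: np.ndarray) -> np.ndarray:
        X, mask, cache = self._cache
        W, V, b = self.weights
        dW, dV, db = self.grads
        B, T, D = X.shape
        H = self.units
        dG = np.zeros((B, T, 4 * H), dtype=self.dtype)
        dh = dh.astype(self.dtype, copy=True)
        dc = np.zeros((B, H), dtype=self.dtype)
        for t in range(T - 1, -1, -1):
            h_prev, c_prev, i, f, o, g, tc = cache[t]
            m = mask[:, t : t + 1]
            dhn = dh * m
            dh_prev = dh * (1.0 - m)
            do = dhn * tc
            dcn = dhn * o * (1.0 - tc * tc) + dc * m
            dc = dcn * f + dc * (1.0 - m)
            di = dcn * g
            df = dcn * c_prev
            dg = dcn * i
            da = np.concatenate(
                [di * i * (1.0 - i), df * f * (1.0 - f), do * o * (1.0 - o),
                 dg * (1.0 - g * g)],
                axis=1,
            )
            dV += h_prev.T @ da
            dh_prev += da @ V.T
            dG[:, t] = da
            dh = dh_prev
        db += dG.sum(axis=(0, 1))
        dW += X.reshape(B * T, D).T @ dG.reshape(B * T, 4 * H)
        return (dG.reshape(B * T, 4 * H) @ W.T).reshape(B, T, D)


class Bidirectional(Layer):
    """Run a forward and a reversed-within-length copy; concatenate states.

    Because the mask is a prefix mask, reversing each row within its true
    length leaves the mask unchanged, so the backward-direction cell sees
    the sequence last-token-first with identical masking.
    """

    def __init__(self, fwd, bwd):
        super().__init__()
        self.fwd = fwd
        self.bwd = bwd

    @property
    def weights(self):
        return self.fwd.weights + self.bwd.weights

    @weights.setter
    def weights(self, value):  # base-class __init__ assigns []
        pass

    @property
    def grads(self):
        return self.fwd.grads + self.bwd.grads

    @grads.setter
    def grads(self, value):
        pass

    @property
    def units(self) -> int:
        return self.fwd.units + self.bwd.units

    @staticmethod
    def _reverse_index(lengths: np.ndarray, T: int) -> np.ndarray:
        t = np.arange(T)[None, :]
        L = np.asarray(lengths)[:, None]
        idx = np.where(t < L, L - 1 - t, t)
        return idx

    def forward(self, X, mask, train: bool = False, lengths=None):
        B, T, _ = X.shape
        self._idx = self._reverse_index(lengths, T)
        rows = np.arange(B)[:, None]
        Xr = X[rows, self._idx]
        hf = self.fwd.forward(X, mask, train=train)
        hb = self.bwd.forward(Xr, mask, train=train)
        return np.concatenate([hf, hb], axis=1)

    def backward(self, dh):
        H = self.fwd.units
        dX = self.fwd.backward(dh[:, :H])
        dXr = self.bwd.backward(dh[:, H:])
        rows = np.arange(dX.shape[0])[:, None]
        dX[rows, self._idx] += dXr
        return dX


class Dense(Layer):
    def __init__(self, rng, in_dim: int, out_dim: int, activation: str = "relu",
                 dtype=np.float32):
        super().__init__()
        if activation not in ("relu", "linear"):
            raise ValueError(f"unsupported activation {activation!r}")
        self.activation = activation
        W = glorot_uniform(rng, (in_dim, out_dim), dtype)
        b = np.zeros(out_dim, dtype=dtype)
        self.weights = [W, b]
        self.grads = [np.zeros_like(W), np.zeros_like(b)]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        W, b = self.weights
        a = x @ W + b
        if self.activation == "relu":
            out = np.maximum(a, 0.0)
        else:
            out = a
        if train:
            self._cache = (x, a)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x, a = self._cache
        W, b = self.weights
        da = dout * (a > 0) if self.activation == "relu" else dout
        self.grads[0] += x.T @ da
        self.grads[1] += da.sum(axis=0)
        return da @ W.T


class Dropout(Layer):
    """Inverted dropout: identity in eval mode."""

    def __init__(self, rate: float):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate {rate} outside [0, 1)")
        self.rate = rate
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout if self._mask is None else dout * self._mask


def bce_with_logits(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy of sigmoid(logits) vs y, and d(loss)/d(logits)."""
    y = y.astype(logits.dtype)
    # BCE = y*softplus(-l) + (1-y)*softplus(l), computed stably
    loss = float(np.mean(np.logaddexp(0.0, logits) - y * logits))
    dlogits = (sigmoid(logits) - y) / logits.size
    return loss, dlogits


class Network:
    """Token embedding -> recurrent layer -> dense relu stack -> linear head.

    ``forward`` returns pre-sigmoid logits; :func:`bce_with_logits` supplies
    the loss and its gradient.  ``feature_maps`` exposes the recurrent
    output and every dense relu output for latent extraction.
    """

    def __init__(self, encoder, recurrent, dense_blocks, head, dtype=np.float32,
                 post_recurrent_drop=None):
        self.encoder = encoder
        self.recurrent = recurrent
        self.post_recurrent_drop = post_recurrent_drop
        self.dense_blocks = dense_blocks  # list of (Dense, Dropout | None)
        self.head = head
        self.dtype = dtype

    # -- plumbing ----------------------------------------------------------
    @property
    def layers(self) -> list[Layer]:
        out = [self.encoder, self.recurrent]
        if self.post_recurrent_drop is not None:
            out.append(self.post_recurrent_drop)
        for dense, drop in self.dense_blocks:
            out.append(dense)
            if drop is not None:
                out.append(drop)
        out.append(self.head)
        return out

    @property
    def weights(self) -> list[np.ndarray]:
        return [w for layer in self.layers for w in layer.weights]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()

    def n_params(self) -> int:
        return sum(layer.n_params() for layer in self.layers)

    def get_weights(self) -> list[np.ndarray]:
        return [w.copy() for w in self.weights]

    def set_weights(self, values: list[np.ndarray]) -> None:
        for w, v in zip(self.weights, values):
            w[...] = v

    # -- forward / backward ------------------------------------------------
    @staticmethod
    def _mask(lengths: np.ndarray, T: int, dtype) -> np.ndarray:
        return (np.arange(T)[None, :] < np.asarray(lengths)[:, None]).astype(dtype)

    def forward(self, tokens: np.ndarray, lengths: np.ndarray, train: bool = False,
                rng=None) -> np.ndarray:
        tokens = np.asarray(tokens)
        mask = self._mask(lengths, tokens.shape[1], self.dtype)
        X = self.encoder.forward(tokens)
        if isinstance(self.recurrent, Bidirectional):
            h = self.recurrent.forward(X, mask, train=train, lengths=lengths)
        else:
            h = self.recurrent.forward(X, mask, train=train)
        feats = [h]
        if self.post_recurrent_drop is not None:
            h = self.post_recurrent_drop.forward(h, train=train, rng=rng)
        for dense, drop in self.dense_blocks:
            h = dense.forward(h, train=train)
            feats.append(h)
            if drop is not None:
                h = drop.forward(h, train=train, rng=rng)
        self._feats = feats
        return self.head.forward(h, train=train)[:, 0]

    def backward(self, dlogits: np.ndarray) -> None:
        dh = self.head.backward(dlogits[:, None].astype(self.dtype))
        for dense, drop in reversed(self.dense_blocks):
            if drop is not None:
                dh = drop.backward(dh)
            dh = dense.backward(dh)
        if self.post_recurrent_drop is not None:
            dh = self.post_recurrent_drop.backward(dh)
        dX = self.recurrent.backward(dh)
        self.encoder.backward(dX)

    def predict_proba(self, tokens, lengths, batch_size: int = 512) -> np.ndarray:
        """Sigmoid output in (0, 1), computed in eval mode, chunked."""
        out = []
        for start in range(0, len(tokens), batch_size):
            sl = slice(start, start + batch_size)
            out.append(sigmoid(self.forward(tokens[sl], lengths[sl], train=False)))
        return np.concatenate(out) if out else np.empty(0, dtype=self.dtype)

    def feature_maps(self, tokens, lengths) -> list[np.ndarray]:
        """[recurrent output, dense_1 output, ...] in eval mode."""
        self.forward(tokens, lengths, train=False)
        return self._feats

    def latent(self, tokens, lengths, layer_index: int, batch_size: int = 512) -> np.ndarray:
        """Activations of the 1-based feature layer (1 = recurrent output)."""
        if not 1 <= layer_index <= 1 + len(self.dense_blocks):
            raise ValueError(f"latent layer index {layer_index} out of range")
        out = []
        for start in range(0, len(tokens), batch_size):
            sl = slice(start, start + batch_size)
            out.append(self.feature_maps(tokens[sl], lengths[sl])[layer_index - 1])
        if not out:
            width = (self.recurrent.units if layer_index == 1
                     else self.dense_blocks[layer_index - 2][0].weights[0].shape[1])
        return np.concatenate(out) if out else np.empty((0, width), dtype=self.dtype)


class Adam:
    """Adaptive-moment optimizer over a flat list of weight arrays."""

    def __init__(self, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-7):
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self._m: list[np.ndarray] | None = None
        self._v: list[np.ndarray] | None = None

    def step(self, weights: list[np.ndarray], grads: list[np.ndarray]) -> None:
        if self._m is None:
            self._m = [np.zeros_like(w) for w in weights]
            self._v = [np.zeros_like(w) for w in weights]
        self.t += 1
        lr_t = self.lr * np.sqrt(1.0 - self.beta2**self.t) / (1.0 - self.beta1**self.t)
        for w, g, m, v in zip(weights, grads, self._m, self._v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * (g * g)
            w -= lr_t * m / (np.sqrt(v) + self.eps)
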