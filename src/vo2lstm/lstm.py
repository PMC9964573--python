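"""A many-to-one LSTM regressor implemented directly on NumPy.

The network consumes a window of L steps x F features and emits one scalar:
stacked LSTM layers (one by default) followed by a fully connected layer
with a single output.  Weights follow the common recurrent-network
conventions: Glorot-uniform input weights, orthogonal recurrent weights,
zero biases except a unit forget-gate bias.  Each layer carries a single
bias vector, so the trainable-parameter count per LSTM layer is
``4H(F + H + 1)`` and the output layer adds ``H + 1``.

Training is mean-squared-error minimisation with Adam on shuffled
minibatches; gradients come from full backpropagation through time.  All
state is NumPy, all randomness is seeded, and the same seed reproduces the
same trained weights bit for bit on a fixed BLAS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LSTMRegressor", "lstm_parameter_count"]


def lstm_parameter_count(n_features: int, hidden_units: int, n_layers: int = 1) -> int:
    """Closed-form trainable parameter count of the regressor.

    Per LSTM layer: input weights (F x 4H), recurrent weights (H x 4H) and
    one bias (4H), i.e. ``4H(F + H + 1)`` where F is that layer's input
    width (the feature count for the first layer, H for the rest); the
    single-output dense head adds ``H + 1``.
    """
    h = hidden_units
    total = 0
    f = n_features
    for _ in range(n_layers):
        total += 4 * h * (f + h + 1)
        f = h
    total += h + 1
    return total


def _sigmoid_(x: np.ndarray) -> np.ndarray:
    """In-place logistic: 4 ufunc passes, no temporaries.

    Large positive pre-activations overflow exp to inf and map cleanly
    to 0 for the reciprocal, so no clipping is needed.
    """
    np.negative(x, out=x)
    with np.errstate(over="ignore"):
        np.exp(x, out=x)
    x += 1.0
    np.reciprocal(x, out=x)
    return x


def _cell_forward(a, cprev, gates_t, c_t, tanh_c_t, h_t, scratch):
    """One LSTM step.

    ``a`` holds the (B, 4H) pre-activations and is destroyed.  Activated
    gates land in ``gates_t`` with shape (4, B, H) — gate-contiguous, which
    keeps every later elementwise pass on contiguous memory (strided slices
    of the (B, 4H) layout cost about twice as much per ufunc).  The tanh
    gate g is copied out first so one full-array logistic can handle i, f
    and o in four passes.
    """
    h = cprev.shape[1]
    i, f, g, o = gates_t[0], gates_t[1], gates_t[2], gates_t[3]
    np.copyto(g, a[:, 2 * h : 3 * h])
    np.tanh(g, out=g)
    _sigmoid_(a)
    np.copyto(i, a[:, :h])
    np.copyto(f, a[:, h : 2 * h])
    np.copyto(o, a[:, 3 * h :])
    np.multiply(f, cprev, out=c_t)
    np.multiply(i, g, out=scratch)
    c_t += scratch
    np.tanh(c_t, out=tanh_c_t)
    np.multiply(o, tanh_c_t, out=h_t)


def _cell_backward(dh, dc_next, gates_t, tanh_c_t, cprev, da_t, dc_out, scratch):
    """Backward through one LSTM step.

    Reads the (4, B, H) gate cache, writes the pre-activation gradients
    into ``da_t`` (shape (B, 4H), as the weight gemms need them) and the
    carried cell-state gradient into ``dc_out``; ``dc_next`` stays intact.
    """
    h = dh.shape[1]
    i, f, g, o = gates_t[0], gates_t[1], gates_t[2], gates_t[3]
    di, df = scratch[0], scratch[1]
    dc = scratch[2]
    # dc = dc_next + dh * o * (1 - tanh_c^2)
    np.multiply(tanh_c_t, tanh_c_t, out=dc)
    np.subtract(1.0, dc, out=dc)
    dc *= o
    dc *= dh
    dc += dc_next
    # gate gradients through the activations, on contiguous scratch
    np.subtract(1.0, i, out=di)
    di *= i
    di *= g
    di *= dc
    np.copyto(da_t[:, :h], di)
    np.subtract(1.0, f, out=df)
    df *= f
    df *= cprev
    df *= dc
    np.copyto(da_t[:, h : 2 * h], df)
    dg = di
    np.multiply(g, g, out=dg)
    np.subtract(1.0, dg, out=dg)
    dg *= i
    dg *= dc
    np.copyto(da_t[:, 2 * h : 3 * h], dg)
    do = df
    np.subtract(1.0, o, out=do)
    do *= o
    do *= tanh_c_t
    do *= dh
    np.copyto(da_t[:, 3 * h :], do)
    # carried cell gradient
    np.multiply(dc, f, out=dc_out)


@dataclass
class _LayerCache:
    # all arrays time-major, so per-step slices are contiguous
    x: np.ndarray  # (L, B, F) layer input
    gates: np.ndarray  # (L, 4, B, H) activated gates [i, f, g, o]
    c: np.ndarray  # (L, B, H) cell states
    h: np.ndarray  # (L, B, H) hidden states
    tanh_c: np.ndarray  # (L, B, H)


class LSTMRegressor:
    """Many-to-one LSTM -> dense(1) regressor.

    Parameters
    ----------
    n_features:
        Input channels per time step.
    hidden_units:
        LSTM state size (H).
    n_layers:
        Number of stacked LSTM layers.
    seed:
        Seed for weight initialization.
    dtype:
        float32 by default; use float64 for gradient checking.
    """

    def __init__(
        self,
        n_features: int,
        hidden_units: int,
        n_layers: int = 1,
        seed: int = 0,
        dtype=np.float32,
    ) -> None:
        if n_features < 1 or hidden_units < 1 or n_layers < 1:
            raise ValueError("n_features, hidden_units and n_layers must be >= 1")
        self.n_features = n_features
        self.hidden_units = hidden_units
        self.n_layers = n_layers
        self.dtype = np.dtype(dtype)
        rng = np.random.default_rng(seed)
        h = hidden_units
        self.layers: list[dict[str, np.ndarray]] = []
        f = n_features
        for _ in range(n_layers):
            wx = self._glorot(rng, f, 4 * h)
            wh = np.concatenate(
                [self._orthogonal(rng, h) for _ in range(4)], axis=1
            ).astype(self.dtype)
            b = np.zeros(4 * h, dtype=self.dtype)
            b[h : 2 * h] = 1.0  # unit forget-gate bias
            self.layers.append({"wx": wx, "wh": wh, "b": b})
            f = h
        self.w_out = self._glorot(rng, h, 1).reshape(h)
        self.b_out = np.zeros((), dtype=self.dtype)
        # reusable large work buffers, keyed by name; avoids re-faulting
        # tens of MB of fresh pages on every minibatch
        self._bufs: dict[tuple, np.ndarray] = {}

    def _buf(self, name: str, shape: tuple[int, ...]) -> np.ndarray:
        key = (name, shape)
        arr = self._bufs.get(key)
        if arr is None:
            arr = np.empty(shape, dtype=self.dtype)
            self._bufs[key] = arr
        return arr

    def _glorot(self, rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-limit, limit, size=(fan_in, fan_out)).astype(self.dtype)

    @staticmethod
    def _orthogonal(rng: np.random.Generator, n: int) -> np.ndarray:
        a = rng.normal(size=(n, n))
        q, r = np.linalg.qr(a)
        return q * np.sign(np.diag(r))

    # -- parameter bookkeeping ------------------------------------------------

    def parameter_tensors(self) -> list[tuple[str, np.ndarray]]:
        """Every trainable array with a name (for enumeration/optimizers)."""
        out = []
        for i, layer in enumerate(self.layers):
            for key in ("wx", "wh", "b"):
                out.append((f"lstm{i}.{key}", layer[key]))
        out.append(("dense.w", self.w_out))
        out.append(("dense.b", self.b_out))
        return out

    def num_parameters(self) -> int:
        """Trainable parameter total by direct enumeration of the arrays."""
        return int(sum(t.size for _, t in self.parameter_tensors()))

    # -- forward / backward ---------------------------------------------------

    def _forward(self, x: np.ndarray, keep_cache: bool):
        """Run the stack on a (B, L, F) batch; internals are time-major."""
        b, length, f = x.shape
        hsz = self.hidden_units
        caches: list[_LayerCache] = []
        inp = self._buf("x_tmajor", (length, b, f))
        np.copyto(inp, x.transpose(1, 0, 2))
        for li, layer in enumerate(self.layers):
            z = self._buf(f"l{li}.z", (length, b, 4 * hsz))
            np.matmul(
                inp.reshape(length * b, -1), layer["wx"],
                out=z.reshape(length * b, 4 * hsz),
            )
            z += layer["b"]
            gates = self._buf(f"l{li}.gates", (length, 4, b, hsz))
            cs = self._buf(f"l{li}.c", (length, b, hsz))
            hs = self._buf(f"l{li}.h", (length, b, hsz))
            tcs = self._buf(f"l{li}.tanh_c", (length, b, hsz))
            cprev = np.zeros((b, hsz), dtype=self.dtype)
            hprev = np.zeros((b, hsz), dtype=self.dtype)
            scratch = np.empty((b, hsz), dtype=self.dtype)
            gbuf = np.empty((b, 4 * hsz), dtype=self.dtype)
            wh = layer["wh"]
            for t in range(length):
                a = z[t]
                np.matmul(hprev, wh, out=gbuf)
                a += gbuf
                _cell_forward(a, cprev, gates[t], cs[t], tcs[t], hs[t], scratch)
                cprev = cs[t]
                hprev = hs[t]
            if keep_cache:
                caches.append(_LayerCache(x=inp, gates=gates, c=cs, h=hs, tanh_c=tcs))
            inp = hs
        y = inp[-1] @ self.w_out + self.b_out
        return y.astype(np.float64), caches

    def predict(self, x: np.ndarray, batch_size: int = 512) -> np.ndarray:
        """Predictions for a (N, L, F) array, in target units."""
        x = np.ascontiguousarray(x, dtype=self.dtype)
        if x.ndim != 3 or x.shape[-1] != self.n_features:
            raise ValueError(
                f"expected input of shape (N, L, {self.n_features}), got {x.shape}"
            )
        if x.shape[0] == 0:
            return np.empty(0)
        outs = []
        for j in range(0, x.shape[0], batch_size):
            y, _ = self._forward(x[j : j + batch_size], keep_cache=False)
            outs.append(y)
        return np.concatenate(outs)

    def _backward(self, caches: list[_LayerCache], dy: np.ndarray):
        """Gradients for all parameters given d(loss)/d(output).

        ``dy`` has shape (B,).  Returns a list aligned with
        :meth:`parameter_tensors`.
        """
        hsz = self.hidden_units
        top = caches[-1]
        length, b, _ = top.h.shape
        dy = dy.astype(self.dtype)

        d_wout = top.h[-1].T @ dy
        d_bout = dy.sum()

        # gradient w.r.t. the top layer's hidden sequence (only last step used)
        dh_seq = self._buf("dh_seq", (length, b, hsz))
        dh_seq[:] = 0.0
        dh_seq[-1] = dy[:, None] * self.w_out

        grads: list[np.ndarray] = []
        for li in range(self.n_layers - 1, -1, -1):
            cache = caches[li]
            layer = self.layers[li]
            wh = layer["wh"]
            d_a = self._buf(f"l{li}.d_a", (length, b, 4 * hsz))
            d_wh = np.zeros_like(wh)
            dh_next = np.zeros((b, hsz), dtype=self.dtype)
            dc_next = np.zeros((b, hsz), dtype=self.dtype)
            zero_c = np.zeros((b, hsz), dtype=self.dtype)
            dc_out = np.empty((b, hsz), dtype=self.dtype)
            scratch = np.empty((3, b, hsz), dtype=self.dtype)
            dh = np.empty((b, hsz), dtype=self.dtype)
            whbuf = np.empty_like(wh)
            wh_t = np.ascontiguousarray(wh.T)
            for t in range(length - 1, -1, -1):
                np.add(dh_seq[t], dh_next, out=dh)
                cprev = cache.c[t - 1] if t > 0 else zero_c
                da = d_a[t]
                _cell_backward(
                    dh, dc_next, cache.gates[t], cache.tanh_c[t], cprev, da, dc_out,
                    scratch,
                )
                dc_next, dc_out = dc_out, dc_next
                if t > 0:
                    np.matmul(cache.h[t - 1].T, da, out=whbuf)
                    d_wh += whbuf
                np.matmul(da, wh_t, out=dh_next)
            flat_x = cache.x.reshape(length * b, -1)
            flat_da = d_a.reshape(length * b, 4 * hsz)
            d_wx = flat_x.T @ flat_da
            d_b = flat_da.sum(axis=0)
            grads[:0] = [d_wx, d_wh, d_b]
            if li > 0:
                dh_seq = (flat_da @ layer["wx"].T).reshape(length, b, -1)
        grads.append(d_wout)
        grads.append(np.asarray(d_bout, dtype=self.dtype))
        return grads

    def loss_and_gradients(self, x: np.ndarray, targets: np.ndarray):
        """Mean-squared-error loss and parameter gradients on one batch."""
        x = np.ascontiguousarray(x, dtype=self.dtype)
        y, caches = self._forward(x, keep_cache=True)
        resid = y - np.asarray(targets, dtype=np.float64)
        loss = float(np.mean(resid**2))
        dy = (2.0 / x.shape[0]) * resid
        grads = self._backward(caches, dy)
        return loss, grads

    # -- training -------------------------------------------------------------

    def fit(
        self,
        x: np.ndarray,
        targets: np.ndarray,
        epochs: int,
        learning_rate: float = 0.005,
        batch_size: int = 64,
        seed: int = 0,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> list[float]:
        """Adam on shuffled minibatches; returns the per-epoch mean loss.

        Raises ``FloatingPointError`` with diagnostics if the loss goes
        non-finite.
        """
        x = np.ascontiguousarray(x, dtype=self.dtype)
        targets = np.asarray(targets, dtype=np.float64)
        n = x.shape[0]
        if n == 0:
            raise ValueError("training set is empty")
        params = [t for _, t in self.parameter_tensors()]
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        rng = np.random.default_rng(seed)
        history: list[float] = []
        step = 0
        for epoch in range(epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for j in range(0, n, batch_size):
                idx = order[j : j + batch_size]
                loss, grads = self.loss_and_gradients(x[idx], targets[idx])
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite training loss at epoch {epoch}, step {step} "
                        f"(lr={learning_rate}, batch={batch_size})"
                    )
                epoch_loss += loss * idx.size
                step += 1
                b1c = 1.0 - beta1**step
                b2c = 1.0 - beta2**step
                for p, mi, vi, gi in zip(params, m, v, grads):
                    mi *= beta1
                    mi += (1.0 - beta1) * gi
                    vi *= beta2
                    vi += (1.0 - beta2) * gi * gi
                    p -= (learning_rate * (mi / b1c) / (np.sqrt(vi / b2c) + eps)).astype(
                        p.dtype
                    )
            history.append(epoch_loss / n)
        return history
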