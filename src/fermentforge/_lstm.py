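"""Numpy LSTM sequence-to-sequence backend.

A compact, self-contained recurrent network used by the forecaster:
``l`` stacked LSTM layers (all but the last returning full sequences),
a dense layer mapping the final hidden state of ``nc`` units to
``k·nc``, a second dense layer to ``pl·k``, a reshape to ``(pl, k)``
and batch normalization over the attribute axis of the reshaped
output.  Training minimizes RMSE with Adam; gradients are computed by
full backpropagation through time.  Everything is float32 and driven
by an explicit seeded Generator, so runs are bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

__all__ = ["VLSTM", "lstm_param_count"]

logger = logging.getLogger(__name__)

DTYPE = np.float32


def lstm_param_count(input_dim: int, units: int) -> int:
    """Trainable parameters of one LSTM layer: 4·((D+H)·H + H)."""
    return 4 * ((input_dim + units) * units + units)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _glorot(rng, shape):
    limit = np.sqrt(6.0 / (shape[0] + shape[1]))
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


def _orthogonal(rng, n, m):
    a = rng.standard_normal((max(n, m), min(n, m)))
    q, _ = np.linalg.qr(a)
    q = q[:n, :m] if q.shape[0] >= n else q.T[:n, :m]
    return q.astype(DTYPE)


class _LSTMLayer:
    def __init__(self, rng, input_dim: int, units: int):
        self.D, self.H = input_dim, units
        self.Wx = _glorot(rng, (input_dim, 4 * units))
        self.Wh = np.concatenate(
            [_orthogonal(rng, units, units) for _ in range(4)], axis=1
        )
        self.b = np.zeros(4 * units, dtype=DTYPE)
        self.b[units : 2 * units] = 1.0  # forget-gate bias

    def params(self):
        return [self.Wx, self.Wh, self.b]

    def forward(self, x):
        """x: (B, T, D) → h_seq (B, T, H); caches for backward."""
        B, T, D = x.shape
        H = self.H
        ax = x.reshape(B * T, D) @ self.Wx
        ax = ax.reshape(B, T, 4 * H) + self.b
        h = np.zeros((B, H), dtype=DTYPE)
        c = np.zeros((B, H), dtype=DTYPE)
        hs = np.empty((B, T, H), dtype=DTYPE)
        cache_gates = np.empty((B, T, 4 * H), dtype=DTYPE)
        cache_c = np.empty((B, T, H), dtype=DTYPE)
        cache_cprev = np.empty((B, T, H), dtype=DTYPE)
        for t in range(T):
            a = ax[:, t, :] + h @ self.Wh
            i = _sigmoid(a[:, :H])
            f = _sigmoid(a[:, H : 2 * H])
            g = np.tanh(a[:, 2 * H : 3 * H])
            o = _sigmoid(a[:, 3 * H :])
            cache_cprev[:, t, :] = c
            c = f * c + i * g
            h = o * np.tanh(c)
            hs[:, t, :] = h
            cache_gates[:, t, :] = np.concatenate([i, f, g, o], axis=1)
            cache_c[:, t, :] = c
        self._cache = (x, hs, cache_gates, cache_c, cache_cprev)
        return hs

    def backward(self, dh_seq):
        """dh_seq: (B, T, H) upstream gradient on the hidden sequence."""
        x, hs, gates, cs, cprevs = self._cache
        B, T, D = x.shape
        H = self.H
        da_seq = np.empty((B, T, 4 * H), dtype=DTYPE)
        dWh = np.zeros_like(self.Wh)
        dh_next = np.zeros((B, H), dtype=DTYPE)
        dc_next = np.zeros((B, H), dtype=DTYPE)
        for t in range(T - 1, -1, -1):
            dh = dh_seq[:, t, :] + dh_next
            i = gates[:, t, :H]
            f = gates[:, t, H : 2 * H]
            g = gates[:, t, 2 * H : 3 * H]
            o = gates[:, t, 3 * H :]
            c = cs[:, t, :]
            tanh_c = np.tanh(c)
            do = dh * tanh_c
            dc = dh * o * (1.0 - tanh_c**2) + dc_next
            di = dc * g
            df = dc * cprevs[:, t, :]
            dg = dc * i
            dc_next = dc * f
            da = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g**2),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            da_seq[:, t, :] = da
            h_prev = hs[:, t - 1, :] if t > 0 else np.zeros((B, H), dtype=DTYPE)
            dWh += h_prev.T @ da
            dh_next = da @ self.Wh.T
        flat_da = da_seq.reshape(B * T, 4 * H)
        dWx = x.reshape(B * T, D).T @ flat_da
        db = flat_da.sum(axis=0)
        dx = (flat_da @ self.Wx.T).reshape(B, T, D)
        self._cache = None
        return dx, [dWx, dWh, db]


class _Dense:
    def __init__(self, rng, n_in: int, n_out: int):
        self.W = _glorot(rng, (n_in, n_out))
        self.b = np.zeros(n_out, dtype=DTYPE)

    def params(self):
        return [self.W, self.b]

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        dx = dy @ self.W.T
        grads = [self._x.T @ dy, dy.sum(axis=0)]
        self._x = None
        return dx, grads


class _BatchNorm:
    """Batch normalization over the trailing feature axis."""

    def __init__(self, k: int, momentum: float = 0.99, eps: float = 1e-3):
        self.gamma = np.ones(k, dtype=DTYPE)
        self.beta = np.zeros(k, dtype=DTYPE)
        self.running_mean = np.zeros(k, dtype=DTYPE)
        self.running_var = np.ones(k, dtype=DTYPE)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, training: bool):
        # x: (B, pl, k); statistics over (B, pl) per attribute
        if training:
            mean = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            ).astype(DTYPE)
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            ).astype(DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_std
        if training:
            self._cache = (xhat, inv_std, x.shape[0] * x.shape[1])
        return self.gamma * xhat + self.beta

    def backward(self, dy):
        xhat, inv_std, n = self._cache
        dgamma = (dy * xhat).sum(axis=(0, 1))
        dbeta = dy.sum(axis=(0, 1))
        dxhat = dy * self.gamma
        dx = (
            inv_std
            / n
            * (n * dxhat - dxhat.sum(axis=(0, 1)) - xhat * (dxhat * xhat).sum(axis=(0, 1)))
        )
        self._cache = None
        return dx.astype(DTYPE), [dgamma, dbeta]


@dataclass
class _AdamState:
    m: list = field(default_factory=list)
    v: list = field(default_factory=list)
    t: int = 0


class VLSTM:
    """Variable-depth, variable-width stacked LSTM forecaster.

    Maps an input window of shape (nt, k) to a prediction of shape
    (pl, k).  ``cells`` and ``layers`` are the auto-tunable width and
    depth hyperparameters.
    """

    def __init__(
        self,
        cells: int,
        layers: int,
        nt: int,
        pl: int,
        k: int,
        seed: int = 0,
        batch_norm: bool = True,
    ):
        if cells < 1 or layers < 1 or nt < 1 or pl < 1 or k < 1:
            raise ValueError("all architecture sizes must be ≥ 1")
        self.cells, self.layers_n = cells, layers
        self.nt, self.pl, self.k = nt, pl, k
        self.batch_norm = batch_norm
        rng = np.random.default_rng(seed)
        self.lstm_layers = []
        d = k
        for _ in range(layers):
            self.lstm_layers.append(_LSTMLayer(rng, d, cells))
            d = cells
        self.dense1 = _Dense(rng, cells, k * cells)
        self.dense2 = _Dense(rng, k * cells, pl * k)
        self.bn = _BatchNorm(k) if batch_norm else None
        self._adam = None

    # -- plumbing -----------------------------------------------------------

    def parameters(self):
        ps = []
        for layer in self.lstm_layers:
            ps.extend(layer.params())
        ps.extend(self.dense1.params())
        ps.extend(self.dense2.params())
        if self.bn is not None:
            ps.extend(self.bn.params())
        return ps

    def param_count(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    # -- forward / backward -------------------------------------------------

    def forward(self, x, training: bool = False):
        """x: (B, nt, k) normalized inputs → (B, pl, k) predictions."""
        x = np.ascontiguousarray(x, dtype=DTYPE)
        h = x
        for layer in self.lstm_layers:
            h = layer.forward(h)
        last = h[:, -1, :]  # final hidden state of the last layer
        z1 = self.dense1.forward(last)
        z2 = self.dense2.forward(z1)
        out = z2.reshape(-1, self.pl, self.k)
        if self.bn is not None:
            out = self.bn.forward(out, training=training)
        if not training:
            for layer in self.lstm_layers:
                layer._cache = None
        return out

    def _backward(self, dout):
        grads_tail = []
        if self.bn is not None:
            dout, g_bn = self.bn.backward(dout)
            grads_tail = g_bn
        dz2 = dout.reshape(dout.shape[0], self.pl * self.k)
        dz1, g_d2 = self.dense2.backward(dz2)
        dlast, g_d1 = self.dense1.backward(dz1)
        B = dlast.shape[0]
        dh_seq = np.zeros((B, self.nt, self.cells), dtype=DTYPE)
        dh_seq[:, -1, :] = dlast
        grads_lstm = []
        dh = dh_seq
        for layer in reversed(self.lstm_layers):
            dh, g = layer.backward(dh)
            grads_lstm = g + grads_lstm
        return grads_lstm + g_d1 + g_d2 + grads_tail

    def loss_and_grads(self, x, y):
        """RMSE loss over the batch and gradients w.r.t. all parameters."""
        y = np.asarray(y, dtype=DTYPE)
        pred = self.forward(x, training=True)
        resid = pred - y
        loss = float(np.sqrt(np.mean(resid.astype(np.float64) ** 2)))
        if loss == 0.0:
            return 0.0, [np.zeros_like(p) for p in self.parameters()]
        dout = (resid / (resid.size * loss)).astype(DTYPE)
        return loss, self._backward(dout)

    # -- optimization -------------------------------------------------------

    def _adam_step(self, grads, lr, beta1=0.9, beta2=0.999, eps=1e-7):
        params = self.parameters()
        if self._adam is None or len(self._adam.m) != len(params):
            self._adam = _AdamState(
                m=[np.zeros_like(p) for p in params],
                v=[np.zeros_like(p) for p in params],
            )
        st = self._adam
        st.t += 1
        for p, g, m, v in zip(params, grads, st.m, st.v):
            m *= beta1
            m += (1 - beta1) * g
            v *= beta2
            v += (1 - beta2) * g**2
            mhat = m / (1 - beta1**st.t)
            vhat = v / (1 - beta2**st.t)
            p -= (lr * mhat / (np.sqrt(vhat) + eps)).astype(DTYPE)

    def evaluate_loss(self, x, y, batch_size: int = 64) -> float:
        """RMSE over a dataset at inference (running batch-norm stats)."""
        y = np.asarray(y, dtype=DTYPE)
        sq_sum, count = 0.0, 0
        for start in range(0, len(x), batch_size):
            pred = self.forward(x[start : start + batch_size], training=False)
            resid = pred.astype(np.float64) - y[start : start + batch_size]
            sq_sum += float(np.sum(resid**2))
            count += resid.size
        if count == 0:
            raise ValueError("cannot evaluate on an empty dataset")
        return float(np.sqrt(sq_sum / count))

    def fit(
        self,
        x,
        y,
        epochs: int = 100,
        batch_size: int = 32,
        lr: float = 1e-4,
        lr_factor: float = 0.25,
        lr_patience: int = 1,
        lr_min: float = 1e-10,
        early_stop_patience: int = 5,
        early_stop_min_delta: float = 1e-5,
        validation_data=None,
        validation_split: float = 0.0,
        seed: int = 0,
        verbose: bool = False,
    ) -> dict:
        """Train with Adam, plateau LR reduction and early stopping.

        Returns a history dict with per-epoch train/validation RMSE and
        learning rates; best-validation weights are restored at the end.
        """
        x = np.asarray(x, dtype=DTYPE)
        y = np.asarray(y, dtype=DTYPE)
        rng = np.random.default_rng(seed)
        if validation_data is None and validation_split > 0:
            n_val = max(1, int(round(len(x) * validation_split)))
            perm = rng.permutation(len(x))
            val_idx, train_idx = perm[:n_val], perm[n_val:]
            validation_data = (x[val_idx], y[val_idx])
            x, y = x[train_idx], y[train_idx]
        history = {"loss": [], "val_loss": [], "lr": []}
        best_val = np.inf
        best_weights = None
        wait_es = wait_lr = 0
        for epoch in range(epochs):
            order = rng.permutation(len(x))
            losses = []
            for start in range(0, len(x), batch_size):
                idx = order[start : start + batch_size]
                loss, grads = self.loss_and_grads(x[idx], y[idx])
                self._adam_step(grads, lr)
                losses.append(loss)
            train_loss = float(np.mean(losses)) if losses else np.nan
            if validation_data is not None:
                val_loss = self.evaluate_loss(*validation_data)
            else:
                val_loss = train_loss
            history["loss"].append(train_loss)
            history["val_loss"].append(val_loss)
            history["lr"].append(lr)
            if verbose:
                logger.info(
                    "epoch %d loss %.5f val %.5f lr %.2e", epoch + 1, train_loss, val_loss, lr
                )
            if val_loss < best_val - early_stop_min_delta:
                best_val = val_loss
                best_weights = [p.copy() for p in self.parameters()]
                wait_es = wait_lr = 0
            else:
                wait_es += 1
                wait_lr += 1
                if wait_lr >= lr_patience and lr > lr_min:
                    lr = max(lr * lr_factor, lr_min)
                    wait_lr = 0
                if wait_es >= early_stop_patience:
                    break
        if best_weights is not None:
            for p, w in zip(self.parameters(), best_weights):
                p[...] = w
        history["best_val_loss"] = float(best_val)
        history["epochs_ran"] = len(history["loss"])
        return history

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        arrays = {f"p{i}": p for i, p in enumerate(self.parameters())}
        if self.bn is not None:
            arrays["bn_mean"] = self.bn.running_mean
            arrays["bn_var"] = self.bn.running_var
        np.savez(
            path,
            meta=np.array(
                [self.cells, self.layers_n, self.nt, self.pl, self.k, int(self.batch_norm)]
            ),
            **arrays,
        )

    @classmethod
    def load(cls, path) -> "VLSTM":
        data = np.load(path)
        cells, layers, nt, pl, k, bn = (int(v) for v in data["meta"])
        model = cls(cells, layers, nt, pl, k, batch_norm=bool(bn))
        for i, p in enumerate(model.parameters()):
            p[...] = data[f"p{i}"]
        if model.bn is not None:
            model.bn.running_mean = data["bn_mean"]
            model.bn.running_var = data["bn_var"]
        return model
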