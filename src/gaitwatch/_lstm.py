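"""A small, fully seeded LSTM sequence-autoencoder core in numpy.

Implements exactly what the per-joint anomaly models need and nothing more:
stacked LSTM layers with full backpropagation through time, inverted
dropout, dense projections, an Adam optimizer, and a sequence autoencoder
(two-layer LSTM encoder -> dense bottleneck -> repeat -> two-layer LSTM
decoder -> per-timestep dense head) trained under mean squared error.

The arrays are tiny (batch <= 64, sequence length ~30, <= 64 hidden units),
so a vectorised numpy implementation trains the full model set in seconds to
minutes on one CPU.  All randomness (weight init, shuffling, dropout) flows
from a single generator, so training is bit-reproducible for a given seed.

Gate order in the packed weight matrices is (i, f, g, o); forget-gate biases
start at 1, a standard stabilisation for short sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["LSTMLayer", "Dense", "AdamState", "SequenceAutoencoder"]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class LSTMLayer:
    """One LSTM layer over (batch, time, features) inputs."""

    def __init__(self, n_in: int, n_units: int, rng: np.random.Generator):
        self.n_in = n_in
        self.n_units = n_units
        self.Wx = _glorot(rng, n_in, 4 * n_units)
        self.Wh = _glorot(rng, n_units, 4 * n_units)
        self.b = np.zeros(4 * n_units)
        self.b[n_units : 2 * n_units] = 1.0  # forget-gate bias

    @property
    def params(self) -> list[np.ndarray]:
        return [self.Wx, self.Wh, self.b]

    def forward(self, X: np.ndarray) -> tuple[np.ndarray, dict]:
        B, L, _ = X.shape
        H = self.n_units
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        Zx = X.reshape(B * L, -1) @ self.Wx  # input projections, all timesteps
        Zx = Zx.reshape(B, L, 4 * H)
        hs = np.empty((B, L, H))
        cache = {
            "X": X,
            "i": np.empty((B, L, H)), "f": np.empty((B, L, H)),
            "g": np.empty((B, L, H)), "o": np.empty((B, L, H)),
            "c": np.empty((B, L, H)), "tc": np.empty((B, L, H)),
            "h_prev": np.empty((B, L, H)), "c_prev": np.empty((B, L, H)),
        }
        for t in range(L):
            a = Zx[:, t] + h @ self.Wh + self.b
            i = _sigmoid(a[:, :H])
            f = _sigmoid(a[:, H : 2 * H])
            g = np.tanh(a[:, 2 * H : 3 * H])
            o = _sigmoid(a[:, 3 * H :])
            cache["h_prev"][:, t] = h
            cache["c_prev"][:, t] = c
            c = f * c + i * g
            tc = np.tanh(c)
            h = o * tc
            cache["i"][:, t] = i
            cache["f"][:, t] = f
            cache["g"][:, t] = g
            cache["o"][:, t] = o
            cache["c"][:, t] = c
            cache["tc"][:, t] = tc
            hs[:, t] = h
        return hs, cache

    def backward(self, dHs: np.ndarray, cache: dict) -> tuple[np.ndarray, list[np.ndarray]]:
        """Gradient of the loss w.r.t. inputs and parameters.

        ``dHs`` carries dL/dh_t for every timestep (zeros where the layer's
        output is unused downstream).
        """
        X = cache["X"]
        B, L, _ = X.shape
        H = self.n_units
        dWx = np.zeros_like(self.Wx)
        dWh = np.zeros_like(self.Wh)
        db = np.zeros_like(self.b)
        dX = np.empty_like(X)
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        dA = np.empty((B, L, 4 * H))
        for t in range(L - 1, -1, -1):
            i, f, g, o = (cache[k][:, t] for k in ("i", "f", "g", "o"))
            tc = cache["tc"][:, t]
            dh = dHs[:, t] + dh_next
            do = dh * tc
            dc = dc_next + dh * o * (1.0 - tc * tc)
            di = dc * g
            df = dc * cache["c_prev"][:, t]
            dg = dc * i
            da = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g * g),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            dA[:, t] = da
            dWh += cache["h_prev"][:, t].T @ da
            dh_next = da @ self.Wh.T
            dc_next = dc * f
        flatA = dA.reshape(B * L, 4 * H)
        dWx = X.reshape(B * L, -1).T @ flatA
        db = flatA.sum(axis=0)
        dX = (flatA @ self.Wx.T).reshape(X.shape)
        return dX, [dWx, dWh, db]


class Dense:
    """Affine map applied to the trailing axis."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = _glorot(rng, n_in, n_out)
        self.b = np.zeros(n_out)

    @property
    def params(self) -> list[np.ndarray]:
        return [self.W, self.b]

    def forward(self, X: np.ndarray) -> np.ndarray:
        return X @ self.W + self.b

    def backward(self, X: np.ndarray, dY: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        flatX = X.reshape(-1, X.shape[-1])
        flatD = dY.reshape(-1, dY.shape[-1])
        dW = flatX.T @ flatD
        db = flatD.sum(axis=0)
        dX = (flatD @ self.W.T).reshape(X.shape)
        return dX, [dW, db]


@dataclass
class AdamState:
    lr: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    t: int = 0
    m: list[np.ndarray] = field(default_factory=list)
    v: list[np.ndarray] = field(default_factory=list)

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        if not self.m:
            self.m = [np.zeros_like(p) for p in params]
            self.v = [np.zeros_like(p) for p in params]
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class SequenceAutoencoder:
    """Two-layer LSTM encoder/decoder with a dense bottleneck.

    The encoder's final hidden state is projected to ``latent_dim``,
    repeated across all timesteps as the decoder input, and the decoder's
    per-timestep states are projected back to the input channel count.
    Dropout (inverted, rate ``dropout``) is applied to the first encoder
    layer's and first decoder layer's output sequences during training only.
    """

    def __init__(
        self,
        n_channels: int,
        enc_units: tuple[int, int],
        latent_dim: int = 16,
        dropout: float = 0.2,
        seed: int = 0,
    ):
        self.n_channels = n_channels
        self.enc_units = tuple(enc_units)
        self.latent_dim = latent_dim
        self.dropout = dropout
        self.seed = seed
        self.rng = np.random.default_rng(seed)
        u1, u2 = enc_units
        self.enc1 = LSTMLayer(n_channels, u1, self.rng)
        self.enc2 = LSTMLayer(u1, u2, self.rng)
        self.to_latent = Dense(u2, latent_dim, self.rng)
        self.dec1 = LSTMLayer(latent_dim, u2, self.rng)
        self.dec2 = LSTMLayer(u2, u1, self.rng)
        self.head = Dense(u1, n_channels, self.rng)

    @property
    def layers(self) -> list:
        return [self.enc1, self.enc2, self.to_latent, self.dec1, self.dec2, self.head]

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    def get_weights(self) -> dict[str, np.ndarray]:
        names = ["enc1", "enc2", "to_latent", "dec1", "dec2", "head"]
        out = {}
        for name, layer in zip(names, self.layers):
            for i, p in enumerate(layer.params):
                out[f"{name}.{i}"] = p
        return out

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        names = ["enc1", "enc2", "to_latent", "dec1", "dec2", "head"]
        for name, layer in zip(names, self.layers):
            for i, p in enumerate(layer.params):
                p[...] = weights[f"{name}.{i}"]

    def _dropout_mask(self, shape: tuple[int, ...]) -> np.ndarray:
        keep = 1.0 - self.dropout
        return (self.rng.random(shape) < keep).astype(np.float64) / keep

    def forward(self, X: np.ndarray, train: bool = False):
        """Reconstruction X_hat (same shape as X) plus a backward cache."""
        B, L, _ = X.shape
        h1, c1 = self.enc1.forward(X)
        m1 = self._dropout_mask(h1.shape) if (train and self.dropout > 0) else None
        h1d = h1 * m1 if m1 is not None else h1
        h2, c2 = self.enc2.forward(h1d)
        z = self.to_latent.forward(h2[:, -1])  # (B, latent)
        rep = np.repeat(z[:, None, :], L, axis=1)
        h3, c3 = self.dec1.forward(rep)
        m3 = self._dropout_mask(h3.shape) if (train and self.dropout > 0) else None
        h3d = h3 * m3 if m3 is not None else h3
        h4, c4 = self.dec2.forward(h3d)
        Xhat = self.head.forward(h4)
        cache = dict(
            X=X, h1=h1, c1=c1, m1=m1, h1d=h1d, h2=h2, c2=c2,
            z=z, rep=rep, h3=h3, c3=c3, m3=m3, h3d=h3d, h4=h4, c4=c4, Xhat=Xhat,
        )
        return Xhat, cache

    def backward(self, cache: dict) -> list[np.ndarray]:
        """Gradients of mean-squared reconstruction error w.r.t. params."""
        X, Xhat = cache["X"], cache["Xhat"]
        B = X.shape[0]
        dXhat = 2.0 * (Xhat - X) / X.size  # d(mean sq err)/dXhat
        dh4, g_head = self.head.backward(cache["h4"], dXhat)
        dh3d, g_dec2 = self.dec2.backward(dh4, cache["c4"])
        dh3 = dh3d * cache["m3"] if cache["m3"] is not None else dh3d
        drep, g_dec1 = self.dec1.backward(dh3, cache["c3"])
        dz = drep.sum(axis=1)
        dh2_last, g_lat = self.to_latent.backward(cache["h2"][:, -1], dz)
        dh2 = np.zeros_like(cache["h2"])
        dh2[:, -1] = dh2_last
        dh1d, g_enc2 = self.enc2.backward(dh2, cache["c2"])
        dh1 = dh1d * cache["m1"] if cache["m1"] is not None else dh1d
        _, g_enc1 = self.enc1.backward(dh1, cache["c1"])
        return g_enc1 + g_enc2 + g_lat + g_dec1 + g_dec2 + g_head

    def fit(
        self,
        X: np.ndarray,
        epochs: int,
        batch_size: int,
        learning_rate: float = 1e-4,
    ) -> list[float]:
        """Minimise MSE with Adam; returns the per-epoch mean training loss."""
        n = X.shape[0]
        opt = AdamState(lr=learning_rate)
        history: list[float] = []
        for epoch in range(epochs):
            order = self.rng.permutation(n)
            losses = []
            for start in range(0, n, batch_size):
                batch = X[order[start : start + batch_size]]
                Xhat, cache = self.forward(batch, train=True)
                loss = float(np.mean((Xhat - batch) ** 2))
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"training diverged (non-finite loss) at epoch {epoch}"
                    )
                grads = self.backward(cache)
                opt.step(self.params, grads)
                losses.append(loss * batch.shape[0])
            history.append(sum(losses) / n)
        return history

    def reconstruct(self, X: np.ndarray) -> np.ndarray:
        """Deterministic (no-dropout) reconstruction."""
        Xhat, _ = self.forward(X, train=False)
        return Xhat
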