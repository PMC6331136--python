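"""A small convolutional network for 4 x 101 encoded RNA windows.

Architecture: one valid-mode convolution over the one-hot (or
coverage-weighted one-hot) input, ReLU, 1-D max pooling, dropout, a dense
hidden layer with ReLU and dropout, and a 2-unit softmax output.  Training
minimizes categorical cross-entropy with the Adadelta update rule
(accumulated squared gradients and squared updates, rho=0.95, eps=1e-6), so
no learning-rate tuning is needed.

The network is deliberately self-contained numpy: forward, backprop and the
optimizer live here, fully seeded, so that training is bitwise reproducible
on one machine.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


@dataclass(frozen=True)
class CNNHyperparams:
    """Hyperparameters of the site-calling CNN (defaults = published optimum)."""

    kernel_size: tuple[int, int] = (4, 5)
    n_filters: int = 32
    pool_size: tuple[int, int] = (1, 4)
    dropout1: float = 0.25
    dense_nodes: int = 12
    dropout2: float = 0.25

    def __post_init__(self) -> None:
        kh, kw = self.kernel_size
        ph, pw = self.pool_size
        if kh != 4 or kw < 1:
            raise ValueError("kernel must span the 4 base rows with width >= 1")
        if ph != 1 or pw < 1:
            raise ValueError("pooling is 1-D over positions with width >= 1")
        if self.n_filters < 1 or self.dense_nodes < 1:
            raise ValueError("filter and dense sizes must be positive")
        for d in (self.dropout1, self.dropout2):
            if not 0.0 <= d < 1.0:
                raise ValueError(f"dropout rate {d} outside [0, 1)")


def conv_positions(input_len: int, kernel_width: int) -> int:
    """Number of valid convolution positions along the sequence axis."""
    n = input_len - kernel_width + 1
    if n < 1:
        raise ValueError(
            f"kernel width {kernel_width} exceeds input length {input_len}"
        )
    return n


def pooled_positions(n_positions: int, pool_width: int) -> int:
    """Number of non-overlapping pooling windows (floor division)."""
    n = n_positions // pool_width
    if n < 1:
        raise ValueError(
            f"pool width {pool_width} exceeds {n_positions} conv positions"
        )
    return n


class _Adadelta:
    """Adadelta state for one parameter array."""

    def __init__(self, shape: tuple[int, ...], rho: float = 0.95, eps: float = 1e-6):
        self.rho = rho
        self.eps = eps
        self.accum_grad = np.zeros(shape)
        self.accum_update = np.zeros(shape)

    def step(self, grad: np.ndarray) -> np.ndarray:
        r, e = self.rho, self.eps
        self.accum_grad = r * self.accum_grad + (1 - r) * grad**2
        update = (
            -np.sqrt(self.accum_update + e) / np.sqrt(self.accum_grad + e) * grad
        )
        self.accum_update = r * self.accum_update + (1 - r) * update**2
        return update


class ConvNet:
    """The 4x101 -> 2-class CNN with its own training loop."""

    def __init__(
        self,
        hp: CNNHyperparams | None = None,
        input_len: int = 101,
        rng: np.random.Generator | None = None,
    ):
        self.hp = hp or CNNHyperparams()
        self.input_len = input_len
        rng = rng or np.random.default_rng()
        kh, kw = self.hp.kernel_size
        self.n_conv = conv_positions(input_len, kw)
        self.n_pool = pooled_positions(self.n_conv, self.hp.pool_size[1])
        n_flat = self.n_pool * self.hp.n_filters

        def glorot(fan_in: int, fan_out: int, shape: tuple[int, ...]) -> np.ndarray:
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-limit, limit, size=shape)

        k = kh * kw
        self.w_conv = glorot(k, self.hp.n_filters, (k, self.hp.n_filters))
        self.b_conv = np.zeros(self.hp.n_filters)
        self.w_dense = glorot(n_flat, self.hp.dense_nodes, (n_flat, self.hp.dense_nodes))
        self.b_dense = np.zeros(self.hp.dense_nodes)
        self.w_out = glorot(self.hp.dense_nodes, 2, (self.hp.dense_nodes, 2))
        self.b_out = np.zeros(2)
        self._opt = {
            name: _Adadelta(getattr(self, name).shape)
            for name in ("w_conv", "b_conv", "w_dense", "b_dense", "w_out", "b_out")
        }

    # -- forward ---------------------------------------------------------

    def _columns(self, x: np.ndarray) -> np.ndarray:
        """im2col: (B, 4, L) -> (B, P, 4*kw) sliding windows."""
        kh, kw = self.hp.kernel_size
        win = sliding_window_view(x, (kh, kw), axis=(1, 2))  # (B, 1, P, kh, kw)
        b = x.shape[0]
        return win.reshape(b, self.n_conv, kh * kw)

    def forward(
        self, x: np.ndarray, train_rng: np.random.Generator | None = None
    ) -> dict[str, np.ndarray]:
        """Run the network; with ``train_rng`` dropout is active (inverted)."""
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 2:
            x = x[np.newaxis]
        if x.shape[1:] != (4, self.input_len):
            raise ValueError(f"expected (n, 4, {self.input_len}), got {x.shape}")
        b = x.shape[0]
        pw = self.hp.pool_size[1]
        cache: dict[str, np.ndarray] = {}

        cols = self._columns(x)
        conv = cols @ self.w_conv + self.b_conv  # (B, P, F)
        relu1 = np.maximum(conv, 0.0)
        trimmed = relu1[:, : self.n_pool * pw, :].reshape(
            b, self.n_pool, pw, self.hp.n_filters
        )
        pool_arg = trimmed.argmax(axis=2)
        pooled = np.take_along_axis(trimmed, pool_arg[:, :, None, :], axis=2)[
            :, :, 0, :
        ]
        if train_rng is not None and self.hp.dropout1 > 0:
            keep = 1.0 - self.hp.dropout1
            mask1 = (train_rng.random(pooled.shape) < keep) / keep
            pooled = pooled * mask1
            cache["mask1"] = mask1
        flat = pooled.reshape(b, -1)
        dense = flat @ self.w_dense + self.b_dense
        relu2 = np.maximum(dense, 0.0)
        hidden = relu2
        if train_rng is not None and self.hp.dropout2 > 0:
            keep = 1.0 - self.hp.dropout2
            mask2 = (train_rng.random(hidden.shape) < keep) / keep
            hidden = hidden * mask2
            cache["mask2"] = mask2
        logits = hidden @ self.w_out + self.b_out
        shifted = logits - logits.max(axis=1, keepdims=True)
        exp = np.exp(shifted)
        probs = exp / exp.sum(axis=1, keepdims=True)

        cache.update(
            cols=cols, conv=conv, pool_arg=pool_arg, flat=flat,
            dense=dense, hidden=hidden, probs=probs,
        )
        return cache

    def predict_proba(self, x: np.ndarray, batch_size: int = 512) -> np.ndarray:
        """Class probabilities (n, 2) with dropout disabled."""
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 2:
            x = x[np.newaxis]
        parts = [
            self.forward(x[i : i + batch_size])["probs"]
            for i in range(0, x.shape[0], batch_size)
        ]
        return np.concatenate(parts, axis=0)

    # -- backward --------------------------------------------------------

    def _backward(
        self, cache: dict[str, np.ndarray], y_onehot: np.ndarray
    ) -> dict[str, np.ndarray]:
        b = y_onehot.shape[0]
        pw = self.hp.pool_size[1]
        f = self.hp.n_filters

        dlogits = (cache["probs"] - y_onehot) / b
        grads = {
            "w_out": cache["hidden"].T @ dlogits,
            "b_out": dlogits.sum(axis=0),
        }
        dhidden = dlogits @ self.w_out.T
        if "mask2" in cache:
            dhidden = dhidden * cache["mask2"]
        dhidden = dhidden * (cache["dense"] > 0)
        grads["w_dense"] = cache["flat"].T @ dhidden
        grads["b_dense"] = dhidden.sum(axis=0)
        dflat = dhidden @ self.w_dense.T
        dpooled = dflat.reshape(b, self.n_pool, f)
        if "mask1" in cache:
            dpooled = dpooled * cache["mask1"]
        # scatter pooled gradients back to the argmax positions
        dtrim = np.zeros((b, self.n_pool, pw, f))
        np.put_along_axis(dtrim, cache["pool_arg"][:, :, None, :],
                          dpooled[:, :, None, :], axis=2)
        dconv = np.zeros((b, self.n_conv, f))
        dconv[:, : self.n_pool * pw, :] = dtrim.reshape(b, self.n_pool * pw, f)
        dconv = dconv * (cache["conv"] > 0)
        grads["w_conv"] = np.einsum("bpk,bpf->kf", cache["cols"], dconv)
        grads["b_conv"] = dconv.sum(axis=(0, 1))
        return grads

    # -- training --------------------------------------------------------

    def train_step(
        self, x: np.ndarray, y: np.ndarray, rng: np.random.Generator
    ) -> float:
        """One minibatch of cross-entropy + Adadelta; returns the batch loss."""
        y_onehot = np.eye(2)[np.asarray(y, dtype=int)]
        cache = self.forward(x, train_rng=rng)
        probs = np.clip(cache["probs"], 1e-12, 1.0)
        loss = float(-(y_onehot * np.log(probs)).sum(axis=1).mean())
        grads = self._backward(cache, y_onehot)
        for name, grad in grads.items():
            param = getattr(self, name)
            param += self._opt[name].step(grad)
        return loss

    def fit(
        self,
        x: np.ndarray,
        y: np.ndarray,
        epochs: int = 50,
        batch_size: int = 64,
        rng: np.random.Generator | None = None,
    ) -> list[float]:
        """Full training loop; returns the mean loss per epoch."""
        rng = rng or np.random.default_rng()
        x = np.asarray(x, dtype=np.float64)
        y = np.asarray(y, dtype=int)
        if x.shape[0] != y.shape[0]:
            raise ValueError("X and y length mismatch")
        history = []
        n = x.shape[0]
        for _ in range(epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                losses.append(self.train_step(x[idx], y[idx], rng))
            history.append(float(np.mean(losses)))
        return history

    # -- persistence -----------------------------------------------------

    def get_weights(self) -> dict[str, np.ndarray]:
        return {
            name: getattr(self, name).copy()
            for name in ("w_conv", "b_conv", "w_dense", "b_dense", "w_out", "b_out")
        }

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for name, value in weights.items():
            target = getattr(self, name)
            if target.shape != value.shape:
                raise ValueError(f"shape mismatch for {name}")
            setattr(self, name, np.asarray(value, dtype=np.float64).copy())
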