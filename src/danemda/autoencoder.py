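"""Stacked auto-encoder compressing enhanced-matrix rows into node embeddings.

Plain numpy implementation: logistic-sigmoid hidden layers, linear
reconstruction output, untied encoder/decoder weights, Glorot-style
initialization, mini-batch gradient descent with Adam-style adaptive
updates (enhanced-matrix entries are small and would otherwise need
per-dataset learning-rate tuning).  Training is greedy layer-wise
pretraining (each layer learns to reconstruct the previous layer's
activations) followed by end-to-end fine-tuning on mean squared
reconstruction error.  Everything is driven by one seed, so identical
input + spec + seed reproduces the trained weights bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass(frozen=True)
class AutoencoderSpec:
    """Architecture and training hyper-parameters.

    ``hidden_dims`` lists the encoder layer widths ending in the code
    dimension; the input width is prepended at training time and the full
    chain must be strictly decreasing.
    """

    hidden_dims: tuple[int, ...] = (256, 64)
    epochs_pretrain: int = 50
    epochs_finetune: int = 100
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.hidden_dims) < 1 or self.hidden_dims[-1] < 2:
            raise ValueError("need at least one hidden layer and code dim >= 2")
        if any(b >= a for a, b in zip(self.hidden_dims, self.hidden_dims[1:])):
            raise ValueError("hidden_dims must be strictly decreasing")
        if min(self.epochs_pretrain, self.epochs_finetune) < 0:
            raise ValueError("epoch counts must be non-negative")
        if self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("invalid batch_size or learning_rate")

    def layer_dims(self, n_input: int) -> tuple[int, ...]:
        """Full layer chain for an input of width ``n_input``.

        Requested hidden widths are capped below the preceding layer so the
        chain stays strictly decreasing on narrow inputs.
        """
        dims = [n_input]
        for h in self.hidden_dims:
            dims.append(min(h, dims[-1] - 1))
        if dims[-1] < 2:
            raise ValueError(
                f"input width {n_input} too narrow for {len(self.hidden_dims)} "
                "hidden layers"
            )
        return tuple(dims)

    @property
    def code_dim(self) -> int:
        return self.hidden_dims[-1]


@dataclass(frozen=True)
class EmbeddingMatrix:
    """Low-dimensional node codes; row order matches the network node index."""

    ids: tuple[str, ...]
    H: np.ndarray

    def row(self, node_id: str) -> np.ndarray:
        return self.H[self.ids.index(node_id)]


def _glorot(rng: np.random.Generator, n_in: int, n_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-limit, limit, size=(n_in, n_out))


class _Adam:
    """Adam-style per-parameter adaptive update (beta1=0.9, beta2=0.999)."""

    def __init__(self, lr: float) -> None:
        self.lr = lr
        self.state: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        self.t = 0

    def step(self, params_grads: list[tuple[np.ndarray, np.ndarray]]) -> None:
        self.t += 1
        b1c = 1 - 0.9**self.t
        b2c = 1 - 0.999**self.t
        for key, (p, g) in enumerate(params_grads):
            m, v = self.state.get(key, (np.zeros_like(p), np.zeros_like(p)))
            m = 0.9 * m + 0.1 * g
            v = 0.999 * v + 0.001 * g * g
            self.state[key] = (m, v)
            p -= self.lr * (m / b1c) / (np.sqrt(v / b2c) + 1e-8)


@dataclass
class StackedAutoencoder:
    spec: AutoencoderSpec
    enc_W: list[np.ndarray] = field(default_factory=list)
    enc_b: list[np.ndarray] = field(default_factory=list)
    dec_W: list[np.ndarray] = field(default_factory=list)
    dec_b: list[np.ndarray] = field(default_factory=list)
    pretrain_losses: list[list[float]] = field(default_factory=list)
    finetune_losses: list[float] = field(default_factory=list)

    # -- forward passes -------------------------------------------------
    def _encode_array(self, X: np.ndarray) -> np.ndarray:
        H = X
        for W, b in zip(self.enc_W, self.enc_b):
            H = _sigmoid(H @ W + b)
        return H

    def _decode_array(self, H: np.ndarray) -> np.ndarray:
        for i, (W, b) in enumerate(zip(self.dec_W, self.dec_b)):
            H = H @ W + b
            if i < len(self.dec_W) - 1:  # final reconstruction layer is linear
                H = _sigmoid(H)
        return H

    def reconstruct(self, X: np.ndarray) -> np.ndarray:
        return self._decode_array(self._encode_array(X))

    def reconstruction_mse(self, X: np.ndarray) -> float:
        return float(np.mean((self.reconstruct(X) - X) ** 2))

    # -- training --------------------------------------------------------
    def fit(self, X: np.ndarray) -> "StackedAutoencoder":
        """Greedy layer-wise pretraining, then end-to-end fine-tuning."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("training input must be a 2-d matrix")
        dims = self.spec.layer_dims(X.shape[1])
        if X.shape[0] < self.spec.code_dim:
            raise ValueError("need at least code_dim training rows")
        rng = np.random.default_rng(self.spec.seed)

        self.enc_W = [_glorot(rng, a, b) for a, b in zip(dims, dims[1:])]
        self.enc_b = [np.zeros(b) for b in dims[1:]]
        rdims = dims[::-1]
        self.dec_W = [_glorot(rng, a, b) for a, b in zip(rdims, rdims[1:])]
        self.dec_b = [np.zeros(b) for b in rdims[1:]]

        # layer-wise pretraining: layer k reconstructs the activations of
        # layer k-1 through its own sigmoid code and a private linear decoder
        self.pretrain_losses = []
        H = X
        n_layers = len(self.enc_W)
        for k in range(n_layers):
            trace = self._pretrain_layer(k, H, rng)
            self.pretrain_losses.append(trace)
            H = _sigmoid(H @ self.enc_W[k] + self.enc_b[k])

        self.finetune_losses = self._finetune(X, rng)
        return self

    def _minibatches(self, n: int, rng: np.random.Generator):
        order = rng.permutation(n)
        bs = self.spec.batch_size
        for start in range(0, n, bs):
            yield order[start : start + bs]

    def _pretrain_layer(
        self, k: int, H: np.ndarray, rng: np.random.Generator
    ) -> list[float]:
        W, b = self.enc_W[k], self.enc_b[k]
        # the mirrored decoder layer (trained jointly, kept for fine-tuning)
        j = len(self.dec_W) - 1 - k
        V, c = self.dec_W[j], self.dec_b[j]
        opt = _Adam(self.spec.learning_rate)
        trace: list[float] = []
        for epoch in range(self.spec.epochs_pretrain):
            total, count = 0.0, 0
            for idx in self._minibatches(H.shape[0], rng):
                x = H[idx]
                h = _sigmoid(x @ W + b)
                r = h @ V + c
                err = r - x
                total += float(np.sum(err**2))
                count += err.size
                g_r = 2.0 * err / err.size
                g_V = h.T @ g_r
                g_c = g_r.sum(axis=0)
                g_h = g_r @ V.T
                g_z = g_h * h * (1 - h)
                g_W = x.T @ g_z
                g_b = g_z.sum(axis=0)
                opt.step([(W, g_W), (b, g_b), (V, g_V), (c, g_c)])
            loss = total / max(count, 1)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite pretraining loss at layer {k}, epoch {epoch}"
                )
            trace.append(loss)
        return trace

    def _finetune(self, X: np.ndarray, rng: np.random.Generator) -> list[float]:
        opt = _Adam(self.spec.learning_rate)
        trace: list[float] = []
        for epoch in range(self.spec.epochs_finetune):
            total, count = 0.0, 0
            for idx in self._minibatches(X.shape[0], rng):
                x = X[idx]
                acts = [x]
                for W, b in zip(self.enc_W, self.enc_b):
                    acts.append(_sigmoid(acts[-1] @ W + b))
                n_dec = len(self.dec_W)
                for i, (W, b) in enumerate(zip(self.dec_W, self.dec_b)):
                    z = acts[-1] @ W + b
                    acts.append(_sigmoid(z) if i < n_dec - 1 else z)
                err = acts[-1] - x
                total += float(np.sum(err**2))
                count += err.size
                grad = 2.0 * err / err.size
                layers = [(self.dec_W[i], self.dec_b[i], i < n_dec - 1)
                          for i in range(n_dec)]
                layers = [(self.enc_W[i], self.enc_b[i], True)
                          for i in range(len(self.enc_W))] + layers
                updates: list[tuple[np.ndarray, np.ndarray]] = []
                for depth in range(len(layers) - 1, -1, -1):
                    W, b, sig = layers[depth]
                    out = acts[depth + 1]
                    if sig:
                        grad = grad * out * (1 - out)
                    g_W = acts[depth].T @ grad
                    g_b = grad.sum(axis=0)
                    grad = grad @ W.T
                    updates.append((W, g_W))
                    updates.append((b, g_b))
                opt.step(updates)
            loss = total / max(count, 1)
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite fine-tuning loss at epoch {epoch}")
            trace.append(loss)
        return trace

    # -- public API ------------------------------------------------------
    def encode(self, M: np.ndarray, ids: tuple[str, ...] | list[str]) -> EmbeddingMatrix:
        """Deterministic forward pass mapping each row of M to its code."""
        M = np.asarray(M, dtype=float)
        if not self.enc_W:
            raise RuntimeError("model is untrained")
        if M.shape[1] != self.enc_W[0].shape[0]:
            raise ValueError(
                f"input width {M.shape[1]} != trained width {self.enc_W[0].shape[0]}"
            )
        if len(ids) != M.shape[0]:
            raise ValueError("ids must match the number of rows")
        return EmbeddingMatrix(ids=tuple(ids), H=self._encode_array(M))

    def save(self, path: str | Path) -> None:
        arrays = {"spec_hidden": np.array(self.spec.hidden_dims)}
        for i, (W, b) in enumerate(zip(self.enc_W, self.enc_b)):
            arrays[f"enc_W{i}"], arrays[f"enc_b{i}"] = W, b
        for i, (W, b) in enumerate(zip(self.dec_W, self.dec_b)):
            arrays[f"dec_W{i}"], arrays[f"dec_b{i}"] = W, b
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str | Path, spec: AutoencoderSpec | None = None
             ) -> "StackedAutoencoder":
        data = np.load(path)
        hidden = tuple(int(x) for x in data["spec_hidden"])
        model = cls(spec=spec or AutoencoderSpec(hidden_dims=hidden))
        n = len(hidden)
        model.enc_W = [data[f"enc_W{i}"] for i in range(n)]
        model.enc_b = [data[f"enc_b{i}"] for i in range(n)]
        model.dec_W = [data[f"dec_W{i}"] for i in range(n)]
        model.dec_b = [data[f"dec_b{i}"] for i in range(n)]
        return model


def train_autoencoder(M: np.ndarray, spec: AutoencoderSpec) -> StackedAutoencoder:
    """Convenience wrapper: build and fit a stacked auto-encoder on ``M``."""
    return StackedAutoencoder(spec=spec).fit(np.asarray(M, dtype=float))
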