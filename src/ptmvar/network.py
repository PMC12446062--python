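"""CNN + bidirectional-GRU sequence classifiers built from architecture genomes.

A model is assembled from an :class:`~ptmvar.nas.ArchitectureGenome`: a
stack of ``same``-padded 1-D convolutional blocks (each optionally with
batch normalization, max pooling and dropout), a fixed bidirectional GRU
with 50 units per direction whose final hidden states are concatenated,
a stack of dense blocks, and a single sigmoid output unit.  Training is
mini-batch gradient descent on binary cross-entropy with early stopping on
the validation set; the weights of the best validation epoch are kept.

Everything is float32 numpy via the in-package autodiff engine; runs are
bit-reproducible given the integer seed.
"""

from __future__ import annotations

import numpy as np

from ._autodiff import Tensor, binary_cross_entropy, max_pool1d, unfold_same
from .seqcore import N_CHANNELS, encode_batch

_ACTIVATIONS = ("relu", "tanh", "elu", "sigmoid")


def _activate(x: Tensor, name: str) -> Tensor:
    if name == "relu":
        return x.relu()
    if name == "tanh":
        return x.tanh()
    if name == "elu":
        return x.elu()
    if name == "sigmoid":
        return x.sigmoid()
    raise ValueError(f"unknown activation {name!r}")


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> Tensor:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, shape), requires_grad=True)


class _BatchNorm:
    """Per-channel batch normalization with running statistics for inference."""

    def __init__(self, channels: int, momentum: float = 0.9):
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.run_mean = np.zeros(channels, dtype=np.float32)
        self.run_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum

    @property
    def params(self):
        return [self.gamma, self.beta]

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        axes = tuple(range(x.data.ndim - 1))  # all but the channel axis
        if training:
            mu = x.mean(axis=axes, keepdims=True)
            centered = x - mu
            var = (centered * centered).mean(axis=axes, keepdims=True)
            norm = centered * (var + 1e-5).sqrt().reciprocal()
            m = self.momentum
            self.run_mean = m * self.run_mean + (1 - m) * mu.data.reshape(-1)
            self.run_var = m * self.run_var + (1 - m) * var.data.reshape(-1)
        else:
            norm = (x - self.run_mean) * (1.0 / np.sqrt(self.run_var + 1e-5))
        return norm * self.gamma + self.beta


class _BiGRU:
    """Bidirectional GRU; returns the concatenated final hidden states."""

    def __init__(self, rng: np.random.Generator, in_dim: int, units: int):
        self.units = units
        self.weights = {}
        for direction in ("fwd", "bwd"):
            for gate in ("z", "r", "h"):
                self.weights[f"W{gate}_{direction}"] = _glorot(
                    rng, in_dim, units, (in_dim, units)
                )
                self.weights[f"U{gate}_{direction}"] = _glorot(
                    rng, units, units, (units, units)
                )
                self.weights[f"b{gate}_{direction}"] = Tensor(
                    np.zeros(units), requires_grad=True
                )

    @property
    def params(self):
        return list(self.weights.values())

    def _run(self, x: Tensor, direction: str) -> Tensor:
        w = self.weights
        batch, length, _ = x.shape
        h = Tensor(np.zeros((batch, self.units)))
        steps = range(length) if direction == "fwd" else range(length - 1, -1, -1)
        for t in steps:
            xt = x.timestep(t)
            z = (xt @ w[f"Wz_{direction}"] + h @ w[f"Uz_{direction}"] + w[f"bz_{direction}"]).sigmoid()
            r = (xt @ w[f"Wr_{direction}"] + h @ w[f"Ur_{direction}"] + w[f"br_{direction}"]).sigmoid()
            cand = (xt @ w[f"Wh_{direction}"] + (r * h) @ w[f"Uh_{direction}"] + w[f"bh_{direction}"]).tanh()
            h = (1.0 - z) * h + z * cand
        return h

    def __call__(self, x: Tensor) -> Tensor:
        return self._run(x, "fwd").concat(self._run(x, "bwd"), axis=-1)


class SequenceClassifier:
    """One CNN/BiGRU/dense network parameterized by an architecture genome."""

    def __init__(self, genome, seed: int = 0):
        self.genome = genome
        self.rng = np.random.default_rng(seed)
        rng = np.random.default_rng(seed + 1)
        self.conv_weights = []
        self.conv_bn = []
        channels = N_CHANNELS
        for gene in genome.conv_layers:
            fan_in = gene.kernel_size * channels
            w = _glorot(rng, fan_in, gene.feature_maps, (fan_in, gene.feature_maps))
            b = Tensor(np.zeros(gene.feature_maps), requires_grad=True)
            self.conv_weights.append((w, b))
            self.conv_bn.append(
                _BatchNorm(gene.feature_maps) if gene.batch_norm else None
            )
            channels = gene.feature_maps
        self.gru = _BiGRU(rng, channels, genome.gru_units)
        dim = 2 * genome.gru_units
        self.dense_weights = []
        self.dense_bn = []
        for gene in genome.dense_layers:
            w = _glorot(rng, dim, gene.units, (dim, gene.units))
            b = Tensor(np.zeros(gene.units), requires_grad=True)
            self.dense_weights.append((w, b))
            self.dense_bn.append(_BatchNorm(gene.units) if gene.batch_norm else None)
            dim = gene.units
        self.out_w = _glorot(rng, dim, 1, (dim, 1))
        self.out_b = Tensor(np.zeros(1), requires_grad=True)

    @property
    def params(self):
        out = [self.out_w, self.out_b]
        for w, b in self.conv_weights + self.dense_weights:
            out += [w, b]
        for bn in self.conv_bn + self.dense_bn:
            if bn is not None:
                out += bn.params
        return out + self.gru.params

    def _dropout(self, x: Tensor, rate: float, training: bool) -> Tensor:
        if not training or rate <= 0.0:
            return x
        mask = (self.rng.random(x.shape) >= rate) / (1.0 - rate)
        return x * mask.astype(np.float32)

    def forward(self, encoded: np.ndarray, training: bool = False) -> Tensor:
        """Probability of modification for a batch of (B, n, 22) windows."""
        x = Tensor(encoded)
        for gene, (w, b), bn in zip(
            self.genome.conv_layers, self.conv_weights, self.conv_bn
        ):
            x = unfold_same(x, gene.kernel_size) @ w + b
            if bn is not None:
                x = bn(x, training)
            x = _activate(x, gene.activation)
            if gene.max_pool:
                x = max_pool1d(x, 2)
            x = self._dropout(x, gene.dropout, training)
        x = self.gru(x)
        for gene, (w, b), bn in zip(
            self.genome.dense_layers, self.dense_weights, self.dense_bn
        ):
            x = x @ w + b
            if bn is not None:
                x = bn(x, training)
            x = _activate(x, gene.activation)
            x = self._dropout(x, gene.dropout, training)
        return (x @ self.out_w + self.out_b).sigmoid()

    def predict_proba(self, peptides, batch_size: int = 256) -> np.ndarray:
        """Scores in [0,1] for an iterable of equal-length peptides."""
        peptides = list(peptides)
        out = np.empty(len(peptides), dtype=np.float32)
        for start in range(0, len(peptides), batch_size):
            batch = encode_batch(peptides[start : start + batch_size])
            out[start : start + batch.shape[0]] = self.forward(batch).data.reshape(-1)
        return out

    def predict_encoded(self, encoded: np.ndarray) -> np.ndarray:
        return self.forward(encoded).data.reshape(-1)

    def get_weights(self) -> list[np.ndarray]:
        state = [p.data.copy() for p in self.params]
        for bn in self.conv_bn + self.dense_bn:
            if bn is not None:
                state += [bn.run_mean.copy(), bn.run_var.copy()]
        return state

    def set_weights(self, state) -> None:
        params = self.params
        for p, s in zip(params, state[: len(params)]):
            p.data = s.copy()
        extra = state[len(params) :]
        i = 0
        for bn in self.conv_bn + self.dense_bn:
            if bn is not None:
                bn.run_mean, bn.run_var = extra[i].copy(), extra[i + 1].copy()
                i += 2


class _Optimizer:
    def __init__(self, params, kind: str, lr: float | None = None):
        self.params = params
        self.kind = kind
        defaults = {"adam": 5e-3, "rmsprop": 2e-3, "sgd": 1e-1}
        if kind not in defaults:
            raise ValueError(f"unknown optimizer {kind!r}")
        self.lr = defaults[kind] if lr is None else lr
        self.state = [
            {"m": np.zeros_like(p.data), "v": np.zeros_like(p.data)} for p in params
        ]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for p, s in zip(self.params, self.state):
            if p.grad is None:
                continue
            g = p.grad
            if self.kind == "sgd":
                s["m"] = 0.9 * s["m"] + g
                p.data -= self.lr * s["m"]
            elif self.kind == "rmsprop":
                s["v"] = 0.9 * s["v"] + 0.1 * g * g
                p.data -= self.lr * g / (np.sqrt(s["v"]) + 1e-7)
            else:  # adam
                s["m"] = 0.9 * s["m"] + 0.1 * g
                s["v"] = 0.999 * s["v"] + 0.001 * g * g
                mhat = s["m"] / (1 - 0.9**self.t)
                vhat = s["v"] / (1 - 0.999**self.t)
                p.data -= self.lr * mhat / (np.sqrt(vhat) + 1e-8)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def train_classifier(
    model: SequenceClassifier,
    train_x: np.ndarray,
    train_y: np.ndarray,
    val_x: np.ndarray,
    val_y: np.ndarray,
    *,
    max_epochs: int = 100,
    batch_size: int = 64,
    patience: int = 5,
    seed: int = 0,
) -> dict:
    """Fit with early stopping; restores the best-validation-accuracy weights.

    Returns a history dict with per-epoch train loss and validation
    accuracy plus the best epoch index.
    """
    if train_x.shape[0] == 0 or val_x.shape[0] == 0:
        raise ValueError("training and validation splits must be non-empty")
    rng = np.random.default_rng(seed)
    opt = _Optimizer(model.params, model.genome.optimizer)
    best_acc, best_state, best_epoch, since_best = -1.0, None, -1, 0
    history = {"train_loss": [], "val_accuracy": []}
    for epoch in range(max_epochs):
        order = rng.permutation(train_x.shape[0])
        losses = []
        for start in range(0, len(order), batch_size):
            idx = order[start : start + batch_size]
            opt.zero_grad()
            prob = model.forward(train_x[idx], training=True)
            loss = binary_cross_entropy(prob, train_y[idx])
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch} for genome {model.genome}"
                )
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        val_prob = model.predict_encoded(val_x)
        val_acc = float(np.mean((val_prob >= 0.5) == (val_y >= 0.5)))
        history["train_loss"].append(float(np.mean(losses)))
        history["val_accuracy"].append(val_acc)
        if val_acc > best_acc:
            best_acc, best_state, best_epoch = val_acc, model.get_weights(), epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= patience:
                break
    model.set_weights(best_state)
    history["best_epoch"] = best_epoch
    history["best_val_accuracy"] = best_acc
    return history
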