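"""Residual multi-branch pixel classifier, implemented directly in NumPy.

The network maps a single pixel's 10 channel intensities x to a Multinoulli
distribution over m barcode classes plus blank:

    P(x in C_i; theta) = softmax(y)_i ,  y = f_theta(x)

f_theta is a fully connected architecture built from residual blocks:
a stem projection input_dim -> width, then `branch_count` parallel branches
(cardinality) whose outputs are summed, each branch a stack of residual
blocks (three dense width x width layers, each followed by batch
normalization and ReLU, with an identity skip summed at the block output),
then optional post-merge dense layers and a final dense layer to the class
logits.  All forward and backward passes are explicit, which keeps the
parameterization transparent and lets inference-time objectives (entropy of
the output) be differentiated with respect to the *input* as well.

Training minimizes the mean negative log-likelihood of the target classes
(equivalently the cross-entropy), see :func:`nll_loss`.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np

_F = np.float32


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters.

    The reference configuration (width 128, 4 branches, 3 residual blocks
    per branch, one post-merge layer, batch norm, 16 classes) has 624,144
    trainable parameters.  A fully degenerate configuration (no blocks, no
    post-merge layers, no normalization) collapses to a single dense
    input -> classes softmax layer.
    """

    input_dim: int = 10
    n_classes: int = 16
    branch_count: int = 4
    blocks_per_branch: int = 3
    width: int = 128
    batch_norm: bool = True
    post_merge_layers: int = 1

    def __post_init__(self) -> None:
        if self.branch_count < 1:
            raise ValueError("branch_count must be >= 1")
        if self.width < 1:
            raise ValueError("width must be >= 1")
        if self.input_dim < 1 or self.n_classes < 2:
            raise ValueError("need input_dim >= 1 and n_classes >= 2")
        if self.blocks_per_branch < 0 or self.post_merge_layers < 0:
            raise ValueError("layer counts must be >= 0")

    @property
    def has_hidden(self) -> bool:
        return self.blocks_per_branch > 0 or self.post_merge_layers > 0

    def param_count(self) -> int:
        """Closed-form trainable parameter count for this configuration."""
        bn = 2 * self.width if self.batch_norm else 0
        dense_hidden = self.width * self.width + self.width + bn
        if not self.has_hidden:
            return self.input_dim * self.n_classes + self.n_classes
        stem = self.input_dim * self.width + self.width + bn
        blocks = self.branch_count * self.blocks_per_branch * 3 * dense_hidden
        post = self.post_merge_layers * dense_hidden
        head = self.width * self.n_classes + self.n_classes
        return stem + blocks + post + head


# ---------------------------------------------------------------------------
# layers

class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        # He initialization, suited to ReLU units
        self.W = (rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / n_in)).astype(_F)
        self.b = np.zeros(n_out, dtype=_F)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool, cache) -> np.ndarray:
        if cache is True:  # "light" caching keeps only what input-gradients need
            self._x = x
        return x @ self.W + self.b

    def backward(self, g: np.ndarray, param_grads: bool = True) -> np.ndarray:
        if param_grads:
            # write gradients in place: the optimizer holds references
            self.gW[...] = self._x.T @ g
            self.gb[...] = g.sum(axis=0)
        return g @ self.W.T

    def clear_cache(self) -> None:
        self._x = None

    # (param, grad, decay?) triples; weight decay applies to W only
    def params(self):
        return [(self.W, self.gW, True), (self.b, self.gb, False)]


class _BatchNorm:
    def __init__(self, n: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(n, dtype=_F)
        self.beta = np.zeros(n, dtype=_F)
        self.ggamma = np.zeros_like(self.gamma)
        self.gbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(n, dtype=_F)
        self.running_var = np.ones(n, dtype=_F)
        self.momentum = momentum
        self.eps = eps
        self._cache = None
        self._train_mode = False
        self._accum = None  # (sum_mean, sum_var, count) during stats refresh

    def forward(self, x: np.ndarray, train: bool, cache: bool) -> np.ndarray:
        self._train_mode = train
        if train:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean).astype(_F)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var).astype(_F)
            inv = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean) * inv
            if cache is True:
                self._cache = (xhat, inv.astype(_F))
            return self.gamma * xhat + self.beta
        inv = 1.0 / np.sqrt(self.running_var + self.eps)
        return self.gamma * (x - self.running_mean) * inv + self.beta

    def backward(self, g: np.ndarray, param_grads: bool = True) -> np.ndarray:
        if self._train_mode:
            xhat, inv = self._cache
            n = g.shape[0]
            self.ggamma[...] = (g * xhat).sum(axis=0)
            self.gbeta[...] = g.sum(axis=0)
            gx = (self.gamma * inv / n) * (
                n * g - self.gbeta - xhat * self.ggamma
            )
            return gx.astype(_F)
        # eval-mode backward: statistics frozen, the map is per-sample affine
        # (used for input-gradient objectives at inference)
        if param_grads:
            self.ggamma[...] = 0
            self.gbeta[...] = 0
        inv = 1.0 / np.sqrt(self.running_var + self.eps)
        return (g * self.gamma * inv).astype(_F)

    def clear_cache(self) -> None:
        self._cache = None

    def begin_accumulate(self) -> None:
        self._accum = (np.zeros_like(self.running_mean, dtype=np.float64),
                       np.zeros_like(self.running_var, dtype=np.float64), 0)

    def end_accumulate(self) -> None:
        s_mean, s_var, count = self._accum
        if count:
            self.running_mean = (s_mean / count).astype(_F)
            self.running_var = (s_var / count).astype(_F)
        self._accum = None

    def params(self):
        return [(self.gamma, self.ggamma, False), (self.beta, self.gbeta, False)]


class _ReLU:
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray, train: bool, cache: bool) -> np.ndarray:
        mask = x > 0
        if cache:
            self._mask = mask
        return np.where(mask, x, 0)

    def backward(self, g: np.ndarray, param_grads: bool = True) -> np.ndarray:
        return np.where(self._mask, g, 0)

    def params(self):
        return []


class _Chain:
    def __init__(self, layers):
        self.layers = list(layers)

    def forward(self, x, train, cache):
        for layer in self.layers:
            x = layer.forward(x, train, cache)
        return x

    def backward(self, g, param_grads=True):
        for layer in reversed(self.layers):
            g = layer.backward(g, param_grads)
        return g

    def params(self):
        return [p for layer in self.layers for p in layer.params()]


class _ResidualBlock:
    """Three dense(+BN)+ReLU layers bypassed by an identity skip."""

    def __init__(self, width: int, batch_norm: bool, rng: np.random.Generator):
        layers = []
        for _ in range(3):
            layers.append(_Dense(width, width, rng))
            if batch_norm:
                layers.append(_BatchNorm(width))
            layers.append(_ReLU())
        self.body = _Chain(layers)

    def forward(self, x, train, cache):
        return x + self.body.forward(x, train, cache)

    def backward(self, g, param_grads=True):
        return g + self.body.backward(g, param_grads)

    def params(self):
        return self.body.params()


def _hidden_unit(n_in, width, batch_norm, rng):
    layers = [_Dense(n_in, width, rng)]
    if batch_norm:
        layers.append(_BatchNorm(width))
    layers.append(_ReLU())
    return layers


class ResidualClassifier:
    """The pixel classifier; see the module docstring for the architecture."""

    def __init__(self, config: NetworkConfig, seed: int = 0,
                 class_names: Sequence[str] | None = None):
        self.config = config
        self.seed = seed
        if class_names is None:
            class_names = ["blank"] + [f"class{i}" for i in range(1, config.n_classes)]
        if len(class_names) != config.n_classes:
            raise ValueError("class registry size must equal n_classes")
        self.class_names = list(class_names)
        rng = np.random.default_rng(seed)

        if config.has_hidden:
            self.stem = _Chain(_hidden_unit(config.input_dim, config.width,
                                            config.batch_norm, rng))
            self.branches = [
                _Chain([_ResidualBlock(config.width, config.batch_norm, rng)
                        for _ in range(config.blocks_per_branch)])
                for _ in range(config.branch_count)
            ]
            post = []
            for _ in range(config.post_merge_layers):
                post.extend(_hidden_unit(config.width, config.width, config.batch_norm, rng))
            self.post = _Chain(post)
            self.head = _Dense(config.width, config.n_classes, rng)
        else:
            self.stem = None
            self.branches = []
            self.post = _Chain([])
            self.head = _Dense(config.input_dim, config.n_classes, rng)

    # -- forward / backward -------------------------------------------------
    def forward_logits(self, x: np.ndarray, train: bool = False,
                       cache=None) -> np.ndarray:
        """Pre-softmax outputs.  ``cache`` keeps the activations needed by
        :meth:`backward`; it defaults to ``train``.  The value ``"light"``
        keeps only what input-gradient backpropagation needs (ReLU masks),
        for inference-time objectives with the model frozen."""
        if cache is None:
            cache = train
        x = np.ascontiguousarray(x, dtype=_F)
        if x.ndim != 2 or x.shape[1] != self.config.input_dim:
            raise ValueError(
                f"expected (batch, {self.config.input_dim}) input, got {x.shape}"
            )
        if self.stem is not None:
            h = self.stem.forward(x, train, cache)
            merged = None
            for branch in self.branches:
                out = branch.forward(h, train, cache)
                merged = out if merged is None else merged + out
            h = self.post.forward(merged, train, cache)
            return self.head.forward(h, train, cache)
        return self.head.forward(x, train, cache)

    def backward(self, g_logits: np.ndarray, param_grads: bool = True) -> np.ndarray:
        """Backpropagate a logit gradient; returns the input gradient.

        ``param_grads=False`` skips accumulating parameter gradients, for
        objectives that only need the gradient with respect to the input
        (e.g. inference-time contrast adaptation with the model frozen).
        """
        g = self.head.backward(g_logits, param_grads)
        if self.stem is None:
            return g
        g = self.post.backward(g, param_grads)
        gh = None
        for branch in self.branches:
            gb = branch.backward(g, param_grads)
            gh = gb if gh is None else gh + gb
        return self.stem.backward(gh, param_grads)

    def predict_proba(self, x: np.ndarray, train: bool = False,
                      cache=None) -> np.ndarray:
        return softmax(self.forward_logits(x, train, cache))

    def refresh_norm_statistics(self, features: np.ndarray,
                                batch_size: int = 2048,
                                max_samples: int = 16384,
                                seed: int = 0) -> None:
        """Recalibrate batch-norm running statistics on clean data.

        Running averages tracked during training reflect *augmented*
        batches; with stochastic contrast augmentation their variance is
        inflated relative to clean inputs, and the mismatch compounds
        through stacked normalization layers, degrading inference-mode
        accuracy.  This pass replaces the running statistics with the mean
        of per-batch statistics of (a subsample of) unaugmented training
        features, the population-statistics estimate of the original batch
        normalization procedure.
        """
        bns = [layer for layer in self._all_layers() if isinstance(layer, _BatchNorm)]
        if not bns:
            return
        features = np.asarray(features, dtype=_F)
        if len(features) > max_samples:
            idx = np.random.default_rng(seed).choice(len(features), max_samples,
                                                     replace=False)
            features = features[idx]
        for bn in bns:
            bn.begin_accumulate()
        for i in range(0, len(features), batch_size):
            batch = features[i : i + batch_size]
            if len(batch) >= 2:
                self.forward_logits(batch, train=True, cache=False)
        for bn in bns:
            bn.end_accumulate()

    def _all_layers(self):
        for c in self._components():
            layers = c.layers if isinstance(c, _Chain) else [c]
            yield from _iter_layers(layers)

    # -- bookkeeping --------------------------------------------------------
    def _components(self):
        comps = []
        if self.stem is not None:
            comps.append(self.stem)
            comps.extend(self.branches)
            comps.append(self.post)
        comps.append(self.head)
        return comps

    def params(self):
        return [p for c in self._components() for p in c.params()]

    def param_count(self) -> int:
        return int(sum(p.size for p, _, _ in self.params()))

    def state_arrays(self) -> list[np.ndarray]:
        """All trainable parameters plus normalization running statistics."""
        arrays = [p for p, _, _ in self.params()]
        for layer in self._all_layers():
            if isinstance(layer, _BatchNorm):
                arrays.extend([layer.running_mean, layer.running_var])
        return arrays

    def get_state(self) -> list[np.ndarray]:
        return [a.copy() for a in self.state_arrays()]

    def set_state(self, state: list[np.ndarray]) -> None:
        for dst, src in zip(self.state_arrays(), state, strict=True):
            dst[...] = src

    # -- persistence --------------------------------------------------------
    def save(self, path, metadata: dict | None = None) -> None:
        arrays = {f"arr_{i}": a for i, a in enumerate(self.state_arrays())}
        header = {
            "schema": 1,
            "config": asdict(self.config),
            "seed": self.seed,
            "class_names": self.class_names,
            "metadata": metadata or {},
        }
        np.savez(path, __header__=np.frombuffer(
            json.dumps(header).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "ResidualClassifier":
        data = np.load(path)
        header = json.loads(bytes(data["__header__"]).decode())
        model = cls(NetworkConfig(**header["config"]), seed=header["seed"],
                    class_names=header["class_names"])
        state = [data[f"arr_{i}"] for i in range(len(data.files) - 1)]
        model.set_state(state)
        return model


def _iter_layers(layers):
    for layer in layers:
        if isinstance(layer, _ResidualBlock):
            yield from layer.body.layers
        else:
            yield layer


# ---------------------------------------------------------------------------
# functional surface

def build_classifier(config: NetworkConfig, seed: int = 0,
                     class_names: Sequence[str] | None = None) -> ResidualClassifier:
    """Construct a classifier with deterministically initialized parameters."""
    return ResidualClassifier(config, seed=seed, class_names=class_names)


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax, numerically stabilized by max subtraction."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def forward(model: ResidualClassifier, pixels: np.ndarray) -> np.ndarray:
    """Class probabilities for a batch of pixel vectors (inference mode)."""
    return model.predict_proba(np.atleast_2d(pixels), train=False)


def nll_loss(probs: np.ndarray, targets: np.ndarray) -> float:
    """Mean negative log probability assigned to each sample's target class."""
    probs = np.atleast_2d(probs)
    targets = np.asarray(targets, dtype=np.int64)
    if targets.ndim != 1 or len(targets) != len(probs):
        raise ValueError("targets must be one class index per sample")
    if len(targets) < 1:
        raise ValueError("batch must be non-empty")
    if targets.min() < 0 or targets.max() >= probs.shape[1]:
        raise ValueError("target class index out of range")
    p = probs[np.arange(len(targets)), targets]
    return float(-np.log(np.clip(p, 1e-12, None)).mean())


class AdamW:
    """Adam with decoupled weight decay; decay applies to weight matrices only."""

    def __init__(self, params, lr: float = 5e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 1e-2):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p) for p, _, _ in self.params]
        self.v = [np.zeros_like(p) for p, _, _ in self.params]

    def step(self) -> None:
        self.t += 1
        bc1 = 1 - self.b1**self.t
        bc2 = 1 - self.b2**self.t
        for (p, g, decay), m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            if decay and self.weight_decay:
                update = update + self.weight_decay * p
            p -= (self.lr * update).astype(p.dtype)
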