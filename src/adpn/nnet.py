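"""A compact 3D convolutional network engine in pure numpy.

The classifier at the heart of the pipeline is a small, depth-configurable 3D
residual network (stem convolution, residual stages with average-pool
downsampling, global average pooling, linear head).  Saliency analysis needs
the gradient of a class score with respect to the final convolutional layer's
activations, so every layer implements an explicit backward pass; gradients
are exact and, because everything is plain numpy, training is bit-reproducible
given the seed.

Convolutions use a shift-and-GEMM scheme: the padded input is sliced at each
of the k^3 kernel offsets and contracted against the corresponding weight
slice, which keeps all heavy lifting inside BLAS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["NetworkSpec", "CNN3D", "build_model", "Adam", "softmax", "cross_entropy"]


class Layer:
    """Base layer: ``forward`` caches what ``backward`` needs."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params, self.grads = [], []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError


class Conv3d(Layer):
    """3x3x3 (configurable) same-padding, stride-1 3D convolution."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.k = k
        fan_in = c_in * k ** 3
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, k, k, k))
        self.b = np.zeros(c_out)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, p = self.k, self.k // 2
        n, ci, d, h, w = x.shape
        self._xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
        self._shape = (n, ci, d, h, w)
        co = self.w.shape[0]
        y = np.zeros((n, co, d * h * w))
        for a in range(k):
            for b in range(k):
                for c in range(k):
                    patch = self._xp[:, :, a:a + d, b:b + h, c:c + w].reshape(n, ci, -1)
                    y += np.einsum("oi,niv->nov", self.w[:, :, a, b, c], patch, optimize=True)
        y = y.reshape(n, co, d, h, w)
        return y + self.b[None, :, None, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        k = self.k
        n, ci, d, h, w = self._shape
        dyf = dy.reshape(dy.shape[0], dy.shape[1], -1)
        dxp = np.zeros_like(self._xp)
        dw = self.grads[0]
        for a in range(k):
            for b in range(k):
                for c in range(k):
                    patch = self._xp[:, :, a:a + d, b:b + h, c:c + w].reshape(n, ci, -1)
                    dw[:, :, a, b, c] += np.einsum("nov,niv->oi", dyf, patch, optimize=True)
                    dpatch = np.einsum("oi,nov->niv", self.w[:, :, a, b, c], dyf, optimize=True)
                    dxp[:, :, a:a + d, b:b + h, c:c + w] += dpatch.reshape(n, ci, d, h, w)
        self.grads[1] += dyf.sum(axis=(0, 2))
        p = k // 2
        return dxp[:, :, p:p + d, p:p + h, p:p + w]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class AvgPool3d(Layer):
    """Non-overlapping 2x2x2 average pooling; dims must be even."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, d, h, w = x.shape
        if d % 2 or h % 2 or w % 2:
            raise ValueError(f"spatial dims must be even for 2x pooling, got {(d, h, w)}")
        self._shape = x.shape
        return x.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2).mean(axis=(3, 5, 7))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, d, h, w = self._shape
        up = np.repeat(np.repeat(np.repeat(dy, 2, axis=2), 2, axis=3), 2, axis=4)
        return up / 8.0


class GlobalAvgPool(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3, 4))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, d, h, w = self._shape
        return np.broadcast_to(dy[:, :, None, None, None], self._shape) / (d * h * w)


class Linear(Layer):
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.w = rng.normal(0.0, np.sqrt(2.0 / c_in), size=(c_out, c_in))
        self.b = np.zeros(c_out)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w.T + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads[0] += dy.T @ self._x
        self.grads[1] += dy.sum(axis=0)
        return dy @ self.w


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class ResidualBlock(Layer):
    """y = relu(x + conv2(relu(conv1(x)))), constant channel width."""

    def __init__(self, channels: int, k: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.conv1 = Conv3d(channels, channels, k, rng)
        self.relu1 = ReLU()
        self.conv2 = Conv3d(channels, channels, k, rng)
        self.relu_out = ReLU()
        self.params = self.conv1.params + self.conv2.params
        self.grads = self.conv1.grads + self.conv2.grads

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = self.relu1.forward(self.conv1.forward(x))
        return self.relu_out.forward(x + self.conv2.forward(h))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        d = self.relu_out.backward(dy)
        dh = self.conv2.backward(d)
        dx = self.conv1.backward(self.relu1.backward(dh))
        return dx + d


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture description for :func:`build_model`.

    ``n_stages`` residual stages follow the stem; the stem and every stage but
    the last end in 2x average pooling, so each input dimension must be
    divisible by ``2**n_stages``.  The last stage's output is the "final
    convolutional layer" used for class-activation mapping.

    ``head`` selects the readout.  ``"flatten"`` (default) applies a linear
    layer to the spatially resolved final activations: on synthetic anatomy
    with no locally identifying texture, a translation-invariant conv stack
    cannot tell one parcel from another, so the readout itself must be allowed
    location sensitivity for the classification signal to be learnable at
    desk scale.  ``"gap"`` gives the classical global-average-pool head.

    ``kernel`` sizes the stem convolution; ``block_kernel`` sizes the residual
    blocks' convolutions and defaults to 1 (bottleneck-style channel mixing).
    The small block kernel keeps the final activations' receptive field tight,
    which keeps class-activation maps spatially crisp at parcel scale; set it
    to 3 for a wider-context variant.
    """

    input_shape: tuple[int, int, int]
    n_stages: int = 1
    blocks_per_stage: int = 1
    base_channels: int = 8
    n_classes: int = 2
    kernel: int = 3
    block_kernel: int = 1
    head: str = "flatten"

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.n_stages < 1 or self.blocks_per_stage < 1:
            raise ValueError("n_stages and blocks_per_stage must be >= 1")
        if self.head not in ("flatten", "gap"):
            raise ValueError("head must be 'flatten' or 'gap'")
        div = 2 ** self.n_stages
        if any(s % div for s in self.input_shape):
            raise ValueError(f"input_shape {self.input_shape} not divisible by {div}")


class CNN3D:
    """Sequential 3D CNN with an identified final-convolution tap point."""

    def __init__(self, layers: list[Layer], final_conv_index: int, spec: NetworkSpec) -> None:
        self.layers = layers
        self.final_conv_index = final_conv_index
        self.spec = spec

    # -- parameter plumbing -------------------------------------------------
    @property
    def params(self) -> list[np.ndarray]:
        return [p for l in self.layers for p in l.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for l in self.layers for g in l.grads]

    def zero_grad(self) -> None:
        for g in self.grads:
            g[...] = 0.0

    # -- passes -------------------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (N, 1, D, H, W) -> logits (N, n_classes)."""
        for i, layer in enumerate(self.layers):
            x = layer.forward(x)
            if i == self.final_conv_index:
                self._final_acts = x
        return x

    def backward(self, dlogits: np.ndarray, to_layer: int = 0) -> np.ndarray:
        """Backpropagate from the logits; returns the gradient arriving at the
        *output* of layer ``to_layer - 1`` (i.e. the input of ``to_layer``)."""
        g = dlogits
        for layer in reversed(self.layers[to_layer:]):
            g = layer.backward(g)
        return g

    def forward_from(self, layer_index: int, activations: np.ndarray) -> np.ndarray:
        """Run the tail of the network starting at ``layer_index`` on given
        activations (used by finite-difference checks of saliency weights)."""
        x = activations
        for layer in self.layers[layer_index:]:
            x = layer.forward(x)
        return x

    def final_conv_activations_and_grad(self, x: np.ndarray, target_class: int
                                        ) -> tuple[np.ndarray, np.ndarray]:
        """Activations A of the final convolutional layer and dScore_c/dA,
        where Score_c is the (pre-softmax) logit of ``target_class``."""
        logits = self.forward(x)
        dlogits = np.zeros_like(logits)
        dlogits[:, target_class] = 1.0
        tap = self.final_conv_index
        grad = self.backward(dlogits, to_layer=tap + 1)
        return self._final_acts, grad


def build_model(spec: NetworkSpec, seed: int) -> CNN3D:
    """Instantiate the residual classifier with Kaiming-style random init."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC44]))
    c, k = spec.base_channels, spec.kernel
    layers: list[Layer] = [Conv3d(1, c, k, rng), ReLU(), AvgPool3d()]
    for stage in range(spec.n_stages):
        for _ in range(spec.blocks_per_stage):
            layers.append(ResidualBlock(c, spec.block_kernel, rng))
        if stage < spec.n_stages - 1:
            layers.append(AvgPool3d())
    final_conv_index = len(layers) - 1
    if spec.head == "gap":
        layers += [GlobalAvgPool(), Linear(c, spec.n_classes, rng)]
    else:
        grid = tuple(s // 2 ** spec.n_stages for s in spec.input_shape)
        lin = Linear(c * int(np.prod(grid)), spec.n_classes, rng)
        lin.w *= 0.05  # small head init: start near the uninformative solution
        layers += [Flatten(), lin]
    return CNN3D(layers, final_conv_index, spec)


# ---------------------------------------------------------------------------
# Loss and optimizer


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = len(labels)
    loss = -np.log(np.clip(p[np.arange(n), labels], 1e-12, None)).mean()
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return float(loss), dlogits / n


class Adam:
    """Standard Adam over a flat parameter list (in-place updates)."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0) -> None:
        self.params = params
        self.lr, self.betas, self.eps, self.wd = lr, betas, eps, weight_decay
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.betas
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            if self.wd:
                g = g + self.wd * p
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
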