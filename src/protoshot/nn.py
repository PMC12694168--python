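"""Minimal neural-network layer library (numpy, CPU).

Implements exactly the pieces the embedding backbone needs -- 3x3
convolution, batch normalization, ReLU, 2x2 max-pooling, global average
pooling, a linear projection -- each with a hand-written backward pass,
plus an Adam optimizer. Forward passes cache what backward needs; a full
model forward/backward operates on (N, C, H, W) batches.

Keeping the autodiff surface this small is deliberate: every gradient is
verified against finite differences in the test suite, and the explicit
backward chain is what makes Grad-CAM (gradient at an internal
convolutional feature map) a one-liner.
"""

from __future__ import annotations

import numpy as np


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = value
        self.grad = np.zeros_like(value)
        self.name = name


class Conv3x3:
    """3x3 convolution, stride 1, zero padding 1 (shape-preserving)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 dtype=np.float32) -> None:
        std = np.sqrt(2.0 / (cin * 9))
        self.W = Param(rng.normal(0, std, (cout, cin * 9)).astype(dtype), "conv.W")
        self.b = Param(np.zeros(cout, dtype=dtype), "conv.b")
        self.cin, self.cout = cin, cout

    @staticmethod
    def _im2col(x: np.ndarray) -> np.ndarray:
        # x (N, C, H, W) -> patches (N, H, W, C*9)
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))
        return win.transpose(0, 2, 3, 1, 4, 5).reshape(n, h, w, c * 9)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._patches = self._im2col(x)
        out = self._patches @ self.W.value.T + self.b.value
        return out.transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray, need_input_grad: bool = True) -> np.ndarray | None:
        n, co, h, w = dout.shape
        d = dout.transpose(0, 2, 3, 1).reshape(-1, co)
        self.W.grad += d.T @ self._patches.reshape(-1, self.cin * 9)
        self.b.grad += d.sum(axis=0)
        if not need_input_grad:  # first layer: skip the most expensive im2col
            return None
        # input gradient = convolution of dout with spatially flipped kernels
        w4 = self.W.value.reshape(co, self.cin, 3, 3)
        w_flip = w4[:, :, ::-1, ::-1].transpose(1, 0, 2, 3).reshape(self.cin, co * 9)
        dpatches = self._im2col(dout)
        dx = dpatches @ w_flip.T
        return dx.transpose(0, 3, 1, 2)

    def params(self) -> list[Param]:
        return [self.W, self.b]


class BatchNorm2d:
    def __init__(self, c: int, dtype=np.float32, momentum: float = 0.1,
                 eps: float = 1e-5) -> None:
        self.gamma = Param(np.ones(c, dtype=dtype), "bn.gamma")
        self.beta = Param(np.zeros(c, dtype=dtype), "bn.beta")
        self.running_mean = np.zeros(c, dtype=dtype)
        self.running_var = np.ones(c, dtype=dtype)
        self.momentum, self.eps = momentum, eps

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        self._train = train
        self._invstd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean[:, None, None]) * self._invstd[:, None, None]
        return self.gamma.value[:, None, None] * self._xhat + self.beta.value[:, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, invstd = self._xhat, self._invstd
        self.gamma.grad += (dout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.gamma.value[:, None, None]
        if not self._train:
            return dxhat * invstd[:, None, None]
        n = dout.shape[0] * dout.shape[2] * dout.shape[3]
        s1 = dxhat.sum(axis=(0, 2, 3))[:, None, None]
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3))[:, None, None]
        return (invstd[:, None, None] / n) * (n * dxhat - s1 - xhat * s2)

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]


class ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask

    def params(self) -> list[Param]:
        return []


class MaxPool2x2:
    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"MaxPool2x2 needs even spatial dims, got {h}x{w}")
        xv = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xv = np.ascontiguousarray(xv).reshape(n, c, h // 2, w // 2, 4)
        self._argmax = xv.argmax(axis=-1)  # ties -> first element of the window
        self._shape = (n, c, h, w)
        return np.take_along_axis(xv, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        d = np.zeros((n, c, h // 2, w // 2, 4), dtype=dout.dtype)
        np.put_along_axis(d, self._argmax[..., None], dout[..., None], axis=-1)
        d = d.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return np.ascontiguousarray(d).reshape(n, c, h, w)

    def params(self) -> list[Param]:
        return []


class GlobalAvgPool:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(dout[:, :, None, None], self._shape) / (h * w)

    def params(self) -> list[Param]:
        return []


class Linear:
    def __init__(self, nin: int, nout: int, rng: np.random.Generator,
                 dtype=np.float32) -> None:
        std = np.sqrt(1.0 / nin)
        self.W = Param(rng.normal(0, std, (nout, nin)).astype(dtype), "linear.W")
        self.b = Param(np.zeros(nout, dtype=dtype), "linear.b")

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value.T + self.b.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.W.grad += dout.T @ self._x
        self.b.grad += dout.sum(axis=0)
        return dout @ self.W.value

    def params(self) -> list[Param]:
        return [self.W, self.b]


class SimpleCNNEmbed:
    """Shallow conv embedding network.

    ``n_blocks`` blocks of [3x3 conv -> batch norm -> ReLU -> 2x2 max-pool],
    then global average pooling and a linear projection to ``embed_dim``.
    Block ReLU outputs and their backward gradients are retained so saliency
    methods can read any block's feature maps.
    """

    def __init__(self, image_size: int, n_blocks: int = 3,
                 channels: tuple[int, ...] = (8, 16, 32), embed_dim: int = 64,
                 in_channels: int = 1, seed: int = 0, dtype=np.float32) -> None:
        if n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if embed_dim < 2:
            raise ValueError("embed_dim must be >= 2")
        if len(channels) != n_blocks:
            raise ValueError("channels must have one entry per block")
        if image_size % (2 ** n_blocks):
            raise ValueError(
                f"image_size {image_size} must be divisible by 2^{n_blocks}"
            )
        rng = np.random.default_rng(np.random.SeedSequence([seed, 29]))
        self.image_size = image_size
        self.in_channels = in_channels
        self.embed_dim = embed_dim
        self.dtype = dtype
        self.blocks = []
        cin = in_channels
        for c in channels:
            self.blocks.append(
                (Conv3x3(cin, c, rng, dtype), BatchNorm2d(c, dtype), ReLU(), MaxPool2x2())
            )
            cin = c
        self.gap = GlobalAvgPool()
        self.proj = Linear(cin, embed_dim, rng, dtype)

    # -- plumbing ----------------------------------------------------------
    def params(self) -> list[Param]:
        out: list[Param] = []
        for block in self.blocks:
            for layer in block:
                out.extend(layer.params())
        out.extend(self.proj.params())
        return out

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0

    # -- forward / backward ------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """x: (N, H, W) grayscale or (N, C, H, W). Returns (N, embed_dim)."""
        if x.ndim == 3:
            x = x[:, None, :, :]
        if x.shape[2] != self.image_size or x.shape[3] != self.image_size:
            raise ValueError(
                f"expected {self.image_size}x{self.image_size} input, "
                f"got {x.shape[2]}x{x.shape[3]}"
            )
        x = x.astype(self.dtype, copy=False)
        self.block_activations: list[np.ndarray] = []
        for conv, bn, relu, pool in self.blocks:
            x = relu.forward(bn.forward(conv.forward(x), train))
            self.block_activations.append(x)
            x = pool.forward(x)
        return self.proj.forward(self.gap.forward(x))

    def backward(self, dz: np.ndarray) -> None:
        """Backprop from embedding gradient; fills Param.grad and
        ``block_gradients`` (gradient at each block's ReLU output)."""
        d = self.gap.backward(self.proj.backward(dz.astype(self.dtype, copy=False)))
        self.block_gradients = [None] * len(self.blocks)
        for i in range(len(self.blocks) - 1, -1, -1):
            conv, bn, relu, pool = self.blocks[i]
            d = pool.backward(d)
            self.block_gradients[i] = d
            d = conv.backward(bn.backward(relu.backward(d)), need_input_grad=i > 0)

    # -- persistence -------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for i, (conv, bn, _, _) in enumerate(self.blocks):
            state[f"b{i}.conv.W"] = conv.W.value
            state[f"b{i}.conv.b"] = conv.b.value
            state[f"b{i}.bn.gamma"] = bn.gamma.value
            state[f"b{i}.bn.beta"] = bn.beta.value
            state[f"b{i}.bn.running_mean"] = bn.running_mean
            state[f"b{i}.bn.running_var"] = bn.running_var
        state["proj.W"] = self.proj.W.value
        state["proj.b"] = self.proj.b.value
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, (conv, bn, _, _) in enumerate(self.blocks):
            conv.W.value = state[f"b{i}.conv.W"].astype(self.dtype)
            conv.b.value = state[f"b{i}.conv.b"].astype(self.dtype)
            bn.gamma.value = state[f"b{i}.bn.gamma"].astype(self.dtype)
            bn.beta.value = state[f"b{i}.bn.beta"].astype(self.dtype)
            bn.running_mean = state[f"b{i}.bn.running_mean"].astype(self.dtype)
            bn.running_var = state[f"b{i}.bn.running_var"].astype(self.dtype)
        self.proj.W.value = state["proj.W"].astype(self.dtype)
        self.proj.b.value = state["proj.b"].astype(self.dtype)


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8) -> None:
        if lr <= 0:
            raise ValueError("learning rate must be > 0")
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * p.grad
            v[...] = b2 * v + (1 - b2) * p.grad ** 2
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.value = p.value - self.lr * mhat / (np.sqrt(vhat) + self.eps)
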