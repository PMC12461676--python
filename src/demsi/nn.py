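"""A small NumPy neural-network engine and the U-Net denoising architecture.

The denoiser is a classic U-Net: an encoder of 3x3 conv + ReLU blocks with
2x2 max-pooling (feature channels doubling each level), a bottleneck, and a
decoder that mirrors the encoder with bilinear 2x upsampling, halving the
channels, and copy-and-concatenate skip connections so high-resolution
detail survives the bottleneck.  A final 1x1 convolution maps back to one
channel with a linear output.

Everything here — convolution via im2col, max-pool argmax bookkeeping,
bilinear interpolation as an explicit linear operator, reverse-mode
gradients and the Adam optimiser — is implemented directly on NumPy arrays.
Gradients are exact (they are verified against numerical differentiation in
the test suite), and all computation is deterministic for a fixed seed.

Layout convention: batches are ``(B, C, H, W)`` float arrays.
"""

from __future__ import annotations

import numpy as np

__all__ = ["UNet", "Adam", "mae_loss", "mae_loss_grad"]


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Param:
    """A learnable tensor with its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class Conv2d:
    """3x3 (or 1x1) convolution, stride 1, zero padding to 'same' size."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 init_std: float = 0.02, dtype=np.float32):
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, kernel
        self.pad = kernel // 2
        w = rng.normal(0.0, init_std, size=(out_ch, in_ch * kernel * kernel))
        self.W = Param(w.astype(dtype))
        self.b = Param(np.zeros(out_ch, dtype=dtype))
        self._cols = None
        self._in_shape = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, H, Wd = x.shape
        k, p = self.k, self.pad
        if p:
            xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        else:
            xp = x
        sw = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        # (B, C, H, W, k, k) -> (B, C*k*k, H*W)
        cols = np.ascontiguousarray(sw.transpose(0, 1, 4, 5, 2, 3)).reshape(B, C * k * k, H * Wd)
        self._cols = cols
        self._in_shape = x.shape
        y = np.matmul(self.W.value, cols) + self.b.value[None, :, None]
        return y.reshape(B, self.out_ch, H, Wd)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, C, H, Wd = self._in_shape
        k, p = self.k, self.pad
        dyf = dy.reshape(B, self.out_ch, H * Wd)
        self.W.grad += np.einsum("bon,bcn->oc", dyf, self._cols)
        self.b.grad += dyf.sum(axis=(0, 2))
        dcols = np.matmul(self.W.value.T, dyf)  # (B, C*k*k, H*W)
        dcols = dcols.reshape(B, C, k, k, H, Wd)
        dxp = np.zeros((B, C, H + 2 * p, W_ := Wd + 2 * p), dtype=dy.dtype)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + H, j : j + Wd] += dcols[:, :, i, j]
        self._cols = None
        return dxp[:, :, p : p + H, p : p + Wd] if p else dxp


class ReLU:
    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        out = dy * self._mask
        self._mask = None
        return out


class MaxPool2x2:
    """2x2 max pooling; input spatial dims must be even."""

    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, H, W = x.shape
        r = x.reshape(B, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        r = r.reshape(B, C, H // 2, W // 2, 4)
        self._argmax = r.argmax(axis=-1)
        self._in_shape = x.shape
        return np.take_along_axis(r, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, C, H, W = self._in_shape
        r = np.zeros((B, C, H // 2, W // 2, 4), dtype=dy.dtype)
        np.put_along_axis(r, self._argmax[..., None], dy[..., None], axis=-1)
        out = r.reshape(B, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        self._argmax = None
        return out.reshape(B, C, H, W)


def _bilinear_matrix(n_in: int, dtype=np.float32) -> np.ndarray:
    """Linear operator for 2x bilinear upsampling along one axis
    (half-pixel alignment, edges clamped)."""
    n_out = 2 * n_in
    A = np.zeros((n_out, n_in), dtype=dtype)
    for i in range(n_out):
        src = (i + 0.5) / 2.0 - 0.5
        lo = int(np.floor(src))
        t = src - lo
        lo_c = min(max(lo, 0), n_in - 1)
        hi_c = min(max(lo + 1, 0), n_in - 1)
        A[i, lo_c] += 1.0 - t
        A[i, hi_c] += t
    return A


class BilinearUp2:
    """Deterministic 2x bilinear upsampling; backward is the exact adjoint."""

    _cache: dict[tuple[int, str], np.ndarray] = {}

    def params(self):
        return []

    def _mat(self, n: int, dtype) -> np.ndarray:
        key = (n, np.dtype(dtype).str)
        if key not in self._cache:
            self._cache[key] = _bilinear_matrix(n, dtype)
        return self._cache[key]

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, H, W = x.shape
        self._in_shape = x.shape
        Ar = self._mat(H, x.dtype)
        Ac = self._mat(W, x.dtype)
        return np.matmul(np.matmul(Ar, x), Ac.T)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, C, H, W = self._in_shape
        Ar = self._mat(H, dy.dtype)
        Ac = self._mat(W, dy.dtype)
        return np.matmul(np.matmul(Ar.T, dy), Ac)


class _ConvBlock:
    """(conv3x3 + ReLU) x n."""

    def __init__(self, in_ch: int, out_ch: int, n_convs: int, rng, init_std, dtype):
        self.layers = []
        c = in_ch
        for _ in range(n_convs):
            self.layers.append(Conv2d(c, out_ch, 3, rng, init_std, dtype))
            self.layers.append(ReLU())
            c = out_ch

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x):
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


# ---------------------------------------------------------------------------
# U-Net
# ---------------------------------------------------------------------------

class UNet:
    """Encoder-decoder with skip connections, single channel in and out.

    Parameters
    ----------
    base_channels : int
        Feature channels at the top level; doubled at each pooling
        (64 with depth 4 gives the 64 -> 1024 ladder).
    depth : int
        Number of 2x2 poolings; input spatial dims must be divisible by
        ``2 ** depth`` (the estimator wrapper pads and crops).
    n_convs : int
        conv3x3 + ReLU repetitions per block.
    init_std : float
        Weights are drawn from N(0, init_std); biases start at zero.
    """

    def __init__(
        self,
        base_channels: int = 64,
        depth: int = 4,
        n_convs: int = 2,
        init_std: float = 0.02,
        seed: int = 0,
        dtype=np.float32,
    ):
        self.base_channels = base_channels
        self.depth = depth
        self.n_convs = n_convs
        self.init_std = init_std
        self.seed = seed
        self.dtype = dtype
        rng = np.random.default_rng(seed)

        self.enc_blocks: list[_ConvBlock] = []
        self.pools: list[MaxPool2x2] = []
        ch = 1
        for d in range(depth):
            out = base_channels * (2**d)
            self.enc_blocks.append(_ConvBlock(ch, out, n_convs, rng, init_std, dtype))
            self.pools.append(MaxPool2x2())
            ch = out
        self.bottleneck = _ConvBlock(ch, base_channels * (2**depth), n_convs, rng, init_std, dtype)
        ch = base_channels * (2**depth)

        self.ups: list[BilinearUp2] = []
        self.dec_blocks: list[_ConvBlock] = []
        for d in reversed(range(depth)):
            skip_ch = base_channels * (2**d)
            self.ups.append(BilinearUp2())
            self.dec_blocks.append(
                _ConvBlock(ch + skip_ch, skip_ch, n_convs, rng, init_std, dtype)
            )
            ch = skip_ch
        self.head = Conv2d(ch, 1, 1, rng, init_std, dtype)

    # -- parameter plumbing -------------------------------------------------

    def params(self) -> list[Param]:
        out = []
        for b in self.enc_blocks:
            out += b.params()
        out += self.bottleneck.params()
        for b in self.dec_blocks:
            out += b.params()
        out += self.head.params()
        return out

    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.params())

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def get_weights(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        own = self.params()
        if len(own) != len(weights):
            raise ValueError("weight list does not match architecture")
        for p, w in zip(own, weights):
            if p.value.shape != w.shape:
                raise ValueError("weight shape mismatch")
            p.value[...] = w

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=self.dtype)
        if x.ndim != 4 or x.shape[1] != 1:
            raise ValueError("expected input of shape (B, 1, H, W)")
        H, W = x.shape[2], x.shape[3]
        f = 2**self.depth
        if H % f or W % f:
            raise ValueError(f"spatial dims must be divisible by {f}; pad first")
        skips = []
        for block, pool in zip(self.enc_blocks, self.pools):
            x = block.forward(x)
            skips.append(x)
            x = pool.forward(x)
        x = self.bottleneck.forward(x)
        self._skip_channels = []
        for up, block, skip in zip(self.ups, self.dec_blocks, reversed(skips)):
            x = up.forward(x)
            self._skip_channels.append((skip.shape[1], x.shape[1]))
            x = np.concatenate([skip, x], axis=1)
            x = block.forward(x)
        return self.head.forward(x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = np.ascontiguousarray(dy, dtype=self.dtype)
        dy = self.head.backward(dy)
        dskips = []
        for up, block, (skip_ch, _) in zip(
            reversed(self.ups), reversed(self.dec_blocks), reversed(self._skip_channels)
        ):
            dy = block.backward(dy)
            dskip, dy = dy[:, :skip_ch], dy[:, skip_ch:]
            dskips.append(dskip)
            dy = up.backward(dy)
        dy = self.bottleneck.backward(dy)
        # dskips were collected outermost-first; deepest encoder block first here
        for block, pool, dskip in zip(
            reversed(self.enc_blocks), reversed(self.pools), reversed(dskips)
        ):
            dy = pool.backward(dy)
            dy = block.backward(dy + dskip)
        return dy


# ---------------------------------------------------------------------------
# loss and optimiser
# ---------------------------------------------------------------------------

def mae_loss(outputs: np.ndarray, targets: np.ndarray) -> float:
    """Mean absolute error over image pairs: the reconstruction loss.

    The per-pair absolute difference is averaged over pixels, and the loss
    averages over the N pairs in the batch — equivalently, a grand mean of
    ``|target - output|``.
    """
    outputs = np.asarray(outputs)
    targets = np.asarray(targets)
    if outputs.shape != targets.shape:
        raise ValueError(f"shape mismatch: {outputs.shape} vs {targets.shape}")
    if outputs.size == 0:
        raise ValueError("empty batch")
    return float(np.mean(np.abs(targets - outputs)))


def mae_loss_grad(outputs: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """d(mae_loss)/d(outputs); the subgradient at ties is 0."""
    if outputs.shape != targets.shape:
        raise ValueError(f"shape mismatch: {outputs.shape} vs {targets.shape}")
    return np.sign(outputs - targets) / outputs.size


class Adam:
    """Adam with the standard momentum defaults (beta1 0.9, beta2 0.999)."""

    def __init__(self, params: list[Param], lr: float = 0.005,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m += (1.0 - b1) * (g - m)
            v += (1.0 - b2) * (g * g - v)
            p.value -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
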