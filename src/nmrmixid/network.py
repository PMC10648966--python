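"""Pseudo-Siamese convolutional network with spatial pyramid pooling.

The model takes a spectral pair (reference flavor, composite flavor) and
outputs the probability that the reference is a component of the composite.
Two convolutional branches with identical architecture but independent
weights (a *pseudo*-Siamese arrangement: the two inputs live on different
scales, so sharing weights would be wrong) each run ``n_conv_blocks`` blocks
of [1-D conv (32 kernels, size 5, He-normal init) -> ReLU -> max-pool 2].
The branch outputs — two (channels x positions) planes — are merged along
the channel-row axis into one single-channel 2-D map (rows interleaved so a
5x5 window always spans both branches), convolved with a 2-D layer (128
kernels, 5x5), pooled by a 4-level spatial pyramid (4x4, 3x3,
2x2, 1x1 = 30 bins, max per bin) into a fixed 3840-vector, and classified by
dense-100 (ReLU) -> dropout 0.2 -> dense-1 (sigmoid).  The SPP layer is what
makes the network length-agnostic: any input long enough to survive the
pooling cascade maps to the same 3840-long feature.

Training minimizes binary cross-entropy with Adam.  Everything — forward,
backward, and the optimizer — is implemented here on numpy arrays in
float32; the branch convolutions and fused ReLU/max-pool stages run as
register-blocked numba kernels, the small 2-D stage as im2col + BLAS
matmul.  Execution is deterministic for a fixed seed in single-threaded
mode.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from numba import njit
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "ModelConfig",
    "TrainedModel",
    "spp_pool",
    "spp_output_length",
    "build_model",
    "train",
    "predict_pairs",
    "PseudoSiameseNetwork",
]

_DTYPE = np.float32
_F32_ZERO = np.float32(0.0)


@dataclass
class ModelConfig:
    """Architecture and training hyperparameters.

    Defaults are the production settings: 9 conv blocks of 32 size-5 kernels,
    a 128-kernel 5x5 2-D conv, the (4,3,2,1) pyramid, dense-100, dropout 0.2,
    Adam at lr 1e-5 for 100 epochs.  ``batch_size`` is not dictated by the
    architecture; 64 is the default.
    """

    n_conv_blocks: int = 9
    conv_kernels: int = 32
    conv_kernel_size: int = 5
    pool_size: int = 2
    conv2d_kernels: int = 128
    conv2d_kernel_size: tuple[int, int] = (5, 5)
    spp_levels: tuple[int, ...] = (4, 3, 2, 1)
    dense_units: int = 100
    dropout_rate: float = 0.2
    learning_rate: float = 1e-5
    epochs: int = 100
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_conv_blocks < 1:
            raise ValueError("n_conv_blocks must be >= 1")
        if not self.spp_levels or any(n < 1 for n in self.spp_levels):
            raise ValueError("spp_levels must be non-empty positive integers")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.learning_rate <= 0 or self.epochs < 1 or self.batch_size < 1:
            raise ValueError("learning_rate, epochs, batch_size must be positive")

    @property
    def min_input_length(self) -> int:
        """Shortest spectrum the pooling cascade and SPP can accept."""
        return max(self.spp_levels) * self.pool_size**self.n_conv_blocks


# ---------------------------------------------------------------------------
# spatial pyramid pooling
# ---------------------------------------------------------------------------

def _bin_edges(size: int, n: int) -> np.ndarray:
    """Boundaries floor(i * size / n), i = 0..n: bins tile [0, size) exactly."""
    return (np.arange(n + 1) * size) // n


def spp_output_length(channels: int, levels: tuple[int, ...]) -> int:
    """Flattened SPP feature length: C * sum(n^2)."""
    return channels * int(sum(n * n for n in levels))


def spp_pool(feature_map: np.ndarray, levels: tuple[int, ...] = (4, 3, 2, 1)) -> np.ndarray:
    """Max-pool an H x W x C feature map over a pyramid of n x n grids.

    Every level n partitions the map into n x n rectangular bins (boundaries
    at floor(i*H/n), floor(j*W/n)); the per-channel maximum of each bin is
    taken and all bins of all levels are concatenated, giving a vector of
    length C * sum(n^2) regardless of H and W.
    """
    fm = np.asarray(feature_map)
    if fm.ndim != 3:
        raise ValueError("feature_map must be H x W x C")
    H, W, C = fm.shape
    out = []
    for n in levels:
        if n > H or n > W:
            raise ValueError(f"pyramid level {n} exceeds feature map size {H}x{W} (empty bin)")
        he, we = _bin_edges(H, n), _bin_edges(W, n)
        for i in range(n):
            for j in range(n):
                out.append(fm[he[i] : he[i + 1], we[j] : we[j + 1], :].max(axis=(0, 1)))
    return np.concatenate(out)


# ---------------------------------------------------------------------------
# layers (branch stages are channels-first with numba kernels; the 2-D
# stage is channels-last numpy; float32 throughout; explicit forward/backward)
# ---------------------------------------------------------------------------

class _Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


def _he_normal(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(_DTYPE)


class _Scratch:
    """Persistent per-layer work buffers.

    The conv/pool stages touch 10-100 MB temporaries per call; allocating
    them fresh would cycle mmap/munmap and page faults every minibatch and
    dominate the runtime, so each layer reuses named scratch arrays."""

    def __init__(self):
        self._bufs: dict = {}

    def _buf(self, name: str, shape: tuple, dtype=_DTYPE) -> np.ndarray:
        b = self._bufs.get(name)
        if b is None or b.shape != shape or b.dtype != dtype:
            b = np.empty(shape, dtype=dtype)
            self._bufs[name] = b
        return b


@njit(cache=True, fastmath=True)
def _k_conv1d_fwd(xp, W, b, y):  # pragma: no cover - exercised via _Conv1d
    # y[bi, o, l] = b[o] + sum_{k,c} W[k, c, o] * xp[bi, c, l + k]
    # register-blocked 4 input channels x 2 output channels so the inner
    # loop is contiguous FMA over l (vectorizable)
    B, Co, L = y.shape
    K, Ci, _ = W.shape
    for bi in range(B):
        o = 0
        while o + 2 <= Co:
            y0 = y[bi, o]
            y1 = y[bi, o + 1]
            for l in range(L):
                y0[l] = b[o]
                y1[l] = b[o + 1]
            for k in range(K):
                c = 0
                while c + 4 <= Ci:
                    x0 = xp[bi, c]
                    x1 = xp[bi, c + 1]
                    x2 = xp[bi, c + 2]
                    x3 = xp[bi, c + 3]
                    w00 = W[k, c, o]
                    w01 = W[k, c, o + 1]
                    w10 = W[k, c + 1, o]
                    w11 = W[k, c + 1, o + 1]
                    w20 = W[k, c + 2, o]
                    w21 = W[k, c + 2, o + 1]
                    w30 = W[k, c + 3, o]
                    w31 = W[k, c + 3, o + 1]
                    for l in range(L):
                        a0 = x0[l + k]
                        a1 = x1[l + k]
                        a2 = x2[l + k]
                        a3 = x3[l + k]
                        y0[l] += w00 * a0 + w10 * a1 + w20 * a2 + w30 * a3
                        y1[l] += w01 * a0 + w11 * a1 + w21 * a2 + w31 * a3
                    c += 4
                while c < Ci:
                    x0 = xp[bi, c]
                    w00 = W[k, c, o]
                    w01 = W[k, c, o + 1]
                    for l in range(L):
                        a0 = x0[l + k]
                        y0[l] += w00 * a0
                        y1[l] += w01 * a0
                    c += 1
            o += 2
        while o < Co:
            y0 = y[bi, o]
            for l in range(L):
                y0[l] = b[o]
            for k in range(K):
                for c in range(Ci):
                    w = W[k, c, o]
                    x0 = xp[bi, c]
                    for l in range(L):
                        y0[l] += w * x0[l + k]
            o += 1


@njit(cache=True, fastmath=True)
def _k_conv1d_bwd(xp, W, gy, gW, gb, gxp):  # pragma: no cover
    # gW[k, c, o] += sum_l xp[bi, c, l + k] * gy[bi, o, l]
    # gxp[bi, c, l + k] += W[k, c, o] * gy[bi, o, l]
    # blocked 2 x 2 so every x/g load feeds two FMAs
    B, Co, L = gy.shape
    K, Ci, _ = W.shape
    for bi in range(B):
        for o in range(Co):
            g = gy[bi, o]
            s = _F32_ZERO
            for l in range(L):
                s += g[l]
            gb[o] += s
        c = 0
        while c + 2 <= Ci:
            x0 = xp[bi, c]
            x1 = xp[bi, c + 1]
            gx0 = gxp[bi, c]
            gx1 = gxp[bi, c + 1]
            for k in range(K):
                o = 0
                while o + 2 <= Co:
                    g0 = gy[bi, o]
                    g1 = gy[bi, o + 1]
                    w00 = W[k, c, o]
                    w01 = W[k, c, o + 1]
                    w10 = W[k, c + 1, o]
                    w11 = W[k, c + 1, o + 1]
                    a00 = _F32_ZERO
                    a01 = _F32_ZERO
                    a10 = _F32_ZERO
                    a11 = _F32_ZERO
                    for l in range(L):
                        b0 = g0[l]
                        b1 = g1[l]
                        xa = x0[l + k]
                        xb = x1[l + k]
                        a00 += xa * b0
                        a01 += xa * b1
                        a10 += xb * b0
                        a11 += xb * b1
                        gx0[l + k] += w00 * b0 + w01 * b1
                        gx1[l + k] += w10 * b0 + w11 * b1
                    gW[k, c, o] += a00
                    gW[k, c, o + 1] += a01
                    gW[k, c + 1, o] += a10
                    gW[k, c + 1, o + 1] += a11
                    o += 2
                while o < Co:
                    g0 = gy[bi, o]
                    w00 = W[k, c, o]
                    w10 = W[k, c + 1, o]
                    a00 = _F32_ZERO
                    a10 = _F32_ZERO
                    for l in range(L):
                        b0 = g0[l]
                        a00 += x0[l + k] * b0
                        a10 += x1[l + k] * b0
                        gx0[l + k] += w00 * b0
                        gx1[l + k] += w10 * b0
                    gW[k, c, o] += a00
                    gW[k, c + 1, o] += a10
                    o += 1
            c += 2
        while c < Ci:
            x0 = xp[bi, c]
            gx0 = gxp[bi, c]
            for k in range(K):
                for o in range(Co):
                    g0 = gy[bi, o]
                    w00 = W[k, c, o]
                    a00 = _F32_ZERO
                    for l in range(L):
                        b0 = g0[l]
                        a00 += x0[l + k] * b0
                        gx0[l + k] += w00 * b0
                    gW[k, c, o] += a00
            c += 1


@njit(cache=True, fastmath=True)
def _k_relupool_fwd(x, size, y, code):  # pragma: no cover
    # y = relu(maxpool(x)); code records the gradient route per output:
    # 0 = clipped by the ReLU, j+1 = window element j won the max
    B, C, lo = y.shape
    for bi in range(B):
        for c in range(C):
            xv = x[bi, c]
            yv = y[bi, c]
            cv = code[bi, c]
            for j in range(lo):
                base = j * size
                m = xv[base]
                w = 0
                for s in range(1, size):
                    v = xv[base + s]
                    better = v > m
                    m = v if better else m
                    w = s if better else w
                pos = m > 0
                yv[j] = m if pos else 0.0
                cv[j] = w + 1 if pos else 0


@njit(cache=True, fastmath=True)
def _k_relupool_bwd(gy, code, size, gx):  # pragma: no cover
    B, C, lo = gy.shape
    L = gx.shape[2]
    for bi in range(B):
        for c in range(C):
            gv = gy[bi, c]
            cv = code[bi, c]
            gxv = gx[bi, c]
            for l in range(L):
                gxv[l] = 0.0
            for j in range(lo):
                w = cv[j]
                if w > 0:
                    gxv[j * size + w - 1] = gv[j]


class _Conv1d(_Scratch):
    """Same-padded 1-D convolution on channels-first (B, C_in, L) ->
    (B, C_out, L), backed by the blocked numba kernels above."""

    def __init__(self, rng, c_in: int, c_out: int, k: int):
        super().__init__()
        self.k, self.c_in = k, c_in
        # W[k] holds the (C_in, C_out) weights of kernel tap k
        self.W = _Param(_he_normal(rng, (k, c_in, c_out), c_in * k))
        self.b = _Param(np.zeros(c_out, dtype=_DTYPE))
        self._cache = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        B, _, L = x.shape
        pad = self.k // 2
        dtype = np.result_type(x.dtype, self.W.value.dtype)
        c_out = self.W.value.shape[2]
        xp = self._buf("xp", (B, self.c_in, L + 2 * pad), dtype)
        xp[:, :, :pad] = 0
        xp[:, :, pad + L :] = 0
        xp[:, :, pad : pad + L] = x
        y = self._buf("y", (B, c_out, L), dtype)
        _k_conv1d_fwd(xp, self.W.value.astype(dtype, copy=False),
                      self.b.value.astype(dtype, copy=False), y)
        if training:
            self._cache = (xp, (B, L))
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xp, (B, L) = self._cache
        self._cache = None
        pad = self.k // 2
        gy = np.ascontiguousarray(gy)
        gxp = self._buf("gxp", xp.shape, xp.dtype)
        gxp[...] = 0
        gw = np.zeros(self.W.value.shape, dtype=xp.dtype)
        gb = np.zeros(self.b.value.shape, dtype=xp.dtype)
        _k_conv1d_bwd(xp, self.W.value.astype(xp.dtype, copy=False), gy, gw, gb, gxp)
        self.W.grad += gw
        self.b.grad += gb
        gx = self._buf("gx", (B, self.c_in, L), xp.dtype)
        gx[...] = gxp[:, :, pad : pad + L]
        return gx


class _ReLUMaxPool1d(_Scratch):
    """Fused ReLU + non-overlapping max pooling on channels-first (B, C, L).

    Because ReLU is monotone, max-pool(ReLU(x)) == ReLU(max-pool(x)); the
    fused form pools the pre-activations first so the nonlinearity and its
    gradient routing run on the pooled (shorter) tensor.  A trailing
    remainder shorter than the pool window is dropped.
    """

    def __init__(self, size: int):
        super().__init__()
        self.size = size
        self._cache = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        B, C, L = x.shape
        lo = L // self.size
        if lo < 1:
            raise ValueError(f"input length {L} too short for pool size {self.size}")
        y = self._buf("y", (B, C, lo), x.dtype)
        code = self._buf("code", (B, C, lo), np.uint8)
        _k_relupool_fwd(np.ascontiguousarray(x), self.size, y, code)
        if training:
            self._cache = (code, (B, C, L), x.dtype)
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        code, (B, C, L), dtype = self._cache
        self._cache = None
        gx = self._buf("gx", (B, C, L), dtype)
        _k_relupool_bwd(np.ascontiguousarray(gy), code, self.size, gx)
        return gx


class _Conv2d:
    """Same-padded 2-D convolution on channels-last (B, H, W, C_in) ->
    (B, H, W, C_out) via im2col + GEMM (the 2-D stage is small)."""

    def __init__(self, rng, c_in: int, c_out: int, kh: int, kw: int):
        self.kh, self.kw, self.c_in = kh, kw, c_in
        fan_in = c_in * kh * kw
        self.W = _Param(_he_normal(rng, (fan_in, c_out), fan_in))
        self.b = _Param(np.zeros(c_out, dtype=_DTYPE))
        self._cache = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        B, H, W, _ = x.shape
        ph, pw = self.kh // 2, self.kw // 2
        xp = np.pad(x, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
        # windows over H and W: (B, H, W, C_in, kh, kw)
        win = sliding_window_view(xp, (self.kh, self.kw), axis=(1, 2))
        cols = win.reshape(B * H * W, self.c_in * self.kh * self.kw)
        y = cols @ self.W.value + self.b.value
        if training:
            self._cache = (cols, (B, H, W))
        return y.reshape(B, H, W, -1)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        cols, (B, H, W) = self._cache
        self._cache = None
        g2 = gy.reshape(B * H * W, -1)
        self.W.grad += cols.T @ g2
        self.b.grad += g2.sum(axis=0)
        gcols = (g2 @ self.W.value.T).reshape(B, H, W, self.c_in, self.kh, self.kw)
        ph, pw = self.kh // 2, self.kw // 2
        gxp = np.zeros((B, H + 2 * ph, W + 2 * pw, self.c_in), dtype=gy.dtype)
        for i in range(self.kh):
            for j in range(self.kw):
                gxp[:, i : i + H, j : j + W, :] += gcols[:, :, :, :, i, j]
        return gxp[:, ph : ph + H, pw : pw + W, :]


class _ReLU:
    def __init__(self):
        self._mask = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        y = np.maximum(x, 0)
        if training:
            self._mask = x > 0
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        g = gy * self._mask
        self._mask = None
        return g


class _SPP:
    """Spatial pyramid max pooling on (B, H, W, C) -> (B, C * sum(n^2))."""

    def __init__(self, levels: tuple[int, ...]):
        self.levels = tuple(levels)
        self._cache = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        B, H, W, C = x.shape
        bins = []
        for n in self.levels:
            if n > H or n > W:
                raise ValueError(
                    f"pyramid level {n} exceeds feature map size {H}x{W} (empty bin)"
                )
            he, we = _bin_edges(H, n), _bin_edges(W, n)
            for i in range(n):
                for j in range(n):
                    bins.append((he[i], he[i + 1], we[j], we[j + 1]))
        outs = []
        idxs = []
        for h0, h1, w0, w1 in bins:
            region = x[:, h0:h1, w0:w1, :].reshape(B, -1, C)
            idx = region.argmax(axis=1)
            outs.append(np.take_along_axis(region, idx[:, None, :], axis=1)[:, 0, :])
            idxs.append(idx)
        if training:
            self._cache = (bins, idxs, (B, H, W, C))
        return np.stack(outs, axis=1).reshape(B, -1)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        bins, idxs, (B, H, W, C) = self._cache
        self._cache = None
        gy = gy.reshape(B, len(bins), C)
        gx = np.zeros((B, H, W, C), dtype=_DTYPE)
        for bi, (h0, h1, w0, w1) in enumerate(bins):
            m = (h1 - h0) * (w1 - w0)
            greg = np.zeros((B, m, C), dtype=_DTYPE)
            np.put_along_axis(greg, idxs[bi][:, None, :], gy[:, bi, :][:, None, :], axis=1)
            gx[:, h0:h1, w0:w1, :] += greg.reshape(B, h1 - h0, w1 - w0, C)
        return gx


class _Dense:
    def __init__(self, rng, n_in: int, n_out: int):
        self.W = _Param(_he_normal(rng, (n_in, n_out), n_in))
        self.b = _Param(np.zeros(n_out, dtype=_DTYPE))
        self._cache = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            self._cache = x
        return x @ self.W.value + self.b.value

    def backward(self, gy: np.ndarray) -> np.ndarray:
        x = self._cache
        self._cache = None
        self.W.grad += x.T @ gy
        self.b.grad += gy.sum(axis=0)
        return gy @ self.W.value.T


class _Dropout:
    def __init__(self, rate: float):
        self.rate = rate
        self.rng: np.random.Generator | None = None
        self._mask = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if not training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(_DTYPE) / keep
        return x * self._mask

    def backward(self, gy: np.ndarray) -> np.ndarray:
        if self._mask is None:  # eval mode or rate == 0
            return gy
        g = gy * self._mask
        self._mask = None
        return g


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------

class PseudoSiameseNetwork:
    """Twin-branch CNN producing one presence logit per spectral pair."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        k = config.conv_kernel_size
        self.branches = []
        for _ in range(2):  # independent weights per branch
            layers = []
            c_in = 1
            for _ in range(config.n_conv_blocks):
                layers.append(_Conv1d(rng, c_in, config.conv_kernels, k))
                layers.append(_ReLUMaxPool1d(config.pool_size))
                c_in = config.conv_kernels
            self.branches.append(layers)
        kh, kw = config.conv2d_kernel_size
        self.conv2d = _Conv2d(rng, 1, config.conv2d_kernels, kh, kw)
        self.relu2d = _ReLU()
        self.spp = _SPP(config.spp_levels)
        n_feat = spp_output_length(config.conv2d_kernels, config.spp_levels)
        self.dense1 = _Dense(rng, n_feat, config.dense_units)
        self.relu_d = _ReLU()
        self.dropout = _Dropout(config.dropout_rate)
        self.dropout.rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
        self.dense2 = _Dense(rng, config.dense_units, 1)

    # -- parameter plumbing -------------------------------------------------
    def _layers(self):
        yield from self.branches[0]
        yield from self.branches[1]
        for lay in (self.conv2d, self.relu2d, self.spp, self.dense1, self.relu_d,
                    self.dropout, self.dense2):
            yield lay

    def params(self) -> list[_Param]:
        out = []
        for lay in self._layers():
            out.extend(lay.params())
        return out

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0

    # -- forward / backward -------------------------------------------------
    def forward_logits(self, references: np.ndarray, composites: np.ndarray,
                       training: bool = False) -> np.ndarray:
        refs = np.ascontiguousarray(references, dtype=_DTYPE)
        comps = np.ascontiguousarray(composites, dtype=_DTYPE)
        if refs.shape != comps.shape or refs.ndim != 2:
            raise ValueError("references and composites must be matching (B, P) arrays")
        if refs.shape[1] < self.config.min_input_length:
            raise ValueError(
                f"input length {refs.shape[1]} too short: need >= "
                f"{self.config.min_input_length} for {self.config.n_conv_blocks} "
                f"pooling stages and the {max(self.config.spp_levels)}-level pyramid"
            )
        outs = []
        for layers, x in zip(self.branches, (refs, comps)):
            h = x[:, None, :]  # (B, 1, P) channels-first
            for lay in layers:
                h = lay.forward(h, training)
            outs.append(h)
        # merge the two (channels x positions) planes along the channel-row
        # axis into one single-channel 2-D map of shape (2*channels,
        # positions), interleaving the rows so every 5x5 window of the 2-D
        # convolution sees both branches (block-stacking them would confine
        # reference/composite interaction to the seam rows)
        B = refs.shape[0]
        C, W = outs[0].shape[1], outs[0].shape[2]
        fmap = np.empty((B, 2 * C, W), dtype=outs[0].dtype)
        fmap[:, 0::2, :] = outs[0]
        fmap[:, 1::2, :] = outs[1]
        fmap = fmap[..., None]
        h = self.conv2d.forward(np.ascontiguousarray(fmap), training)
        h = self.relu2d.forward(h, training)
        h = self.spp.forward(h, training)
        h = self.dense1.forward(h, training)
        h = self.relu_d.forward(h, training)
        h = self.dropout.forward(h, training)
        return self.dense2.forward(h, training)[:, 0]

    def backward(self, dlogits: np.ndarray) -> None:
        g = dlogits[:, None].astype(_DTYPE)
        g = self.dense2.backward(g)
        g = self.dropout.backward(g)
        g = self.relu_d.backward(g)
        g = self.dense1.backward(g)
        g = self.spp.backward(g)
        g = self.relu2d.backward(g)
        g = self.conv2d.backward(g)[..., 0]  # (B, 2C, L) channels-first
        for layers, gb in zip(self.branches, (g[:, 0::2, :], g[:, 1::2, :])):
            gb = np.ascontiguousarray(gb)
            for lay in reversed(layers):
                gb = lay.backward(gb)

    def predict_proba(self, references: np.ndarray, composites: np.ndarray,
                      batch_size: int = 256) -> np.ndarray:
        """Presence probabilities, batched, in input order."""
        n = len(references)
        out = np.empty(n, dtype=np.float64)
        for i in range(0, n, batch_size):
            z = self.forward_logits(references[i : i + batch_size],
                                    composites[i : i + batch_size], training=False)
            out[i : i + batch_size] = 1.0 / (1.0 + np.exp(-z.astype(np.float64)))
        return out


class _Adam:
    def __init__(self, params: list[_Param], lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad**2
            p.value -= (self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)).astype(_DTYPE)


@dataclass
class TrainedModel:
    """A fitted network plus its config and per-epoch training history."""

    config: ModelConfig
    network: PseudoSiameseNetwork
    history: dict = field(default_factory=dict)

    def predict_proba(self, references: np.ndarray, composites: np.ndarray) -> np.ndarray:
        return self.network.predict_proba(references, composites)

    def save(self, path) -> None:
        arrays = {f"param_{i}": p.value for i, p in enumerate(self.network.params())}
        cfg = asdict(self.config)
        np.savez(
            path,
            __config__=np.frombuffer(json.dumps(cfg).encode(), dtype=np.uint8),
            __history__=np.frombuffer(json.dumps(self.history).encode(), dtype=np.uint8),
            **arrays,
        )

    @classmethod
    def load(cls, path) -> "TrainedModel":
        with np.load(path) as data:
            cfg = json.loads(bytes(data["__config__"]).decode())
            for key in ("conv2d_kernel_size", "spp_levels"):
                cfg[key] = tuple(cfg[key])
            history = json.loads(bytes(data["__history__"]).decode())
            config = ModelConfig(**cfg)
            net = PseudoSiameseNetwork(config)
            for i, p in enumerate(net.params()):
                p.value[...] = data[f"param_{i}"]
        return cls(config, net, history)


def build_model(config: ModelConfig | None = None) -> PseudoSiameseNetwork:
    """Construct an untrained network (He-normal init, seeded by config)."""
    return PseudoSiameseNetwork(config or ModelConfig())


def _bce_with_logits(z: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy and its gradient w.r.t. the logits."""
    z64 = z.astype(np.float64)
    loss = float(np.mean(np.logaddexp(0.0, z64) - y * z64))
    p = 1.0 / (1.0 + np.exp(-z64))
    return loss, ((p - y) / len(y)).astype(_DTYPE)


def train(
    model: PseudoSiameseNetwork,
    train_pairs,
    val_pairs=None,
    config: ModelConfig | None = None,
    verbose: bool = False,
) -> TrainedModel:
    """Fit the network with Adam on binary cross-entropy.

    ``train_pairs``/``val_pairs`` are PairSet-like objects exposing
    ``references``, ``composites`` and ``labels``.  The returned model's
    ``history`` holds per-epoch train and validation loss/accuracy.
    """
    config = config or model.config
    refs = train_pairs.references
    comps = train_pairs.composites
    labels = np.asarray(train_pairs.labels, dtype=np.float64)
    if len(labels) == 0:
        raise ValueError("training set is empty")
    if len(np.unique(labels)) < 2:
        warnings.warn("training labels are single-class; the fit will be degenerate")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    model.dropout.rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    opt = _Adam(model.params(), config.learning_rate)
    history: dict[str, list[float]] = {
        "loss": [], "accuracy": [], "val_loss": [], "val_accuracy": []
    }
    n = len(labels)
    for epoch in range(config.epochs):
        perm = rng.permutation(n)
        tot_loss = 0.0
        tot_correct = 0
        for start in range(0, n, config.batch_size):
            idx = perm[start : start + config.batch_size]
            y = labels[idx]
            z = model.forward_logits(refs[idx], comps[idx], training=True)
            loss, dz = _bce_with_logits(z, y)
            model.zero_grad()
            model.backward(dz)
            opt.step()
            tot_loss += loss * len(idx)
            tot_correct += int(np.sum((z > 0) == (y > 0.5)))
        history["loss"].append(tot_loss / n)
        history["accuracy"].append(tot_correct / n)
        if val_pairs is not None and len(val_pairs.labels):
            vp = model.predict_proba(val_pairs.references, val_pairs.composites,
                                     batch_size=config.batch_size)
            vy = np.asarray(val_pairs.labels, dtype=np.float64)
            eps = 1e-12
            vloss = float(np.mean(-(vy * np.log(vp + eps) + (1 - vy) * np.log(1 - vp + eps))))
            history["val_loss"].append(vloss)
            history["val_accuracy"].append(float(np.mean((vp > 0.5) == (vy > 0.5))))
        if verbose:
            msg = f"epoch {epoch + 1}/{config.epochs} loss={history['loss'][-1]:.4f} acc={history['accuracy'][-1]:.4f}"
            if history["val_loss"]:
                msg += f" val_loss={history['val_loss'][-1]:.4f} val_acc={history['val_accuracy'][-1]:.4f}"
            print(msg)
    return TrainedModel(config, model, history)


def predict_pairs(model, pairs, batch_size: int = 256) -> np.ndarray:
    """Presence probability for each pair (order-preserving,
    batch-size independent)."""
    net = model.network if isinstance(model, TrainedModel) else model
    refs = pairs.references
    comps = pairs.composites
    if len(refs) == 0:
        return np.zeros(0)
    return net.predict_proba(refs, comps, batch_size=batch_size)
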