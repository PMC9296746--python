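"""A u-shaped 3D convolutional network for projection-stack regression.

The input is a single-channel 3D stack whose axes are (projection angle,
detector row, detector column); the angle axis is pooled exactly like a
spatial axis, which the cyclic angular padding makes safe at the
wrap-around.  Encoder blocks run two 3x3x3 convolutions with instance
normalization and leaky ReLU, doubling the channel count, each followed
by 2x max-pooling; the decoder mirrors them with 2x2x2 stride-2
transposed convolutions and skip connections; two final 1x1x1
convolutions with ReLU reduce to one non-negative output channel.
"""

from __future__ import annotations

import numpy as np

from .layers import (Conv1x1, Conv3x3, InstanceNorm, Layer, LeakyReLU,
                     MaxPool2, Param, ReLU, UpConv2, l1_loss)

__all__ = ["UNet3D", "ConvBlock"]

F32 = np.float32
_AXIS_NAMES = ("angle", "detector-row", "detector-column")


class ConvBlock(Layer):
    """Two (conv 3x3x3 -> instance norm -> leaky ReLU) stages."""

    def __init__(self, cin: int, cout: int, rng, negative_slope: float):
        self.layers = [
            Conv3x3(cin, cout, rng), InstanceNorm(), LeakyReLU(negative_slope),
            Conv3x3(cout, cout, rng), InstanceNorm(), LeakyReLU(negative_slope),
        ]
        self.params = tuple(p for l in self.layers for p in l.params)

    def forward(self, x):
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, gy):
        for l in reversed(self.layers):
            gy = l.backward(gy)
        return gy


class UNet3D:
    """u-net with configurable depth and base channel count.

    ``depth`` encoder blocks with channels ``base * 2**i`` (every spatial
    input dimension must be divisible by ``2**depth``), a bottleneck
    block at ``base * 2**depth`` channels, and a mirrored decoder.
    """

    def __init__(self, base_channels: int = 32, depth: int = 4,
                 negative_slope: float = 0.01, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.depth = depth
        self.base_channels = base_channels
        c = base_channels
        self.encoders = []
        cin = 1
        for i in range(depth):
            self.encoders.append(ConvBlock(cin, c * 2**i, rng, negative_slope))
            cin = c * 2**i
        self.pools = [MaxPool2() for _ in range(depth)]
        self.bottleneck = ConvBlock(cin, c * 2**depth, rng, negative_slope)
        self.upconvs = []
        self.decoders = []
        for i in reversed(range(depth)):
            self.upconvs.append(UpConv2(c * 2 ** (i + 1), c * 2**i, rng))
            self.decoders.append(
                ConvBlock(2 * c * 2**i, c * 2**i, rng, negative_slope))
        mid = max(c // 2, 1)
        # small positive bias keeps the ReLU head alive at initialization
        self.head = [Conv1x1(c, mid, rng, bias_init=0.1), ReLU(),
                     Conv1x1(mid, 1, rng, bias_init=0.1), ReLU()]
        self._modules = (self.encoders + self.pools + [self.bottleneck]
                         + self.upconvs + self.decoders + self.head)
        self._skip_channels = None

    # -- parameter access ------------------------------------------------
    def parameters(self) -> list[Param]:
        return [p for m in self._modules for p in m.params]

    def get_weights(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(weights) != len(params):
            raise ValueError("weight list does not match the architecture")
        for p, w in zip(params, weights):
            if p.value.shape != w.shape:
                raise ValueError("weight shape mismatch")
            p.value = w.astype(F32)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    # -- forward / backward ----------------------------------------------
    def _check_shape(self, x: np.ndarray) -> None:
        if x.ndim != 5 or x.shape[-1] != 1:
            raise ValueError("expected input of shape (N, D, H, W, 1)")
        div = 2**self.depth
        for axis, size in zip(_AXIS_NAMES, x.shape[1:4]):
            if size % div != 0:
                raise ValueError(
                    f"{axis} dimension {size} is not divisible by "
                    f"2**depth = {div}")

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=F32)
        self._check_shape(x)
        skips = []
        h = x
        for enc, pool in zip(self.encoders, self.pools):
            h = enc.forward(h)
            skips.append(h)
            h = pool.forward(h)
        h = self.bottleneck.forward(h)
        self._skip_channels = []
        for up, dec, skip in zip(self.upconvs, self.decoders,
                                 reversed(skips)):
            h = up.forward(h)
            self._skip_channels.append(skip.shape[-1])
            h = np.concatenate([skip, h], axis=-1)
            h = dec.forward(h)
        for l in self.head:
            h = l.forward(h)
        return h

    def backward(self, gy: np.ndarray) -> np.ndarray:
        for l in reversed(self.head):
            gy = l.backward(gy)
        gskips = []
        for up, dec, csk in zip(reversed(self.upconvs),
                                reversed(self.decoders),
                                reversed(self._skip_channels)):
            g = dec.backward(gy)
            gskips.append(g[..., :csk])
            gy = up.backward(g[..., csk:])
        gy = self.bottleneck.backward(gy)
        # gskips were collected shallow-to-deep; encoders unwind deep-to-shallow
        for enc, pool, gskip in zip(reversed(self.encoders),
                                    reversed(self.pools), reversed(gskips)):
            gy = pool.backward(gy)
            gy = enc.backward(gy + gskip)
        return gy

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Forward pass for inference (same computation; kept for
        readability at call sites)."""
        return self.forward(x)

    def loss_and_grad(self, x: np.ndarray, target: np.ndarray) -> float:
        """One forward/backward pass accumulating parameter gradients."""
        pred = self.forward(x)
        loss, g = l1_loss(pred, np.asarray(target, dtype=F32))
        self.backward(g)
        return loss
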