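"""A configurable U-Net for 3-class slice segmentation.

Plain convolutional encoder (no pretrained weights), nearest-neighbour
upsampling decoder with skip concatenation, and batch normalization
after every decoder convolution.  The number of downsampling steps
equals ``len(decoder_channels)``; the published full-scale architecture
(depth 5, decoder channels 256..16) is expressible via the same config,
while desk-scale defaults keep CPU training fast.

Arrays are NHWC.
"""

from __future__ import annotations

import numpy as np

from .layers import Adam, BatchNorm2d, Conv2d, MaxPool2, ReLU, Upsample2

__all__ = ["UNet", "softmax"]


class _ConvBlock:
    """conv -> [BN] -> ReLU, twice."""

    def __init__(self, c_in, c_out, rng, batchnorm=False, dtype=np.float32):
        self.layers = []
        for cin in (c_in, c_out):
            self.layers.append(Conv2d(cin, c_out, 3, rng=rng, dtype=dtype))
            if batchnorm:
                self.layers.append(BatchNorm2d(c_out, dtype=dtype))
            self.layers.append(ReLU())

    def forward(self, x, train):
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


class UNet:
    """Encoder depth = len(decoder_channels); classes are exclusive labels
    {background (incl. blood pool), healthy myocardium, scar}."""

    def __init__(
        self,
        decoder_channels: tuple[int, ...] = (32, 16, 8),
        in_channels: int = 1,
        n_classes: int = 3,
        seed: int = 0,
        dtype=np.float32,
    ):
        rng = np.random.default_rng(seed)
        self.decoder_channels = tuple(decoder_channels)
        self.n_classes = n_classes
        self.dtype = dtype
        enc_channels = tuple(reversed(self.decoder_channels))

        self.enc_blocks = []
        self.pools = []
        c_prev = in_channels
        for c in enc_channels:
            self.enc_blocks.append(_ConvBlock(c_prev, c, rng, dtype=dtype))
            self.pools.append(MaxPool2())
            c_prev = c
        self.bottleneck = _ConvBlock(c_prev, 2 * c_prev, rng, dtype=dtype)
        c_prev = 2 * c_prev

        self.ups = []
        self.dec_blocks = []
        for skip_c, c in zip(reversed(enc_channels), self.decoder_channels):
            self.ups.append(Upsample2())
            self.dec_blocks.append(
                _ConvBlock(c_prev + skip_c, c, rng, batchnorm=True, dtype=dtype)
            )
            c_prev = c
        self.head = Conv2d(c_prev, n_classes, 1, rng=rng, dtype=dtype)

    # -- plumbing ----------------------------------------------------------
    def _all_layers(self):
        layers = []
        for b in self.enc_blocks:
            layers.extend(b.layers)
        layers.extend(self.bottleneck.layers)
        for b in self.dec_blocks:
            layers.extend(b.layers)
        layers.append(self.head)
        return layers

    def make_optimizer(self, lr=1e-3, beta1=0.9, beta2=0.999):
        return Adam(self._all_layers(), lr=lr, beta1=beta1, beta2=beta2)

    def state_dict(self):
        state = {}
        for i, l in enumerate(self._all_layers()):
            for k, v in l.params.items():
                state[f"{i}.{k}"] = v.copy()
            if isinstance(l, BatchNorm2d):
                state[f"{i}.running_mean"] = l.running_mean.copy()
                state[f"{i}.running_var"] = l.running_var.copy()
        return state

    def load_state_dict(self, state):
        for i, l in enumerate(self._all_layers()):
            for k in l.params:
                l.params[k][...] = state[f"{i}.{k}"]
            if isinstance(l, BatchNorm2d):
                l.running_mean = state[f"{i}.running_mean"].copy()
                l.running_var = state[f"{i}.running_var"].copy()

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """x: (N, H, W, C) with H, W divisible by 2**depth -> logits."""
        x = np.ascontiguousarray(x, dtype=self.dtype)
        skips = []
        for block, pool in zip(self.enc_blocks, self.pools):
            x = block.forward(x, train)
            skips.append(x)
            x = pool.forward(x, train)
        x = self.bottleneck.forward(x, train)
        self._skip_channels = []
        for up, block, skip in zip(self.ups, self.dec_blocks, reversed(skips)):
            x = up.forward(x, train)
            self._skip_channels.append(skip.shape[-1])
            x = np.concatenate([skip, x], axis=-1)
            x = block.forward(x, train)
        return self.head.forward(x, train)

    def backward(self, dlogits: np.ndarray) -> None:
        dy = self.head.backward(dlogits)
        dskips = []
        for block, up, c_skip in zip(
            reversed(self.dec_blocks), reversed(self.ups),
            reversed(self._skip_channels),
        ):
            dy = block.backward(dy)
            dskip, dy = dy[..., :c_skip], dy[..., c_skip:]
            dskips.append(dskip)
            dy = up.backward(dy)
        dy = self.bottleneck.backward(dy)
        for block, pool, dskip in zip(
            reversed(self.enc_blocks), reversed(self.pools), reversed(dskips)
        ):
            dy = pool.backward(dy)
            dy = block.backward(dy + dskip)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Softmax class probabilities (NHWC) in eval mode (running BN
        statistics)."""
        logits = self.forward(x, train=False)
        return softmax(logits, axis=-1)


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)
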