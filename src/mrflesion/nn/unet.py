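"""2-D U-net: encoder depth three, skip connections, linear final 1x1 conv.

Channel widths start at ``base_channels`` and double at every resolution
halving.  The final activation is linear — the network is a regression
network; probability channels are clipped to [0, 1] only at evaluation time
so the lesion probability background stays non-zero and thresholding sweeps
remain meaningful.
"""

from __future__ import annotations

import numpy as np

from .layers import Conv2d, MaxPool2, ReLU, Upsample2

__all__ = ["UNet2D"]


class _Block:
    """conv-relu-conv-relu."""

    def __init__(self, in_ch, out_ch, rng):
        self.c1 = Conv2d(in_ch, out_ch, 3, rng)
        self.r1 = ReLU()
        self.c2 = Conv2d(out_ch, out_ch, 3, rng)
        self.r2 = ReLU()

    def forward(self, x, train=True):
        return self.r2.forward(
            self.c2.forward(self.r1.forward(self.c1.forward(x, train), train), train),
            train,
        )

    def backward(self, g):
        return self.c1.backward(self.r1.backward(self.c2.backward(self.r2.backward(g))))

    @property
    def params(self):
        return self.c1.params + self.c2.params


class UNet2D:
    """Encoder-decoder with ``depth`` resolution halvings and skips."""

    def __init__(self, in_ch: int, out_ch: int, base_channels: int = 32,
                 depth: int = 3, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.in_ch, self.out_ch = in_ch, out_ch
        self.depth, self.base_channels = depth, base_channels
        self.enc = []
        c_prev = in_ch
        for d in range(depth):
            c = base_channels * 2**d
            self.enc.append(_Block(c_prev, c, rng))
            c_prev = c
        self.pools = [MaxPool2() for _ in range(depth)]
        self.bottleneck = _Block(c_prev, base_channels * 2**depth, rng)
        self.ups = [Upsample2() for _ in range(depth)]
        self.dec = []
        c_prev = base_channels * 2**depth
        for d in reversed(range(depth)):
            c = base_channels * 2**d
            self.dec.append(_Block(c_prev + c, c, rng))
            c_prev = c
        self.head = Conv2d(c_prev, out_ch, 1, rng)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if x.shape[1] != self.in_ch:
            raise ValueError(f"expected {self.in_ch} input channels, got {x.shape[1]}")
        if x.shape[2] % 2**self.depth or x.shape[3] % 2**self.depth:
            raise ValueError(
                f"spatial size {x.shape[2:]} not divisible by 2^{self.depth}"
            )
        skips = []
        h = x.astype(np.float32, copy=False)
        for blk, pool in zip(self.enc, self.pools):
            h = blk.forward(h, train)
            skips.append(h)
            h = pool.forward(h, train)
        h = self.bottleneck.forward(h, train)
        self._skip_channels = [s.shape[1] for s in skips]
        for up, blk, skip in zip(self.ups, self.dec, reversed(skips)):
            h = up.forward(h, train)
            h = np.concatenate([skip, h], axis=1)
            h = blk.forward(h, train)
        return self.head.forward(h, train)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        g = self.head.backward(gout)
        gskips = []
        for up, blk, c_skip in zip(
            reversed(self.ups), reversed(self.dec), self._skip_channels
        ):
            g = blk.backward(g)
            gskips.append(g[:, :c_skip])
            g = up.backward(g[:, c_skip:])
        g = self.bottleneck.backward(g)
        # gskips were collected shallow-first; the encoder unwinds deep-first
        for blk, pool, gskip in zip(
            reversed(self.enc), reversed(self.pools), reversed(gskips)
        ):
            g = pool.backward(g)
            g = blk.backward(g + gskip)
        return g

    @property
    def params(self):
        out = []
        for blk in self.enc:
            out += blk.params
        out += self.bottleneck.params
        for blk in self.dec:
            out += blk.params
        out += self.head.params
        return out

    def n_parameters(self) -> int:
        return sum(p.size for p, _ in self.params)

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p, _ in self.params]

    def set_weights(self, weights) -> None:
        for (p, _), w in zip(self.params, weights):
            p[...] = w
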