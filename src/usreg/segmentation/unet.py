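"""A compact 3D U-Net built from the numpy layers.

Architecture: analysis and synthesis paths with a configurable number of
resolution steps (two by default), two conv(3^3)+norm+ReLU blocks per level,
max-pool downsampling, transposed-conv upsampling with skip concatenation,
and dropout before each convolution of the synthesis path only.  Input sizes
not divisible by 2**steps are reflect-padded internally and cropped back, so
the output grid always equals the input grid.
"""

from __future__ import annotations

import numpy as np

from .layers import Adam, BatchNorm, Conv1, Conv3, Dropout, MaxPool2, ReLU, UpConv2, sigmoid

__all__ = ["UNet3D"]


class _ConvBlock:
    def __init__(self, c_in, c_out, rng, dropout=0.0, drop_rng=None, dtype=np.float32):
        self.dropout = Dropout(dropout, drop_rng) if dropout > 0 else None
        self.conv = Conv3(c_in, c_out, rng, dtype=dtype)
        self.norm = BatchNorm(c_out, dtype=dtype)
        self.act = ReLU()

    def params(self):
        return self.conv.params() + self.norm.params()

    def forward(self, x, training):
        if self.dropout is not None:
            x = self.dropout.forward(x, training)
        return self.act.forward(self.norm.forward(self.conv.forward(x, training), training), training)

    def backward(self, dy):
        dx = self.conv.backward(self.norm.backward(self.act.backward(dy)))
        if self.dropout is not None:
            dx = self.dropout.backward(dx)
        return dx


class UNet3D:
    """3D U-Net; ``forward`` returns voxel-wise logits of the same shape."""

    def __init__(self, steps: int = 2, base_channels: int = 16, dropout: float = 0.4,
                 in_channels: int = 1, seed: int = 0, dtype=np.float32):
        self.steps = steps
        rng = np.random.default_rng(seed)
        self.drop_rng = np.random.default_rng(seed + 1)
        self.dtype = dtype

        ch = [base_channels * 2**s for s in range(steps + 1)]
        self.enc = []
        c_prev = in_channels
        for s in range(steps):
            self.enc.append(
                (
                    _ConvBlock(c_prev, ch[s], rng, dtype=dtype),
                    _ConvBlock(ch[s], ch[s], rng, dtype=dtype),
                    MaxPool2(),
                )
            )
            c_prev = ch[s]
        self.bottom = (
            _ConvBlock(c_prev, ch[steps], rng, dtype=dtype),
            _ConvBlock(ch[steps], ch[steps], rng, dtype=dtype),
        )
        self.dec = []
        c_prev = ch[steps]
        for s in reversed(range(steps)):
            up = UpConv2(c_prev, ch[s], rng, dtype=dtype)
            b1 = _ConvBlock(2 * ch[s], ch[s], rng, dropout=dropout, drop_rng=self.drop_rng, dtype=dtype)
            b2 = _ConvBlock(ch[s], ch[s], rng, dropout=dropout, drop_rng=self.drop_rng, dtype=dtype)
            self.dec.append((up, b1, b2))
            c_prev = ch[s]
        self.final = Conv1(c_prev, 1, rng, dtype=dtype)

    # -- parameter plumbing ----------------------------------------------
    def _layers(self):
        out = []
        for b1, b2, _ in self.enc:
            out += [b1, b2]
        out += list(self.bottom)
        for up, b1, b2 in self.dec:
            out += [up, b1, b2]
        out.append(self.final)
        return out

    def params(self):
        ps = []
        for layer in self._layers():
            ps += layer.params()
        return ps

    def make_optimizer(self, lr: float) -> Adam:
        return Adam(self.params(), lr=lr)

    def state_dict(self) -> dict:
        state = {}
        for i, layer in enumerate(self._layers()):
            for j, p in enumerate(layer.params()):
                state[f"p{i}_{j}"] = p.value.copy()
            if isinstance(layer, _ConvBlock):
                state[f"p{i}_rm"] = layer.norm.running_mean.copy()
                state[f"p{i}_rv"] = layer.norm.running_var.copy()
        return state

    def load_state_dict(self, state: dict):
        for i, layer in enumerate(self._layers()):
            for j, p in enumerate(layer.params()):
                p.value = state[f"p{i}_{j}"].copy()
            if isinstance(layer, _ConvBlock):
                layer.norm.running_mean = state[f"p{i}_rm"].copy()
                layer.norm.running_var = state[f"p{i}_rv"].copy()

    # -- forward / backward ----------------------------------------------
    def _pad_to_multiple(self, x):
        m = 2**self.steps
        pads = [(0, (-x.shape[2 + a]) % m) for a in range(3)]
        if any(p[1] for p in pads):
            x = np.pad(x, ((0, 0), (0, 0), *pads), mode="reflect")
        return x, pads

    def forward(self, x, training: bool = False):
        x = np.asarray(x, dtype=self.dtype)
        orig = x.shape[2:]
        x, self._pads = self._pad_to_multiple(x)
        skips = []
        for b1, b2, pool in self.enc:
            x = b2.forward(b1.forward(x, training), training)
            skips.append(x)
            x = pool.forward(x, training)
        x = self.bottom[1].forward(self.bottom[0].forward(x, training), training)
        self._skip_channels = []
        for (up, b1, b2), skip in zip(self.dec, reversed(skips)):
            x = up.forward(x, training)
            self._skip_channels.append(skip.shape[1])
            x = np.concatenate([skip, x], axis=1)
            x = b2.forward(b1.forward(x, training), training)
        x = self.final.forward(x, training)
        self._training = training
        return x[:, :, : orig[0], : orig[1], : orig[2]]

    def backward(self, dlogits):
        pads = self._pads
        if any(p[1] for p in pads):
            dlogits = np.pad(dlogits, ((0, 0), (0, 0), *pads))
        dx = self.final.backward(np.asarray(dlogits, dtype=self.dtype))
        dskips = []
        for (up, b1, b2), c_skip in zip(reversed(self.dec), reversed(self._skip_channels)):
            dx = b1.backward(b2.backward(dx))
            dskips.append(dx[:, :c_skip])
            dx = up.backward(dx[:, c_skip:])
        dx = self.bottom[0].backward(self.bottom[1].backward(dx))
        for (b1, b2, pool), dskip in zip(reversed(self.enc), reversed(dskips)):
            dx = pool.backward(dx)
            dx = dx + dskip
            dx = b1.backward(b2.backward(dx))
        return dx

    def predict_proba(self, x):
        """Sigmoid probabilities in eval mode."""
        return sigmoid(self.forward(x, training=False))
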