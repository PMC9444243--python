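"""Tiny encoder/decoder network for per-pixel classification.

One pooling stage, nearest-neighbour upsampling and a skip connection —
a desk-scale stand-in for heavier encoder/decoder segmentation nets.
Fully convolutional, so inputs of arbitrary (even-padded) size work.
"""

from __future__ import annotations

import numpy as np

from divtrap._nn.layers import Conv2d, MaxPool2x2, Param, ReLU, Upsample2x, softmax


class TinyEncoderDecoder:
    def __init__(self, cin: int, n_classes: int, width: int = 8, seed: int = 0) -> None:
        rng = np.random.default_rng(seed)
        f = width
        self.cin = cin
        self.n_classes = n_classes
        self.width = width
        self.enc1 = Conv2d(cin, f, 3, rng=rng)
        self.enc2 = Conv2d(f, f, 3, rng=rng)
        self.pool = MaxPool2x2()
        self.mid = Conv2d(f, 2 * f, 3, rng=rng)
        self.up = Upsample2x()
        self.dec1 = Conv2d(3 * f, f, 3, rng=rng)
        self.head = Conv2d(f, n_classes, 1, rng=rng)
        self.head.w.value[...] = 0.0  # zero-init head: class-permutation equivariance
        self.relus = [ReLU() for _ in range(4)]
        self.fitted = False

    @property
    def params(self) -> list[Param]:
        layers = [self.enc1, self.enc2, self.mid, self.dec1, self.head]
        return [p for l in layers for p in l.params]

    def forward(self, x: np.ndarray) -> np.ndarray:
        """(N, C, H, W) -> logits (N, n_classes, H, W); H, W must be even."""
        a = self.relus[0].forward(self.enc1.forward(x))
        skip = self.relus[1].forward(self.enc2.forward(a))
        b = self.pool.forward(skip)
        b = self.relus[2].forward(self.mid.forward(b))
        b = self.up.forward(b)
        merged = np.concatenate([b, skip], axis=1)
        d = self.relus[3].forward(self.dec1.forward(merged))
        return self.head.forward(d)

    def backward(self, dlogits: np.ndarray) -> None:
        dd = self.head.backward(dlogits)
        dmerged = self.dec1.backward(self.relus[3].backward(dd))
        f2 = 2 * self.width
        db = dmerged[:, :f2]
        dskip = dmerged[:, f2:]
        db = self.up.backward(db)
        db = self.mid.backward(self.relus[2].backward(db))
        dskip = dskip + self.pool.backward(db)
        da = self.enc2.backward(self.relus[1].backward(dskip))
        self.enc1.backward(self.relus[0].backward(da))

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """(N, C, H, W) any size -> per-pixel probabilities (N, K, H, W)."""
        n, c, h, w = x.shape
        ph, pw = h % 2, w % 2
        if ph or pw:
            x = np.pad(x, ((0, 0), (0, 0), (0, ph), (0, pw)), mode="edge")
        logits = self.forward(x)
        return softmax(logits[:, :, :h, :w], axis=1)

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{k}": p.value for k, p in enumerate(self.params)}

    def load_state(self, arrays: dict[str, np.ndarray]) -> None:
        for k, p in enumerate(self.params):
            p.value[...] = arrays[f"p{k}"]
        self.fitted = True
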