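"""Bidirectional LSTM sequence-to-sequence classifier with manual BPTT.

Sequences of unequal length are zero-padded and masked: padded steps
carry the hidden state through unchanged and contribute no loss.
"""

from __future__ import annotations

import numpy as np

from divtrap._nn.layers import Param, _he_init, softmax, softmax_xent
from divtrap._nn.optim import Adam


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class _LSTMDirection:
    """One direction of the biLSTM; gate order is (i, f, o, g)."""

    def __init__(self, din: int, hidden: int, rng: np.random.Generator) -> None:
        self.din, self.hidden = din, hidden
        h = hidden
        self.wx = Param(_he_init(rng, (din, 4 * h), din), "lstm.wx")
        self.wh = Param(_he_init(rng, (h, 4 * h), h), "lstm.wh")
        b = np.zeros(4 * h)
        b[h : 2 * h] = 1.0  # forget-gate bias, standard trick
        self.b = Param(b, "lstm.b")

    @property
    def params(self) -> list[Param]:
        return [self.wx, self.wh, self.b]

    def forward(self, x: np.ndarray, mask: np.ndarray, reverse: bool) -> np.ndarray:
        n, t, _ = x.shape
        h = self.hidden
        order = range(t - 1, -1, -1) if reverse else range(t)
        hs = np.zeros((n, t, h))
        hprev = np.zeros((n, h))
        cprev = np.zeros((n, h))
        cache = []
        for step in order:
            xt = x[:, step]
            m = mask[:, step][:, None]
            z = xt @ self.wx.value + hprev @ self.wh.value + self.b.value
            i = _sigmoid(z[:, :h])
            f = _sigmoid(z[:, h : 2 * h])
            o = _sigmoid(z[:, 2 * h : 3 * h])
            g = np.tanh(z[:, 3 * h :])
            c_new = f * cprev + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            hcur = m * h_new + (1.0 - m) * hprev
            ccur = m * c_new + (1.0 - m) * cprev
            hs[:, step] = hcur
            cache.append((step, xt, hprev, cprev, i, f, o, g, c_new, tc, m))
            hprev, cprev = hcur, ccur
        self._cache = cache
        return hs

    def backward(self, dhs: np.ndarray) -> np.ndarray:
        h = self.hidden
        dx = np.zeros((dhs.shape[0], dhs.shape[1], self.din))
        dh_next = np.zeros((dhs.shape[0], h))
        dc_next = np.zeros((dhs.shape[0], h))
        for step, xt, hprev, cprev, i, f, o, g, c_new, tc, m in reversed(self._cache):
            dh = dhs[:, step] + dh_next
            # gate through mask: masked steps pass gradient straight to prev
            dh_cell = m * dh
            dc_cell = m * dc_next
            do = dh_cell * tc
            dc = dc_cell + dh_cell * o * (1.0 - tc * tc)
            di = dc * g
            df = dc * cprev
            dg = dc * i
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    do * o * (1.0 - o),
                    dg * (1.0 - g * g),
                ],
                axis=1,
            )
            self.wx.grad += xt.T @ dz
            self.wh.grad += hprev.T @ dz
            self.b.grad += dz.sum(axis=0)
            dx[:, step] = dz @ self.wx.value.T
            dh_next = (1.0 - m) * dh + dz @ self.wh.value.T
            dc_next = (1.0 - m) * dc_next + dc * f
        return dx


class BiLSTMSeq2Seq:
    """biLSTM over feature sequences emitting per-frame class probabilities."""

    def __init__(self, din: int, n_classes: int, hidden: int = 150, seed: int = 0) -> None:
        rng = np.random.default_rng(seed)
        self.din = din
        self.n_classes = n_classes
        self.hidden = hidden
        self.fwd = _LSTMDirection(din, hidden, rng)
        self.bwd = _LSTMDirection(din, hidden, rng)
        # zero-init output head keeps training equivariant to class relabeling
        self.wo = Param(np.zeros((2 * hidden, n_classes)), "out.w")
        self.bo = Param(np.zeros(n_classes), "out.b")
        self.fitted = False

    @property
    def params(self) -> list[Param]:
        return self.fwd.params + self.bwd.params + [self.wo, self.bo]

    def _logits(self, x: np.ndarray, mask: np.ndarray) -> np.ndarray:
        hf = self.fwd.forward(x, mask, reverse=False)
        hb = self.bwd.forward(x, mask, reverse=True)
        self._h = np.concatenate([hf, hb], axis=2)
        return self._h @ self.wo.value + self.bo.value

    def _backward(self, dlogits: np.ndarray) -> None:
        n, t, _ = dlogits.shape
        hflat = self._h.reshape(n * t, -1)
        self.wo.grad += hflat.T @ dlogits.reshape(n * t, -1)
        self.bo.grad += dlogits.sum(axis=(0, 1))
        dh = dlogits @ self.wo.value.T
        half = self.hidden
        self.fwd.backward(dh[:, :, :half])
        self.bwd.backward(dh[:, :, half:])

    @staticmethod
    def _pad(sequences: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
        tmax = max(s.shape[0] for s in sequences)
        din = sequences[0].shape[1]
        x = np.zeros((len(sequences), tmax, din))
        mask = np.zeros((len(sequences), tmax))
        for k, s in enumerate(sequences):
            x[k, : s.shape[0]] = s
            mask[k, : s.shape[0]] = 1.0
        return x, mask

    def fit(
        self,
        sequences: list[np.ndarray],
        labels: list[np.ndarray],
        *,
        epochs: int = 40,
        lr: float = 1e-2,
        batch_size: int = 16,
        seed: int = 0,
        input_noise: float = 0.0,
        verbose: bool = False,
    ) -> list[float]:
        for s, y in zip(sequences, labels):
            if s.shape[0] != len(y):
                raise ValueError("feature/label sequence length mismatch")
        rng = np.random.default_rng(seed)
        opt = Adam(self.params, lr=lr)
        losses = []
        idx = np.arange(len(sequences))
        feat_scale = float(np.std(np.concatenate([s.ravel() for s in sequences])))
        for _ in range(epochs):
            rng.shuffle(idx)
            ep_loss = 0.0
            for start in range(0, len(idx), batch_size):
                sel = idx[start : start + batch_size]
                x, mask = self._pad([sequences[k] for k in sel])
                if input_noise > 0:
                    # jitter inputs so the model must lean on temporal
                    # context instead of copying per-frame features
                    x = x + rng.normal(0, input_noise * feat_scale, size=x.shape)
                ypad = np.zeros(x.shape[:2], dtype=int)
                for row, k in enumerate(sel):
                    ypad[row, : len(labels[k])] = labels[k]
                for p in self.params:
                    p.zero_grad()
                logits = self._logits(x, mask)
                n, t, ncls = logits.shape
                loss, dflat = softmax_xent(
                    logits.reshape(n * t, ncls), ypad.reshape(n * t), mask.reshape(n * t)
                )
                self._backward(dflat.reshape(n, t, ncls))
                opt.step()
                ep_loss += loss * len(sel)
            losses.append(ep_loss / len(idx))
        self.fitted = True
        return losses

    def predict_proba(self, sequence: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise RuntimeError("model is not fitted")
        x, mask = self._pad([np.asarray(sequence, dtype=np.float64)])
        logits = self._logits(x, mask)
        return softmax(logits[0], axis=1)

    def state_dict(self) -> dict[str, np.ndarray]:
        return {p.name + f".{k}": p.value for k, p in enumerate(self.params)}

    def load_state(self, arrays: dict[str, np.ndarray]) -> None:
        for k, p in enumerate(self.params):
            p.value[...] = arrays[p.name + f".{k}"]
        self.fitted = True
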