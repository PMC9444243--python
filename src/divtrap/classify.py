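"""Per-frame cell/trap state classification and biLSTM sequence classification.

Six states in canonical order: unbud, small, large, dead, clog, empty.
The frame classifier is a small configurable conv net (a large backbone
buys nothing at trap-image scale); the sequence model is a bidirectional
LSTM over the conv net's penultimate-layer activations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.transform import resize

from divtrap import CLASS_INDEX, CLASSES
from divtrap._nn import Adam, BiLSTMSeq2Seq, Sequential, softmax, softmax_xent
from divtrap._nn.layers import Conv2d, Dense, Flatten, MaxPool2x2, ReLU
from divtrap.roi import TrapMovie


class DegenerateTrainingError(ValueError):
    """Training set contains fewer than two classes."""


class NotFittedError(RuntimeError):
    pass


class IncompatibleModelsError(ValueError):
    """CNN feature width does not match the LSTM input width."""


@dataclass
class LabelSequence:
    """Per-frame class labels with optional T x 6 class probabilities."""

    labels: list[str]
    probs: np.ndarray | None = None
    frame_interval_min: float = 5.0

    def __post_init__(self) -> None:
        for lab in self.labels:
            if lab not in CLASS_INDEX:
                raise ValueError(f"unknown class label {lab!r}")
        if self.probs is not None:
            self.probs = np.asarray(self.probs, dtype=np.float64)
            if self.probs.shape != (len(self.labels), len(CLASSES)):
                raise ValueError("probs must be T x 6")
            if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-6):
                raise ValueError("probability rows must sum to 1")
            agree = [
                CLASSES[int(np.argmax(row))] == lab
                for row, lab in zip(self.probs, self.labels)
            ]
            if not all(agree):
                raise ValueError("labels must equal argmax(probs) (ties -> class order)")

    def __len__(self) -> int:
        return len(self.labels)

    def indices(self) -> np.ndarray:
        return np.array([CLASS_INDEX[lab] for lab in self.labels], dtype=int)


@dataclass
class TrainConfig:
    epochs: int = 30
    learning_rate: float = 3e-3
    batch_size: int = 64
    seed: int = 0
    optimizer: str = "adam"


@dataclass
class ClassifierModel:
    """Fitted frame classifier: conv backbone + linear class head."""

    input_size: tuple[int, int]
    in_channels: int
    conv_widths: list[int]
    feature_dim: int
    config: TrainConfig
    net: Sequential | None = None
    classes: tuple[str, ...] = CLASSES
    train_accuracy: float | None = None
    loss_history: list[float] = field(default_factory=list)
    resized_inputs: bool = False

    @property
    def fitted(self) -> bool:
        return self.net is not None and self.train_accuracy is not None


def build_frame_cnn(
    input_size: tuple[int, int] = (48, 48),
    in_channels: int = 3,
    conv_widths: list[int] | None = None,
    feature_dim: int = 32,
    seed: int = 0,
) -> ClassifierModel:
    conv_widths = list(conv_widths or [8, 16, 32])
    h, w = input_size
    if h % (2 ** len(conv_widths)) or w % (2 ** len(conv_widths)):
        raise ValueError("input size must be divisible by 2**n_conv_blocks")
    rng = np.random.default_rng(seed)
    layers: list = []
    cin = in_channels
    for cw in conv_widths:
        layers += [Conv2d(cin, cw, 3, rng=rng), ReLU(), MaxPool2x2()]
        cin = cw
    hh, ww = h // 2 ** len(conv_widths), w // 2 ** len(conv_widths)
    layers += [Flatten(), Dense(hh * ww * cin, feature_dim, rng=rng), ReLU()]
    # zero-init head => training is equivariant under class relabeling
    layers += [Dense(feature_dim, len(CLASSES), zero_init=True)]
    return ClassifierModel(
        input_size=(h, w),
        in_channels=in_channels,
        conv_widths=conv_widths,
        feature_dim=feature_dim,
        config=TrainConfig(seed=seed),
        net=Sequential(layers),
    )


def _prep_images(model: ClassifierModel, images: np.ndarray) -> np.ndarray:
    """(N, H, W, C) -> (N, C, h, w) float, resized to the model input size."""
    images = np.asarray(images, dtype=np.float64)
    if images.ndim == 3:
        images = images[..., None]
    if images.shape[-1] != model.in_channels:
        raise ValueError(
            f"expected {model.in_channels} channels, got {images.shape[-1]}"
        )
    h, w = model.input_size
    if images.shape[1:3] != (h, w):
        images = np.stack(
            [resize(im, (h, w, model.in_channels), preserve_range=True) for im in images]
        )
        model.resized_inputs = True
    return np.transpose(images, (0, 3, 1, 2))


def train_frame_cnn(
    images: np.ndarray,
    labels: list[str],
    config: TrainConfig | None = None,
    *,
    model: ClassifierModel | None = None,
) -> ClassifierModel:
    """Fit the per-frame classifier with Adam on cross-entropy.

    Reproducible given ``config.seed`` (init + shuffling use one RNG).
    """
    config = config or TrainConfig()
    y = np.array([CLASS_INDEX[lab] for lab in labels], dtype=int)
    if len(np.unique(y)) < 2:
        raise DegenerateTrainingError("training set must contain at least two classes")
    images = np.asarray(images, dtype=np.float64)
    if images.ndim == 3:
        images = images[..., None]
    if model is None:
        h0, w0 = images.shape[1:3]
        insize = (h0, w0) if (h0 % 8 == 0 and w0 % 8 == 0) else (48, 48)
        model = build_frame_cnn(
            input_size=insize, in_channels=images.shape[-1], seed=config.seed
        )
    model.config = config
    x = _prep_images(model, images)
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.net.params, lr=config.learning_rate)
    idx = np.arange(len(y))
    for _ in range(config.epochs):
        rng.shuffle(idx)
        ep_loss = 0.0
        for start in range(0, len(idx), config.batch_size):
            sel = idx[start : start + config.batch_size]
            for p in model.net.params:
                p.zero_grad()
            logits = model.net.forward(x[sel])
            loss, dlogits = softmax_xent(logits, y[sel])
            model.net.backward(dlogits)
            opt.step()
            ep_loss += loss * len(sel)
        model.loss_history.append(ep_loss / len(idx))
    preds = np.argmax(model.net.forward(x), axis=1)
    model.train_accuracy = float(np.mean(preds == y))
    return model


def _forward_batched(model: ClassifierModel, x: np.ndarray, upto=None, batch=256):
    outs = [model.net.forward(x[i : i + batch], upto=upto) for i in range(0, len(x), batch)]
    return np.concatenate(outs, axis=0)


def classify_frames(model: ClassifierModel, movie: TrapMovie) -> LabelSequence:
    """Statelessly classify every frame of a movie."""
    if not model.fitted:
        raise NotFittedError("frame classifier is not fitted")
    x = _prep_images(model, movie.frames)
    probs = softmax(_forward_batched(model, x), axis=1)
    labels = [CLASSES[int(k)] for k in np.argmax(probs, axis=1)]
    return LabelSequence(labels=labels, probs=probs, frame_interval_min=movie.frame_interval_min)


def extract_features(model: ClassifierModel, movie: TrapMovie) -> np.ndarray:
    """Penultimate-layer activations, shape (T, feature_dim)."""
    if not model.fitted:
        raise NotFittedError("frame classifier is not fitted")
    x = _prep_images(model, movie.frames)
    return _forward_batched(model, x, upto=-1)


def train_sequence_lstm(
    feature_sequences: list[np.ndarray],
    label_sequences: list[LabelSequence] | list[list[str]],
    *,
    hidden: int = 150,
    epochs: int = 40,
    learning_rate: float = 1e-2,
    batch_size: int = 16,
    seed: int = 0,
    input_noise: float = 0.0,
) -> BiLSTMSeq2Seq:
    """Fit the biLSTM sequence model on CNN feature sequences."""
    ys = []
    for seq in label_sequences:
        if isinstance(seq, LabelSequence):
            ys.append(seq.indices())
        else:
            ys.append(np.array([CLASS_INDEX[lab] for lab in seq], dtype=int))
    for f, y in zip(feature_sequences, ys):
        if f.shape[0] != len(y):
            raise ValueError("feature and label sequences differ in length")
    din = feature_sequences[0].shape[1]
    lstm = BiLSTMSeq2Seq(din, len(CLASSES), hidden=hidden, seed=seed)
    lstm.fit(
        [np.asarray(f, dtype=np.float64) for f in feature_sequences],
        ys,
        epochs=epochs,
        lr=learning_rate,
        batch_size=batch_size,
        seed=seed,
        input_noise=input_noise,
    )
    return lstm


def classify_sequence(
    cnn: ClassifierModel,
    lstm: BiLSTMSeq2Seq,
    movie: TrapMovie,
    *,
    smooth_window: int = 3,
) -> LabelSequence:
    """Full CNN -> biLSTM sequence classification of one movie.

    Output probabilities are temporally averaged over ``smooth_window``
    frames (odd; 1 disables), which suppresses single-frame flip-flops
    at marginal decisions. Deterministic given the models.
    """
    if not lstm.fitted:
        raise NotFittedError("sequence model is not fitted")
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ValueError("smooth_window must be a positive odd integer")
    feats = extract_features(cnn, movie)
    if feats.shape[1] != lstm.din:
        raise IncompatibleModelsError(
            f"CNN feature width {feats.shape[1]} != LSTM input width {lstm.din}"
        )
    probs = lstm.predict_proba(feats)
    if smooth_window > 1 and probs.shape[0] > 1:
        from scipy.ndimage import uniform_filter1d

        probs = uniform_filter1d(probs, size=smooth_window, axis=0, mode="nearest")
        probs /= probs.sum(axis=1, keepdims=True)
    labels = [CLASSES[int(k)] for k in np.argmax(probs, axis=1)]
    return LabelSequence(labels=labels, probs=probs, frame_interval_min=movie.frame_interval_min)


def postprocess_cnn_labels(seq: LabelSequence) -> LabelSequence:
    """Remove isolated 'dead' frames (two consecutive are required for death).

    An isolated 'dead' frame (neither neighbour 'dead' in the input) is
    relabeled to the nearest preceding non-'dead' label; at the first
    frame, to the nearest following non-'dead' label. Runs of >= 2 'dead'
    are untouched. Idempotent.
    """
    labels = list(seq.labels)
    t = len(labels)
    out = list(labels)
    for k in range(t):
        if labels[k] != "dead":
            continue
        prev_dead = k > 0 and labels[k - 1] == "dead"
        next_dead = k < t - 1 and labels[k + 1] == "dead"
        if prev_dead or next_dead:
            continue
        repl = None
        for j in range(k - 1, -1, -1):
            if labels[j] != "dead":
                repl = labels[j]
                break
        if repl is None:
            for j in range(k + 1, t):
                if labels[j] != "dead":
                    repl = labels[j]
                    break
        if repl is not None:
            out[k] = repl
    return LabelSequence(labels=out, probs=None, frame_interval_min=seq.frame_interval_min)


# ---------------------------------------------------------------------------
# persistence: one binary blob + JSON sidecar


def save_frame_cnn(model: ClassifierModel, path: str | Path) -> None:
    path = Path(path)
    arrays = {f"p{k}": p.value for k, p in enumerate(model.net.params)}
    np.savez(path.with_suffix(".npz"), **arrays)
    sidecar = {
        "kind": "frame_cnn",
        "input_size": list(model.input_size),
        "in_channels": model.in_channels,
        "conv_widths": model.conv_widths,
        "feature_dim": model.feature_dim,
        "classes": list(model.classes),
        "train_accuracy": model.train_accuracy,
        "config": vars(model.config),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_frame_cnn(path: str | Path) -> ClassifierModel:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    model = build_frame_cnn(
        input_size=tuple(sidecar["input_size"]),
        in_channels=sidecar["in_channels"],
        conv_widths=sidecar["conv_widths"],
        feature_dim=sidecar["feature_dim"],
    )
    with np.load(path.with_suffix(".npz")) as data:
        for k, p in enumerate(model.net.params):
            p.value[...] = data[f"p{k}"]
    model.train_accuracy = sidecar["train_accuracy"]
    model.config = TrainConfig(**sidecar["config"])
    return model


def save_lstm(lstm: BiLSTMSeq2Seq, path: str | Path) -> None:
    path = Path(path)
    arrays = {f"p{k}": p.value for k, p in enumerate(lstm.params)}
    np.savez(path.with_suffix(".npz"), **arrays)
    sidecar = {
        "kind": "bilstm",
        "din": lstm.din,
        "n_classes": lstm.n_classes,
        "hidden": lstm.hidden,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_lstm(path: str | Path) -> BiLSTMSeq2Seq:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    lstm = BiLSTMSeq2Seq(sidecar["din"], sidecar["n_classes"], hidden=sidecar["hidden"])
    with np.load(path.with_suffix(".npz")) as data:
        for k, p in enumerate(lstm.params):
            p.value[...] = data[f"p{k}"]
    lstm.fitted = True
    return lstm
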