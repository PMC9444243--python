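"""Semantic segmentation of trap images and per-cell quantification.

Brightfield masks use three classes (0 background, 1 mother, 2 other);
fluorescence masks use two (0 background, 1 nucleus). The segmenter is
a tiny fully-convolutional encoder/decoder; two normalized coordinate
channels are appended to the input so the net can exploit the conserved
central position of the mother in the trap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from divtrap._nn import TinyEncoderDecoder

BRIGHTFIELD_CLASSES = ("background", "mother", "other")
NUCLEUS_CLASSES = ("background", "nucleus")


@dataclass
class SegmentationMask:
    """Per-pixel class map plus per-class probability maps for one frame."""

    class_map: np.ndarray  # (H, W) int
    prob_maps: np.ndarray  # (K, H, W)
    threshold_used: float
    classes: tuple[str, ...] = BRIGHTFIELD_CLASSES

    def __post_init__(self) -> None:
        self.class_map = np.asarray(self.class_map, dtype=int)
        self.prob_maps = np.asarray(self.prob_maps, dtype=np.float64)
        k = len(self.classes)
        if self.prob_maps.shape[0] != k:
            raise ValueError("one probability map per class required")
        if not np.allclose(self.prob_maps.sum(axis=0), 1.0, atol=1e-6):
            raise ValueError("per-pixel probabilities must sum to 1")
        if self.class_map.min() < 0 or self.class_map.max() >= k:
            raise ValueError("class_map contains invalid codes")


@dataclass
class SegmenterModel:
    net: TinyEncoderDecoder
    classes: tuple[str, ...]
    in_channels: int
    use_coords: bool = True
    target_class: int = 1
    loss_history: list[float] = field(default_factory=list)

    @property
    def fitted(self) -> bool:
        return self.net.fitted


def _coord_channels(h: int, w: int) -> np.ndarray:
    rr = np.linspace(-1.0, 1.0, h)[:, None] * np.ones((1, w))
    cc = np.ones((h, 1)) * np.linspace(-1.0, 1.0, w)[None, :]
    return np.stack([rr, cc])


def _prep(model_channels: int, use_coords: bool, images: np.ndarray) -> np.ndarray:
    """(N, H, W[, C]) -> (N, C+2, H, W) with coordinate channels appended."""
    images = np.asarray(images, dtype=np.float64)
    if images.ndim == 3:
        images = images[..., None]
    if images.shape[-1] != model_channels:
        raise ValueError(f"expected {model_channels} image channels")
    x = np.transpose(images, (0, 3, 1, 2))
    if use_coords:
        n, _, h, w = x.shape
        coords = np.broadcast_to(_coord_channels(h, w), (n, 2, h, w))
        x = np.concatenate([x, coords], axis=1)
    return x


class InvalidLabelError(ValueError):
    pass


def train_segmenter(
    images: np.ndarray,
    masks: np.ndarray,
    classes: tuple[str, ...] = BRIGHTFIELD_CLASSES,
    *,
    width: int = 8,
    epochs: int = 20,
    learning_rate: float = 3e-3,
    batch_size: int = 8,
    seed: int = 0,
    use_coords: bool = True,
) -> SegmenterModel:
    """Fit the encoder/decoder on images + integer masks (pixel CE loss)."""
    from divtrap._nn import Adam, softmax_xent

    images = np.asarray(images, dtype=np.float64)
    masks = np.asarray(masks, dtype=int)
    if images.ndim == 3:
        images = images[..., None]
    if images.shape[:3] != masks.shape:
        raise ValueError("image and mask shapes differ")
    k = len(classes)
    if masks.min() < 0 or masks.max() >= k:
        raise InvalidLabelError("masks contain codes outside the class set")
    in_channels = images.shape[-1]
    cin = in_channels + (2 if use_coords else 0)
    net = TinyEncoderDecoder(cin, k, width=width, seed=seed)
    model = SegmenterModel(net=net, classes=classes, in_channels=in_channels, use_coords=use_coords)
    x = _prep(in_channels, use_coords, images)
    rng = np.random.default_rng(seed)
    opt = Adam(net.params, lr=learning_rate)
    idx = np.arange(len(masks))
    for _ in range(epochs):
        rng.shuffle(idx)
        ep_loss = 0.0
        for start in range(0, len(idx), batch_size):
            sel = idx[start : start + batch_size]
            for p in net.params:
                p.zero_grad()
            logits = net.forward(x[sel])
            n, kk, h, w = logits.shape
            flat = logits.transpose(0, 2, 3, 1).reshape(-1, kk)
            y = masks[sel].reshape(-1)
            loss, dflat = softmax_xent(flat, y)
            net.backward(dflat.reshape(n, h, w, kk).transpose(0, 3, 1, 2))
            opt.step()
            ep_loss += loss * len(sel)
        model.loss_history.append(ep_loss / len(idx))
    net.fitted = True
    return model


def predict_proba(model: SegmenterModel, image: np.ndarray) -> np.ndarray:
    """Per-class probability maps (K, H, W) for a single image."""
    if not model.fitted:
        raise RuntimeError("segmenter is not fitted")
    x = _prep(model.in_channels, model.use_coords, np.asarray(image)[None])
    return model.net.predict_proba(x)[0]


def predict_mask(
    model: SegmenterModel,
    image: np.ndarray,
    threshold: float = 0.5,
    *,
    trap_center: tuple[float, float] | None = None,
) -> SegmentationMask:
    """Threshold the target class and keep the central mother component.

    A pixel gets the target class iff its probability >= threshold,
    otherwise the argmax of the remaining classes. For 3-class masks only
    the connected component of the mother class whose centroid is
    nearest ``trap_center`` (default: image center) is kept as mother;
    the rest is relabeled 'other'.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    probs = predict_proba(model, image)
    k, h, w = probs.shape
    tc = model.target_class
    others = [i for i in range(k) if i != tc]
    class_map = np.asarray(others, dtype=int)[np.argmax(probs[others], axis=0)]
    class_map = np.where(probs[tc] >= threshold, tc, class_map)
    if "mother" in model.classes and "other" in model.classes:
        other_code = model.classes.index("other")
        class_map = _keep_central_component(class_map, tc, other_code, trap_center)
    return SegmentationMask(
        class_map=class_map,
        prob_maps=probs,
        threshold_used=threshold,
        classes=model.classes,
    )


def _keep_central_component(
    class_map: np.ndarray,
    target: int,
    relabel_to: int,
    trap_center: tuple[float, float] | None,
) -> np.ndarray:
    h, w = class_map.shape
    center = trap_center or ((h - 1) / 2.0, (w - 1) / 2.0)
    comps = cc_label(class_map == target, connectivity=2)
    if comps.max() <= 1:
        return class_map
    best, best_d = None, np.inf
    for prop in regionprops(comps):
        d = (prop.centroid[0] - center[0]) ** 2 + (prop.centroid[1] - center[1]) ** 2
        if d < best_d:
            best, best_d = prop.label, d
    out = class_map.copy()
    out[(comps > 0) & (comps != best)] = relabel_to
    return out


def binary_metrics(true_mask: np.ndarray, pred_mask: np.ndarray) -> dict[str, float | None]:
    tp = int(np.sum(true_mask & pred_mask))
    fp = int(np.sum(~true_mask & pred_mask))
    fn = int(np.sum(true_mask & ~pred_mask))
    precision = tp / (tp + fp) if tp + fp else None
    recall = tp / (tp + fn) if tp + fn else None
    if precision and recall:
        f1 = 2 * precision * recall / (precision + recall)
    elif precision == 0.0 or recall == 0.0:
        f1 = 0.0
    else:
        f1 = None
    return {"tp": tp, "fp": fp, "fn": fn, "precision": precision, "recall": recall, "f1": f1}


def select_threshold(
    model: SegmenterModel,
    images: np.ndarray,
    masks: np.ndarray,
    grid: list[float] | np.ndarray,
) -> tuple[float, pd.DataFrame]:
    """Argmax-F1 threshold over a grid (ties -> larger threshold)."""
    grid = sorted(float(g) for g in grid)
    if not grid:
        raise ValueError("threshold grid is empty")
    if any(not 0 < g < 1 for g in grid):
        raise ValueError("grid values must lie in (0, 1)")
    images = np.asarray(images, dtype=np.float64)
    masks = np.asarray(masks, dtype=int)
    if len(images) == 0:
        raise ValueError("validation set is empty")
    tc = model.target_class
    rows = []
    for thr in grid:
        tp = fp = fn = 0
        for im, mk in zip(images, masks):
            pred = predict_mask(model, im, thr).class_map == tc
            tp += int(np.sum((mk == tc) & pred))
            fp += int(np.sum((mk != tc) & pred))
            fn += int(np.sum((mk == tc) & ~pred))
        precision = tp / (tp + fp) if tp + fp else None
        recall = tp / (tp + fn) if tp + fn else None
        f1 = (
            2 * precision * recall / (precision + recall)
            if precision and recall
            else (0.0 if (precision is not None or recall is not None) else None)
        )
        rows.append({"threshold": thr, "precision": precision, "recall": recall, "f1": f1})
    table = pd.DataFrame(rows)
    scored = table.dropna(subset=["f1"])
    if scored.empty:
        best = grid[-1]
    else:
        fmax = scored["f1"].max()
        best = float(scored.loc[scored["f1"] >= fmax - 1e-12, "threshold"].max())
    return best, table


@dataclass
class QuantTrace:
    """Per-frame geometry and fluorescence quantities."""

    mother_area_px: np.ndarray
    mother_area_um2: np.ndarray
    nucleus_area_px: np.ndarray
    total_nuclear_fluorescence: np.ndarray
    mean_cyto_fluorescence: np.ndarray
    pixel_size_um: float

    def to_frame(self, frame_interval_min: float = 5.0) -> pd.DataFrame:
        t = np.arange(len(self.mother_area_px))
        return pd.DataFrame(
            {
                "frame": t,
                "time_min": t * frame_interval_min,
                "mother_area_px": self.mother_area_px,
                "mother_area_um2": self.mother_area_um2,
                "nucleus_area_px": self.nucleus_area_px,
                "total_nuclear_fluorescence": self.total_nuclear_fluorescence,
                "mean_cyto_fluorescence": self.mean_cyto_fluorescence,
            }
        )


def quantify(
    mother_masks: list[SegmentationMask] | list[np.ndarray],
    nucleus_masks: list[SegmentationMask] | list[np.ndarray] | None,
    fluo_frames: np.ndarray,
    pixel_size_um: float = 1.0,
) -> QuantTrace:
    """Areas and background-subtracted fluorescence per frame.

    Background is the per-frame median intensity over background-class
    pixels of the nucleus mask (or of the mother mask when no nucleus
    masks are supplied). Frames with an empty mother mask report area 0
    and an absent (NaN) cytoplasmic mean.
    """
    fluo = np.asarray(fluo_frames, dtype=np.float64)
    t = len(mother_masks)
    if fluo.shape[0] != t:
        raise ValueError("masks and fluorescence movie must align frame-by-frame")

    def as_map(m):
        return m.class_map if isinstance(m, SegmentationMask) else np.asarray(m, dtype=int)

    m_area = np.zeros(t)
    n_area = np.zeros(t)
    total_nuc = np.zeros(t)
    mean_cyto = np.full(t, np.nan)
    for k in range(t):
        mmap = as_map(mother_masks[k])
        mother = mmap == 1
        m_area[k] = mother.sum()
        frame = fluo[k]
        if nucleus_masks is not None:
            nmap = as_map(nucleus_masks[k])
            nucleus = nmap == 1
            bg_pixels = frame[nmap == 0]
        else:
            nucleus = np.zeros_like(mother)
            bg_pixels = frame[mmap == 0]
        background = float(np.median(bg_pixels)) if bg_pixels.size else 0.0
        n_area[k] = nucleus.sum()
        total_nuc[k] = float((frame[nucleus] - background).sum())
        if mother.any():
            mean_cyto[k] = float((frame[mother] - background).mean())
    return QuantTrace(
        mother_area_px=m_area,
        mother_area_um2=m_area * pixel_size_um**2,
        nucleus_area_px=n_area,
        total_nuclear_fluorescence=total_nuc,
        mean_cyto_fluorescence=mean_cyto,
        pixel_size_um=pixel_size_um,
    )


def cross_validate_segmenter(
    images: np.ndarray,
    masks: np.ndarray,
    *,
    n_draws: int = 30,
    n_train: int = 200,
    n_test: int = 50,
    seed: int = 0,
    threshold: float = 0.5,
    classes: tuple[str, ...] = BRIGHTFIELD_CLASSES,
    **train_kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random train/test draws; per-draw precision/recall/F1 + summary.

    Draws are without replacement within a draw and independent across
    draws; everything derives from ``seed``.
    """
    images = np.asarray(images, dtype=np.float64)
    masks = np.asarray(masks, dtype=int)
    n = len(images)
    if n_train + n_test > n:
        raise ValueError("n_train + n_test exceeds the annotated set size")
    rng = np.random.default_rng(seed)
    rows = []
    for draw in range(n_draws):
        perm = rng.permutation(n)
        tr, te = perm[:n_train], perm[n_train : n_train + n_test]
        model = train_segmenter(
            images[tr], masks[tr], classes, seed=int(rng.integers(2**31)), **train_kwargs
        )
        tp = fp = fn = 0
        tc = model.target_class
        for im, mk in zip(images[te], masks[te]):
            pred = predict_mask(model, im, threshold).class_map == tc
            tp += int(np.sum((mk == tc) & pred))
            fp += int(np.sum((mk != tc) & pred))
            fn += int(np.sum((mk == tc) & ~pred))
        precision = tp / (tp + fp) if tp + fp else np.nan
        recall = tp / (tp + fn) if tp + fn else np.nan
        f1 = (
            2 * precision * recall / (precision + recall)
            if (tp + fp) and (tp + fn) and (precision + recall)
            else np.nan
        )
        rows.append({"draw": draw, "precision": precision, "recall": recall, "f1": f1})
    table = pd.DataFrame(rows)
    summary = table[["precision", "recall", "f1"]].agg(["mean", "std"])
    return table, summary
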