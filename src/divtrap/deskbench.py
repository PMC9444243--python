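"""Desk-scale end-to-end benchmark protocol on synthetic data.

Everything trains on 1 CPU in minutes: a tiny frame CNN + biLSTM on 100
synthetic movies (150 frames, 48x48 px) tested on 50 held-out movies, a
tiny encoder/decoder segmenter on 200 frames, and a SEP biLSTM on 200
probability sequences tested on 100 cells. Used by the acceptance tests;
all randomness derives from the seeds passed in.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np

from divtrap.benchmarks import (
    class_metrics,
    confusion_matrix,
    correlation_r2,
    pair_generation_events,
)
from divtrap.classify import (
    ClassifierModel,
    LabelSequence,
    TrainConfig,
    classify_sequence,
    extract_features,
    train_frame_cnn,
    train_sequence_lstm,
)
from divtrap.lifespan import reconstruct_lifespan
from divtrap.segment import predict_mask, select_threshold, train_segmenter
from divtrap.sep import predict_sep, train_sep_lstm
from divtrap.survival import logrank_test
from divtrap.trapsynth import (
    HistoryParams,
    RenderParams,
    SynthScene,
    render_trap_movie,
    simulate_cell_history,
)

DESK_HISTORY = HistoryParams(
    t_frames=150,
    death_hazard=0.06,
    sep_hazard=0.08,
    clog_prob=0.10,
    empty_prob=0.08,
    initial_unbud_frames=6,
)
# fixed mother size for the state classifier (budding state is the signal);
# the segmenter cohort below varies it so area recovery is measurable
DESK_RENDER = RenderParams(
    height=48,
    width=48,
    with_fluorescence=False,
    mother_radius_range=(8.0, 8.0),
    mother_growth_per_gen=0.0,
)
# dimmer buds give the segmenter an intensity cue at the mother/bud
# boundary, where the per-pixel classes would otherwise be ambiguous
SEG_RENDER = RenderParams(
    height=48, width=48, with_fluorescence=False, bud_level_frac=0.78
)

SEP_HISTORY = HistoryParams(
    t_frames=400,
    death_hazard=0.0,
    death_hazard_post=0.10,
    sep_hazard=0.15,
    pre_cv=0.15,
    initial_unbud_frames=3,
)


def make_scenes(
    n: int,
    base_seed: int,
    params: HistoryParams = DESK_HISTORY,
    render: RenderParams = DESK_RENDER,
) -> list[SynthScene]:
    return [
        render_trap_movie(
            simulate_cell_history(params, seed=base_seed + s),
            render,
            seed=base_seed + 77_777 + s,
        )
        for s in range(n)
    ]


def truth_sequence(scene: SynthScene) -> LabelSequence:
    return LabelSequence(
        labels=scene.truth.per_frame_labels,
        frame_interval_min=scene.truth.params.frame_interval_min,
    )


def balanced_frames(scenes, per_class: int, seed: int, with_masks: bool = False):
    """Class-balanced frame sample across scenes (images, labels[, masks])."""
    rng = np.random.default_rng(seed)
    by_class = defaultdict(list)
    for sc in scenes:
        for t, lab in enumerate(sc.truth.per_frame_labels):
            by_class[lab].append((sc, t))
    images, labels, masks = [], [], []
    for lab, entries in sorted(by_class.items()):
        idx = rng.choice(len(entries), size=min(per_class, len(entries)), replace=False)
        for i in idx:
            sc, t = entries[i]
            images.append(sc.movie.frames[t, :, :, 0])
            labels.append(lab)
            masks.append(sc.masks[t])
    images = np.stack(images)[..., None]
    if with_masks:
        return images, labels, np.stack(masks)
    return images, labels


def train_pipeline(train_scenes: list[SynthScene], seed: int = 0):
    """Frame CNN (18 epochs) + biLSTM (hidden 48, input-noise 0.3)."""
    images, labels = balanced_frames(train_scenes, per_class=350, seed=seed + 42)
    cnn = train_frame_cnn(images, labels, TrainConfig(epochs=18, seed=seed))
    feats = [extract_features(cnn, _bf(sc)) for sc in train_scenes]
    labs = [sc.truth.per_frame_labels for sc in train_scenes]
    lstm = train_sequence_lstm(
        feats, labs, hidden=48, epochs=40, seed=seed + 1, input_noise=0.3
    )
    return cnn, lstm


def _bf(scene: SynthScene):
    movie = scene.movie
    if movie.frames.shape[-1] > 1:
        from divtrap.roi import TrapMovie

        return TrapMovie(
            frames=movie.frames[:, :, :, :1],
            frame_interval_min=movie.frame_interval_min,
            channel_names=["brightfield"],
            roi_id=movie.roi_id,
        )
    return movie


@dataclass
class PipelineMetrics:
    per_class_f1: dict[str, float]
    frame_error: float
    event_tp: int
    event_fp: int
    event_fn: int
    ghost_free_fraction: float
    cycle_duration_r2: float
    rls_r2: float
    logrank_p: float


def evaluate_pipeline(
    cnn: ClassifierModel,
    lstm,
    test_scenes: list[SynthScene],
    *,
    tolerance_frames: int = 2,
) -> PipelineMetrics:
    all_true, all_pred = [], []
    tp = fp = fn = 0
    ghost_free = 0
    dur_t, dur_p = [], []
    rls_t, rls_p = [], []
    for sc in test_scenes:
        seq = classify_sequence(cnn, lstm, _bf(sc), smooth_window=5)
        all_true += sc.truth.per_frame_labels
        all_pred += seq.labels
        rec = reconstruct_lifespan(seq)
        tru = reconstruct_lifespan(truth_sequence(sc))
        pairing = pair_generation_events(
            tru.budding_frames, rec.budding_frames, tolerance_frames
        )
        tp += pairing.tp
        fp += pairing.fp
        fn += pairing.fn
        ghost_free += pairing.fp == 0
        match = dict(pairing.pairs)
        for a, b in zip(tru.budding_frames, tru.budding_frames[1:]):
            if a in match and b in match and match[b] > match[a]:
                dur_t.append((b - a) * tru.frame_interval_min)
                dur_p.append((match[b] - match[a]) * rec.frame_interval_min)
        if not tru.excluded and not rec.excluded:
            rls_t.append(tru.rls)
            rls_p.append(rec.rls)
    metrics = class_metrics(confusion_matrix(all_true, all_pred))
    return PipelineMetrics(
        per_class_f1=metrics["f1"].dropna().to_dict(),
        frame_error=float(np.mean([a != b for a, b in zip(all_true, all_pred)])),
        event_tp=tp,
        event_fp=fp,
        event_fn=fn,
        ghost_free_fraction=ghost_free / len(test_scenes),
        cycle_duration_r2=correlation_r2(dur_t, dur_p),
        rls_r2=correlation_r2(rls_t, rls_p),
        logrank_p=logrank_test(
            [(r, False) for r in rls_t], [(r, False) for r in rls_p]
        )[1],
    )


@dataclass
class SegmenterMetrics:
    threshold: float
    mother_f1: float
    mother_precision: float
    mother_recall: float
    area_r2: float


def run_segmenter_benchmark(
    seed: int = 0,
    *,
    n_train_frames: int = 200,
    n_test_frames: int = 100,
    epochs: int = 40,
    learning_rate: float = 5e-3,
) -> SegmenterMetrics:
    """Train the tiny segmenter on class-stratified frames; test area recovery."""
    params = HistoryParams(
        t_frames=30,
        death_hazard=0.10,
        sep_hazard=0.05,
        clog_prob=0.0,
        empty_prob=0.05,
        initial_unbud_frames=3,
    )
    train_scenes = make_scenes(50, seed * 1000 + 1, params, SEG_RENDER)
    test_scenes = make_scenes(25, seed * 1000 + 70_001, params, SEG_RENDER)
    per = max(1, n_train_frames // 5)
    xtr, _, mtr = balanced_frames(train_scenes, per_class=per, seed=seed + 3, with_masks=True)
    xte, _, mte = balanced_frames(
        test_scenes, per_class=max(1, n_test_frames // 5), seed=seed + 4, with_masks=True
    )
    model = train_segmenter(
        xtr[..., 0], mtr, epochs=epochs, learning_rate=learning_rate, seed=seed
    )
    best, _ = select_threshold(model, xte[:30, ..., 0], mte[:30], [0.3, 0.5, 0.7, 0.9])
    tp = fp = fn = 0
    area_t, area_p = [], []
    for im, mk in zip(xte[..., 0], mte):
        pred = predict_mask(model, im, best).class_map
        tp += int(np.sum((mk == 1) & (pred == 1)))
        fp += int(np.sum((mk != 1) & (pred == 1)))
        fn += int(np.sum((mk == 1) & (pred != 1)))
        area_t.append(int((mk == 1).sum()))
        area_p.append(int((pred == 1).sum()))
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    return SegmenterMetrics(
        threshold=best,
        mother_f1=2 * precision * recall / (precision + recall),
        mother_precision=precision,
        mother_recall=recall,
        area_r2=correlation_r2(area_t, area_p),
    )


@dataclass
class SepMetrics:
    per_frame_accuracy: float
    within_2_fraction: float
    n_test: int


def _soft_probs(labels: list[str], rng: np.random.Generator, conf: float = 0.9) -> np.ndarray:
    index = {"unbud": 0, "small": 1, "large": 2, "dead": 3}
    t = len(labels)
    p = np.full((t, 4), (1.0 - conf) / 3.0)
    for k, lab in enumerate(labels):
        p[k, index.get(lab, 0)] = conf
    p = p + rng.uniform(0, 0.05, size=p.shape)
    return p / p.sum(axis=1, keepdims=True)


def run_sep_benchmark(
    seed: int = 0, *, n_train: int = 200, n_test: int = 100, epochs: int = 30
) -> SepMetrics:
    """Train the pre/post-SEP biLSTM on soft class-probability sequences."""
    rng = np.random.default_rng(seed + 11)

    def cohort(n, base):
        seqs, states, hists = [], [], []
        s = base
        while len(seqs) < n:
            h = simulate_cell_history(SEP_HISTORY, seed=s)
            s += 1
            if h.sep_frame is None or h.rls < 4:
                continue
            seqs.append(_soft_probs(h.per_frame_labels, rng))
            states.append(h.sep_states())
            hists.append(h)
        return seqs, states, hists

    tr_s, tr_st, _ = cohort(n_train, seed * 1000)
    te_s, te_st, te_h = cohort(n_test, seed * 1000 + 500_000)
    model = train_sep_lstm(tr_s, tr_st, hidden=32, epochs=epochs, seed=seed + 5)
    acc = []
    within = 0
    for probs, states, h in zip(te_s, te_st, te_h):
        rec = predict_sep(model, probs, budding_frames=h.budding_frames)
        acc.append(np.mean([a == b for a, b in zip(rec.per_frame_state, states)]))
        if (
            rec.sep_generation is not None
            and h.sep_generation is not None
            and abs(rec.sep_generation - h.sep_generation) <= 2
        ):
            within += 1
    return SepMetrics(
        per_frame_accuracy=float(np.mean(acc)),
        within_2_fraction=within / n_test,
        n_test=n_test,
    )
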