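"""Senescence-entry-point (SEP) detection.

A biLSTM sequence-to-sequence classifier assigns pre/post labels per
frame from the four cell-state probabilities (unbud, small, large,
dead); raw predictions are reduced to a single changepoint minimizing
disagreement. A rule-based detector on cycle durations serves as an
independent oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from divtrap._nn import BiLSTMSeq2Seq

SEP_INPUT_CLASSES = ("unbud", "small", "large", "dead")


@dataclass
class SEPRecord:
    sep_frame: int | None
    sep_generation: int | None
    per_frame_state: list[str]  # 'pre_sep' / 'post_sep'
    method: str  # 'lstm' | 'rule'
    roi_id: str = "roi"
    n_raw_disagreements: int = 0
    changepoint_index: int | None = None

    def __post_init__(self) -> None:
        states = self.per_frame_state
        if any(s not in ("pre_sep", "post_sep") for s in states):
            raise ValueError("states must be pre_sep/post_sep")
        # enforced changepoint: all pre before all post
        first_post = next((k for k, s in enumerate(states) if s == "post_sep"), None)
        if first_post is not None and any(s == "pre_sep" for s in states[first_post:]):
            raise ValueError("per_frame_state must be a single changepoint")
        if first_post != self.changepoint_index:
            raise ValueError("changepoint_index must be the first post_sep index")


def best_changepoint(raw_post: np.ndarray) -> tuple[int, int]:
    """Split index minimizing disagreement with raw binary predictions.

    raw_post: length-T 0/1 array (1 = post). Returns (split, cost);
    split in [0, T], frames >= split are post. Ties -> earliest split.
    """
    raw_post = np.asarray(raw_post, dtype=int)
    # cost(s) = (#post in [0, s)) + (#pre in [s, T))
    post_before = np.concatenate([[0], np.cumsum(raw_post)])
    pre_after = (len(raw_post) - post_before[-1]) - (
        np.arange(len(raw_post) + 1) - post_before
    )
    costs = post_before + pre_after
    split = int(np.argmin(costs))
    return split, int(costs[split])


def train_sep_lstm(
    prob_sequences: list[np.ndarray],
    state_sequences: list[list[str]] | list[np.ndarray],
    *,
    hidden: int = 150,
    epochs: int = 40,
    learning_rate: float = 1e-2,
    batch_size: int = 16,
    seed: int = 0,
) -> BiLSTMSeq2Seq:
    """Fit the pre/post classifier on T x 4 class-probability sequences."""
    ys = []
    single_state = 0
    for states in state_sequences:
        if isinstance(states, np.ndarray) and states.dtype != object:
            y = np.asarray(states, dtype=int)
        else:
            y = np.array([0 if s == "pre_sep" else 1 for s in states], dtype=int)
        if len(np.unique(y)) < 2:
            single_state += 1
        ys.append(y)
    if single_state:
        import warnings

        warnings.warn(
            f"{single_state} training sequence(s) contain a single state",
            stacklevel=2,
        )
    seqs = [np.asarray(p, dtype=np.float64) for p in prob_sequences]
    if any(s.shape[1] != len(SEP_INPUT_CLASSES) for s in seqs):
        raise ValueError("probability sequences must be T x 4")
    model = BiLSTMSeq2Seq(len(SEP_INPUT_CLASSES), 2, hidden=hidden, seed=seed)
    model.fit(seqs, ys, epochs=epochs, lr=learning_rate, batch_size=batch_size, seed=seed)
    return model


def predict_sep(
    model: BiLSTMSeq2Seq,
    prob_sequence: np.ndarray,
    *,
    budding_frames: list[int] | None = None,
    roi_id: str = "roi",
) -> SEPRecord:
    """Per-frame prediction reduced to a single changepoint.

    SEP is absent when the best split is the sequence end. When
    ``budding_frames`` is given, ``sep_generation`` is the number of
    budding events at or before the SEP frame.
    """
    probs = np.asarray(prob_sequence, dtype=np.float64)
    if probs.ndim != 2 or probs.shape[0] < 1:
        raise ValueError("prob_sequence must be T x 4 with T >= 1")
    raw = np.argmax(model.predict_proba(probs), axis=1)
    split, cost = best_changepoint(raw)
    t = len(raw)
    states = ["pre_sep"] * split + ["post_sep"] * (t - split)
    sep_frame = split if split < t else None
    sep_gen = None
    if sep_frame is not None and budding_frames is not None:
        sep_gen = int(sum(1 for b in budding_frames if b <= sep_frame))
    return SEPRecord(
        sep_frame=sep_frame,
        sep_generation=sep_gen,
        per_frame_state=states,
        method="lstm",
        roi_id=roi_id,
        n_raw_disagreements=cost,
        changepoint_index=sep_frame,
    )


def sep_rule_oracle(
    cycle_durations: list[float] | np.ndarray,
    *,
    threshold_factor: float = 1.5,
    budding_frames: list[int] | None = None,
    roi_id: str = "roi",
) -> SEPRecord:
    """Rule-based SEP: first generation whose cycle duration exceeds
    ``threshold_factor`` x median of all prior durations and stays
    elevated for >= 2 of the next 3 generations (or all remaining, when
    fewer than 2 remain)."""
    d = np.asarray(cycle_durations, dtype=np.float64)
    n = len(d)
    sep_gen = None
    if n >= 3:
        for g in range(1, n):
            thr = threshold_factor * float(np.median(d[:g]))
            if d[g] <= thr:
                continue
            nxt = d[g + 1 : g + 4]
            if len(nxt) == 0 or np.sum(nxt > thr) >= min(2, len(nxt)):
                sep_gen = g
                break
    if sep_gen is None:
        states = ["pre_sep"] * n
        sep_frame = None
    else:
        states = ["pre_sep"] * sep_gen + ["post_sep"] * (n - sep_gen)
        sep_frame = (
            int(budding_frames[sep_gen]) if budding_frames is not None else sep_gen
        )
    return SEPRecord(
        sep_frame=sep_frame,
        sep_generation=sep_gen,
        per_frame_state=states,
        method="rule",
        roi_id=roi_id,
        changepoint_index=sep_gen,
    )
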