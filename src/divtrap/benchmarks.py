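"""Classifier and event-detection benchmarking.

Confusion matrices and per-class precision/recall/F1 in the canonical
six-class order, tolerance-based one-to-one pairing of generation
events (optimal assignment), correlation metrics, and a whole-pipeline
report combining frame, event and survival comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from divtrap import CLASS_INDEX, CLASSES
from divtrap.lifespan import LifespanRecord
from divtrap.survival import km_estimate, logrank_test, ranksum_test


class UndefinedCorrelationError(ValueError):
    pass


def confusion_matrix(true_labels, pred_labels) -> np.ndarray:
    """6x6 counts; rows = truth, columns = prediction, canonical order."""
    if len(true_labels) != len(pred_labels):
        raise ValueError("label lists differ in length")
    m = np.zeros((len(CLASSES), len(CLASSES)), dtype=int)
    for t, p in zip(true_labels, pred_labels):
        m[CLASS_INDEX[t], CLASS_INDEX[p]] += 1
    return m


def class_metrics(confusion: np.ndarray) -> pd.DataFrame:
    """Per-class precision/recall/F1; undefined values reported as NaN."""
    confusion = np.asarray(confusion)
    if (confusion < 0).any():
        raise ValueError("confusion counts must be non-negative")
    rows = []
    for k, name in enumerate(CLASSES):
        tp = confusion[k, k]
        fp = confusion[:, k].sum() - tp
        fn = confusion[k, :].sum() - tp
        precision = tp / (tp + fp) if tp + fp else np.nan
        recall = tp / (tp + fn) if tp + fn else np.nan
        if np.isnan(precision) or np.isnan(recall):
            f1 = np.nan
        elif precision + recall == 0:
            f1 = 0.0
        else:
            f1 = 2 * precision * recall / (precision + recall)
        rows.append({"class": name, "precision": precision, "recall": recall, "f1": f1})
    return pd.DataFrame(rows).set_index("class")


@dataclass
class EventPairing:
    tp: int
    fp: int
    fn: int
    pairs: list[tuple[int, int]]  # (true_frame, pred_frame)
    total_offset: int

    @property
    def precision(self) -> float | None:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else None

    @property
    def recall(self) -> float | None:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else None


def pair_generation_events(
    true_events, pred_events, tolerance_frames: int = 2
) -> EventPairing:
    """One-to-one event matching within a frame tolerance.

    Maximizes the number of matched pairs with |Δframe| <= tolerance,
    then minimizes the total |Δframe| (optimal assignment). Unmatched
    predicted events are FP, unmatched true events FN.
    """
    true_events = list(true_events)
    pred_events = list(pred_events)
    if true_events != sorted(true_events) or pred_events != sorted(pred_events):
        raise ValueError("event lists must be ascending")
    if tolerance_frames < 0:
        raise ValueError("tolerance must be >= 0")
    n, m = len(true_events), len(pred_events)
    if n == 0 or m == 0:
        return EventPairing(tp=0, fp=m, fn=n, pairs=[], total_offset=0)
    cost = np.abs(
        np.asarray(true_events, dtype=float)[:, None]
        - np.asarray(pred_events, dtype=float)[None, :]
    )
    # infeasible penalty large enough that max cardinality always wins
    penalty = (min(n, m) + 1) * (tolerance_frames + 1.0)
    cost = np.where(cost <= tolerance_frames, cost, penalty)
    rows, cols = linear_sum_assignment(cost)
    pairs = [
        (true_events[i], pred_events[j])
        for i, j in zip(rows, cols)
        if cost[i, j] <= tolerance_frames
    ]
    tp = len(pairs)
    total = int(sum(abs(a - b) for a, b in pairs))
    return EventPairing(tp=tp, fp=m - tp, fn=n - tp, pairs=sorted(pairs), total_offset=total)


def correlation_r2(x, y) -> float:
    """Squared Pearson correlation coefficient."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("x and y must share a length >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation undefined for a constant vector")
    r = np.corrcoef(x, y)[0, 1]
    return float(r**2)


@dataclass
class BenchmarkReport:
    confusion: np.ndarray | None
    per_class: pd.DataFrame | None
    event_tp: int = 0
    event_fp: int = 0
    event_fn: int = 0
    event_precision: float | None = None
    event_recall: float | None = None
    cycle_duration_r2: float | None = None
    rls_r2: float | None = None
    ranksum_p: float | None = None
    logrank_p: float | None = None
    n_cells: int = 0
    per_cell_pairings: dict[str, EventPairing] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "confusion": None if self.confusion is None else self.confusion.tolist(),
            "per_class": None
            if self.per_class is None
            else self.per_class.reset_index().to_dict(orient="records"),
            "event_tp": self.event_tp,
            "event_fp": self.event_fp,
            "event_fn": self.event_fn,
            "event_precision": self.event_precision,
            "event_recall": self.event_recall,
            "cycle_duration_r2": self.cycle_duration_r2,
            "rls_r2": self.rls_r2,
            "ranksum_p": self.ranksum_p,
            "logrank_p": self.logrank_p,
            "n_cells": self.n_cells,
        }


def benchmark_pipeline(
    records_true: dict[str, LifespanRecord],
    records_pred: dict[str, LifespanRecord],
    *,
    labels_true: dict[str, list[str]] | None = None,
    labels_pred: dict[str, list[str]] | None = None,
    tolerance_frames: int = 2,
) -> BenchmarkReport:
    """Aggregate frame, event, duration, and survival benchmarks.

    Inputs are keyed by roi_id; only common ids are compared.
    """
    common = sorted(set(records_true) & set(records_pred))
    if not common:
        raise ValueError("no common roi_ids between truth and predictions")

    confusion = None
    per_class = None
    if labels_true is not None and labels_pred is not None:
        lab_ids = sorted(set(labels_true) & set(labels_pred) & set(common))
        all_t = [lab for rid in lab_ids for lab in labels_true[rid]]
        all_p = [lab for rid in lab_ids for lab in labels_pred[rid]]
        confusion = confusion_matrix(all_t, all_p)
        per_class = class_metrics(confusion)

    tp = fp = fn = 0
    pairings: dict[str, EventPairing] = {}
    dur_true: list[float] = []
    dur_pred: list[float] = []
    for rid in common:
        rt, rp = records_true[rid], records_pred[rid]
        pairing = pair_generation_events(
            rt.budding_frames, rp.budding_frames, tolerance_frames
        )
        pairings[rid] = pairing
        tp += pairing.tp
        fp += pairing.fp
        fn += pairing.fn
        # paired consecutive true events -> matched cycle-duration pairs
        match = dict(pairing.pairs)
        for a, b in zip(rt.budding_frames, rt.budding_frames[1:]):
            if a in match and b in match and match[b] > match[a]:
                dur_true.append((b - a) * rt.frame_interval_min)
                dur_pred.append((match[b] - match[a]) * rp.frame_interval_min)

    rls_t = [records_true[rid].rls for rid in common]
    rls_p = [records_pred[rid].rls for rid in common]
    try:
        rls_r2 = correlation_r2(rls_t, rls_p)
    except (ValueError, UndefinedCorrelationError):
        rls_r2 = None
    try:
        cyc_r2 = correlation_r2(dur_true, dur_pred) if len(dur_true) >= 2 else None
    except UndefinedCorrelationError:
        cyc_r2 = None

    all_dur_t = [d for rid in common for d in records_true[rid].cycle_durations_min]
    all_dur_p = [d for rid in common for d in records_pred[rid].cycle_durations_min]
    ranksum_p = (
        ranksum_test(all_dur_t, all_dur_p)[1] if all_dur_t and all_dur_p else None
    )
    try:
        logrank_p = logrank_test(
            [records_true[rid] for rid in common],
            [records_pred[rid] for rid in common],
        )[1]
    except ValueError:
        logrank_p = None

    report = BenchmarkReport(
        confusion=confusion,
        per_class=per_class,
        event_tp=tp,
        event_fp=fp,
        event_fn=fn,
        event_precision=tp / (tp + fp) if tp + fp else None,
        event_recall=tp / (tp + fn) if tp + fn else None,
        cycle_duration_r2=cyc_r2,
        rls_r2=rls_r2,
        ranksum_p=ranksum_p,
        logrank_p=logrank_p,
        n_cells=len(common),
        per_cell_pairings=pairings,
    )
    return report


def km_median(records) -> float | None:
    """Median RLS per the declared convention (no interpolation)."""
    return km_estimate(records).median
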