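"""Budding-event detection, stop rules, and lifespan reconstruction.

A budding event is the entry into a new cell cycle, read off the label
sequence as a transition into 'small' from 'large' or 'unbud' (with an
optional fallback counting unbud->large transitions where the 'small'
frame was skipped). The lifespan stops at the earliest of: a 'dead'
frame, a division arrest longer than the arrest window (default 10 h),
a 'clog' frame, or an 'empty' frame; clog/empty records are flagged
excluded from survival analyses, and sequences reaching the final frame
without a stop are right-censored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from divtrap.classify import LabelSequence, postprocess_cnn_labels


@dataclass
class LifespanRecord:
    roi_id: str
    budding_frames: list[int]
    cycle_durations_min: list[float]
    death_frame: int | None
    end_reason: str  # dead | arrest | clog | empty | end_of_movie
    censored: bool
    rls: int
    frame_interval_min: float
    excluded: bool = False
    end_frame: int | None = None
    fallback_events: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.end_reason not in {"dead", "arrest", "clog", "empty", "end_of_movie"}:
            raise ValueError(f"bad end_reason {self.end_reason!r}")
        if list(self.budding_frames) != sorted(set(self.budding_frames)):
            raise ValueError("budding_frames must be strictly increasing")
        if self.censored != (self.end_reason == "end_of_movie"):
            raise ValueError("censored iff end_reason == end_of_movie")
        if self.rls != len(self.budding_frames):
            raise ValueError("rls must equal the number of budding events")


def detect_budding_events(
    seq: LabelSequence | list[str], *, skipped_small_fallback: bool = True
) -> list[int]:
    """Frames at which a new generation starts.

    An event at every frame t with label 'small' whose predecessor is
    'large' or 'unbud' (frame 0 counts if already 'small'); with the
    fallback enabled, an unbud->large transition also counts (bud
    appeared and crossed the size threshold between two frames).
    """
    labels = seq.labels if isinstance(seq, LabelSequence) else list(seq)
    events = []
    for t, lab in enumerate(labels):
        if lab == "small":
            if t == 0 or labels[t - 1] in ("large", "unbud"):
                events.append(t)
        elif skipped_small_fallback and lab == "large":
            if t > 0 and labels[t - 1] == "unbud":
                events.append(t)
    return events


def _fallback_frames(labels: list[str]) -> set[int]:
    return {
        t
        for t in range(1, len(labels))
        if labels[t] == "large" and labels[t - 1] == "unbud"
    }


def reconstruct_lifespan(
    seq: LabelSequence,
    *,
    roi_id: str = "roi",
    arrest_window_min: float = 600.0,
    pp_mode: str = "none",
    skipped_small_fallback: bool = True,
) -> LifespanRecord:
    """Apply the stop rules to a label sequence and build a LifespanRecord.

    ``pp_mode='cnn_pp'`` first removes isolated 'dead' frames, so death
    requires two consecutive 'dead' labels; with ``pp_mode='none'`` the
    first 'dead' frame stops the lifespan.
    """
    if pp_mode not in ("none", "cnn_pp"):
        raise ValueError("pp_mode must be 'none' or 'cnn_pp'")
    interval = seq.frame_interval_min
    if interval <= 0:
        raise ValueError("frame_interval_min must be set and positive")
    if pp_mode == "cnn_pp":
        seq = postprocess_cnn_labels(seq)
    labels = list(seq.labels)
    t_total = len(labels)
    window = int(round(arrest_window_min / interval))

    events = detect_budding_events(seq, skipped_small_fallback=skipped_small_fallback)

    # tie-break at an equal stop frame: a class label occurs AT its frame,
    # while an arrest timestamped r+window is only established strictly
    # after it ("more than 10 h"), so labels win ties
    candidates: list[tuple[int, int, str]] = []  # (frame, priority, reason)
    for reason, prio in (("dead", 1), ("clog", 2), ("empty", 3)):
        hits = [t for t, lab in enumerate(labels) if lab == reason]
        if hits:
            candidates.append((hits[0], prio, reason))
    # division arrest: > window frames without a new budding event, counted
    # from frame 0 and from every event
    refs = [0] + events
    for r in refs:
        nxt = next((e for e in events if e > r), None)
        gap_end = nxt if nxt is not None else t_total - 1
        if gap_end - r > window:
            candidates.append((r + window, 4, "arrest"))
            break  # earliest arrest only

    if candidates:
        stop_frame, _, reason = min(candidates, key=lambda c: (c[0], c[1]))
        kept = [e for e in events if e < stop_frame]
        death_frame = stop_frame if reason in ("dead", "arrest") else None
        excluded = reason in ("clog", "empty")
        censored = False
    else:
        stop_frame = t_total - 1
        reason = "end_of_movie"
        kept = list(events)
        death_frame = None
        excluded = False
        censored = True

    fallback = sorted(set(kept) & _fallback_frames(labels))
    durations = [float((b - a) * interval) for a, b in zip(kept, kept[1:])]
    return LifespanRecord(
        roi_id=roi_id,
        budding_frames=kept,
        cycle_durations_min=durations,
        death_frame=death_frame,
        end_reason=reason,
        censored=censored,
        rls=len(kept),
        frame_interval_min=interval,
        excluded=excluded,
        end_frame=stop_frame,
        fallback_events=fallback,
    )


@dataclass
class AlignedTrace:
    offsets: np.ndarray  # aligned index grid, anchor at 0
    matrix: np.ndarray  # n_records x len(offsets), NaN where unavailable
    mean: np.ndarray
    sem: np.ndarray
    counts: np.ndarray
    n_skipped: int = 0


def align_trajectories(
    traces: list[np.ndarray | list[float]],
    anchors: list[int | None],
) -> AlignedTrace:
    """Shift per-record traces so their anchors coincide at index 0.

    Records with a missing (None) anchor are skipped and counted.
    """
    usable = [
        (np.asarray(tr, dtype=np.float64), a)
        for tr, a in zip(traces, anchors)
        if a is not None
    ]
    n_skipped = len(traces) - len(usable)
    if not usable:
        raise ValueError("no records with an anchor")
    lo = min(-a for _, a in usable)
    hi = max(len(tr) - a for tr, a in usable)
    offsets = np.arange(lo, hi)
    matrix = np.full((len(usable), len(offsets)), np.nan)
    for row, (tr, a) in enumerate(usable):
        matrix[row, -a - lo : -a - lo + len(tr)] = tr
    counts = np.sum(~np.isnan(matrix), axis=0)
    import warnings as _warnings

    with np.errstate(invalid="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(matrix, axis=0)
        sd = np.nanstd(matrix, axis=0, ddof=1)
    sem = np.where(counts > 1, sd / np.sqrt(np.maximum(counts, 1)), 0.0)
    return AlignedTrace(offsets, matrix, mean, sem, counts, n_skipped)


def death_fraction_trace(records: list[LifespanRecord], t_total: int) -> np.ndarray:
    """Per-frame fraction of (non-excluded) cells dead; non-decreasing."""
    kept = [r for r in records if not r.excluded]
    if not kept:
        raise ValueError("no non-excluded records")
    deaths = np.array(
        [r.death_frame for r in kept if r.death_frame is not None], dtype=int
    )
    frames = np.arange(t_total)
    return (deaths[None, :] <= frames[:, None]).sum(axis=1) / len(kept)
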