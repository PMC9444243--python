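"""Stochastic single-cell division histories.

Cycle durations are lognormal: short and regular before the SEP, with a
doubled mean and a linear per-generation increase after it. Death is a
constant per-generation hazard (geometric lifespan in the default
setting), so analytic checks against the geometric law are available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np


@dataclass
class HistoryParams:
    t_frames: int = 150
    frame_interval_min: float = 5.0
    # pre-SEP cycle-duration law (lognormal, minutes)
    pre_mean_min: float = 90.0
    pre_cv: float = 0.15
    # post-SEP law: mean raised by a factor plus a per-generation slope
    post_mean_factor: float = 2.0
    post_slope_min: float = 15.0
    post_cv: float = 0.15
    # per-generation hazards
    death_hazard: float = 0.05
    death_hazard_post: float | None = None  # None -> same as death_hazard
    sep_hazard: float = 0.0
    min_generations_before_sep: int = 3
    initial_unbud_frames: int = 2
    # cap keeps any inter-budding gap below the 10-h arrest window
    max_cycle_frames: int = 100
    # rare trap-level scenarios
    clog_prob: float = 0.0
    empty_prob: float = 0.0

    def validate(self) -> None:
        if self.t_frames < 1:
            raise ValueError("t_frames must be >= 1")
        if self.frame_interval_min <= 0:
            raise ValueError("frame_interval_min must be > 0")
        for name in ("pre_mean_min", "post_mean_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("pre_cv", "post_cv", "post_slope_min", "initial_unbud_frames"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("death_hazard", "sep_hazard", "clog_prob", "empty_prob"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class CellHistory:
    budding_frames: list[int]
    sep_frame: int | None
    sep_generation: int | None
    death_frame: int | None
    end_reason: str
    per_frame_labels: list[str]
    params: HistoryParams
    cycle_durations_min: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        bf = self.budding_frames
        if any(b >= a for a, b in zip(bf[1:], bf)):
            raise ValueError("budding_frames must be strictly increasing")
        if self.death_frame is not None and bf and bf[-1] >= self.death_frame:
            raise ValueError("budding_frames must precede death_frame")
        if self.sep_frame is not None:
            if not bf or not bf[0] <= self.sep_frame:
                raise ValueError("sep_frame must follow the first budding")
            if self.death_frame is not None and self.sep_frame >= self.death_frame:
                raise ValueError("sep_frame must precede death_frame")
        if self.death_frame is not None and any(
            lab != "dead" for lab in self.per_frame_labels[self.death_frame :]
        ):
            raise ValueError("labels after death must all be 'dead'")

    @property
    def rls(self) -> int:
        return len(self.budding_frames)

    def sep_states(self) -> list[str]:
        """Per-frame pre/post SEP groundtruth."""
        t = len(self.per_frame_labels)
        if self.sep_frame is None:
            return ["pre_sep"] * t
        return ["pre_sep"] * self.sep_frame + ["post_sep"] * (t - self.sep_frame)


def _lognormal(rng: np.random.Generator, mean: float, cv: float) -> float:
    if cv == 0:
        return mean
    sigma2 = math.log(1.0 + cv**2)
    mu = math.log(mean) - sigma2 / 2.0
    return float(rng.lognormal(mu, math.sqrt(sigma2)))


def simulate_cell_history(params: HistoryParams, seed: int) -> CellHistory:
    """Draw one cell's full division history; reproducible given seed."""
    params.validate()
    rng = np.random.default_rng(seed)
    t_total = params.t_frames
    interval = params.frame_interval_min

    scenario = rng.random()
    if scenario < params.empty_prob:
        return CellHistory(
            budding_frames=[],
            sep_frame=None,
            sep_generation=None,
            death_frame=None,
            end_reason="empty",
            per_frame_labels=["empty"] * t_total,
            params=params,
        )
    clog_frame = None
    if scenario < params.empty_prob + params.clog_prob:
        clog_frame = int(rng.integers(t_total // 4, max(t_total // 4 + 1, 3 * t_total // 4)))

    labels = ["unbud"] * t_total
    budding_frames: list[int] = []
    durations_min: list[float] = []
    sep_frame: int | None = None
    sep_generation: int | None = None
    death_frame: int | None = None
    gen = 0
    cursor = params.initial_unbud_frames

    while cursor < t_total and death_frame is None:
        budding_frames.append(cursor)
        gen += 1
        if (
            sep_frame is None
            and params.sep_hazard > 0
            and gen > params.min_generations_before_sep
            and rng.random() < params.sep_hazard
        ):
            sep_frame = cursor
            sep_generation = gen
        if sep_frame is None:
            dur_min = _lognormal(rng, params.pre_mean_min, params.pre_cv)
            hazard = params.death_hazard
        else:
            mean = (
                params.pre_mean_min * params.post_mean_factor
                + params.post_slope_min * (gen - sep_generation)
            )
            dur_min = _lognormal(rng, mean, params.post_cv)
            hazard = (
                params.death_hazard
                if params.death_hazard_post is None
                else params.death_hazard_post
            )
        dur_frames = min(max(2, int(round(dur_min / interval))), params.max_cycle_frames)
        n_small = max(1, dur_frames // 2)
        end = min(cursor + dur_frames, t_total)
        for t in range(cursor, end):
            labels[t] = "small" if t - cursor < n_small else "large"
        if cursor + dur_frames <= t_total:
            durations_min.append(dur_frames * interval)
        if rng.random() < hazard:
            death_frame = cursor + dur_frames
        cursor += dur_frames

    end_reason = "end_of_movie"
    if death_frame is not None and death_frame < t_total:
        for t in range(death_frame, t_total):
            labels[t] = "dead"
        end_reason = "dead"
    else:
        death_frame = None

    budding_frames = [b for b in budding_frames if b < t_total]
    if sep_frame is not None and sep_frame >= t_total:
        sep_frame = sep_generation = None

    if clog_frame is not None:
        # trap overfills: truncate the history at the clog
        budding_frames = [b for b in budding_frames if b < clog_frame]
        if death_frame is not None and death_frame <= clog_frame:
            clog_frame = None  # died first, keep the death history
        else:
            for t in range(clog_frame, t_total):
                labels[t] = "clog"
            death_frame = None
            end_reason = "clog"
            if sep_frame is not None and sep_frame >= clog_frame:
                sep_frame = sep_generation = None
            durations_min = [
                (b - a) * interval for a, b in zip(budding_frames, budding_frames[1:])
            ]

    return CellHistory(
        budding_frames=budding_frames,
        sep_frame=sep_frame,
        sep_generation=sep_generation,
        death_frame=death_frame,
        end_reason=end_reason,
        per_frame_labels=labels,
        params=params,
        cycle_durations_min=durations_min,
    )
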