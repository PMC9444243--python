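"""Controlled corruption of label sequences, emulating classifier errors."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from divtrap import CLASSES
from divtrap.classify import LabelSequence


@dataclass
class LabelNoise:
    """flip_rate: per-frame probability of a uniform flip to another class;
    isolated_dead_rate: per-frame probability of injecting an isolated
    'dead' label (never two consecutive)."""

    flip_rate: float = 0.0
    isolated_dead_rate: float = 0.0

    def validate(self) -> None:
        for name in ("flip_rate", "isolated_dead_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


def corrupt_labels(
    seq: LabelSequence | list[str], noise: LabelNoise, seed: int
) -> LabelSequence:
    """Apply class flips then isolated-'dead' injections; seed-reproducible."""
    noise.validate()
    if isinstance(seq, LabelSequence):
        labels = list(seq.labels)
        interval = seq.frame_interval_min
    else:
        labels = list(seq)
        interval = 5.0
    rng = np.random.default_rng(seed)
    t = len(labels)

    if noise.flip_rate > 0:
        flips = rng.random(t) < noise.flip_rate
        for k in np.flatnonzero(flips):
            others = [c for c in CLASSES if c != labels[k]]
            labels[k] = others[int(rng.integers(len(others)))]

    if noise.isolated_dead_rate > 0:
        candidates = rng.random(t) < noise.isolated_dead_rate
        for k in np.flatnonzero(candidates):
            if labels[k] == "dead":
                continue
            if k > 0 and labels[k - 1] == "dead":
                continue
            if k < t - 1 and labels[k + 1] == "dead":
                continue
            labels[k] = "dead"

    return LabelSequence(labels=labels, probs=None, frame_interval_min=interval)
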