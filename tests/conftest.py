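"""Shared fixtures.

The heavy desk-scale training fixtures are session-scoped and lazy, so
module tests stay fast and the trained models are built once and shared
with the acceptance tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import pytest

from divtrap.classify import ClassifierModel, TrainConfig, train_frame_cnn
from divtrap.deskbench import balanced_frames, make_scenes, train_pipeline
from divtrap.trapsynth import SynthScene


@dataclass
class TrainedPipeline:
    cnn: ClassifierModel
    lstm: object
    train_scenes: list[SynthScene]
    test_scenes: list[SynthScene]


@pytest.fixture(scope="session")
def desk_pipeline() -> TrainedPipeline:
    """100 training + 50 test movies with a trained frame CNN + biLSTM."""
    train_scenes = make_scenes(100, 0)
    test_scenes = make_scenes(50, 5000)
    cnn, lstm = train_pipeline(train_scenes, seed=0)
    return TrainedPipeline(
        cnn=cnn, lstm=lstm, train_scenes=train_scenes, test_scenes=test_scenes
    )


@pytest.fixture(scope="session")
def tiny_cnn() -> ClassifierModel:
    """Frame classifier trained on 600 balanced frames (100 per class)."""
    scenes = make_scenes(20, 900)
    images, labels = balanced_frames(scenes, per_class=100, seed=7)
    return train_frame_cnn(
        images, labels, TrainConfig(epochs=15, batch_size=32, seed=3)
    )
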