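"""Frame CNN and sequence classifier contracts (desk-scale models)."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from divtrap import CLASSES
from divtrap.trapsynth import HistoryParams
from divtrap.classify import (
    DegenerateTrainingError,
    IncompatibleModelsError,
    LabelSequence,
    NotFittedError,
    TrainConfig,
    build_frame_cnn,
    classify_frames,
    classify_sequence,
    extract_features,
    load_frame_cnn,
    load_lstm,
    postprocess_cnn_labels,
    save_frame_cnn,
    save_lstm,
    train_frame_cnn,
    train_sequence_lstm,
)
from divtrap.deskbench import balanced_frames, make_scenes
from divtrap.roi import TrapMovie
from divtrap.trapsynth import HistoryParams


def small_training_set(seed=0, n=60):
    rng = np.random.default_rng(seed)
    images = rng.random((n, 16, 16, 1))
    labels = [CLASSES[i % 3] for i in range(n)]
    # make classes separable by mean intensity
    for k, lab in enumerate(labels):
        images[k] += CLASSES.index(lab)
    return images, labels


class TestLabelSequence:
    def test_probs_must_sum_to_one(self):
        with pytest.raises(ValueError):
            LabelSequence(labels=["large"], probs=np.array([[0.5, 0, 0, 0, 0, 0]]))

    def test_labels_must_match_argmax(self):
        probs = np.zeros((1, 6))
        probs[0, CLASSES.index("small")] = 1.0
        with pytest.raises(ValueError):
            LabelSequence(labels=["large"], probs=probs)

    def test_unknown_label(self):
        with pytest.raises(ValueError):
            LabelSequence(labels=["weird"])


TOY_CONFIG = dict(epochs=15, batch_size=8, learning_rate=1e-2)


class TestTrainFrameCnn:
    def test_single_class_rejected(self):
        images = np.zeros((10, 16, 16, 1))
        with pytest.raises(DegenerateTrainingError):
            train_frame_cnn(images, ["large"] * 10, TrainConfig(epochs=1))

    def test_seed_determinism(self):
        images, labels = small_training_set()
        preds = []
        for _ in range(2):
            model = train_frame_cnn(
                images, labels, TrainConfig(epochs=3, batch_size=8, seed=5)
            )
            movie = TrapMovie(frames=images[:10], frame_interval_min=5.0)
            preds.append(classify_frames(model, movie).probs)
        assert np.array_equal(preds[0], preds[1])

    def test_class_permutation_symmetry(self):
        images, labels = small_training_set()
        perm = {"unbud": "clog", "small": "empty", "large": "dead",
                "dead": "large", "clog": "unbud", "empty": "small"}
        movie = TrapMovie(frames=images[:12], frame_interval_min=5.0)
        base = train_frame_cnn(
            images, labels, TrainConfig(epochs=3, batch_size=8, seed=5)
        )
        permuted = train_frame_cnn(
            images,
            [perm[lab] for lab in labels],
            TrainConfig(epochs=3, batch_size=8, seed=5),
        )
        a = classify_frames(base, movie).labels
        b = classify_frames(permuted, movie).labels
        assert [perm[lab] for lab in a] == b

    def test_reports_training_accuracy(self):
        images, labels = small_training_set()
        model = train_frame_cnn(images, labels, TrainConfig(seed=1, **TOY_CONFIG))
        assert model.train_accuracy is not None
        assert model.train_accuracy > 0.9

    def test_per_class_f1_on_held_out_frames(self, tiny_cnn):
        # 600 balanced training frames -> F1 >= 0.85 per class on 300 frames
        from divtrap.benchmarks import class_metrics, confusion_matrix

        test_scenes = make_scenes(20, 8800) + make_scenes(
            3, 9900, params=HistoryParams(t_frames=150, empty_prob=1.0)
        )
        images, labels = balanced_frames(test_scenes, per_class=50, seed=8)
        seq = classify_frames(
            tiny_cnn, TrapMovie(frames=images, frame_interval_min=5.0)
        )
        table = class_metrics(confusion_matrix(labels, seq.labels))
        present = set(labels)
        for cls in present:
            assert table.loc[cls, "f1"] >= 0.85, (cls, table)


class TestClassifyFrames:
    def test_stateless_duplicate_frames(self, tiny_cnn):
        sc = make_scenes(1, 4242)[0]
        frames = np.concatenate([sc.movie.frames[:1], sc.movie.frames[:1]])
        movie = TrapMovie(frames=frames, frame_interval_min=5.0)
        seq = classify_frames(tiny_cnn, movie)
        assert np.array_equal(seq.probs[0], seq.probs[1])

    def test_probability_rows_normalized(self, tiny_cnn):
        sc = make_scenes(1, 4243)[0]
        seq = classify_frames(tiny_cnn, sc.movie)
        assert np.allclose(seq.probs.sum(axis=1), 1.0, atol=1e-6)

    def test_channel_mismatch_rejected(self, tiny_cnn):
        movie = TrapMovie(frames=np.zeros((2, 48, 48, 3)), frame_interval_min=5.0)
        with pytest.raises(ValueError):
            classify_frames(tiny_cnn, movie)

    def test_unfitted_model_rejected(self):
        model = build_frame_cnn()
        movie = TrapMovie(frames=np.zeros((1, 48, 48, 3)), frame_interval_min=5.0)
        with pytest.raises(NotFittedError):
            classify_frames(model, movie)

    def test_accuracy_on_noiseless_scenes(self):
        # model trained and tested on noiseless renders
        from divtrap.trapsynth import RenderParams

        rp = RenderParams(
            height=48, width=48, with_fluorescence=False,
            noise_sigma=0.0, signal_noise_frac=0.0,
            mother_radius_range=(8.0, 8.0), mother_growth_per_gen=0.0,
        )
        train_scenes = make_scenes(12, 300, render=rp)
        images, labels = balanced_frames(train_scenes, per_class=100, seed=8)
        model = train_frame_cnn(
            images, labels, TrainConfig(epochs=15, batch_size=32, seed=4)
        )
        correct = total = 0
        for sc in make_scenes(5, 8800, render=rp):
            seq = classify_frames(model, sc.movie)
            correct += sum(
                a == b for a, b in zip(seq.labels, sc.truth.per_frame_labels)
            )
            total += len(seq.labels)
        assert correct / total >= 0.9


class TestFeatures:
    def test_shape_and_determinism(self, tiny_cnn):
        sc = make_scenes(1, 4244)[0]
        feats = extract_features(tiny_cnn, sc.movie)
        assert feats.shape == (sc.movie.n_frames, tiny_cnn.feature_dim)
        frames = np.concatenate([sc.movie.frames[:1], sc.movie.frames[:1]])
        movie = TrapMovie(frames=frames, frame_interval_min=5.0)
        f2 = extract_features(tiny_cnn, movie)
        assert np.array_equal(f2[0], f2[1])

    def test_unfitted_error(self):
        model = build_frame_cnn()
        movie = TrapMovie(frames=np.zeros((1, 48, 48, 3)), frame_interval_min=5.0)
        with pytest.raises(NotFittedError):
            extract_features(model, movie)

    def test_features_linearly_separable(self, tiny_cnn):
        # probe classifier on two visually distinct classes
        scenes = make_scenes(6, 4250)
        feats, labels = [], []
        for sc in scenes:
            f = extract_features(tiny_cnn, sc.movie)
            for t, lab in enumerate(sc.truth.per_frame_labels):
                if lab in ("dead", "large"):
                    feats.append(f[t])
                    labels.append(lab == "dead")
        from sklearn.linear_model import LogisticRegression

        probe = LogisticRegression(max_iter=1000).fit(feats, labels)
        assert probe.score(feats, labels) >= 0.95


class TestSequenceLstm:
    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            train_sequence_lstm(
                [np.zeros((5, 4))], [["large"] * 6], hidden=4, epochs=1
            )

    def test_constant_label_sequences_fit_perfectly(self):
        rng = np.random.default_rng(0)
        feats = [rng.random((10, 4)) + (k % 2) for k in range(6)]
        labels = [["large" if k % 2 else "small"] * 10 for k in range(6)]
        lstm = train_sequence_lstm(feats, labels, hidden=8, epochs=30, seed=0)
        for f, labs in zip(feats, labels):
            pred = np.argmax(lstm.predict_proba(f), axis=1)
            assert all(CLASSES[i] == labs[0] for i in pred)

    def test_t1_movie(self, tiny_cnn):
        sc = make_scenes(1, 4260)[0]
        feats = [extract_features(tiny_cnn, sc.movie)]
        labels = [sc.truth.per_frame_labels]
        lstm = train_sequence_lstm(feats, labels, hidden=8, epochs=2, seed=0)
        movie = TrapMovie(frames=sc.movie.frames[:1], frame_interval_min=5.0)
        seq = classify_sequence(tiny_cnn, lstm, movie)
        assert len(seq) == 1
        assert np.allclose(seq.probs.sum(axis=1), 1.0, atol=1e-6)

    def test_incompatible_widths(self, tiny_cnn):
        from divtrap._nn import BiLSTMSeq2Seq

        lstm = BiLSTMSeq2Seq(tiny_cnn.feature_dim + 1, 6, hidden=4)
        lstm.fitted = True
        sc = make_scenes(1, 4261)[0]
        with pytest.raises(IncompatibleModelsError):
            classify_sequence(tiny_cnn, lstm, sc.movie)

    def test_smooth_window_validation(self, tiny_cnn):
        from divtrap._nn import BiLSTMSeq2Seq

        lstm = BiLSTMSeq2Seq(tiny_cnn.feature_dim, 6, hidden=4)
        lstm.fitted = True
        sc = make_scenes(1, 4262)[0]
        with pytest.raises(ValueError):
            classify_sequence(tiny_cnn, lstm, sc.movie, smooth_window=2)


class TestPostprocess:
    def test_isolated_dead_relabeled(self):
        seq = LabelSequence(labels=["large", "dead", "large"])
        assert postprocess_cnn_labels(seq).labels == ["large", "large", "large"]

    def test_dead_run_untouched(self):
        seq = LabelSequence(labels=["large", "dead", "dead", "dead"])
        assert postprocess_cnn_labels(seq).labels == ["large", "dead", "dead", "dead"]

    def test_leading_dead_uses_following_label(self):
        seq = LabelSequence(labels=["dead", "large", "small"])
        assert postprocess_cnn_labels(seq).labels == ["large", "large", "small"]

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            labels = [CLASSES[i] for i in rng.integers(0, 6, size=30)]
            once = postprocess_cnn_labels(LabelSequence(labels=labels))
            twice = postprocess_cnn_labels(once)
            assert once.labels == twice.labels

    def test_all_dead_unchanged(self):
        seq = LabelSequence(labels=["dead"] * 4)
        assert postprocess_cnn_labels(seq).labels == ["dead"] * 4

    @given(st.lists(st.sampled_from(CLASSES), min_size=1, max_size=40))
    @settings(max_examples=100, deadline=None)
    def test_property_idempotent_and_preserves_dead_runs(self, labels):
        once = postprocess_cnn_labels(LabelSequence(labels=labels))
        assert postprocess_cnn_labels(once).labels == once.labels
        # runs of >= 2 dead frames survive untouched
        for t in range(len(labels) - 1):
            if labels[t] == "dead" and labels[t + 1] == "dead":
                assert once.labels[t] == "dead"
                assert once.labels[t + 1] == "dead"


class TestPersistence:
    def test_cnn_round_trip(self, tiny_cnn, tmp_path):
        save_frame_cnn(tiny_cnn, tmp_path / "model")
        loaded = load_frame_cnn(tmp_path / "model")
        sc = make_scenes(1, 4270)[0]
        a = classify_frames(tiny_cnn, sc.movie).probs
        b = classify_frames(loaded, sc.movie).probs
        assert np.array_equal(a, b)

    def test_lstm_round_trip(self, tmp_path):
        rng = np.random.default_rng(2)
        feats = [rng.random((8, 4)) for _ in range(4)]
        labels = [["small"] * 8 for _ in range(4)]
        lstm = train_sequence_lstm(feats, labels, hidden=5, epochs=2, seed=0)
        save_lstm(lstm, tmp_path / "lstm")
        loaded = load_lstm(tmp_path / "lstm")
        assert np.array_equal(lstm.predict_proba(feats[0]), loaded.predict_proba(feats[0]))
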