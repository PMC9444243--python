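"""Budding-event detection, stop rules, alignment, and death fractions."""

import numpy as np
import pytest

from divtrap.classify import LabelSequence
from divtrap.lifespan import (
    align_trajectories,
    death_fraction_trace,
    detect_budding_events,
    LifespanRecord,
    reconstruct_lifespan,
)
from divtrap.trapsynth import HistoryParams, simulate_cell_history


def seq(labels, interval=5.0):
    return LabelSequence(labels=labels, frame_interval_min=interval)


class TestDetectBuddingEvents:
    def test_transition_rule(self):
        labels = ["unbud", "unbud", "small", "small", "large", "large", "small", "small", "large"]
        assert detect_budding_events(seq(labels)) == [2, 6]

    def test_all_large_no_events(self):
        assert detect_budding_events(seq(["large"] * 10)) == []

    def test_skipped_small_fallback(self):
        assert detect_budding_events(seq(["unbud", "large", "small"])) == [1, 2]

    def test_fallback_disabled(self):
        assert detect_budding_events(
            seq(["unbud", "large", "small"]), skipped_small_fallback=False
        ) == [2]

    def test_small_at_frame_zero_counts(self):
        assert detect_budding_events(seq(["small", "large"])) == [0]

    def test_brute_force_equivalence_on_random_sequences(self):
        # independent oracle: explicit enumeration of the transition pairs
        rng = np.random.default_rng(0)
        classes = ["unbud", "small", "large", "dead", "clog", "empty"]
        for _ in range(200):
            labels = [classes[i] for i in rng.integers(0, 6, size=30)]
            expected = []
            for t, lab in enumerate(labels):
                prev = labels[t - 1] if t else None
                if lab == "small" and prev in (None, "large", "unbud"):
                    expected.append(t)
                elif lab == "large" and prev == "unbud":
                    expected.append(t)
            assert detect_budding_events(seq(labels)) == expected


def brute_force_stop(labels, window):
    """Independent frame-by-frame scan of the four stop rules.

    At each frame, an overdue arrest (established strictly after its
    timestamp) fires before the frame's own label, because its stop
    frame lies in the past; a label at the same frame as the arrest
    timestamp beats the arrest.
    """
    events = set(detect_budding_events(seq(labels)))
    last_event = 0
    seen = []
    for t, lab in enumerate(labels):
        if t - last_event > window:
            stop = last_event + window
            return stop, "arrest", [e for e in seen if e < stop]
        if lab in ("dead", "clog", "empty"):
            return t, lab, [e for e in seen if e < t]
        if t in events:
            seen.append(t)
            last_event = t
    if (len(labels) - 1) - last_event > window:
        stop = last_event + window
        return stop, "arrest", [e for e in seen if e < stop]
    return None, "end_of_movie", seen


def oracle_mismatch(labels, window=120):
    rec = reconstruct_lifespan(seq(labels), arrest_window_min=window * 5.0)
    stop, reason, events = brute_force_stop(labels, window)
    if reason != rec.end_reason:
        return f"reason {reason} != {rec.end_reason} for {labels}"
    if events != rec.budding_frames:
        return f"events {events} != {rec.budding_frames}"
    return None


class TestReconstructLifespan:
    def test_arrest_after_ten_hours(self):
        labels = ["unbud", "small"] + ["large"] * 125
        rec = reconstruct_lifespan(seq(labels))
        assert rec.end_reason == "arrest"
        assert rec.rls == 1
        assert rec.death_frame == 1 + 120

    def test_dead_stop(self):
        rec = reconstruct_lifespan(seq(["unbud", "small", "large", "dead", "dead"]))
        assert rec.end_reason == "dead"
        assert rec.death_frame == 3
        assert rec.rls == 1
        assert not rec.censored

    def test_end_of_movie_censored(self):
        rec = reconstruct_lifespan(seq(["unbud", "small", "large", "small", "large"]))
        assert rec.end_reason == "end_of_movie"
        assert rec.censored
        assert rec.death_frame is None

    def test_clog_excluded(self):
        rec = reconstruct_lifespan(seq(["unbud", "small", "large", "clog", "clog"]))
        assert rec.end_reason == "clog"
        assert rec.excluded

    def test_cnn_pp_requires_two_dead_frames(self):
        labels = ["small", "large", "dead", "large", "small", "large"]
        plain = reconstruct_lifespan(seq(labels), pp_mode="none")
        pp = reconstruct_lifespan(seq(labels), pp_mode="cnn_pp")
        assert plain.end_reason == "dead"
        assert pp.end_reason == "end_of_movie"

    def test_invalid_pp_mode(self):
        with pytest.raises(ValueError):
            reconstruct_lifespan(seq(["large"]), pp_mode="bogus")

    def test_durations_match_event_spacing(self):
        labels = ["unbud"] * 2 + (["small"] * 9 + ["large"] * 9) * 3
        rec = reconstruct_lifespan(seq(labels))
        assert rec.budding_frames == [2, 20, 38]
        assert rec.cycle_durations_min == [90.0, 90.0]

    def test_stop_rule_precedence_brute_force_1000_random(self):
        rng = np.random.default_rng(1)
        classes = ["unbud", "small", "large", "dead", "clog", "empty"]
        # weights favour long live stretches so all rules get exercised
        w = np.array([0.1, 0.35, 0.4, 0.05, 0.05, 0.05])
        for _ in range(1000):
            labels = [classes[i] for i in rng.choice(6, size=200, p=w)]
            assert oracle_mismatch(labels) is None

    def test_generator_round_trip_500(self):
        params = HistoryParams(t_frames=150, death_hazard=0.08, sep_hazard=0.08)
        for s in range(500):
            h = simulate_cell_history(params, seed=s)
            rec = reconstruct_lifespan(seq(h.per_frame_labels))
            assert rec.budding_frames == h.budding_frames
            assert rec.rls == h.rls
            assert rec.end_reason == h.end_reason

    def test_conservation_invariant(self):
        params = HistoryParams(t_frames=150, death_hazard=0.05, sep_hazard=0.1)
        for s in range(50):
            h = simulate_cell_history(params, seed=s + 300)
            rec = reconstruct_lifespan(seq(h.per_frame_labels))
            assert rec.rls == len(rec.budding_frames)
            if len(rec.budding_frames) >= 2:
                assert sum(rec.cycle_durations_min) == pytest.approx(
                    (rec.budding_frames[-1] - rec.budding_frames[0]) * 5.0
                )


class TestRecordValidation:
    def test_censored_flag_must_match_end_reason(self):
        with pytest.raises(ValueError):
            LifespanRecord(
                roi_id="x",
                budding_frames=[1],
                cycle_durations_min=[],
                death_frame=None,
                end_reason="dead",
                censored=True,
                rls=1,
                frame_interval_min=5.0,
            )

    def test_rls_must_match_event_count(self):
        with pytest.raises(ValueError):
            LifespanRecord(
                roi_id="x",
                budding_frames=[1, 5],
                cycle_durations_min=[20.0],
                death_frame=10,
                end_reason="dead",
                censored=False,
                rls=3,
                frame_interval_min=5.0,
            )


class TestAlignTrajectories:
    def test_identical_trajectories_sem_zero(self):
        traces = [[1.0, 2.0, 3.0]] * 4
        out = align_trajectories(traces, [1] * 4)
        assert np.allclose(out.mean, [1, 2, 3])
        assert np.allclose(out.sem, 0)

    def test_anchor_shift(self):
        out = align_trajectories(
            [np.arange(6.0), np.arange(7.0)], [2, 5]
        )
        i0 = int(np.where(out.offsets == 0)[0][0])
        assert out.matrix[0, i0] == 2.0
        assert out.matrix[1, i0] == 5.0

    def test_missing_anchor_skipped(self):
        out = align_trajectories([[1.0, 2.0], [3.0, 4.0]], [0, None])
        assert out.n_skipped == 1
        assert out.matrix.shape[0] == 1

    def test_synthetic_sep_slowdown(self):
        params = HistoryParams(
            t_frames=400, death_hazard=0.0, death_hazard_post=0.05, sep_hazard=0.2
        )
        traces, anchors = [], []
        for s in range(300):
            h = simulate_cell_history(params, seed=s)
            if h.sep_generation is None or h.rls < h.sep_generation + 4:
                continue
            dur = [
                (b - a) * 5.0
                for a, b in zip(h.budding_frames, h.budding_frames[1:])
            ]
            traces.append(dur)
            anchors.append(h.sep_generation - 1)
        out = align_trajectories(traces, anchors)
        i = {off: k for k, off in enumerate(out.offsets)}
        assert out.mean[i[3]] >= 1.5 * out.mean[i[-3]]


class TestDeathFraction:
    def _rec(self, death_frame, reason="dead", excluded=False):
        censored = reason == "end_of_movie"
        return LifespanRecord(
            roi_id="r",
            budding_frames=[],
            cycle_durations_min=[],
            death_frame=death_frame,
            end_reason=reason,
            censored=censored,
            rls=0,
            frame_interval_min=5.0,
            excluded=excluded,
        )

    def test_no_deaths_zero_trace(self):
        recs = [self._rec(None, "end_of_movie") for _ in range(5)]
        assert np.all(death_fraction_trace(recs, 20) == 0)

    def test_step_at_common_death(self):
        recs = [self._rec(10) for _ in range(4)]
        trace = death_fraction_trace(recs, 15)
        assert np.all(trace[:10] == 0)
        assert np.all(trace[10:] == 1)

    def test_monotone_non_decreasing(self):
        rng = np.random.default_rng(2)
        recs = [self._rec(int(d)) for d in rng.integers(0, 50, size=100)]
        trace = death_fraction_trace(recs, 60)
        assert np.all(np.diff(trace) >= 0)

    def test_geometric_model_matches_cdf(self):
        # death at generation G ~ Geometric(p); at 18 frames per cycle the
        # death frame CDF follows the geometric law
        p = 0.1
        params = HistoryParams(
            t_frames=4000, pre_cv=0.0, death_hazard=p, sep_hazard=0.0,
            initial_unbud_frames=0,
        )
        from divtrap.lifespan import reconstruct_lifespan as rl

        recs = []
        for s in range(2000):
            h = simulate_cell_history(params, seed=s)
            recs.append(
                rl(LabelSequence(labels=h.per_frame_labels, frame_interval_min=5.0))
            )
        trace = death_fraction_trace(recs, 4000)
        for gens in (5, 10, 20):
            t = gens * 18
            expect = 1 - (1 - p) ** gens
            se = np.sqrt(expect * (1 - expect) / len(recs))
            assert abs(trace[t] - expect) < 3 * se + 1e-9
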