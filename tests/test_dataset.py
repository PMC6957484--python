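"""Labelling, eligibility, splitting, balancing and sequence assembly."""

import numpy as np
import pytest

from ecglow.dataset import (LABEL_GUARD, LABEL_LOW, LABEL_NORMAL, LABEL_RANGE,
                            LabeledBeat, balance_classes, build_segments,
                            check_eligibility, classify_glucose, label_beats,
                            split_nights)
from ecglow.preprocess import Beat
from ecglow.simulate import CGMSeries


def _beat(t: float) -> Beat:
    return Beat(r_time=t, r_index=int(t * 250), raw_window=np.zeros(160),
                series=np.zeros(53), activity=0.0)


def _labeled(t: float, glucose: float, mode: str = "train", night: int = 0) -> LabeledBeat:
    return LabeledBeat(beat=_beat(t), glucose=glucose,
                       label=classify_glucose(glucose, mode), night=night)


def _cgm(times, values):
    return CGMSeries(timestamps=np.asarray(times, dtype=float),
                     values=np.asarray(values, dtype=float),
                     lag_applied=300.0, mard_target=0.0)


class TestLabeling:
    def test_beat_reads_cgm_value_five_minutes_ahead(self):
        # beat at 01:00:00; step-wise readings; lag 300 s -> reading covering 01:05:00
        cgm = _cgm([3300, 3900, 4800], [5.0, 3.5, 6.0])
        out = label_beats([_beat(3600.0)], cgm, lag=300.0, mode="train")
        assert out[0].glucose == 3.5  # reading at 3900 covers [3900, 4800) ∋ 3900

    def test_threshold_definitions(self):
        assert classify_glucose(3.9) == LABEL_LOW
        assert classify_glucose(4.5) == LABEL_NORMAL
        assert classify_glucose(8.0) == LABEL_RANGE

    def test_guard_band_applies_to_training_only(self):
        assert classify_glucose(4.1, "train") == LABEL_GUARD
        assert classify_glucose(4.1, "test") == LABEL_NORMAL

    def test_uncovered_beats_dropped(self):
        cgm = _cgm([1000.0], [5.0])
        out = label_beats([_beat(100.0), _beat(900.0)], cgm, lag=300.0)
        # beat at 100 s: 100+300=400 < first reading time -> dropped
        assert len(out) == 1 and out[0].beat.r_time == 900.0

    def test_every_beat_gets_exactly_one_label(self):
        rng = np.random.default_rng(0)
        cgm = _cgm(np.arange(0, 4000, 900), rng.uniform(3, 9, 5))
        beats = [_beat(t) for t in np.linspace(0, 3000, 40)]
        out = label_beats(beats, cgm, lag=300.0)
        valid = {LABEL_LOW, LABEL_NORMAL, LABEL_GUARD, LABEL_RANGE}
        assert all(lb.label in valid for lb in out)


class TestEligibility:
    def test_no_readings_below_guard_is_ineligible(self):
        rep = check_eligibility(np.full(100, 5.5))
        assert not rep.eligible and rep.pct_below_4_2 == 0.0

    def test_twelve_percent_low_is_eligible(self):
        g = np.concatenate([np.full(12, 3.8), np.full(88, 5.0)])
        assert check_eligibility(g).eligible

    def test_exactly_ten_percent_boundary_counts(self):
        g = np.concatenate([np.full(10, 3.8), np.full(90, 6.0)])
        rep = check_eligibility(g)
        assert rep.pct_below_4_2 == pytest.approx(10.0)
        assert rep.eligible

    def test_high_p80_is_ineligible(self):
        g = np.concatenate([np.full(20, 3.8), np.full(80, 9.0)])
        assert not check_eligibility(g).eligible


def _night_with_event(night: int, low: bool, n: int = 120) -> list:
    """One hour of beats; when `low`, minutes 10-30 sit below threshold."""
    out = []
    for i in range(n):
        t = night * 36000.0 + i * 30.0
        g = 3.2 if (low and 20 <= i < 60) else 5.5
        out.append(_labeled(t, g, night=night))
    return out


class TestSplitNights:
    def test_three_nights_rejected(self):
        by_night = {k: _night_with_event(k, True) for k in range(3)}
        with pytest.raises(ValueError):
            split_nights(by_night)

    def test_too_few_low_event_nights_rejected(self):
        by_night = {k: _night_with_event(k, k == 0) for k in range(5)}
        with pytest.raises(ValueError):
            split_nights(by_night)

    def test_no_night_leakage_and_low_events_on_both_sides(self):
        by_night = {k: _night_with_event(k, k < 4) for k in range(10)}
        split = split_nights(by_night, seed=3)
        assert not set(split.train_nights) & set(split.test_nights)
        assert set(split.train_nights) | set(split.test_nights) == set(range(10))
        low = set(range(4))
        assert len(low & set(split.train_nights)) >= 2
        assert len(low & set(split.test_nights)) >= 1

    def test_validation_membership_deterministic(self):
        by_night = {k: _night_with_event(k, k < 3) for k in range(6)}
        a = split_nights(by_night, seed=5)
        b = split_nights(by_night, seed=5)
        assert [lb.beat.r_time for lb in a.val] == [lb.beat.r_time for lb in b.val]
        assert len(a.val) == round(0.2 * (len(a.val) + len(a.train)))

    def test_validation_beats_not_in_gradient_stream(self):
        by_night = {k: _night_with_event(k, k < 3) for k in range(6)}
        split = split_nights(by_night, seed=1)
        val_ids = {id(lb) for lb in split.val}
        assert not val_ids & {id(lb) for lb in split.train}


class TestBalancing:
    def test_downsamples_to_four_to_one(self):
        beats = ([_labeled(i, 3.0) for i in range(100)]
                 + [_labeled(i + 1000, 5.0) for i in range(1000)])
        out, rep = balance_classes(beats, seed=0)
        assert rep.triggered and rep.n_normal_after == 400 and rep.n_low_after == 100
        assert len(out) == 500

    def test_unchanged_when_low_at_least_quarter(self):
        beats = ([_labeled(i, 3.0) for i in range(100)]
                 + [_labeled(i + 1000, 5.0) for i in range(300)])
        out, rep = balance_classes(beats, seed=0)
        assert not rep.triggered and len(out) == 400

    def test_equal_classes_unchanged(self):
        beats = ([_labeled(i, 3.0) for i in range(100)]
                 + [_labeled(i + 1000, 5.0) for i in range(100)])
        out, rep = balance_classes(beats, seed=0)
        assert not rep.triggered and len(out) == 200

    def test_idempotent(self):
        beats = ([_labeled(i, 3.0) for i in range(100)]
                 + [_labeled(i + 1000, 5.0) for i in range(1000)])
        once, _ = balance_classes(beats, seed=4)
        twice, rep = balance_classes(once, seed=4)
        assert len(twice) == len(once) and not rep.triggered

    def test_missing_class_rejected(self):
        with pytest.raises(ValueError):
            balance_classes([_labeled(1.0, 5.0)])


def _uniform_beats(duration_s: float, rr: float, glucose_fn) -> list:
    out = []
    t = 0.0
    while t < duration_s:
        out.append(_labeled(t, glucose_fn(t)))
        t += rr
    return out


class TestSegments:
    def test_slow_hr_excerpt_dropped(self):
        # 150 beats in 5 min (30 bpm) -> below the 200-beat (40 bpm) rule
        beats = _uniform_beats(300.0, 2.0, lambda t: 5.0)
        segs, log = build_segments(beats)
        assert segs == [] and log.dropped["too_few_beats"] == 1

    def test_short_low_event_dropped(self):
        # low glucose only between 30 s and 270 s (4 min) inside normal surroundings
        beats = _uniform_beats(900.0, 1.0, lambda t: 3.0 if 30 <= t < 270 else 5.0)
        segs, log = build_segments(beats)
        assert log.dropped["mixed_label"] >= 1  # the excerpt containing the event mixes
        assert all(s.label == "normal" for s in segs)

    def test_pure_low_event_shorter_than_excerpt_grid_dropped(self):
        beats = _uniform_beats(240.0, 1.0, lambda t: 3.0)  # a 4-min night fragment
        segs, log = build_segments(beats)
        assert segs == []

    def test_sequence_is_first_200_beats_of_excerpt(self):
        beats = _uniform_beats(600.0, 300.0 / 230.0, lambda t: 5.0)  # 230 beats / 5 min
        segs, _ = build_segments(beats)
        assert len(segs) == 2
        assert all(len(s.beats) == 200 for s in segs)
        assert segs[0].beats == beats[:200]

    def test_segment_purity(self):
        beats = _uniform_beats(1800.0, 1.0,
                               lambda t: 3.0 if 600 <= t < 1500 else 5.0)
        segs, _ = build_segments(beats)
        for s in segs:
            labels = {lb.label for lb in s.beats}
            assert labels == {s.label}

    def test_guard_band_excerpts_excluded(self):
        beats = _uniform_beats(300.0, 1.0, lambda t: 4.1)
        segs, log = build_segments(beats, mode="train")
        assert segs == [] and log.dropped["excluded"] == 1
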