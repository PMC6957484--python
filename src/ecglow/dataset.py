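"""Labelling, eligibility, night-wise splits, class balancing and 5-minute
sequence assembly.

Glucose bands: a beat is *low* when its CGM-derived glucose is below
4.0 mmol/L and *normal* between 4.0 and 7.5 mmol/L.  During training a guard
band [4.0, 4.2) absorbs CGM error near the threshold; readings above
7.5 mmol/L fall outside the normal band and are excluded.  Each beat is
matched to the CGM reading whose validity interval (step function, valid
until the next reading) contains the beat time plus the sensor lag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import Beat
from .simulate import CGMSeries

LOW_THRESHOLD = 4.0
GUARD_BAND = 4.2
NORMAL_HIGH = 7.5

LABEL_LOW = "low"
LABEL_NORMAL = "normal"
LABEL_GUARD = "excluded_guard"
LABEL_RANGE = "excluded_range"


@dataclass
class LabeledBeat:
    beat: Beat
    glucose: float
    label: str
    night: int = 0


@dataclass
class EligibilityReport:
    pct_below_4_2: float
    p80_glucose: float
    eligible: bool


@dataclass
class BalancingReport:
    n_low_before: int
    n_normal_before: int
    n_low_after: int
    n_normal_after: int
    triggered: bool


@dataclass
class BeatDataset:
    train: list[LabeledBeat]
    val: list[LabeledBeat]
    test: list[LabeledBeat]
    train_nights: list[int]
    test_nights: list[int]
    balancing: BalancingReport | None = None
    seed: int = 0


@dataclass
class SegmentSequence:
    beats: list[LabeledBeat]   # exactly 200 consecutive beats
    start_time: float
    label: str
    night: int = 0


@dataclass
class SegmentLog:
    n_excerpts: int = 0
    n_kept: int = 0
    dropped: dict = field(default_factory=lambda: {"too_few_beats": 0, "mixed_label": 0,
                                                   "short_event": 0, "excluded": 0})


def classify_glucose(glucose: float, mode: str = "train") -> str:
    """Map a glucose value to its label under the train/test band rules."""
    if glucose < LOW_THRESHOLD:
        return LABEL_LOW
    if glucose > NORMAL_HIGH:
        return LABEL_RANGE
    if mode == "train" and glucose < GUARD_BAND:
        return LABEL_GUARD
    return LABEL_NORMAL


def label_beats(beats: list[Beat], cgm: CGMSeries, lag: float = 300.0,
                mode: str = "train", night: int = 0) -> list[LabeledBeat]:
    """Attach to each beat the CGM reading covering (r_time + lag).

    Readings are step functions valid from their timestamp until the next
    reading.  Beats falling before the first reading's validity window are
    dropped (uncovered).
    """
    if mode not in ("train", "test"):
        raise ValueError("mode must be 'train' or 'test'")
    ts = np.asarray(cgm.timestamps)
    vals = np.asarray(cgm.values)
    out: list[LabeledBeat] = []
    for b in beats:
        t = b.r_time + lag
        k = int(np.searchsorted(ts, t, side="right")) - 1
        if k < 0:
            continue  # uncovered: dropped
        out.append(LabeledBeat(beat=b, glucose=float(vals[k]),
                               label=classify_glucose(float(vals[k]), mode), night=night))
    return out


def check_eligibility(glucose_values: np.ndarray,
                      min_pct: float = 10.0, p80_max: float = NORMAL_HIGH) -> EligibilityReport:
    """Subject eligibility: >=10% of readings below 4.2 mmol/L and 80th
    percentile (linear-interpolation quantile) below 7.5 mmol/L."""
    g = np.asarray(glucose_values, dtype=float)
    if g.size == 0:
        raise ValueError("need at least one night of readings")
    pct = 100.0 * np.mean(g < GUARD_BAND)
    p80 = float(np.quantile(g, 0.80))
    return EligibilityReport(pct_below_4_2=pct, p80_glucose=p80,
                             eligible=bool(pct >= min_pct and p80 < p80_max))


def _nights_with_low_events(beats_by_night: dict[int, list[LabeledBeat]],
                            min_duration_s: float = 300.0) -> list[int]:
    """Nights containing at least one low-glucose run lasting >= min_duration_s."""
    nights = []
    for night, beats in beats_by_night.items():
        run_start = None
        found = False
        for lb in beats:
            if lb.glucose < LOW_THRESHOLD:
                if run_start is None:
                    run_start = lb.beat.r_time
                elif lb.beat.r_time - run_start >= min_duration_s:
                    found = True
                    break
            else:
                run_start = None
        if found:
            nights.append(night)
    return nights


def split_nights(beats_by_night: dict[int, list[LabeledBeat]], seed: int = 0,
                 train_fraction: float = 0.6,
                 validation_fraction: float = 0.2) -> BeatDataset:
    """Partition nights into train/test sides, each with low-event nights.

    Requires >= 4 nights with >= 2 nights carrying low events lasting 5 min or
    more.  Train receives ~``train_fraction`` of nights and at least as many
    low-event nights as test.  Validation is 20% of train beats sampled without
    replacement (seeded); validation beats are held out of gradient batches.
    Test beats are re-labelled under test-mode band rules (no guard band).
    """
    nights = sorted(beats_by_night)
    if len(nights) < 4:
        raise ValueError("need at least 4 nights to split")
    low_nights = _nights_with_low_events(beats_by_night)
    if len(low_nights) < 2:
        raise ValueError(
            "ineligible recording: need >= 2 nights with low-glucose events of >= 5 min")
    rng = np.random.default_rng(seed)
    other = [n for n in nights if n not in low_nights]
    low_shuffled = list(rng.permutation(low_nights))
    other_shuffled = list(rng.permutation(other))

    n_train = max(2, int(round(train_fraction * len(nights))))
    n_train = min(n_train, len(nights) - 1)
    # deal low-event nights alternately (train first) so both sides get some
    train_nights, test_nights = [], []
    for i, n in enumerate(low_shuffled):
        (train_nights if i % 2 == 0 else test_nights).append(int(n))
    for n in other_shuffled:
        (train_nights if len(train_nights) < n_train else test_nights).append(int(n))
    if not test_nights:
        test_nights.append(train_nights.pop())

    train_beats = [lb for n in train_nights for lb in beats_by_night[n]]
    test_beats = [
        LabeledBeat(beat=lb.beat, glucose=lb.glucose,
                    label=classify_glucose(lb.glucose, "test"), night=lb.night)
        for n in test_nights for lb in beats_by_night[n]
    ]
    usable = [lb for lb in train_beats if lb.label in (LABEL_LOW, LABEL_NORMAL)]
    n_val = int(round(validation_fraction * len(usable)))
    val_idx = set(rng.choice(len(usable), size=n_val, replace=False).tolist())
    val = [lb for i, lb in enumerate(usable) if i in val_idx]
    train = [lb for i, lb in enumerate(usable) if i not in val_idx]
    return BeatDataset(train=train, val=val, test=test_beats,
                       train_nights=sorted(train_nights), test_nights=sorted(test_nights),
                       seed=seed)


def balance_classes(train: list[LabeledBeat], seed: int = 0,
                    trigger: float = 0.25) -> tuple[list[LabeledBeat], BalancingReport]:
    """Downsample normals (without replacement) to 4x the lows when lows fall
    below 25% of normals; never oversample."""
    lows = [lb for lb in train if lb.label == LABEL_LOW]
    normals = [lb for lb in train if lb.label == LABEL_NORMAL]
    if not lows or not normals:
        raise ValueError("both classes must be present for balancing")
    report = BalancingReport(n_low_before=len(lows), n_normal_before=len(normals),
                             n_low_after=len(lows), n_normal_after=len(normals),
                             triggered=False)
    if len(lows) < trigger * len(normals):
        rng = np.random.default_rng(seed)
        target = int(round(len(lows) / trigger))
        keep = rng.choice(len(normals), size=target, replace=False)
        normals = [normals[i] for i in sorted(keep)]
        report.n_normal_after = len(normals)
        report.triggered = True
    return lows + normals, report


def _event_durations(beats: list[LabeledBeat]) -> dict[int, float]:
    """Duration (s) of the maximal same-low-status run containing each beat index."""
    durations: dict[int, float] = {}
    i = 0
    n = len(beats)
    while i < n:
        status = beats[i].glucose < LOW_THRESHOLD
        j = i
        while j + 1 < n and (beats[j + 1].glucose < LOW_THRESHOLD) == status:
            j += 1
        span = beats[j].beat.r_time - beats[i].beat.r_time
        for k in range(i, j + 1):
            durations[k] = span
        i = j + 1
    return durations


def build_segments(beats: list[LabeledBeat], night: int = 0,
                   excerpt_s: float = 300.0, n_beats: int = 200,
                   min_event_s: float = 300.0,
                   mode: str = "train") -> tuple[list[SegmentSequence], SegmentLog]:
    """Non-overlapping 5-minute excerpts -> 200-beat sequences.

    The excerpt grid is aligned to the night's first quality beat.  An excerpt
    is kept iff it holds >= 200 beats (HR > 40 bpm), all beats share one
    usable label, and the underlying glucose event spans >= ``min_event_s``.
    The sequence is the first 200 beats of the excerpt.
    """
    log = SegmentLog()
    if not beats:
        return [], log
    beats = sorted(beats, key=lambda lb: lb.beat.r_time)
    durations = _event_durations(beats)
    t0 = beats[0].beat.r_time
    t_end = beats[-1].beat.r_time
    segments: list[SegmentSequence] = []
    start = t0
    idx = 0
    while start < t_end:
        stop = start + excerpt_s
        chunk, chunk_idx = [], []
        while idx < len(beats) and beats[idx].beat.r_time < stop:
            chunk.append(beats[idx])
            chunk_idx.append(idx)
            idx += 1
        if chunk:
            log.n_excerpts += 1
            labels = {lb.label for lb in chunk}
            if len(chunk) < n_beats:
                log.dropped["too_few_beats"] += 1
            elif labels & {LABEL_GUARD, LABEL_RANGE}:
                log.dropped["excluded"] += 1
            elif len(labels) != 1:
                log.dropped["mixed_label"] += 1
            elif min(durations[k] for k in chunk_idx) < min_event_s:
                log.dropped["short_event"] += 1
            else:
                segments.append(SegmentSequence(beats=chunk[:n_beats], start_time=start,
                                                label=chunk[0].label, night=night))
                log.n_kept += 1
        start = stop
    return segments, log
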