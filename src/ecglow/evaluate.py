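"""Metrics, 10-minute majority-vote alarms and the nightly timeline.

Per-beat probabilities are aggregated into non-overlapping 10-minute windows
by majority vote (ties alarm: a detector should favour sensitivity), each
window carrying a certainty class from the mean winning-class probability
(> 0.7 = "dark").  Confusion-matrix metrics treat low glucose as the positive
class; AUC uses the Mann-Whitney rank statistic with midranks for ties.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

VOTE_WINDOW_S = 600.0
CERTAINTY_THRESHOLD = 0.7


@dataclass
class IntervalPrediction:
    start: float
    end: float
    label: str                 # 'low' | 'normal'
    vote_fraction: float       # fraction of beats voting low
    mean_prob: float           # mean winning-class probability
    certainty: str             # 'dark' | 'light'
    n_beats: int
    truth: str | None = None   # majority of truth labels, None if mixed/absent


@dataclass
class MetricsReport:
    sensitivity: float   # percent
    specificity: float   # percent
    accuracy: float      # percent
    auc: float | None
    tp: int
    fp: int
    tn: int
    fn: int
    tally: str = ""      # "correct/total = %" for interval metrics

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def rank_auc(scores: np.ndarray, labels: np.ndarray) -> float | None:
    """AUC by the Mann-Whitney rank formulation; None when truth is single-class."""
    labels = np.asarray(labels).astype(int)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        return None
    r = rankdata(np.asarray(scores, dtype=float))
    return float((r[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def majority_vote(times: np.ndarray, p_low: np.ndarray,
                  truth_labels: np.ndarray | None = None,
                  window: float = VOTE_WINDOW_S, night_start: float = 0.0,
                  certainty_threshold: float = CERTAINTY_THRESHOLD) -> list[IntervalPrediction]:
    """Aggregate per-beat predictions into 10-minute interval alarms.

    Windows are aligned to ``night_start``; windows without beats are skipped.
    A window is labelled low iff the fraction of beats with p_low > 0.5 is
    >= 0.5 (ties break toward the alarm).  When per-beat truth labels (1 = low,
    0 = normal, -1 = excluded) are given, each interval's truth is the
    majority beat label, or None when excluded/mixed beats exceed half.
    """
    times = np.asarray(times, dtype=float)
    p_low = np.asarray(p_low, dtype=float)
    order = np.argsort(times)
    times, p_low = times[order], p_low[order]
    if truth_labels is not None:
        truth_labels = np.asarray(truth_labels)[order]
    out: list[IntervalPrediction] = []
    if times.size == 0:
        return out
    w0 = int(np.floor((times[0] - night_start) / window))
    w1 = int(np.floor((times[-1] - night_start) / window))
    for w in range(w0, w1 + 1):
        lo = night_start + w * window
        hi = lo + window
        mask = (times >= lo) & (times < hi)
        n = int(mask.sum())
        if n == 0:
            continue
        votes_low = p_low[mask] > 0.5
        frac = float(votes_low.mean())
        label = "low" if frac >= 0.5 else "normal"
        win_probs = p_low[mask] if label == "low" else 1.0 - p_low[mask]
        mean_prob = float(win_probs.mean())
        truth = None
        if truth_labels is not None:
            tl = truth_labels[mask]
            n_low = int(np.sum(tl == 1))
            n_norm = int(np.sum(tl == 0))
            if n_low + n_norm > n / 2:
                truth = "low" if n_low > n_norm else "normal"
        out.append(IntervalPrediction(
            start=lo, end=hi, label=label, vote_fraction=frac, mean_prob=mean_prob,
            certainty="dark" if mean_prob > certainty_threshold else "light",
            n_beats=n, truth=truth))
    return out


def compute_metrics(p_low: np.ndarray, truth: np.ndarray,
                    threshold: float = 0.5) -> MetricsReport:
    """Confusion-matrix metrics (low = positive) plus rank AUC."""
    p_low = np.asarray(p_low, dtype=float)
    truth = np.asarray(truth).astype(int)
    if p_low.shape != truth.shape:
        raise ValueError("predictions and truth must align")
    pred = p_low > threshold
    tp = int(np.sum(pred & (truth == 1)))
    fn = int(np.sum(~pred & (truth == 1)))
    tn = int(np.sum(~pred & (truth == 0)))
    fp = int(np.sum(pred & (truth == 0)))
    total = tp + fp + tn + fn
    sens = 100.0 * tp / (tp + fn) if tp + fn else float("nan")
    spec = 100.0 * tn / (tn + fp) if tn + fp else float("nan")
    acc = 100.0 * (tp + tn) / total if total else float("nan")
    return MetricsReport(sensitivity=sens, specificity=spec, accuracy=acc,
                         auc=rank_auc(p_low, truth), tp=tp, fp=fp, tn=tn, fn=fn)


def interval_metrics(intervals: list[IntervalPrediction]) -> MetricsReport:
    """Metrics over interval predictions with defined truth, plus the
    "correct/total = %" tally the nightly reports print."""
    usable = [iv for iv in intervals if iv.truth is not None]
    if not usable:
        raise ValueError("no intervals with defined ground truth")
    pred = np.asarray([1.0 if iv.label == "low" else 0.0 for iv in usable])
    truth = np.asarray([1 if iv.truth == "low" else 0 for iv in usable])
    rep = compute_metrics(pred, truth)
    correct = int(np.sum(pred == truth))
    rep.tally = f"{correct}/{len(usable)} = {100.0 * correct / len(usable):.1f}%"
    rep.auc = None  # binary interval labels carry no ranking information
    return rep


@dataclass
class NightTimeline:
    cgm_times: np.ndarray
    cgm_values: np.ndarray
    band_low: np.ndarray      # CGM value - 10%
    band_high: np.ndarray     # CGM value + 10%
    intervals: list[IntervalPrediction]
    true_times: np.ndarray | None = None
    true_values: np.ndarray | None = None


def build_timeline(intervals: list[IntervalPrediction], cgm,
                   true_glucose=None) -> NightTimeline:
    """Plot-ready nightly timeline: CGM trace, +-10% band, coloured intervals."""
    values = np.asarray(cgm.values, dtype=float)
    return NightTimeline(
        cgm_times=np.asarray(cgm.timestamps, dtype=float),
        cgm_values=values,
        band_low=values * 0.9,
        band_high=values * 1.1,
        intervals=intervals,
        true_times=None if true_glucose is None else np.asarray(true_glucose.timestamps),
        true_values=None if true_glucose is None else np.asarray(true_glucose.values),
    )


def plot_timeline(timeline: NightTimeline, path: str, low_threshold: float = 4.0) -> None:
    """Render the timeline figure (CGM line, shaded band, red/green interval dots)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 4))
    t_h = timeline.cgm_times / 3600.0
    ax.fill_between(t_h, timeline.band_low, timeline.band_high, color="0.8", label="CGM ±10%")
    ax.plot(t_h, timeline.cgm_values, "k-", lw=1.2, label="CGM")
    if timeline.true_times is not None:
        ax.plot(timeline.true_times / 3600.0, timeline.true_values, "b--", lw=0.8,
                alpha=0.6, label="true glucose")
    ax.axhline(low_threshold, color="0.4", ls=":", lw=0.8)
    colors = {("low", "dark"): "#8b0000", ("low", "light"): "#ff7f50",
              ("normal", "dark"): "#006400", ("normal", "light"): "#90ee90"}
    for iv in timeline.intervals:
        ax.plot(0.5 * (iv.start + iv.end) / 3600.0, low_threshold - 1.0, "o",
                color=colors[(iv.label, iv.certainty)], ms=5)
    ax.set_xlabel("hours since midnight")
    ax.set_ylabel("glucose (mmol/L)")
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
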