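"""ECG-feature statistics: per-beat feature extraction, intra-subject
Mann-Whitney tests and inter-subject Kruskal-Wallis with Dunn's post hoc.

Features are measured on the raw 160-sample mV windows (amplitudes would be
meaningless after z-scoring): Q, R and T amplitudes from the window-median
baseline, peak-to-peak QT interval, R/T amplitude ratio and the slope of the
line through the T peak and T offset.  Beats whose T wave cannot be segmented
are excluded and counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats as sp_stats

FS = 250.0
R_INDEX = 60          # R peak sits at sample 60 of the 160-sample window
T_SEARCH_MS = (120.0, 396.0)   # post-R search window for the T peak
Q_SEARCH_MS = 60.0             # pre-R search window for the Q trough
T_MIN_AMP_MV = 0.05            # below this the T wave is deemed undetectable
T_OFFSET_FRACTION = 0.1        # |v - baseline| <= 0.1 |t_amp| marks T offset

FEATURE_NAMES = ("q_amp", "r_amp", "t_amp", "qt_interval", "rt_ratio", "t_slope")


@dataclass
class BeatFeatures:
    q_amp: float = np.nan
    r_amp: float = np.nan
    t_amp: float = np.nan
    qt_interval: float = np.nan   # ms, peak to peak
    rt_ratio: float = np.nan
    t_slope: float = np.nan       # mV / ms
    valid: bool = False

    def as_array(self) -> np.ndarray:
        return np.asarray([getattr(self, n) for n in FEATURE_NAMES])


@dataclass
class TestResult:
    test: str
    statistic: float
    p_value: float
    group_sizes: tuple
    significant_05: bool = False
    flagged_01: bool = False
    note: str = ""


@dataclass
class StatReport:
    per_feature: dict = field(default_factory=dict)        # feature -> TestResult
    pairwise: dict = field(default_factory=dict)           # feature -> {(a, b): adj p}
    normality: dict = field(default_factory=dict)          # feature -> {group: p}


def extract_features(raw_window: np.ndarray, fs: float = FS,
                     qt_from: str = "q") -> BeatFeatures:
    """Feature extraction from one 160-sample raw beat window.

    ``qt_from`` selects the QT convention: Q-peak-to-T-peak (default) or
    R-peak-to-T-peak (``"r"``).
    """
    w = np.asarray(raw_window, dtype=float)
    if w.size != 160:
        raise ValueError(f"expected a 160-sample window, got {w.size}")
    baseline = float(np.median(w))
    ms_per_sample = 1000.0 / fs

    r_amp = float(w[R_INDEX] - baseline)
    q_lo = R_INDEX - int(Q_SEARCH_MS / ms_per_sample)
    q_seg = w[q_lo:R_INDEX]
    q_idx = q_lo + int(np.argmin(q_seg))
    q_amp = float(w[q_idx] - baseline)

    t_lo = R_INDEX + int(T_SEARCH_MS[0] / ms_per_sample)
    t_hi = min(w.size, R_INDEX + int(T_SEARCH_MS[1] / ms_per_sample) + 1)
    t_seg = w[t_lo:t_hi]
    t_idx = t_lo + int(np.argmax(np.abs(t_seg - baseline)))
    t_amp = float(w[t_idx] - baseline)

    feats = BeatFeatures(q_amp=q_amp, r_amp=r_amp, t_amp=t_amp)
    if abs(t_amp) < T_MIN_AMP_MV:
        return feats  # T undetectable -> invalid

    t_off = None
    for i in range(t_idx + 1, w.size):
        if abs(w[i] - baseline) <= T_OFFSET_FRACTION * abs(t_amp):
            t_off = i
            break
    if t_off is None:
        return feats  # T offset outside the window -> invalid

    anchor = q_idx if qt_from == "q" else R_INDEX
    feats.qt_interval = (t_idx - anchor) * ms_per_sample
    feats.rt_ratio = r_amp / t_amp
    feats.t_slope = (w[t_off] - w[t_idx]) / ((t_off - t_idx) * ms_per_sample)
    feats.valid = True
    return feats


def features_table(raw_windows: np.ndarray, fs: float = FS,
                   qt_from: str = "q") -> tuple[np.ndarray, int]:
    """(n_valid, 6) feature matrix and the number of excluded beats."""
    rows, excluded = [], 0
    for w in raw_windows:
        f = extract_features(w, fs=fs, qt_from=qt_from)
        if f.valid:
            rows.append(f.as_array())
        else:
            excluded += 1
    return (np.vstack(rows) if rows else np.empty((0, len(FEATURE_NAMES)))), excluded


def _balanced(a: np.ndarray, b: np.ndarray, rng: np.random.Generator):
    n = min(len(a), len(b))
    if len(a) > n:
        a = a[rng.choice(len(a), size=n, replace=False)]
    if len(b) > n:
        b = b[rng.choice(len(b), size=n, replace=False)]
    return a, b


def intra_subject_tests(features_low: np.ndarray, features_normal: np.ndarray,
                        balance: bool = True, seed: int = 0,
                        min_n: int = 20) -> StatReport:
    """Two-sided Mann-Whitney per feature between low and normal beats.

    Normality is screened per group with Shapiro-Wilk on a subsample of at
    most 5000 beats; samples are class-balanced by seeded downsampling of the
    majority class before testing.
    """
    if len(features_low) < min_n or len(features_normal) < min_n:
        raise ValueError(f"need at least {min_n} valid beats per class")
    rng = np.random.default_rng(seed)
    report = StatReport()
    for j, name in enumerate(FEATURE_NAMES):
        a, b = features_low[:, j], features_normal[:, j]
        if balance:
            a, b = _balanced(a, b, rng)
        report.normality[name] = {
            "low": _shapiro_p(a, rng), "normal": _shapiro_p(b, rng)}
        if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
            report.per_feature[name] = TestResult(
                test="mann-whitney", statistic=float("nan"), p_value=1.0,
                group_sizes=(len(a), len(b)), note="degenerate: constant samples")
            continue
        stat, p = sp_stats.mannwhitneyu(a, b, alternative="two-sided")
        report.per_feature[name] = TestResult(
            test="mann-whitney", statistic=float(stat), p_value=float(p),
            group_sizes=(len(a), len(b)),
            significant_05=bool(p < 0.05), flagged_01=bool(p < 0.01))
    return report


def _shapiro_p(x: np.ndarray, rng: np.random.Generator, cap: int = 5000) -> float:
    if np.ptp(x) == 0:
        return float("nan")
    if len(x) > cap:
        x = x[rng.choice(len(x), size=cap, replace=False)]
    return float(sp_stats.shapiro(x).pvalue)


def dunn_posthoc(groups: dict[str, np.ndarray]) -> dict[tuple[str, str], float]:
    """All-pairs Dunn's z-tests on pooled ranks (tie-corrected), Holm-adjusted."""
    from statsmodels.stats.multitest import multipletests

    names = list(groups)
    pooled = np.concatenate([np.asarray(groups[k], dtype=float) for k in names])
    ranks = sp_stats.rankdata(pooled)
    n = pooled.size
    mean_ranks, sizes, start = {}, {}, 0
    for k in names:
        g = len(groups[k])
        mean_ranks[k] = ranks[start:start + g].mean()
        sizes[k] = g
        start += g
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts ** 3 - tie_counts) / (12.0 * (n - 1))
    pairs = list(combinations(names, 2))
    raw = []
    for a, b in pairs:
        se = np.sqrt((n * (n + 1) / 12.0 - tie_term) * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        raw.append(2.0 * sp_stats.norm.sf(abs(z)))
    adj = multipletests(raw, method="holm")[1]
    return {pair: float(p) for pair, p in zip(pairs, adj)}


def inter_subject_tests(features_by_subject: dict[str, np.ndarray],
                        alpha: float = 0.05) -> StatReport:
    """Omnibus Kruskal-Wallis across subjects per feature; when significant,
    Dunn's pairwise post hoc with Holm adjustment."""
    if len(features_by_subject) < 2:
        raise ValueError("need at least 2 subjects")
    report = StatReport()
    for j, name in enumerate(FEATURE_NAMES):
        groups = {s: f[:, j] for s, f in features_by_subject.items()}
        samples = list(groups.values())
        if all(np.ptp(g) == 0 for g in samples) and len({g[0] for g in samples}) == 1:
            stat, p = 0.0, 1.0
        else:
            stat, p = sp_stats.kruskal(*samples)
        report.per_feature[name] = TestResult(
            test="kruskal-wallis", statistic=float(stat), p_value=float(p),
            group_sizes=tuple(len(g) for g in samples),
            significant_05=bool(p < alpha), flagged_01=bool(p < 0.01))
        if p < alpha:
            report.pairwise[name] = dunn_posthoc(groups)
    return report
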