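"""End-to-end orchestration: simulation -> preprocessing -> dataset ->
training -> alarms, shared by the CLI `demo` command and by experiment
scripts.

The personalised experiment trains one detector per subject on CGM-labelled
beats from the training nights and evaluates on held-out nights, both against
the CGM labels (what a deployment would see) and against the simulator's
ground-truth glucose (parameter recovery: did the detector learn the injected
glucose-morphology coupling?).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from . import dataset as ds
from . import evaluate as ev
from . import models
from . import preprocess as pp
from .simulate import SubjectProfile, SubjectRecording, simulate_subject


@dataclass
class NightBeats:
    night: int
    labeled: list          # train-mode labels from CGM
    true_glucose_at_beats: np.ndarray
    log: pp.PreprocessLog


@dataclass
class ExperimentResult:
    detector: object
    history: models.TrainingHistory
    beat_dataset: ds.BeatDataset
    balancing: ds.BalancingReport
    beat_auc_truth: float | None
    beat_auc_cgm: float | None
    vote_metrics_truth: ev.MetricsReport
    vote_metrics_cgm: ev.MetricsReport | None
    intervals: list
    counts: dict


def preprocess_recording(rec: SubjectRecording, lag: float = 300.0) -> list[NightBeats]:
    """Detect, filter and label the beats of every night of a recording."""
    nights: list[NightBeats] = []
    for k, night in enumerate(rec.nights):
        beats, log = pp.preprocess_night(night.ecg, night.accel)
        labeled = ds.label_beats(beats, night.cgm, lag=lag, mode="train", night=k)
        true_g = night.true_glucose.at(np.asarray([lb.beat.r_time for lb in labeled]))
        nights.append(NightBeats(night=k, labeled=labeled,
                                 true_glucose_at_beats=true_g, log=log))
    return nights


def beat_arrays(labeled: list) -> dict:
    """Stack labelled beats into model-ready arrays (y: 1 = low)."""
    return {
        "x": np.stack([lb.beat.series for lb in labeled]).astype(np.float32),
        "act": np.asarray([lb.beat.activity for lb in labeled], dtype=np.float32),
        "y": np.asarray([1 if lb.label == ds.LABEL_LOW else 0 for lb in labeled]),
    }


def uncoupled_profile(profile: SubjectProfile) -> SubjectProfile:
    """Same subject with the glucose -> morphology coupling switched off."""
    return dataclasses.replace(
        profile,
        hypo_effect=dataclasses.replace(profile.hypo_effect, delta_qt_ms=0.0,
                                        t_amp_scale=1.0, p_amp_scale=1.0))


def run_cnn_experiment(rec: SubjectRecording, seed: int = 0,
                       tcfg: models.TrainingConfig | None = None,
                       cnn_config: models.CNNConfig | None = None,
                       lag: float = 300.0) -> ExperimentResult:
    """Personalised CNN experiment on one (typically simulated) subject."""
    tcfg = tcfg or models.TrainingConfig(seed=seed)
    cnn_config = cnn_config or models.CNNConfig()

    nights = preprocess_recording(rec, lag=lag)
    cgm_values = np.concatenate([np.asarray(n.cgm.values) for n in rec.nights])
    elig = ds.check_eligibility(cgm_values)
    if not elig.eligible:
        raise ValueError(
            f"subject ineligible: {elig.pct_below_4_2:.1f}% of readings below 4.2 mmol/L "
            f"(need >= 10%), 80th percentile {elig.p80_glucose:.1f} mmol/L (need < 7.5)")

    by_night = {nb.night: nb.labeled for nb in nights}
    split = ds.split_nights(by_night, seed=seed)
    balanced_train, balancing = ds.balance_classes(split.train, seed=seed)

    detector = models.build_cnn(cnn_config, seed=seed)
    history = models.train(detector, beat_arrays(balanced_train),
                           beat_arrays(split.val), tcfg)

    # --- held-out evaluation ------------------------------------------------
    truth_by_night = {nb.night: nb.true_glucose_at_beats for nb in nights}
    test_nb = [nb for nb in nights if nb.night in split.test_nights]
    test_beats = [lb for nb in test_nb for lb in nb.labeled]
    test_arrays = {
        "x": np.stack([lb.beat.series for lb in test_beats]).astype(np.float32),
        "act": np.asarray([lb.beat.activity for lb in test_beats], dtype=np.float32),
    }
    p_low = models.predict(detector, test_arrays["x"], test_arrays["act"])
    times = np.asarray([lb.beat.r_time for lb in test_beats])
    night_ids = np.asarray([lb.night for lb in test_beats])

    truth_labels = np.concatenate([
        (truth_by_night[nb.night] < ds.LOW_THRESHOLD).astype(int) for nb in test_nb
    ]) if test_nb else np.asarray([], dtype=int)
    cgm_labels = np.asarray([
        {ds.LABEL_LOW: 1, ds.LABEL_NORMAL: 0}.get(
            ds.classify_glucose(lb.glucose, "test"), -1)
        for lb in test_beats])

    beat_auc_truth = ev.rank_auc(p_low, truth_labels)
    usable = cgm_labels >= 0
    beat_auc_cgm = ev.rank_auc(p_low[usable], cgm_labels[usable]) if usable.any() else None

    intervals_truth: list = []
    intervals_cgm: list = []
    for nb in test_nb:
        m = night_ids == nb.night
        intervals_truth += ev.majority_vote(times[m], p_low[m], truth_labels[m])
        intervals_cgm += ev.majority_vote(times[m], p_low[m], cgm_labels[m])
    vote_truth = ev.interval_metrics(intervals_truth)
    try:
        vote_cgm = ev.interval_metrics(intervals_cgm)
    except ValueError:
        vote_cgm = None

    counts = {
        "n_nights": len(rec.nights),
        "train_nights": split.train_nights,
        "test_nights": split.test_nights,
        "n_train": len(balanced_train),
        "n_val": len(split.val),
        "n_test": len(test_beats),
        "balancing": dataclasses.asdict(balancing),
        "per_night_kept": {nb.night: nb.log.n_kept for nb in nights},
    }
    return ExperimentResult(
        detector=detector, history=history, beat_dataset=split, balancing=balancing,
        beat_auc_truth=beat_auc_truth, beat_auc_cgm=beat_auc_cgm,
        vote_metrics_truth=vote_truth, vote_metrics_cgm=vote_cgm,
        intervals=intervals_truth, counts=counts)


def demo_profile(seed: int = 0) -> SubjectProfile:
    """Default strong-coupling subject used by the demo command."""
    return SubjectProfile(subject_id=f"demo-{seed}", seed=seed)


def run_demo(seed: int = 0, n_nights: int = 4, night_minutes: int = 240,
             max_steps: int = 200) -> dict:
    """Small seeded end-to-end run; returns a JSON-ready metrics dictionary."""
    profile = demo_profile(seed)
    rec = simulate_subject(profile, n_nights=n_nights, seed=seed,
                           night_minutes=night_minutes)
    tcfg = models.TrainingConfig(seed=seed, max_steps=max_steps)
    res = run_cnn_experiment(rec, seed=seed, tcfg=tcfg)
    return {
        "seed": seed,
        "counts": res.counts,
        "beat_auc_truth": res.beat_auc_truth,
        "beat_auc_cgm": res.beat_auc_cgm,
        "vote_sensitivity_pct": res.vote_metrics_truth.sensitivity,
        "vote_specificity_pct": res.vote_metrics_truth.specificity,
        "vote_tally": res.vote_metrics_truth.tally,
        "interval_labels": [iv.label for iv in res.intervals],
        "best_val_auc": res.history.best_auc,
        "best_step": res.history.best_step,
    }
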