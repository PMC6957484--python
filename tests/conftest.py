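"""Shared fixtures.

Heavy, session-scoped fixtures (a simulated subject and a trained personalised
CNN) are built once and shared across the evaluation, explanation and
acceptance tests so the suite stays within a desk-scale runtime.
"""

from __future__ import annotations

import numpy as np
import pytest

from ecglow import models, pipeline
from ecglow.simulate import (GlucoseDynamics, NoiseModel, SubjectProfile,
                             simulate_night, simulate_subject)

RECOVERY_SEED = 11
RECOVERY_NIGHTS = 6
RECOVERY_NIGHT_MINUTES = 180
RECOVERY_MAX_STEPS = 1500


@pytest.fixture(scope="session")
def clean_profile() -> SubjectProfile:
    """Noise-free subject: deterministic HR, no wander/artifacts, quiet glucose."""
    return SubjectProfile(
        subject_id="clean",
        heart_rate_sd=0.0,
        glucose_dynamics=GlucoseDynamics(dip_rate=0.0, noise_sd=0.0),
        noise=NoiseModel(ecg_sd=0.0, baseline_wander_amp=0.0, artifact_rate=0.0),
    )


@pytest.fixture(scope="session")
def clean_night(clean_profile):
    """A short noise-free night (60 bpm, constant glucose)."""
    return simulate_night(clean_profile, seed=42, night_minutes=10)


@pytest.fixture(scope="session")
def short_recording():
    """Small multi-night recording with default (strong-coupling) dynamics."""
    profile = SubjectProfile(subject_id="short", seed=7)
    return simulate_subject(profile, n_nights=4, seed=7, night_minutes=90)


@pytest.fixture(scope="session")
def recovery_experiment():
    """The full personalised-CNN parameter-recovery experiment (trained once).

    Strong coupling (dQT = +40 ms, T amplitude x0.7), 6 nights of 3 h,
    CGM-labelled training with MARD 11.4%, held-out-night evaluation.
    """
    profile = SubjectProfile(subject_id="recovery", seed=RECOVERY_SEED)
    rec = simulate_subject(profile, n_nights=RECOVERY_NIGHTS, seed=RECOVERY_SEED,
                           night_minutes=RECOVERY_NIGHT_MINUTES)
    tcfg = models.TrainingConfig(seed=RECOVERY_SEED, max_steps=RECOVERY_MAX_STEPS)
    return pipeline.run_cnn_experiment(rec, seed=RECOVERY_SEED, tcfg=tcfg)


@pytest.fixture(scope="session")
def toy_localised_classes():
    """Synthetic beat classes differing only at positions 35-50 of 53."""
    rng = np.random.default_rng(5)
    n = 1500
    x = rng.normal(0.0, 0.3, (n, 53)).astype(np.float32)
    base = np.exp(-0.5 * ((np.arange(53) - 18) / 4.0) ** 2).astype(np.float32)
    x += base  # a shared "QRS" bump so the difference region is not the only structure
    y = rng.integers(0, 2, n)
    bump = np.zeros(53, dtype=np.float32)
    bump[35:50] = 1.0
    x[y == 1] += bump
    act = rng.normal(0.0, 0.05, n).astype(np.float32)
    return x, act, y


@pytest.fixture(scope="session")
def toy_localised_cnn(toy_localised_classes):
    """Small CNN trained on the localised-difference toy problem."""
    x, act, y = toy_localised_classes
    cfg = models.CNNConfig(n_conv_layers=6, filters_per_layer=16, fc_units=16)
    det = models.build_cnn(cfg, seed=1)
    n_train = 1000
    tr = {"x": x[:n_train], "act": act[:n_train], "y": y[:n_train]}
    va = {"x": x[n_train:], "act": act[n_train:], "y": y[n_train:]}
    models.train(det, tr, va, models.TrainingConfig(seed=1, max_steps=300, batch_size=100))
    return det
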