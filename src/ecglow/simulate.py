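"""Synthetic co-simulation of nocturnal ECG, accelerometry, glucose and CGM.

The generator stands in for private wearable recordings: a single-lead ECG at
250 Hz built from per-beat sums of five Gaussian waves (P, Q, R, S, T), a true
interstitial-glucose trace on a 1-minute grid for the nocturnal window
(midnight to 9 AM), a CGM observation process (15-min sampling, ~5-min lag,
multiplicative error calibrated to a target MARD) and 1-Hz triaxial
accelerations.  Low glucose perturbs beat morphology through a step coupling:
below an onset threshold the T wave shifts later (QT prolongation), the T
amplitude is rescaled (flattening) and the P amplitude is rescaled.

All outputs are pure functions of ``(profile, seed)``; a ground-truth channel
(beat times and the exact wave parameters used per beat) is kept so that
downstream detectors and feature extractors can be scored against the truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

FS_HZ = 250
NIGHT_MINUTES = 540  # midnight .. 9 AM
GLUCOSE_FLOOR = 2.2  # mmol/L, hard floor of the simulated trace
GLUCOSE_CEIL = 12.0


@dataclass(frozen=True)
class WaveParams:
    """One Gaussian wave: amplitude (mV), center (ms relative to R), width (ms)."""

    amplitude: float
    center: float
    width: float

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError(f"wave width must be positive, got {self.width}")


@dataclass(frozen=True)
class MorphParams:
    """Full beat morphology: the five PQRST Gaussian waves."""

    p: WaveParams
    q: WaveParams
    r: WaveParams
    s: WaveParams
    t: WaveParams

    def waves(self) -> dict[str, WaveParams]:
        return {"P": self.p, "Q": self.q, "R": self.r, "S": self.s, "T": self.t}


@dataclass(frozen=True)
class HypoEffect:
    """Step change of beat morphology below ``onset_glucose``."""

    delta_qt_ms: float = 40.0
    t_amp_scale: float = 0.7
    p_amp_scale: float = 1.3
    onset_glucose: float = 4.0


@dataclass(frozen=True)
class GlucoseDynamics:
    """Night-time glucose model: baseline + smoothed noise + Poisson dips."""

    baseline: float = 5.5          # mmol/L
    dip_rate: float = 3.0          # dips / night
    dip_depth_mean: float = 2.8    # mmol/L
    dip_depth_sd: float = 0.3
    dip_duration_mean: float = 60.0  # min
    dip_duration_sd: float = 10.0
    smoothness: float = 20.0       # min, kernel width of the noise smoother
    noise_sd: float = 0.25         # mmol/L


@dataclass(frozen=True)
class NoiseModel:
    ecg_sd: float = 0.02             # mV additive white noise
    baseline_wander_amp: float = 0.1  # mV, slow sinusoidal wander
    artifact_rate: float = 1.0        # bursts / hour


def default_wave_params() -> MorphParams:
    """A generic adult resting-ECG morphology (amplitudes within 0.25..15 mV device range)."""
    return MorphParams(
        p=WaveParams(0.15, -180.0, 20.0),
        q=WaveParams(-0.20, -25.0, 8.0),
        r=WaveParams(1.20, 0.0, 10.0),
        s=WaveParams(-0.25, 25.0, 8.0),
        t=WaveParams(0.35, 260.0, 35.0),
    )


@dataclass(frozen=True)
class SubjectProfile:
    subject_id: str = "S1"
    heart_rate_mean: float = 60.0  # bpm
    heart_rate_sd: float = 5.0
    wave_params: MorphParams = field(default_factory=default_wave_params)
    hypo_effect: HypoEffect = field(default_factory=HypoEffect)
    glucose_dynamics: GlucoseDynamics = field(default_factory=GlucoseDynamics)
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0

    def __post_init__(self):
        waves = self.wave_params.waves()
        if any(abs(w.amplitude) > 15.0 for w in waves.values()):
            raise ValueError("wave amplitudes must stay within the 15 mV device range")
        centers = [waves[k].center for k in ("P", "Q", "R", "S", "T")]
        if not all(a < b for a, b in zip(centers, centers[1:])):
            raise ValueError("wave centers must be ordered P < Q < R < S < T")
        if waves["R"].center != 0.0:
            raise ValueError("R wave is the fiducial point and must sit at 0 ms")


@dataclass(frozen=True)
class TrueGlucoseTrace:
    timestamps: np.ndarray  # seconds since midnight, 1-min grid
    values: np.ndarray      # mmol/L
    n_dips: int = 0         # how many dip events were superposed (truth metadata)

    def at(self, t) -> np.ndarray:
        """Linear interpolation of the trace at arbitrary times (seconds)."""
        return np.interp(t, self.timestamps, self.values)


@dataclass(frozen=True)
class CGMSeries:
    timestamps: np.ndarray  # seconds, regular grid
    values: np.ndarray      # mmol/L
    lag_applied: float      # seconds
    mard_target: float      # percent

    @property
    def interval(self) -> float:
        return float(self.timestamps[1] - self.timestamps[0]) if len(self.timestamps) > 1 else np.nan


@dataclass(frozen=True)
class RawECG:
    samples: np.ndarray   # mV
    fs: float = FS_HZ     # Hz
    start_time: float = 0.0  # seconds since midnight

    def __post_init__(self):
        if self.fs != FS_HZ:
            raise ValueError(f"250 Hz required, got {self.fs}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("ECG samples must be finite")


@dataclass(frozen=True)
class NightRecording:
    ecg: RawECG
    accel: np.ndarray          # (n, 4): time_s, x_g, y_g, z_g at 1 Hz
    true_glucose: TrueGlucoseTrace
    cgm: CGMSeries
    truth_r_times: np.ndarray  # seconds, strictly increasing
    truth_morphs: list         # MorphParams per beat


@dataclass(frozen=True)
class SubjectRecording:
    profile: SubjectProfile
    nights: list


# ----------------------------------------------------------------------------
# Beat synthesis and glucose -> morphology coupling
# ----------------------------------------------------------------------------

def synth_beat(morph: MorphParams, fs: float = FS_HZ, t_start_ms: float = -400.0,
               t_end_ms: float = 600.0) -> tuple[np.ndarray, np.ndarray]:
    """Render one beat as a dense sum of the five Gaussians.

    Returns ``(t_ms, waveform_mv)`` sampled at ``fs`` over [t_start_ms, t_end_ms].
    """
    for w in morph.waves().values():
        if w.width <= 0:
            raise ValueError("non-positive wave width")
    step = 1000.0 / fs
    t = np.arange(t_start_ms, t_end_ms + step / 2, step)
    y = np.zeros_like(t)
    for w in morph.waves().values():
        y += w.amplitude * np.exp(-((t - w.center) ** 2) / (2.0 * w.width ** 2))
    return t, y


def couple_morphology(glucose: float, profile: SubjectProfile) -> MorphParams:
    """Morphology at a given true glucose: a step change below the onset threshold."""
    if glucose <= 0:
        raise ValueError("glucose must be positive")
    base = profile.wave_params
    eff = profile.hypo_effect
    if glucose >= eff.onset_glucose:
        return base
    return dataclasses.replace(
        base,
        t=dataclasses.replace(base.t, center=base.t.center + eff.delta_qt_ms,
                              amplitude=base.t.amplitude * eff.t_amp_scale),
        p=dataclasses.replace(base.p, amplitude=base.p.amplitude * eff.p_amp_scale),
    )


# ----------------------------------------------------------------------------
# Glucose and CGM
# ----------------------------------------------------------------------------

def simulate_glucose_night(profile: SubjectProfile, seed: int,
                           night_minutes: int = NIGHT_MINUTES) -> TrueGlucoseTrace:
    """True interstitial glucose on a 1-minute grid covering the night.

    baseline + Gaussian noise smoothed with a Gaussian kernel (+- raised-cosine
    dips placed by a Poisson process), clipped into the physiological band.
    """
    dyn = profile.glucose_dynamics
    rng = np.random.default_rng(seed)
    t_min = np.arange(night_minutes + 1, dtype=float)  # inclusive grid
    values = np.full_like(t_min, dyn.baseline)

    if dyn.noise_sd > 0:
        from scipy.ndimage import gaussian_filter1d

        white = rng.normal(0.0, 1.0, size=t_min.size)
        smooth = gaussian_filter1d(white, sigma=dyn.smoothness, mode="reflect")
        sd = smooth.std()
        if sd > 0:
            values += dyn.noise_sd * smooth / sd
    else:
        rng.normal(0.0, 1.0, size=t_min.size)  # keep stream alignment

    n_dips = rng.poisson(dyn.dip_rate)
    for _ in range(n_dips):
        start = rng.uniform(0, night_minutes)
        depth = min(
            abs(rng.normal(dyn.dip_depth_mean, dyn.dip_depth_sd)),
            dyn.baseline - GLUCOSE_FLOOR,
        )
        duration = max(10.0, rng.normal(dyn.dip_duration_mean, dyn.dip_duration_sd))
        phase = (t_min - start) / duration
        inside = (phase >= 0) & (phase <= 1)
        values[inside] -= depth * 0.5 * (1 - np.cos(2 * np.pi * phase[inside]))

    values = np.clip(values, GLUCOSE_FLOOR, GLUCOSE_CEIL)
    return TrueGlucoseTrace(timestamps=t_min * 60.0, values=values, n_dips=int(n_dips))


def _mard_sigma(mard_pct: float, trunc: float = 3.0) -> float:
    """Relative-error sigma so that E|eps| equals the MARD target under +-trunc·sigma truncation."""
    from scipy.stats import norm

    shrink = (1.0 - np.exp(-trunc ** 2 / 2.0)) / (2.0 * norm.cdf(trunc) - 1.0)
    return (mard_pct / 100.0) / (np.sqrt(2.0 / np.pi) * shrink)


def cgm_observe(trace: TrueGlucoseTrace, lag: float = 300.0, mard_target: float = 11.4,
                interval: float = 900.0, seed: int = 0) -> CGMSeries:
    """Observe a true trace through the CGM: lag, 15-min grid, multiplicative error.

    reading(t) = true(t - lag) * (1 + eps), eps ~ N(0, sigma) truncated at 3 sigma,
    sigma calibrated so E|eps| = mard_target / 100.
    """
    if lag < 0:
        raise ValueError("lag must be non-negative")
    t0, t1 = float(trace.timestamps[0]), float(trace.timestamps[-1])
    if t0 + lag > t1:
        raise ValueError("trace too short to honour the requested lag")
    grid = np.arange(t0 + lag, t1 + interval / 2, interval)
    grid = grid[grid - lag <= t1]
    truth = trace.at(grid - lag)
    if mard_target > 0:
        rng = np.random.default_rng(seed)
        sigma = _mard_sigma(mard_target)
        eps = rng.normal(0.0, sigma, size=grid.size)
        eps = np.clip(eps, -3 * sigma, 3 * sigma)
        values = truth * (1.0 + eps)
    else:
        values = truth.copy()
    return CGMSeries(timestamps=grid, values=np.maximum(values, 0.1),
                     lag_applied=lag, mard_target=mard_target)


# ----------------------------------------------------------------------------
# Full-night rendering
# ----------------------------------------------------------------------------

def _beat_times(profile: SubjectProfile, duration_s: float, rng: np.random.Generator) -> np.ndarray:
    """R-peak times from a per-beat instantaneous-HR model."""
    times = []
    t = 0.8  # leave headroom for the first beat's P wave
    while t < duration_s - 1.0:
        hr = profile.heart_rate_mean
        if profile.heart_rate_sd > 0:
            hr = np.clip(rng.normal(hr, profile.heart_rate_sd), 35.0, 180.0)
        else:
            rng.normal(hr, 1.0)  # keep stream alignment
        times.append(t)
        t += 60.0 / hr
    return np.asarray(times)


def _render_ecg(r_times: np.ndarray, morphs: list, n_samples: int,
                fs: float = FS_HZ) -> np.ndarray:
    """Sum per-beat Gaussian waves into a continuous signal (7-sigma support)."""
    sig = np.zeros(n_samples)
    for r_t, morph in zip(r_times, morphs):
        for w in morph.waves().values():
            c_s = r_t + w.center / 1000.0
            half_s = 7.0 * w.width / 1000.0
            i0 = max(0, int(np.ceil((c_s - half_s) * fs)))
            i1 = min(n_samples, int(np.floor((c_s + half_s) * fs)) + 1)
            if i1 <= i0:
                continue
            t_ms = (np.arange(i0, i1) / fs - c_s) * 1000.0
            sig[i0:i1] += w.amplitude * np.exp(-(t_ms ** 2) / (2.0 * w.width ** 2))
    return sig


def _simulate_accel(duration_s: float, artifact_rate: float,
                    rng: np.random.Generator) -> np.ndarray:
    """1-Hz triaxial accelerations in g: rest posture plus occasional movement bursts."""
    t = np.arange(int(duration_s))
    xyz = np.column_stack([
        rng.normal(0.0, 0.01, t.size),
        rng.normal(0.0, 0.01, t.size),
        1.0 + rng.normal(0.0, 0.01, t.size),
    ])
    n_bursts = rng.poisson(artifact_rate * duration_s / 3600.0)
    for _ in range(n_bursts):
        s = int(rng.uniform(0, max(1, t.size - 30)))
        xyz[s:s + 30] += rng.normal(0.0, 0.4, size=(min(30, t.size - s), 3))
    return np.column_stack([t.astype(float), xyz])


def simulate_night(profile: SubjectProfile, seed: int,
                   night_minutes: int = NIGHT_MINUTES,
                   cgm_lag: float = 300.0, cgm_interval: float = 900.0,
                   mard_target: float = 11.4) -> NightRecording:
    """One night: glucose, coupled beats, continuous ECG, accelerations, CGM."""
    trace = simulate_glucose_night(profile, seed=seed, night_minutes=night_minutes)
    rng = np.random.default_rng((seed, 1))
    duration_s = night_minutes * 60.0
    n_samples = int(duration_s * FS_HZ)

    r_times = _beat_times(profile, duration_s, rng)
    glucose_at_beats = trace.at(r_times)
    morphs = [couple_morphology(g, profile) for g in glucose_at_beats]
    sig = _render_ecg(r_times, morphs, n_samples)

    noise = profile.noise
    t_s = np.arange(n_samples) / FS_HZ
    if noise.baseline_wander_amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        sig = sig + noise.baseline_wander_amp * np.sin(2 * np.pi * 0.25 * t_s + phase)
    if noise.ecg_sd > 0:
        sig = sig + rng.normal(0.0, noise.ecg_sd, size=n_samples)
    n_art = rng.poisson(noise.artifact_rate * duration_s / 3600.0)
    for _ in range(n_art):
        s = int(rng.uniform(0, n_samples - FS_HZ // 2))
        sig[s:s + FS_HZ // 2] += rng.normal(0.0, 1.0, size=FS_HZ // 2)

    accel = _simulate_accel(duration_s, noise.artifact_rate, rng)
    cgm = cgm_observe(trace, lag=cgm_lag, mard_target=mard_target,
                      interval=cgm_interval, seed=int(np.random.default_rng((seed, 2)).integers(2 ** 31)))
    return NightRecording(
        ecg=RawECG(samples=sig, fs=FS_HZ, start_time=0.0),
        accel=accel,
        true_glucose=trace,
        cgm=cgm,
        truth_r_times=r_times,
        truth_morphs=morphs,
    )


def simulate_subject(profile: SubjectProfile, n_nights: int = 10, seed: int | None = None,
                     night_minutes: int = NIGHT_MINUTES, mard_target: float = 11.4,
                     cgm_lag: float = 300.0, cgm_interval: float = 900.0) -> SubjectRecording:
    """A multi-night recording bundle for one subject (deterministic in (profile, seed))."""
    if n_nights < 2:
        raise ValueError("need at least 2 nights")
    base_seed = profile.seed if seed is None else seed
    nights = [
        simulate_night(profile, seed=int(np.random.default_rng((base_seed, k)).integers(2 ** 31)),
                       night_minutes=night_minutes, cgm_lag=cgm_lag,
                       cgm_interval=cgm_interval, mard_target=mard_target)
        for k in range(n_nights)
    ]
    return SubjectRecording(profile=profile, nights=nights)
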