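"""Synthetic multi-subject motor-imagery EEG with ERD/ERS structure.

Emulates a cue-paced two-class (left/right hand) motor-imagery protocol
recorded from three sensorimotor electrodes (C3, Cz, C4) at 250 Hz.  During
the imagery period (3-7 s of an 8 s trial) the mu (8-14 Hz) and beta
(14-30 Hz) rhythms over the motor cortex *contralateral* to the imagined
hand desynchronize: their amplitude drops by a subject-specific fraction
(``erd_depth``).  The ipsilateral electrode shows a weaker drop controlled
by ``lateralization`` (1 = fully lateralized, 0 = symmetric).  Cz carries a
weak class-independent rhythm.  Background activity is pink (1/f) noise
band-limited to roughly 1-45 Hz, so that essentially all signal power lies
in the physiological band.

Subjects differ in rhythm frequency, ERD depth, lateralization and noise
level, which is the stand-in for between-subject variability that makes
cross-subject transfer non-trivial.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CHANNELS = ("C3", "Cz", "C4")
LABELS = ("left", "right")

#: imagery window within a trial, seconds
IMAGERY_WINDOW = (3.0, 7.0)

# parameter draw ranges for make_subject
_MU_RANGE = (9.0, 13.0)
_BETA_RANGE = (18.0, 24.0)
_ERD_RANGE = (0.45, 0.75)
_LAT_RANGE = (0.6, 1.0)
_NOISE_RANGE = (0.8, 1.2)

# rhythm amplitudes relative to noise_sd
_MU_AMP = 1.3
_BETA_AMP = 0.6
_CZ_AMP = 0.4

_RAMP_S = 0.25  # raised-cosine ramp on the ERD envelope, seconds


@dataclass(frozen=True)
class SubjectProfile:
    """Generative parameters of one simulated subject."""

    subject_id: int
    mu_freq: float
    beta_freq: float
    erd_depth: float
    lateralization: float
    noise_sd: float
    seed: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.erd_depth <= 1.0:
            raise ValueError(f"erd_depth must be in [0, 1], got {self.erd_depth}")
        if not 0.0 <= self.lateralization <= 1.0:
            raise ValueError(
                f"lateralization must be in [0, 1], got {self.lateralization}"
            )
        if not 8.0 <= self.mu_freq <= 30.0:
            raise ValueError(f"mu_freq must lie in the 8-30 Hz band, got {self.mu_freq}")
        if not 8.0 <= self.beta_freq <= 30.0:
            raise ValueError(
                f"beta_freq must lie in the 8-30 Hz band, got {self.beta_freq}"
            )
        if self.noise_sd <= 0:
            raise ValueError(f"noise_sd must be positive, got {self.noise_sd}")


@dataclass(frozen=True)
class EEGTrial:
    """One labelled 3-channel epoch, microvolt-scaled."""

    subject_id: int
    session_id: int
    trial_id: int
    label: str
    fs: float
    channels: tuple[str, ...]
    signal: np.ndarray  # [n_channels, n_samples]
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        if self.signal.ndim != 2 or self.signal.shape[0] != len(self.channels):
            raise ValueError(
                f"signal must be [n_channels={len(self.channels)}, n_samples], "
                f"got shape {self.signal.shape}"
            )

    @property
    def duration_s(self) -> float:
        return self.signal.shape[1] / self.fs

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]


def make_subject(
    subject_id: int, seed: int, overrides: dict | None = None
) -> SubjectProfile:
    """Draw a deterministic subject profile.

    The same ``(subject_id, seed)`` pair always yields the same profile.
    ``overrides`` pins individual parameters; out-of-range values raise.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, subject_id)))
    params = dict(
        subject_id=subject_id,
        mu_freq=rng.uniform(*_MU_RANGE),
        beta_freq=rng.uniform(*_BETA_RANGE),
        erd_depth=rng.uniform(*_ERD_RANGE),
        lateralization=rng.uniform(*_LAT_RANGE),
        noise_sd=rng.uniform(*_NOISE_RANGE),
        seed=seed,
    )
    if overrides:
        unknown = set(overrides) - set(params)
        if unknown:
            raise ValueError(f"unknown profile overrides: {sorted(unknown)}")
        params.update(overrides)
    return SubjectProfile(**params)


def _pink_noise(rng: np.random.Generator, n: int, fs: float, sd: float) -> np.ndarray:
    """Band-limited 1/f noise: flat-ish 1/f amplitude over ~1-45 Hz, steep
    roll-off outside, unit-free amplitude scaled to standard deviation sd."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    amp = 1.0 / np.maximum(freqs, 1.0)
    # confine the noise to ~1-45 Hz: zero below 1 Hz, raised-cosine ramp
    # over 1-2 Hz, steep exponential roll-off above 45 Hz
    amp[freqs > 45.0] *= np.exp(-(freqs[freqs > 45.0] - 45.0) / 1.5)
    ramp = (freqs >= 1.0) & (freqs < 2.0)
    amp[ramp] *= 0.5 * (1 - np.cos(np.pi * (freqs[ramp] - 1.0)))
    amp[freqs < 1.0] = 0.0
    phases = rng.uniform(0, 2 * np.pi, size=freqs.size)
    spec = amp * np.exp(1j * phases)
    spec[0] = 0.0
    x = np.fft.irfft(spec, n=n)
    x /= x.std() + 1e-30
    return sd * x


def _erd_envelope(
    t: np.ndarray, depth: float, fs: float, window: tuple[float, float] = IMAGERY_WINDOW
) -> np.ndarray:
    """Multiplicative amplitude envelope: 1 at baseline, (1 - depth) during the
    imagery window, with raised-cosine ramps to avoid spectral splatter."""
    start, end = window
    env = np.ones_like(t)
    ramp = _RAMP_S

    def smooth(u: np.ndarray) -> np.ndarray:
        # 0 -> 1 raised cosine on u in [0, 1]
        return 0.5 * (1 - np.cos(np.pi * np.clip(u, 0.0, 1.0)))

    drop = smooth((t - start) / ramp) - smooth((t - end) / ramp)
    return env - depth * drop


def simulate_trials(
    profile: SubjectProfile,
    n_trials: int,
    duration_s: float = 8.0,
    fs: float = 250.0,
    session_id: int = 1,
) -> list[EEGTrial]:
    """Generate ``n_trials`` labelled trials for one subject.

    Labels are exactly balanced (n_trials must be even) and interleaved in a
    seeded random order.  Each trial is pink background noise plus mu and
    beta oscillations whose amplitude over the contralateral electrode is
    suppressed by ``erd_depth`` during the 3-7 s imagery window; the
    ipsilateral suppression is scaled down by ``lateralization``.
    Deterministic given (profile, n_trials, duration, fs).
    """
    if n_trials < 2 or n_trials % 2:
        raise ValueError(f"n_trials must be even and >= 2, got {n_trials}")
    if duration_s < 7.0:
        raise ValueError(
            f"duration_s must be >= 7 s so the 3-7 s imagery epoch exists, "
            f"got {duration_s}"
        )

    rng = np.random.default_rng(
        np.random.SeedSequence((profile.seed, profile.subject_id, session_id, 7))
    )
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs

    labels = np.array([0, 1] * (n_trials // 2))
    rng.shuffle(labels)

    contra_env = _erd_envelope(t, profile.erd_depth, fs)
    ipsi_depth = profile.erd_depth * (1.0 - profile.lateralization)
    ipsi_env = _erd_envelope(t, ipsi_depth, fs)
    flat = np.ones_like(t)

    trials: list[EEGTrial] = []
    for k, lab in enumerate(labels):
        label = LABELS[lab]
        sig = np.empty((3, n))
        # left imagery -> contralateral hemisphere is right -> C4; right -> C3
        if label == "left":
            envs = (ipsi_env, flat, contra_env)  # C3, Cz, C4
        else:
            envs = (contra_env, flat, ipsi_env)
        for ch, env in enumerate(envs):
            noise = _pink_noise(rng, n, fs, profile.noise_sd)
            mu_ph, beta_ph = rng.uniform(0, 2 * np.pi, 2)
            amp = _CZ_AMP if ch == 1 else 1.0
            mu = _MU_AMP * amp * np.sin(2 * np.pi * profile.mu_freq * t + mu_ph)
            beta = _BETA_AMP * amp * np.sin(2 * np.pi * profile.beta_freq * t + beta_ph)
            sig[ch] = noise + profile.noise_sd * env * (mu + beta)
        trials.append(
            EEGTrial(
                subject_id=profile.subject_id,
                session_id=session_id,
                trial_id=k,
                label=label,
                fs=fs,
                channels=CHANNELS,
                signal=sig,
            )
        )
    return trials


def simulate_cohort(
    n_subjects: int = 9,
    n_trials: int = 720,
    seed: int = 0,
    duration_s: float = 8.0,
    fs: float = 250.0,
    profile_overrides: dict | None = None,
) -> dict[int, list[EEGTrial]]:
    """Simulate a cohort: ``n_subjects`` subjects with ``n_trials`` each.

    Subject ids run 1..n_subjects.  One master seed drives everything.
    """
    cohort: dict[int, list[EEGTrial]] = {}
    for sid in range(1, n_subjects + 1):
        profile = make_subject(sid, seed, overrides=profile_overrides)
        cohort[sid] = simulate_trials(profile, n_trials, duration_s, fs)
    return cohort


def band_power(trial: EEGTrial, band: tuple[float, float], window=IMAGERY_WINDOW):
    """Mean power per channel in a frequency band over a time window (Welch)."""
    from scipy.signal import welch

    i0, i1 = (int(round(w * trial.fs)) for w in window)
    seg = trial.signal[:, i0:i1]
    f, p = welch(seg, fs=trial.fs, nperseg=min(256, seg.shape[1]), axis=-1)
    sel = (f >= band[0]) & (f <= band[1])
    return p[:, sel].mean(axis=-1)
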