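"""STFT spectrogram imaging of filtered epochs.

Each 3-channel epoch becomes two views of one short-time Fourier transform:

* ``stacked`` — the three per-channel power matrices vertically concatenated
  (C3 on top, then Cz, then C4) and resized to a 64x64 grayscale image.
  This is the input to the perceptual hash.
* ``planes`` — each channel resized to 64x64 independently and stacked along
  a third axis, giving a 64x64x3 tensor for the CNN (electrode-as-plane, not
  RGB).

Power is magnitude-squared STFT, cropped to the 8-30 Hz pass-band,
log10-scaled and min-max normalized to [0, 1] per trial.  The min-max is
taken jointly over the three channels so the contralateral-vs-ipsilateral
power asymmetry (the ERD signature) survives normalization.  A constant
(zero-range) power matrix maps to all zeros by rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import ShortTimeFFT
from scipy.signal.windows import hann
from skimage.transform import resize

from .synthetic import EEGTrial

_EPS = 1e-12
IMAGE_SIZE = 64


@dataclass(frozen=True)
class StftSpec:
    window_size: int = 256
    overlap: int = 224
    window_fn: str = "hann"
    freq_crop: tuple[float, float] | None = (8.0, 30.0)
    log_power: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.overlap < self.window_size:
            raise ValueError(
                f"need 0 <= overlap < window_size, got {self.overlap}/{self.window_size}"
            )
        if self.window_fn != "hann":
            raise ValueError(f"unsupported window {self.window_fn!r}")

    @property
    def hop(self) -> int:
        return self.window_size - self.overlap


@dataclass(frozen=True)
class SpectrogramImage:
    """Normalized time-frequency views of one trial."""

    stacked: np.ndarray  # [64, 64], grayscale in [0, 1] -- hash input
    planes: np.ndarray  # [64, 64, 3] in [0, 1] -- CNN input
    subject_id: int
    trial_id: int
    label: str
    session_id: int = 1


@dataclass(frozen=True)
class TargetPrototype:
    """Per-class average stacked spectrogram of a target subject's training set."""

    image: np.ndarray  # [64, 64]
    label: str
    n_trials: int


def stft_spectrogram(trial: EEGTrial, spec: StftSpec = StftSpec()) -> np.ndarray:
    """Per-channel normalized power matrices, shape [3, n_freq, n_time].

    Magnitude-squared STFT per channel, frequency axis cropped to
    ``freq_crop``, log10 power, then joint min-max normalization to [0, 1].
    """
    n = trial.n_samples
    if n < spec.window_size:
        raise ValueError(
            f"epoch of {n} samples shorter than STFT window {spec.window_size}"
        )
    win = hann(spec.window_size, sym=True)
    stft = ShortTimeFFT(win, hop=spec.hop, fs=trial.fs, fft_mode="onesided")
    # p0/p1 restrict to windows fully inside the signal (no zero-padding)
    p0 = stft.lower_border_end[1]
    p1 = stft.upper_border_begin(n)[1]
    S = stft.stft(trial.signal, p0=p0, p1=p1, axis=-1)
    power = np.abs(S) ** 2
    freqs = stft.f
    if spec.freq_crop is not None:
        lo, hi = spec.freq_crop
        sel = (freqs >= lo) & (freqs <= hi)
        power = power[:, sel, :]
    if spec.log_power:
        power = np.log10(power + _EPS)
    lo, hi = power.min(), power.max()
    if hi - lo < _EPS:
        return np.zeros_like(power)
    return (power - lo) / (hi - lo)


def stack_and_resize(channel_power: np.ndarray, *, trial: EEGTrial | None = None,
                     size: int = IMAGE_SIZE) -> SpectrogramImage:
    """Build both image views from per-channel power matrices.

    ``channel_power`` is [3, n_freq, n_time] as returned by
    :func:`stft_spectrogram`.  Stacked view: vertical concatenation (C3, Cz,
    C4 top to bottom) resized to 64x64 with bilinear interpolation.  Planes
    view: each channel resized to 64x64 independently, stacked on axis 2 in
    order (C3, Cz, C4).
    """
    if channel_power.ndim != 3 or channel_power.shape[0] != 3:
        raise ValueError(
            f"expected [3, n_freq, n_time] channel power, got {channel_power.shape}"
        )

    def _resize(img: np.ndarray) -> np.ndarray:
        out = resize(img, (size, size), order=1, mode="edge",
                     anti_aliasing=False, preserve_range=True)
        return np.clip(out, 0.0, 1.0)

    stacked = _resize(np.concatenate(list(channel_power), axis=0))
    planes = np.stack([_resize(c) for c in channel_power], axis=2)
    if trial is None:
        return SpectrogramImage(stacked, planes, subject_id=-1, trial_id=-1,
                                label="left")
    return SpectrogramImage(
        stacked, planes,
        subject_id=trial.subject_id, trial_id=trial.trial_id,
        label=trial.label, session_id=trial.session_id,
    )


def compute_spectrogram(trial: EEGTrial, spec: StftSpec = StftSpec()) -> SpectrogramImage:
    """Full epoch -> SpectrogramImage pipeline for one trial."""
    return stack_and_resize(stft_spectrogram(trial, spec), trial=trial)


def class_prototypes(
    images: list[SpectrogramImage], pooled: bool = False
) -> dict[str, TargetPrototype]:
    """Element-wise mean stacked spectrogram per class (the target template).

    With ``pooled=True`` a single prototype over all trials is returned under
    the key ``"all"``.
    """
    if not images:
        raise ValueError("cannot build prototypes from an empty image list")
    if pooled:
        mean = np.mean([im.stacked for im in images], axis=0)
        return {"all": TargetPrototype(mean, "all", len(images))}
    out: dict[str, TargetPrototype] = {}
    for label in ("left", "right"):
        members = [im.stacked for im in images if im.label == label]
        if not members:
            raise ValueError(f"no trials of class {label!r} to average")
        out[label] = TargetPrototype(np.mean(members, axis=0), label, len(members))
    return out
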