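"""Band-pass filtering (8-30 Hz Butterworth, order 6) and epoch extraction.

The filter is applied to the full trial before the 3-7 s imagery epoch is
cut, so that filter edge transients fall outside the analysed window.
Zero-phase (forward-backward) application is the default: phase handling
matters because downstream time-frequency analysis reads ERD timing off the
epoch.  Forward-backward filtering doubles the effective order; set
``zero_phase=False`` for a causal single pass.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import butter, sosfilt, sosfiltfilt

from .synthetic import EEGTrial


@dataclass(frozen=True)
class FilterSpec:
    band: tuple[float, float] = (8.0, 30.0)
    order: int = 6
    family: str = "butterworth"
    zero_phase: bool = True

    def __post_init__(self) -> None:
        low, high = self.band
        if not 0 < low < high:
            raise ValueError(f"need 0 < low < high, got band={self.band}")
        if self.order < 1:
            raise ValueError(f"order must be >= 1, got {self.order}")
        if self.family != "butterworth":
            raise ValueError(f"unsupported filter family {self.family!r}")


@dataclass(frozen=True)
class Epoch:
    """Half-open time window [start, end) in seconds relative to trial onset."""

    window: tuple[float, float] = (3.0, 7.0)

    def __post_init__(self) -> None:
        start, end = self.window
        if end <= start:
            raise ValueError(f"epoch end must exceed start, got {self.window}")


def bandpass(trial: EEGTrial, spec: FilterSpec = FilterSpec()) -> EEGTrial:
    """Band-pass filter a trial; returns a new trial with filter metadata."""
    low, high = spec.band
    if trial.fs <= 2 * high:
        raise ValueError(
            f"band {spec.band} infeasible at fs={trial.fs} Hz (need fs > {2 * high})"
        )
    sos = butter(spec.order, spec.band, btype="bandpass", fs=trial.fs, output="sos")
    if spec.zero_phase:
        filtered = sosfiltfilt(sos, trial.signal, axis=-1)
    else:
        filtered = sosfilt(sos, trial.signal, axis=-1)
    meta = dict(trial.meta)
    meta["filter"] = dict(
        band=spec.band, order=spec.order, family=spec.family, zero_phase=spec.zero_phase
    )
    return replace(trial, signal=np.ascontiguousarray(filtered), meta=meta)


def extract_epoch(trial: EEGTrial, epoch: Epoch = Epoch()) -> EEGTrial:
    """Cut the epoch window from a trial; half-open sample indexing [start, end)."""
    start, end = epoch.window
    i0 = int(round(start * trial.fs))
    i1 = int(round(end * trial.fs))
    if i0 < 0 or i1 > trial.n_samples:
        raise ValueError(
            f"epoch window {epoch.window} s exceeds trial of "
            f"{trial.duration_s:.3f} s"
        )
    meta = dict(trial.meta)
    meta["epoch"] = dict(window=epoch.window)
    return replace(trial, signal=trial.signal[:, i0:i1].copy(), meta=meta)


def preprocess_trial(
    trial: EEGTrial, spec: FilterSpec = FilterSpec(), epoch: Epoch = Epoch()
) -> EEGTrial:
    """Filter the full trial, then extract the imagery epoch."""
    return extract_epoch(bandpass(trial, spec), epoch)
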