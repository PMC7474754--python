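"""HDF5 trial-container format.

Layout: one group per subject named ``subject_<id>`` holding

    signals    float64 [n_trials, n_channels, n_samples]
    labels     int64   [n_trials]      (0 = left, 1 = right)
    trial_ids  int64   [n_trials]
    session_ids int64  [n_trials]

with file-level attributes ``fs`` (Hz), ``channels`` and optionally
``seed`` (generator seed for synthetic data).  Round-trips are lossless
(floating point exact).
"""

from __future__ import annotations

import numpy as np
import h5py

from .synthetic import CHANNELS, LABELS, EEGTrial

INT_TO_LABEL = dict(enumerate(LABELS))
LABEL_TO_INT = {v: k for k, v in INT_TO_LABEL.items()}


def write_container(
    dataset: dict[int, list[EEGTrial]], path: str, seed: int | None = None
) -> None:
    """Write a cohort (subject id -> trials) to an HDF5 file."""
    if not dataset:
        raise ValueError("refusing to write an empty dataset")
    with h5py.File(path, "w") as f:
        first = next(iter(dataset.values()))[0]
        f.attrs["fs"] = first.fs
        f.attrs["channels"] = list(first.channels)
        if seed is not None:
            f.attrs["seed"] = seed
        for sid, trials in sorted(dataset.items()):
            if not trials:
                raise ValueError(f"subject {sid} has no trials")
            g = f.create_group(f"subject_{sid}")
            g.create_dataset(
                "signals", data=np.stack([t.signal for t in trials])
            )
            g.create_dataset(
                "labels", data=np.array([LABEL_TO_INT[t.label] for t in trials])
            )
            g.create_dataset("trial_ids", data=np.array([t.trial_id for t in trials]))
            g.create_dataset(
                "session_ids", data=np.array([t.session_id for t in trials])
            )


def read_container(path: str) -> dict[int, list[EEGTrial]]:
    """Read a cohort back; validates labels, shapes and required attributes."""
    dataset: dict[int, list[EEGTrial]] = {}
    with h5py.File(path, "r") as f:
        for attr in ("fs", "channels"):
            if attr not in f.attrs:
                raise ValueError(f"container missing required attribute {attr!r}")
        fs = float(f.attrs["fs"])
        channels = tuple(
            c.decode() if isinstance(c, bytes) else str(c) for c in f.attrs["channels"]
        )
        for name in sorted(f.keys()):
            if not name.startswith("subject_"):
                continue
            sid = int(name.split("_", 1)[1])
            g = f[name]
            signals = np.asarray(g["signals"])
            labels = np.asarray(g["labels"])
            if signals.ndim != 3 or signals.shape[1] != len(channels):
                raise ValueError(
                    f"{name}: signals must be [n_trials, {len(channels)}, n_samples], "
                    f"got {signals.shape}"
                )
            if signals.shape[0] == 0:
                raise ValueError(f"{name}: empty subject group")
            bad = {int(v) for v in np.unique(labels)} - set(INT_TO_LABEL)
            if bad:
                raise ValueError(
                    f"{name}: unknown label value(s) {sorted(bad)}; "
                    f"expected {sorted(INT_TO_LABEL)}"
                )
            trial_ids = np.asarray(g["trial_ids"]) if "trial_ids" in g else np.arange(
                signals.shape[0]
            )
            session_ids = (
                np.asarray(g["session_ids"])
                if "session_ids" in g
                else np.ones(signals.shape[0], dtype=int)
            )
            dataset[sid] = [
                EEGTrial(
                    subject_id=sid,
                    session_id=int(session_ids[i]),
                    trial_id=int(trial_ids[i]),
                    label=INT_TO_LABEL[int(labels[i])],
                    fs=fs,
                    channels=channels,
                    signal=signals[i],
                )
                for i in range(signals.shape[0])
            ]
    if not dataset:
        raise ValueError("container holds no subject groups")
    return dataset


def trials_from_mne_raw(
    raw,
    events: np.ndarray,
    event_id: dict[str, int],
    subject_id: int,
    duration_s: float = 8.0,
    channels: tuple[str, ...] = CHANNELS,
) -> list[EEGTrial]:
    """Adapter from an ``mne.io.Raw`` recording (e.g. loaded from EDF/GDF)
    to the trial container model.

    ``events`` is the standard (n, 3) MNE event array; ``event_id`` maps
    the labels ``"left"``/``"right"`` to event codes.  Cuts a
    ``duration_s`` window starting at each event onset from the three
    sensorimotor channels.  Channel picking is by name and case-insensitive.
    """
    name_map = {name.lower(): i for i, name in enumerate(raw.ch_names)}
    try:
        picks = [name_map[c.lower()] for c in channels]
    except KeyError as e:
        raise ValueError(f"recording lacks required channel {e}") from None
    fs = float(raw.info["sfreq"])
    data = raw.get_data(picks=picks)
    n_win = int(round(duration_s * fs))
    code_to_label = {v: k for k, v in event_id.items()}
    unknown = set(code_to_label.values()) - set(LABELS)
    if unknown:
        raise ValueError(f"event_id labels must be in {LABELS}, got {sorted(unknown)}")
    trials = []
    for k, (onset, _, code) in enumerate(np.asarray(events)):
        if int(code) not in code_to_label:
            continue
        if onset + n_win > data.shape[1]:
            raise ValueError(f"event at sample {onset} exceeds the recording")
        trials.append(
            EEGTrial(
                subject_id=subject_id,
                session_id=1,
                trial_id=k,
                label=code_to_label[int(code)],
                fs=fs,
                channels=tuple(channels),
                signal=data[:, int(onset) : int(onset) + n_win] * 1e6,  # V -> uV
            )
        )
    if not trials:
        raise ValueError("no events matched event_id")
    return trials
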