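"""Instance transfer: from Hamming distances to a weighted training set.

Every source-domain trial (a trial from another subject) is hashed and
compared against the target subject's class prototype of the *same* class.
The Hamming distance d_H in [0, 64] is converted to a training weight

    w = 1 - d_H / 64,

so that trials whose spectrograms resemble the target's contribute more.
The raw distance is recorded alongside the weight.  A distance threshold
selects which source trials are transferred at all (threshold 64 transfers
everything, weighted; threshold 0 degenerates to subject-dependent
training).  The transferred portion is class-balanced by subsampling the
larger class highest-weight-first; the target subject's own trials always
enter with weight 1 and are never subsampled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phash import HASH_BITS, HashCode, hamming, phash
from .spectrogram import SpectrogramImage, TargetPrototype


@dataclass(frozen=True)
class TransferInstance:
    """One source trial scored against the matching-class target prototype."""

    subject_id: int
    trial_id: int
    label: str
    d_hash: int
    weight: float
    selected: bool = False
    image: SpectrogramImage | None = field(default=None, compare=False, repr=False)


@dataclass(frozen=True)
class TransferPolicy:
    distance_threshold: int = 16
    weighting_mode: str = "loss_weight"  # loss_weight | replicate | uniform
    balance_classes: bool = True
    max_instances_per_source_subject: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.distance_threshold <= HASH_BITS:
            raise ValueError(
                f"distance_threshold must be in [0, {HASH_BITS}], "
                f"got {self.distance_threshold}"
            )
        if self.weighting_mode not in ("loss_weight", "replicate", "uniform"):
            raise ValueError(f"unknown weighting_mode {self.weighting_mode!r}")


@dataclass
class WeightedTrainingSet:
    """CNN-ready training set: images, integer labels, per-sample weights."""

    X: np.ndarray  # [n, 64, 64, 3]
    y: np.ndarray  # [n] in {0, 1} (0 = left, 1 = right)
    weights: np.ndarray  # [n] in (0, 1]
    n_target: int  # first n_target rows are the target subject's own trials
    transfer_log: dict = field(default_factory=dict)


LABEL_TO_INT = {"left": 0, "right": 1}


def score_sources(
    sources: list[SpectrogramImage],
    prototypes: dict[str, TargetPrototype],
) -> list[TransferInstance]:
    """Score every source trial against the prototype of its own class.

    Returns one :class:`TransferInstance` per source trial with its Hamming
    distance and weight; selection is applied separately by
    :func:`assemble_itsd_training_set`.
    """
    proto_hashes: dict[str, HashCode] = {}
    for label, proto in prototypes.items():
        proto_hashes[label] = phash(proto.image, source_id=("prototype", label))
    out = []
    for im in sources:
        key = im.label if im.label in proto_hashes else "all"
        if key not in proto_hashes:
            raise ValueError(f"no prototype for class {im.label!r}")
        d = hamming(phash(im.stacked), proto_hashes[key])
        out.append(
            TransferInstance(
                subject_id=im.subject_id,
                trial_id=im.trial_id,
                label=im.label,
                d_hash=d,
                weight=1.0 - d / HASH_BITS,
                image=im,
            )
        )
    return out


def select_instances(
    scored: list[TransferInstance], policy: TransferPolicy
) -> list[TransferInstance]:
    """Apply the distance threshold, per-subject cap and class balancing."""
    kept = [s for s in scored if s.d_hash <= policy.distance_threshold]

    if policy.max_instances_per_source_subject is not None:
        by_subject: dict[int, list[TransferInstance]] = {}
        for s in kept:
            by_subject.setdefault(s.subject_id, []).append(s)
        kept = []
        for sid in sorted(by_subject):
            group = sorted(
                by_subject[sid], key=lambda s: (-s.weight, s.subject_id, s.trial_id)
            )
            kept.extend(group[: policy.max_instances_per_source_subject])

    if policy.balance_classes:
        by_class: dict[str, list[TransferInstance]] = {"left": [], "right": []}
        for s in kept:
            by_class.setdefault(s.label, []).append(s)
        n_min = min(len(v) for v in by_class.values()) if by_class else 0
        kept = []
        for label, group in by_class.items():
            group = sorted(group, key=lambda s: (-s.weight, s.subject_id, s.trial_id))
            kept.extend(group[:n_min])

    kept.sort(key=lambda s: (s.subject_id, s.trial_id))
    return [
        TransferInstance(
            s.subject_id, s.trial_id, s.label, s.d_hash, s.weight, True, s.image
        )
        for s in kept
    ]


def assemble_itsd_training_set(
    target_images: list[SpectrogramImage],
    scored: list[TransferInstance],
    policy: TransferPolicy = TransferPolicy(),
) -> WeightedTrainingSet:
    """Target trials (weight 1) plus selected, weighted source trials.

    ``replicate`` weighting duplicates each selected instance
    round(4 * weight) times at weight 1 instead of carrying a loss weight;
    ``uniform`` transfers selected instances at weight 1.
    """
    target_labels = {im.label for im in target_images}
    selected = select_instances(scored, policy)
    if len(target_labels) < 2 and not selected:
        raise ValueError(
            "target training set is single-class and no source instances "
            "survive the transfer threshold"
        )

    X = [im.planes for im in target_images]
    y = [LABEL_TO_INT[im.label] for im in target_images]
    w = [1.0] * len(target_images)
    n_target = len(target_images)

    per_subject: dict[int, int] = {}
    per_class = {"left": 0, "right": 0}
    for s in selected:
        if s.image is None:
            raise ValueError("selected instance carries no image data")
        reps, weight = 1, s.weight
        if policy.weighting_mode == "replicate":
            reps, weight = max(1, int(round(4 * s.weight))), 1.0
        elif policy.weighting_mode == "uniform":
            weight = 1.0
        for _ in range(reps):
            X.append(s.image.planes)
            y.append(LABEL_TO_INT[s.label])
            w.append(weight)
        per_subject[s.subject_id] = per_subject.get(s.subject_id, 0) + 1
        per_class[s.label] += 1

    log = dict(
        n_target=n_target,
        n_transferred=len(selected),
        per_source_subject=per_subject,
        per_class=per_class,
        threshold=policy.distance_threshold,
        weighting_mode=policy.weighting_mode,
    )
    return WeightedTrainingSet(
        X=np.asarray(X, dtype=np.float32),
        y=np.asarray(y, dtype=np.int64),
        weights=np.asarray(w, dtype=np.float64),
        n_target=n_target,
        transfer_log=log,
    )
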