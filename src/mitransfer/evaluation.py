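"""Training strategies (SD, SI, ITSD), cross-validation and metrics.

* SD  — subject-dependent: stratified k-fold (default 10) over the target
  subject's own trials; train on k-1 folds, test on the held-out fold.
* SI  — subject-independent: train on every trial of every *other* subject,
  test on the full target set.
* ITSD — SD folds, but each fold's training portion is augmented with
  similarity-weighted source trials.  Class prototypes and transfer weights
  are computed only from that fold's training portion, so no test trial ever
  influences instance selection (leakage-free by construction).

Accuracy is complemented by a chance-corrected kappa,
kappa = (acc - rand) / (1 - rand) with rand = 0.5 for this balanced
two-class task.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold

from .cnn import CnnConfig, build_model, predict, train
from .spectrogram import SpectrogramImage, class_prototypes
from .transfer import (
    LABEL_TO_INT,
    TransferPolicy,
    WeightedTrainingSet,
    assemble_itsd_training_set,
    score_sources,
)

STRATEGIES = ("SD", "SI", "ITSD")


@dataclass(frozen=True)
class StrategySpec:
    strategy: str
    target_subject: int
    n_folds: int = 10
    seed: int = 0
    transfer_policy: TransferPolicy = field(default_factory=TransferPolicy)
    cnn: CnnConfig = field(default_factory=CnnConfig)
    epochs: int | None = None  # None -> cnn.max_epochs
    max_target_train: int | None = None  # cap on per-fold target training trials

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"strategy must be one of {STRATEGIES}")
        if self.n_folds < 2:
            raise ValueError("need at least 2 folds")


@dataclass
class Fold:
    """One train/test split with provenance ids for leakage auditing."""

    train_set: WeightedTrainingSet
    test_images: list[SpectrogramImage]
    train_ids: list[tuple[int, int]]  # (subject_id, trial_id) incl. transferred
    test_ids: list[tuple[int, int]]
    prototype_ids: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class StrategyReport:
    spec: StrategySpec
    fold_accuracy: list[float]
    fold_kappa: list[float]
    confusion_matrices: list[np.ndarray]
    partition_sizes: list[tuple[int, int]]  # (n_train, n_test) per fold
    transfer_logs: list[dict]

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracy))

    @property
    def std_accuracy(self) -> float:
        return float(np.std(self.fold_accuracy))

    @property
    def mean_kappa(self) -> float:
        return float(np.mean(self.fold_kappa))

    def summary(self) -> dict:
        return dict(
            strategy=self.spec.strategy,
            target_subject=self.spec.target_subject,
            mean_accuracy=self.mean_accuracy,
            std_accuracy=self.std_accuracy,
            mean_kappa=self.mean_kappa,
            fold_accuracy=list(self.fold_accuracy),
            fold_kappa=list(self.fold_kappa),
            partition_sizes=[list(p) for p in self.partition_sizes],
            transfer=[dict(t) for t in self.transfer_logs],
        )


def kappa(acc: float, rand: float = 0.5) -> float:
    """Chance-corrected agreement: (acc - rand) / (1 - rand)."""
    if not 0.0 <= acc <= 1.0:
        raise ValueError(f"accuracy must be in [0, 1], got {acc}")
    if not 0.0 <= rand < 1.0:
        raise ValueError(f"rand must be in [0, 1), got {rand}")
    return (acc - rand) / (1.0 - rand)


def _target_only_set(images: list[SpectrogramImage]) -> WeightedTrainingSet:
    X = np.asarray([im.planes for im in images], dtype=np.float32)
    y = np.asarray([LABEL_TO_INT[im.label] for im in images], dtype=np.int64)
    return WeightedTrainingSet(
        X=X, y=y, weights=np.ones(len(images)), n_target=len(images)
    )


def _cap_stratified(
    images: list[SpectrogramImage], cap: int, rng: np.random.Generator
) -> list[SpectrogramImage]:
    """Seeded stratified subsample to at most ``cap`` trials (balanced)."""
    if cap is None or len(images) <= cap:
        return images
    per_class = cap // 2
    out: list[SpectrogramImage] = []
    for label in ("left", "right"):
        members = [im for im in images if im.label == label]
        pick = rng.choice(len(members), size=min(per_class, len(members)),
                         replace=False)
        out.extend(members[i] for i in sorted(pick))
    return out


def partition(
    spec: StrategySpec, dataset: dict[int, list[SpectrogramImage]]
) -> list[Fold]:
    """Build the train/test folds for a strategy over a spectrogram dataset.

    ``dataset`` maps subject id to that subject's spectrogram images.
    """
    if spec.target_subject not in dataset:
        raise ValueError(f"target subject {spec.target_subject} not in dataset")
    target = dataset[spec.target_subject]
    others = [
        im for sid, ims in sorted(dataset.items())
        if sid != spec.target_subject for im in ims
    ]

    if spec.strategy == "SI":
        if not others:
            raise ValueError("SI strategy requires at least 2 subjects")
        return [
            Fold(
                train_set=_target_only_set(others),
                test_images=list(target),
                train_ids=[(im.subject_id, im.trial_id) for im in others],
                test_ids=[(im.subject_id, im.trial_id) for im in target],
            )
        ]

    y = np.asarray([LABEL_TO_INT[im.label] for im in target])
    skf = StratifiedKFold(n_splits=spec.n_folds, shuffle=True, random_state=spec.seed)
    cap_rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 11)))
    folds: list[Fold] = []
    for train_idx, test_idx in skf.split(np.zeros(len(y)), y):
        tr = [target[i] for i in train_idx]
        te = [target[i] for i in test_idx]
        if spec.max_target_train is not None:
            tr = _cap_stratified(tr, spec.max_target_train, cap_rng)
        if spec.strategy == "SD":
            folds.append(
                Fold(
                    train_set=_target_only_set(tr),
                    test_images=te,
                    train_ids=[(im.subject_id, im.trial_id) for im in tr],
                    test_ids=[(im.subject_id, im.trial_id) for im in te],
                )
            )
        else:  # ITSD: prototypes from the fold-training portion only
            protos = class_prototypes(tr)
            scored = score_sources(others, protos)
            train_set = assemble_itsd_training_set(tr, scored, spec.transfer_policy)
            sel = [s for s in scored if s.d_hash <= spec.transfer_policy.distance_threshold]
            folds.append(
                Fold(
                    train_set=train_set,
                    test_images=te,
                    train_ids=[(im.subject_id, im.trial_id) for im in tr]
                    + [(s.subject_id, s.trial_id) for s in sel],
                    test_ids=[(im.subject_id, im.trial_id) for im in te],
                    prototype_ids=[(im.subject_id, im.trial_id) for im in tr],
                )
            )
    return folds


def run_strategy(
    spec: StrategySpec, dataset: dict[int, list[SpectrogramImage]]
) -> StrategyReport:
    """Train a fresh seeded model per fold and report accuracy and kappa."""
    folds = partition(spec, dataset)
    accs, kaps, cms, sizes, logs = [], [], [], [], []
    for k, fold in enumerate(folds):
        cfg = replace(spec.cnn, seed=int(np.random.SeedSequence(
            (spec.seed, spec.target_subject, k)).generate_state(1)[0] % (2**31)))
        model = build_model(cfg)
        train(model, fold.train_set.X, fold.train_set.y, fold.train_set.weights,
              epochs=spec.epochs)
        Xte = np.asarray([im.planes for im in fold.test_images], dtype=np.float64)
        yte = np.asarray([LABEL_TO_INT[im.label] for im in fold.test_images])
        pred, _ = predict(model, Xte)
        acc = float((pred == yte).mean())
        accs.append(acc)
        kaps.append(kappa(acc))
        cms.append(confusion_matrix(yte, pred, labels=[0, 1]))
        sizes.append((len(fold.train_set.y), len(fold.test_images)))
        logs.append(fold.train_set.transfer_log)
    return StrategyReport(
        spec=spec,
        fold_accuracy=accs,
        fold_kappa=kaps,
        confusion_matrices=cms,
        partition_sizes=sizes,
        transfer_logs=logs,
    )
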