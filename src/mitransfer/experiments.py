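"""Scaled-down study drivers: SD vs ITSD comparison, negative control,
and a separable-image training demo.

These functions are the package's reproducible experiments.  They run the
full pipeline (simulate -> filter -> epoch -> spectrogram -> hash ->
transfer -> CNN -> metrics) at desk scale: the paper-scale protocol
(9 subjects x 720 trials, 10-fold CV, thousands of transferred instances)
is shrunk to sizes a single CPU core handles in minutes, while preserving
the structure of the comparison — a data-starved target subject, a pool of
heterogeneous source subjects, and leakage-free per-fold transfer.

The CNN is trained with a larger learning rate (0.02) than the paper-scale
default (1e-4): with only tens to hundreds of training images and a handful
of epochs, the conservative rate would leave the network near its random
initialisation.  The architecture and optimizer are unchanged.
"""

from __future__ import annotations

import numpy as np

from .cnn import CnnConfig, build_model, predict, train
from .evaluation import StrategySpec, kappa, run_strategy
from .preprocess import Epoch, FilterSpec, preprocess_trial
from .spectrogram import SpectrogramImage, StftSpec, compute_spectrogram
from .synthetic import EEGTrial, make_subject, simulate_trials
from .transfer import TransferPolicy

#: learning rate used by the desk-scale experiments (see module docstring)
EXPERIMENT_LR = 0.02


def spectrogram_dataset(
    cohort: dict[int, list[EEGTrial]],
    filter_spec: FilterSpec = FilterSpec(),
    epoch: Epoch = Epoch(),
    stft_spec: StftSpec = StftSpec(),
) -> dict[int, list[SpectrogramImage]]:
    """Filter, epoch and image every trial of a cohort."""
    return {
        sid: [
            compute_spectrogram(preprocess_trial(t, filter_spec, epoch), stft_spec)
            for t in trials
        ]
        for sid, trials in cohort.items()
    }


def _shared_erd_cohort(
    seed: int, n_subjects: int, n_trials: int, erd_range=(0.5, 0.75)
) -> dict[int, list[EEGTrial]]:
    """Cohort whose subjects all express a clear ERD (depth >= 0.5)."""
    rng = np.random.default_rng(np.random.SeedSequence((seed, 23)))
    cohort = {}
    for sid in range(1, n_subjects + 1):
        profile = make_subject(
            sid, seed, overrides={"erd_depth": float(rng.uniform(*erd_range))}
        )
        cohort[sid] = simulate_trials(profile, n_trials)
    return cohort


def itsd_vs_sd(
    seed: int,
    n_subjects: int = 9,
    n_trials: int = 90,
    n_folds: int = 3,
    max_target_train: int = 60,
    target_subject: int | None = None,
    epochs: int = 12,
    policy: TransferPolicy | None = None,
) -> dict:
    """Run SD and ITSD on one target subject of a shared-ERD cohort.

    The target's per-fold training portion is capped at ``max_target_train``
    trials, emulating the small-calibration regime where instance transfer
    is supposed to help.  Returns per-strategy reports and mean accuracies.
    """
    if policy is None:
        policy = TransferPolicy(
            distance_threshold=16, max_instances_per_source_subject=25
        )
    if target_subject is None:
        target_subject = 1 + (seed % n_subjects)
    cohort = _shared_erd_cohort(seed, n_subjects, n_trials)
    dataset = spectrogram_dataset(cohort)
    cnn = CnnConfig(learning_rate=EXPERIMENT_LR, seed=seed)
    common = dict(
        target_subject=target_subject,
        n_folds=n_folds,
        seed=seed,
        cnn=cnn,
        epochs=epochs,
        max_target_train=max_target_train,
    )
    sd = run_strategy(StrategySpec(strategy="SD", **common), dataset)
    itsd = run_strategy(
        StrategySpec(strategy="ITSD", transfer_policy=policy, **common), dataset
    )
    return dict(
        seed=seed,
        target_subject=target_subject,
        sd=sd,
        itsd=itsd,
        sd_accuracy=sd.mean_accuracy,
        itsd_accuracy=itsd.mean_accuracy,
    )


def itsd_vs_sd_over_seeds(seeds: list[int], **kwargs) -> dict:
    """Repeat :func:`itsd_vs_sd` over seeds and aggregate the means."""
    runs = [itsd_vs_sd(s, **kwargs) for s in seeds]
    return dict(
        runs=runs,
        sd_mean=float(np.mean([r["sd_accuracy"] for r in runs])),
        itsd_mean=float(np.mean([r["itsd_accuracy"] for r in runs])),
    )


def negative_control(
    seed: int, n_trials: int = 240, n_folds: int = 3, epochs: int = 2
) -> dict:
    """SD run on label-permuted data: accuracy should sit at chance.

    Labels of one subject's trials are randomly permuted before the
    spectrograms are computed, destroying the label/ERD association while
    keeping both marginals intact.
    """
    profile = make_subject(1, seed)
    trials = simulate_trials(profile, n_trials)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 77)))
    labels = [t.label for t in trials]
    perm = rng.permutation(len(labels))
    from dataclasses import replace as _replace

    permuted = [_replace(t, label=labels[perm[i]]) for i, t in enumerate(trials)]
    dataset = {1: [compute_spectrogram(preprocess_trial(t)) for t in permuted]}
    spec = StrategySpec(
        strategy="SD",
        target_subject=1,
        n_folds=n_folds,
        seed=seed,
        cnn=CnnConfig(learning_rate=EXPERIMENT_LR, seed=seed),
        epochs=epochs,
    )
    report = run_strategy(spec, dataset)
    n_test = sum(n for _, n in report.partition_sizes)
    pooled_acc = float(
        np.average(report.fold_accuracy, weights=[n for _, n in report.partition_sizes])
    )
    return dict(
        report=report,
        accuracy=pooled_acc,
        kappa=kappa(pooled_acc),
        n_test=n_test,
    )


def make_separable_images(
    n: int, seed: int, offset: float = 0.35, noise_sd: float = 0.15
) -> tuple[np.ndarray, np.ndarray]:
    """Linearly separable 64x64x3 images: the two classes differ by a
    band-power offset in opposite image planes (a cartoon of lateralized
    ERD).  Returns (X [n,64,64,3], y [n])."""
    rng = np.random.default_rng(seed)
    y = (np.arange(n) % 2)[rng.permutation(n)]
    X = rng.normal(0.5, noise_sd, size=(n, 64, 64, 3))
    band = slice(20, 36)
    for i, lab in enumerate(y):
        X[i, band, :, 0 if lab == 0 else 2] -= offset
    return np.clip(X, 0.0, 1.0), y.astype(np.int64)


def separable_training_demo(seed: int, n: int = 400, epochs: int = 30) -> dict:
    """Train the CNN on separable synthetic images; returns final train accuracy."""
    X, y = make_separable_images(n, seed)
    cfg = CnnConfig(learning_rate=EXPERIMENT_LR, seed=seed, max_epochs=epochs)
    model = build_model(cfg)
    train(model, X, y.astype(np.int64))
    pred, _ = predict(model, X)
    return dict(
        train_accuracy=float((pred == y).mean()),
        n=n,
        epochs=epochs,
        n_parameters=model.n_parameters,
        history=model.history,
    )
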