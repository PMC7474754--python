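"""End-to-end run configuration and pipeline driver.

A :class:`RunConfig` gathers every stage parameter plus one master seed in a
single document that round-trips through YAML/JSON.  :func:`run_pipeline`
chains simulate -> preprocess -> spectrogram -> (hash -> transfer) ->
train -> evaluate and writes a JSON report that embeds the resolved config,
so a single integer reproduces a full run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .cnn import CnnConfig
from .container import read_container, write_container
from .evaluation import StrategySpec, run_strategy
from .experiments import spectrogram_dataset
from .preprocess import Epoch, FilterSpec
from .spectrogram import StftSpec
from .synthetic import simulate_cohort
from .transfer import TransferPolicy

log = logging.getLogger("mitransfer")


@dataclass(frozen=True)
class RunConfig:
    strategy: str = "ITSD"
    target_subject: int = 1
    n_subjects: int = 9
    n_trials: int = 720
    n_folds: int = 10
    seed: int = 0
    epochs: int | None = None
    max_target_train: int | None = None
    data_path: str | None = None  # read an existing container instead of simulating
    filter_spec: FilterSpec = field(default_factory=FilterSpec)
    epoch: Epoch = field(default_factory=Epoch)
    stft_spec: StftSpec = field(default_factory=StftSpec)
    transfer_policy: TransferPolicy = field(default_factory=TransferPolicy)
    cnn: CnnConfig = field(default_factory=CnnConfig)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        casts = {
            "filter_spec": FilterSpec,
            "epoch": Epoch,
            "stft_spec": StftSpec,
            "transfer_policy": TransferPolicy,
            "cnn": CnnConfig,
        }
        for key, typ in casts.items():
            if key in d and isinstance(d[key], dict):
                sub = dict(d[key])
                for f_ in dataclasses.fields(typ):
                    if f_.name in sub and isinstance(sub[f_.name], list):
                        sub[f_.name] = tuple(sub[f_.name])
                d[key] = typ(**sub)
        return cls(**d)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(self.to_dict())), fh)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _content_hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def derive_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed from one master seed (< 2**31)."""
    return int(
        np.random.SeedSequence(
            (master_seed, int.from_bytes(stage.encode()[:4].ljust(4, b"\0"), "big"))
        ).generate_state(1)[0]
        % (2**31)
    )


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute the full pipeline and write ``report.json`` under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings = {}

    t0 = time.perf_counter()
    if config.data_path:
        cohort = read_container(config.data_path)
        log.info("loaded container %s: %d subjects", config.data_path, len(cohort))
    else:
        cohort = simulate_cohort(
            n_subjects=config.n_subjects,
            n_trials=config.n_trials,
            seed=derive_seed(config.seed, "sim"),
        )
        log.info("simulated %d subjects x %d trials", config.n_subjects, config.n_trials)
    timings["simulate_or_load"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    dataset = spectrogram_dataset(
        cohort, config.filter_spec, config.epoch, config.stft_spec
    )
    timings["preprocess_spectrogram"] = time.perf_counter() - t0
    log.info(
        "spectrograms: %d trials", sum(len(v) for v in dataset.values())
    )
    if config.strategy != "ITSD":
        log.info("strategy %s: hash/transfer stages skipped", config.strategy)

    t0 = time.perf_counter()
    spec = StrategySpec(
        strategy=config.strategy,
        target_subject=config.target_subject,
        n_folds=config.n_folds,
        seed=derive_seed(config.seed, "eval"),
        transfer_policy=config.transfer_policy,
        cnn=config.cnn,
        epochs=config.epochs,
        max_target_train=config.max_target_train,
    )
    report = run_strategy(spec, dataset)
    timings["train_evaluate"] = time.perf_counter() - t0

    doc = dict(
        config=json.loads(json.dumps(config.to_dict())),
        config_hash=_content_hash(config.to_dict()),
        report=report.summary(),
        timings_s={k: round(v, 3) for k, v in timings.items()},
    )
    (out / "report.json").write_text(json.dumps(doc, indent=2))
    log.info(
        "strategy %s subject %d: accuracy %.3f +- %.3f, kappa %.3f",
        config.strategy, config.target_subject,
        report.mean_accuracy, report.std_accuracy, report.mean_kappa,
    )
    return doc
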