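"""Instance-transfer scoring, selection, balancing and set assembly."""

import numpy as np
import pytest

import mitransfer as mt
from mitransfer.spectrogram import SpectrogramImage, TargetPrototype
from mitransfer.transfer import TransferPolicy, select_instances


def _image(subject, trial, label, rng):
    stacked = rng.random((64, 64))
    return SpectrogramImage(
        stacked=stacked,
        planes=rng.random((64, 64, 3)),
        subject_id=subject,
        trial_id=trial,
        label=label,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(13)


@pytest.fixture()
def sources(rng):
    return [
        _image(s, t, ("left", "right")[t % 2], rng)
        for s in (2, 3)
        for t in range(10)
    ]


@pytest.fixture()
def prototypes(rng):
    return {
        lab: TargetPrototype(rng.random((64, 64)), lab, 5)
        for lab in ("left", "right")
    }


class TestScoreSources:
    def test_exact_prototype_match_scores_zero_distance(self, prototypes, sources):
        clone = SpectrogramImage(
            stacked=prototypes["left"].image.copy(),
            planes=np.zeros((64, 64, 3)),
            subject_id=9,
            trial_id=0,
            label="left",
        )
        scored = mt.score_sources([clone] + sources, prototypes)
        assert scored[0].d_hash == 0
        assert scored[0].weight == 1.0

    def test_weight_decreases_with_distance(self, prototypes, sources):
        scored = mt.score_sources(sources, prototypes)
        for s in scored:
            assert s.weight == pytest.approx(1.0 - s.d_hash / 64)

    def test_order_invariant(self, prototypes, sources):
        fwd = mt.score_sources(sources, prototypes)
        rev = mt.score_sources(sources[::-1], prototypes)
        key = lambda s: (s.subject_id, s.trial_id)
        assert sorted([(key(s), s.d_hash) for s in fwd]) == sorted(
            [(key(s), s.d_hash) for s in rev]
        )

    def test_missing_prototype_class_rejected(self, prototypes, sources):
        del prototypes["right"]
        with pytest.raises(ValueError, match="prototype"):
            mt.score_sources(sources, prototypes)


class TestSelection:
    def test_threshold_zero_without_exact_match_selects_nothing(
        self, prototypes, sources
    ):
        scored = mt.score_sources(sources, prototypes)
        if all(s.d_hash > 0 for s in scored):
            sel = select_instances(scored, TransferPolicy(distance_threshold=0))
            assert sel == []

    def test_threshold_64_selects_everything_balanced(self, prototypes, sources):
        scored = mt.score_sources(sources, prototypes)
        sel = select_instances(scored, TransferPolicy(distance_threshold=64))
        labels = [s.label for s in sel]
        assert labels.count("left") == labels.count("right")
        assert len(sel) == 20  # the full (balanced) source pool

    def test_balancing_subsamples_larger_class_by_weight(self, prototypes, rng):
        lefts = [_image(2, t, "left", rng) for t in range(10)]
        rights = [_image(3, t, "right", rng) for t in range(6)]
        scored = mt.score_sources(lefts + rights, prototypes)
        sel = select_instances(scored, TransferPolicy(distance_threshold=64))
        by_class = {"left": [], "right": []}
        for s in sel:
            by_class[s.label].append(s)
        assert len(by_class["left"]) == len(by_class["right"]) == 6
        # kept lefts are the highest-weight ones
        left_weights = sorted(
            (s.weight for s in scored if s.label == "left"), reverse=True
        )
        assert sorted((s.weight for s in by_class["left"]), reverse=True) == \
            left_weights[:6]

    def test_per_subject_cap(self, prototypes, sources):
        scored = mt.score_sources(sources, prototypes)
        sel = select_instances(
            scored,
            TransferPolicy(
                distance_threshold=64,
                max_instances_per_source_subject=3,
                balance_classes=False,
            ),
        )
        counts = {}
        for s in sel:
            counts[s.subject_id] = counts.get(s.subject_id, 0) + 1
        assert all(c <= 3 for c in counts.values())


class TestAssemble:
    def test_targets_keep_weight_one_and_are_never_subsampled(
        self, prototypes, sources, rng
    ):
        targets = [_image(1, t, ("left", "right")[t % 2], rng) for t in range(8)]
        scored = mt.score_sources(sources, prototypes)
        ts = mt.assemble_itsd_training_set(
            targets, scored, TransferPolicy(distance_threshold=64)
        )
        assert ts.n_target == 8
        np.testing.assert_array_equal(ts.weights[:8], 1.0)

    def test_weights_in_unit_interval(self, prototypes, sources, rng):
        targets = [_image(1, t, ("left", "right")[t % 2], rng) for t in range(4)]
        scored = mt.score_sources(sources, prototypes)
        ts = mt.assemble_itsd_training_set(
            targets, scored, TransferPolicy(distance_threshold=64)
        )
        assert (ts.weights > 0).all() and (ts.weights <= 1).all()

    def test_degenerate_threshold_reduces_to_target_only(
        self, prototypes, sources, rng
    ):
        targets = [_image(1, t, ("left", "right")[t % 2], rng) for t in range(4)]
        scored = mt.score_sources(sources, prototypes)
        if all(s.d_hash > 0 for s in scored):
            ts = mt.assemble_itsd_training_set(
                targets, scored, TransferPolicy(distance_threshold=0)
            )
            assert len(ts.y) == ts.n_target == 4

    def test_transfer_log_counts(self, prototypes, sources, rng):
        targets = [_image(1, t, ("left", "right")[t % 2], rng) for t in range(4)]
        scored = mt.score_sources(sources, prototypes)
        ts = mt.assemble_itsd_training_set(
            targets, scored, TransferPolicy(distance_threshold=64)
        )
        log = ts.transfer_log
        assert log["n_target"] == 4
        assert log["n_transferred"] == sum(log["per_source_subject"].values())
        assert log["per_class"]["left"] == log["per_class"]["right"]

    def test_invalid_policy_rejected(self):
        with pytest.raises(ValueError):
            TransferPolicy(distance_threshold=65)
        with pytest.raises(ValueError):
            TransferPolicy(weighting_mode="magic")


def test_same_class_trials_hash_closer_than_cross_class():
    """Across synthetic subjects sharing ERD structure, same-class trials
    sit at a smaller Hamming distance than different-class trials — the
    premise that makes instance transfer positive."""
    from mitransfer.experiments import _shared_erd_cohort, spectrogram_dataset

    ds = spectrogram_dataset(_shared_erd_cohort(3, 2, 40))
    h1 = [(mt.phash(im.stacked), im.label) for im in ds[1]]
    h2 = [(mt.phash(im.stacked), im.label) for im in ds[2]]
    same, diff = [], []
    for ha, la in h1:
        for hb, lb in h2:
            (same if la == lb else diff).append(mt.hamming(ha, hb))
    assert len(same) >= 200 and len(diff) >= 200
    assert np.mean(same) < np.mean(diff)
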