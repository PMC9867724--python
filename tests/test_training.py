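"""Splits, early stopping, and the training loop contracts."""

import numpy as np
import pytest

from scanmil import EarlyStopper, InMemoryStore, MILHead, TrainConfig, make_splits, train_model
from scanmil.errors import ConfigurationError, TrainingDivergedError, ValidationError
from scanmil.training import run_repeats


def _ids_labels(n, pos_frac=0.5, seed=0):
    rng = np.random.default_rng(seed)
    ids = [f"s{i}" for i in range(n)]
    labels = (rng.random(n) < pos_frac).astype(int)
    labels[:2] = [0, 1]
    return ids, labels


class TestSplits:
    def test_100_scans_split_exactly(self):
        ids, labels = _ids_labels(100)
        split = make_splits(ids, labels, seed=1)
        assert split.sizes() == {"train": 70, "val": 10, "test": 20}

    def test_865_scans_rounding(self):
        ids, labels = _ids_labels(865)
        sizes = make_splits(ids, labels, seed=2).sizes()
        assert sizes["test"] == 173
        assert sizes["val"] in (86, 87)
        assert sizes["train"] in (605, 606)
        assert sum(sizes.values()) == 865

    def test_disjoint_and_exhaustive(self):
        ids, labels = _ids_labels(137)
        split = make_splits(ids, labels, seed=3)
        all_ids = split.ids("train") + split.ids("val") + split.ids("test")
        assert sorted(all_ids) == sorted(ids)

    def test_seed_reproducible_and_seed_sensitive(self):
        ids, labels = _ids_labels(60)
        a = make_splits(ids, labels, seed=4).roles
        b = make_splits(ids, labels, seed=4).roles
        c = make_splits(ids, labels, seed=5).roles
        assert a == b
        assert a != c

    def test_stratification_preserves_class_balance(self):
        ids, labels = _ids_labels(200, pos_frac=0.3, seed=9)
        split = make_splits(ids, labels, seed=6)
        lab = dict(zip(ids, labels))
        overall = np.mean(labels)
        for role in ("train", "val", "test"):
            frac = np.mean([lab[s] for s in split.ids(role)])
            assert abs(frac - overall) < 0.1

    def test_single_class_rejected(self):
        ids = [f"s{i}" for i in range(20)]
        with pytest.raises(ValidationError):
            make_splits(ids, [1] * 20)

    def test_bad_fractions_rejected(self):
        ids, labels = _ids_labels(50)
        with pytest.raises(ConfigurationError):
            make_splits(ids, labels, TrainConfig(fractions=(0.5, 0.2, 0.2)))


class TestEarlyStopper:
    def test_scripted_trajectory_stops_after_patience(self):
        """[1.0, 0.9, then seven >= 0.9] stops at the 7th bad epoch, best = 2."""
        stopper = EarlyStopper(patience=7)
        losses = [1.0, 0.9] + [0.9] * 7
        stops = [stopper.update(l, state=i + 1) for i, l in enumerate(losses)]
        assert stops == [False] * 8 + [True]
        assert stopper.best_epoch == 2
        assert stopper.best_state == 2

    def test_strictly_decreasing_never_stops(self):
        stopper = EarlyStopper(patience=7)
        assert not any(stopper.update(1.0 / (i + 1)) for i in range(50))

    def test_improvement_requires_min_delta(self):
        stopper = EarlyStopper(patience=2, min_delta=1e-6)
        assert stopper.update(0.5) is False
        assert stopper.update(0.5 - 1e-9) is False  # below min_delta: no improvement
        assert stopper.update(0.5 - 1e-9) is True

    def test_recovery_resets_patience(self):
        stopper = EarlyStopper(patience=3)
        seq = [1.0, 1.1, 1.2, 0.5, 0.9, 0.9, 0.9]
        stops = [stopper.update(l) for l in seq]
        assert stops == [False, False, False, False, False, False, True]
        assert stopper.best_epoch == 4


def _toy_problem(n=40, d=8, seed=0):
    """Separable bag dataset: positive bags contain one shifted instance."""
    rng = np.random.default_rng(seed)
    arrays, labels = {}, {}
    for i in range(n):
        y = i % 2
        X = rng.normal(size=(int(rng.integers(4, 9)), d))
        if y:
            X[0] += 3.0
        arrays[f"s{i}"] = X
        labels[f"s{i}"] = y
    return InMemoryStore(arrays), labels


class TestTrainModel:
    def test_no_test_scan_accessed_during_training(self):
        store, labels = _toy_problem()
        ids = store.scan_ids()
        split = make_splits(ids, [labels[s] for s in ids], seed=0)
        model = MILHead(8, hidden=8, embed=8, attn_hidden=4, lr=1e-3, seed=0)
        train_model(model, store, labels, split, TrainConfig(max_epochs=3), seed=0)
        assert set(store.access_log).isdisjoint(split.ids("test"))

    def test_training_descends_and_restores_best(self):
        store, labels = _toy_problem()
        ids = store.scan_ids()
        split = make_splits(ids, [labels[s] for s in ids], seed=1)
        model = MILHead(8, hidden=8, embed=8, attn_hidden=4, lr=1e-2, seed=0)
        log = train_model(model, store, labels, split,
                          TrainConfig(max_epochs=40), seed=0)
        assert log.train_loss[-1] < log.train_loss[0]
        assert 1 <= log.best_epoch <= log.stopped_epoch
        # restored parameters reproduce the best validation loss
        val = np.mean([model.loss(store.get(s), labels[s]) for s in split.ids("val")])
        assert val == pytest.approx(min(log.val_loss), abs=1e-6)

    def test_nan_loss_aborts(self):
        store, labels = _toy_problem(n=20)

        class ExplodingModel(MILHead):
            def train_step(self, X, y, rng):
                return np.nan

        model = ExplodingModel(8, hidden=4, embed=4, attn_hidden=2)
        ids = store.scan_ids()
        split = make_splits(ids, [labels[s] for s in ids], seed=0)
        with pytest.raises(TrainingDivergedError):
            train_model(model, store, labels, split, TrainConfig(max_epochs=2))


class TestRunRepeats:
    def test_repeats_have_disjoint_roles_and_own_test_sets(self):
        store, labels = _toy_problem(n=30)
        results = run_repeats(
            lambda s: MILHead(8, hidden=6, embed=6, attn_hidden=3, seed=s),
            store, labels, TrainConfig(max_epochs=2), master_seed=0, n_repeats=3,
        )
        assert len(results) == 3
        for r in results:
            assert sorted(r.test_ids) == sorted(r.split.ids("test"))
            assert len(r.test_scores) == len(r.test_ids)

    def test_master_seed_determinism(self):
        store, labels = _toy_problem(n=24)
        def go():
            return run_repeats(
                lambda s: MILHead(8, hidden=6, embed=6, attn_hidden=3, seed=s),
                store, labels, TrainConfig(max_epochs=2), master_seed=7, n_repeats=2,
            )
        a, b = go(), go()
        for ra, rb in zip(a, b):
            assert ra.test_ids == rb.test_ids
            assert np.array_equal(ra.test_scores, rb.test_scores)
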