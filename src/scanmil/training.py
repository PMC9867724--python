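"""Training recipe: stratified splits, bag-level optimization, early stopping.

Models are trained on bag-level binary cross entropy with Adam (beta1 = 0.9,
beta2 = 0.99, initial learning rate 1e-4), one bag per optimization step
(bags have variable instance counts). Scans are partitioned 70/10/20 into
train/validation/test, stratified by label, and the whole protocol is
repeated over independently drawn splits (5 by default). Early stopping
halts training when the validation loss has not improved for ``patience``
consecutive epochs (7 by default) and restores the best-validation weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .errors import ConfigurationError, TrainingDivergedError, ValidationError

__all__ = [
    "TrainConfig",
    "SplitAssignment",
    "make_splits",
    "EarlyStopper",
    "TrainingLog",
    "train_model",
    "run_repeats",
    "RepeatResult",
    "InMemoryStore",
]

ROLES = ("train", "val", "test")


@dataclass
class TrainConfig:
    """Hyperparameters of the training protocol."""

    lr: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.99
    init_std: float | None = None  # None = fan-in scaled normal
    max_epochs: int = 30
    patience: int = 7
    min_delta: float = 1e-6  # improvement = strictly lower by at least this
    fractions: tuple[float, float, float] = (0.70, 0.10, 0.20)
    n_repeats: int = 5

    def validate(self) -> None:
        if not np.isclose(sum(self.fractions), 1.0):
            raise ConfigurationError("split fractions must sum to 1")
        if self.patience < 1:
            raise ConfigurationError("patience must be >= 1")
        if self.max_epochs < 1:
            raise ConfigurationError("max_epochs must be >= 1")


@dataclass
class SplitAssignment:
    """Mapping scan_id -> role for one repeat."""

    roles: dict

    def ids(self, role: str) -> list:
        if role not in ROLES:
            raise ValidationError(f"unknown role {role!r}")
        return [sid for sid, r in self.roles.items() if r == role]

    def sizes(self) -> dict:
        return {r: len(self.ids(r)) for r in ROLES}


def _largest_remainder(counts: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation of ``total`` across classes proportional to counts."""
    quotas = counts * total / counts.sum()
    alloc = np.floor(quotas).astype(int)
    remainder = quotas - alloc
    short = total - alloc.sum()
    order = np.argsort(-remainder, kind="stable")
    for idx in order[:short]:
        alloc[idx] += 1
    return np.minimum(alloc, counts)


def make_splits(
    scan_ids: Sequence[str],
    labels: Sequence[int],
    config: TrainConfig | None = None,
    seed: int = 0,
) -> SplitAssignment:
    """Random stratified train/val/test partition.

    Global role sizes come from rounding the configured fractions (ties round
    half to even), so e.g. 100 scans split exactly 70/10/20. Within each
    class, scans are shuffled and allocated by largest remainder so the
    global sizes are met exactly while both classes appear in every role in
    proportion.
    """
    config = config or TrainConfig()
    config.validate()
    scan_ids = list(scan_ids)
    labels = np.asarray(labels)
    if len(scan_ids) != len(labels):
        raise ValidationError("scan_ids and labels must align")
    if len(scan_ids) < 10:
        raise ValidationError("need at least 10 scans to split")
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValidationError("both classes must be present to stratify")
    n = len(scan_ids)
    n_test = round(config.fractions[2] * n)
    n_val = round(config.fractions[1] * n)
    rng = np.random.default_rng(seed)
    per_class = [np.array([s for s, l in zip(scan_ids, labels) if l == c]) for c in classes]
    for arr in per_class:
        rng.shuffle(arr)
    counts = np.array([len(a) for a in per_class])
    test_alloc = _largest_remainder(counts, n_test)
    val_alloc = _largest_remainder(counts - test_alloc, n_val)
    roles = {}
    for arr, n_t, n_v in zip(per_class, test_alloc, val_alloc):
        for sid in arr[:n_t]:
            roles[str(sid)] = "test"
        for sid in arr[n_t : n_t + n_v]:
            roles[str(sid)] = "val"
        for sid in arr[n_t + n_v :]:
            roles[str(sid)] = "train"
    return SplitAssignment(roles)


class EarlyStopper:
    """Patience-based early stopping on validation loss.

    ``update`` returns True when training should stop: the validation loss
    has failed to improve (drop below the best by at least ``min_delta``)
    for ``patience`` consecutive epochs. The best epoch's state is retained
    for restoration.
    """

    def __init__(self, patience: int = 7, min_delta: float = 1e-6):
        self.patience = patience
        self.min_delta = min_delta
        self.best_loss = np.inf
        self.best_epoch = 0  # 1-based
        self.best_state = None
        self._bad_epochs = 0
        self._epoch = 0

    def update(self, val_loss: float, state=None) -> bool:
        self._epoch += 1
        if val_loss < self.best_loss - self.min_delta or self._epoch == 1:
            self.best_loss = val_loss
            self.best_epoch = self._epoch
            self.best_state = state
            self._bad_epochs = 0
        else:
            self._bad_epochs += 1
        return self._bad_epochs >= self.patience


@dataclass
class TrainingLog:
    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    best_epoch: int = 0
    stopped_epoch: int = 0


class InMemoryStore:
    """Generic scan_id -> array mapping with the same access log as FeatureStore."""

    def __init__(self, arrays: dict):
        self._arrays = dict(arrays)
        self.access_log: list[str] = []

    def scan_ids(self):
        return list(self._arrays)

    def get(self, scan_id):
        if scan_id not in self._arrays:
            raise ValidationError(f"no data for scan {scan_id!r}")
        self.access_log.append(scan_id)
        return self._arrays[scan_id]


def _mean_loss(model, store, ids, labels) -> float:
    return float(np.mean([model.loss(store.get(s), labels[s]) for s in ids]))


def train_model(
    model,
    store,
    labels: dict,
    split: SplitAssignment,
    config: TrainConfig | None = None,
    seed: int = 0,
) -> TrainingLog:
    """Train ``model`` on the split's train scans with early stopping.

    Only train and validation scans are read from ``store``; held-out test
    scans are never touched. On return the model carries the parameters of
    the best-validation-loss epoch.
    """
    config = config or TrainConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    train_ids = split.ids("train")
    val_ids = split.ids("val")
    if not train_ids or not val_ids:
        raise ValidationError("split must contain train and val scans")
    stopper = EarlyStopper(config.patience, config.min_delta)
    log = TrainingLog()
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(train_ids))
        losses = []
        for k in order:
            sid = train_ids[k]
            losses.append(model.train_step(store.get(sid), labels[sid], rng))
        epoch_train = float(np.mean(losses))
        if not np.isfinite(epoch_train):
            raise TrainingDivergedError(
                f"non-finite training loss at epoch {epoch}"
            )
        epoch_val = _mean_loss(model, store, val_ids, labels)
        log.train_loss.append(epoch_train)
        log.val_loss.append(epoch_val)
        stop = stopper.update(epoch_val, model.state_dict())
        log.stopped_epoch = epoch
        if stop:
            break
    log.best_epoch = stopper.best_epoch
    if stopper.best_state is not None:
        model.load_state_dict(stopper.best_state)
    return log


@dataclass
class RepeatResult:
    """One repeat: the trained model plus held-out test predictions."""

    repeat: int
    model: object
    split: SplitAssignment
    log: TrainingLog
    test_ids: list
    test_scores: np.ndarray
    test_labels: np.ndarray
    test_attention: dict = field(default_factory=dict)


def run_repeats(
    model_factory: Callable[[int], object],
    store,
    labels: dict,
    config: TrainConfig | None = None,
    master_seed: int = 0,
    n_repeats: Optional[int] = None,
) -> list[RepeatResult]:
    """Run the full repeated-split protocol.

    ``model_factory(seed)`` must build a fresh untrained model. Each repeat
    draws its own split, model-init and shuffling seeds from the master seed;
    predictions are made only on that repeat's test scans.
    """
    config = config or TrainConfig()
    n_repeats = n_repeats or config.n_repeats
    master = np.random.default_rng(master_seed)
    scan_ids = store.scan_ids()
    label_vec = [labels[s] for s in scan_ids]
    results = []
    for rep in range(n_repeats):
        split_seed, model_seed, train_seed = master.integers(0, 2**31 - 1, size=3)
        split = make_splits(scan_ids, label_vec, config, seed=int(split_seed))
        model = model_factory(int(model_seed))
        log = train_model(model, store, labels, split, config, seed=int(train_seed))
        test_ids = split.ids("test")
        preds = [model.predict_bag(store.get(s), s) for s in test_ids]
        attn = {
            p.scan_id: p.attention for p in preds if p.attention is not None
        }
        results.append(
            RepeatResult(
                repeat=rep,
                model=model,
                split=split,
                log=log,
                test_ids=test_ids,
                test_scores=np.array([p.probability for p in preds]),
                test_labels=np.array([labels[s] for s in test_ids]),
                test_attention=attn,
            )
        )
    return results
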