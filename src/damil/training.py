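"""Training protocol and patient-level stratified cross-validation.

Bags are drawn one at a time (batch size one) with replacement under
inverse-class-frequency weights; optimization is Adam with L2 weight
decay on unweighted cross-entropy. Early stopping starts counting after
the initial epochs and fires after `patience` consecutive epochs
without a strict improvement in validation loss.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from damil.bags import NRC, RC, EmbeddingBag
from damil.keyset import CrlConfig, KeySet, build_keyset
from damil.model import (
    DamilConfig,
    DamilParams,
    forward,
    init_params,
    loss_and_grads,
)

CLASS_INDEX = {NRC: 0, RC: 1}


class LeakageError(RuntimeError):
    """A non-training slide leaked into the key set."""


@dataclass
class TrainConfig:
    learning_rate: float = 8e-5
    weight_decay: float = 1e-5
    min_epochs: int = 5
    patience: int = 5
    max_epochs: int = 50
    batch_size: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size != 1:
            raise ValueError("MIL training uses batch size one")
        for name in ("learning_rate", "weight_decay", "min_epochs", "patience", "max_epochs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class FoldSplit:
    train: list[str]
    validation: list[str]
    test: list[str]


@dataclass
class SplitPlan:
    folds: list[FoldSplit]

    @property
    def k(self) -> int:
        return len(self.folds)


@dataclass
class TrainState:
    epoch: int = 0
    train_losses: list[float] = field(default_factory=list)
    val_losses: list[float] = field(default_factory=list)
    best_epoch: int = 0
    best_val_loss: float = math.inf
    stop_reason: str = ""


class EarlyStopping:
    """Best-so-far tracking with a post-warmup patience counter.

    An epoch "improves" iff its validation loss is strictly below the
    best seen. Non-improving epochs are only counted once the epoch
    index exceeds `min_epochs`; with a flat trace from epoch 1 and
    min_epochs = patience = 5, training stops at epoch 10.
    """

    def __init__(self, min_epochs: int, patience: int):
        self.min_epochs = min_epochs
        self.patience = patience
        self.best = math.inf
        self.best_epoch = 0
        self.bad_epochs = 0

    def update(self, epoch: int, val_loss: float) -> bool:
        """Record an epoch; returns True if training should stop."""
        if val_loss < self.best:
            self.best = val_loss
            self.best_epoch = epoch
            self.bad_epochs = 0
            return False
        if epoch > self.min_epochs:
            self.bad_epochs += 1
        return self.bad_epochs >= self.patience


class Adam:
    """Adam with additive (L2) weight decay, per the classic update."""

    def __init__(self, lr: float, weight_decay: float = 0.0, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.wd = lr, weight_decay
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}

    def step(self, params: DamilParams, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        arrays = params.arrays()
        for name, grad in grads.items():
            p = arrays[name]
            g = grad + self.wd * p
            m = self.m.setdefault(name, np.zeros_like(p))
            v = self.v.setdefault(name, np.zeros_like(p))
            m += (1 - self.beta1) * (g - m)
            v += (1 - self.beta2) * (g * g - v)
            mhat = m / (1 - self.beta1**self.t)
            vhat = v / (1 - self.beta2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _stratified_folds(
    patients: list[str], k: int, rng: np.random.Generator
) -> list[list[str]]:
    shuffled = list(patients)
    rng.shuffle(shuffled)
    sizes = [len(shuffled) // k + (1 if i < len(shuffled) % k else 0) for i in range(k)]
    folds, start = [], 0
    for size in sizes:
        folds.append(shuffled[start : start + size])
        start += size
    return folds


def make_splits(
    cohort: pd.DataFrame,
    k: int = 5,
    val_fraction: float = 1.0 / 6.0,
    seed: int = 0,
) -> SplitPlan:
    """Patient-level stratified k-fold train/validation/test plan.

    Test folds partition each class into k groups whose sizes differ by
    at most one; within each fold the remaining patients are split into
    train/validation per class at `val_fraction`. All slides of a
    patient travel together because the plan is expressed in patient
    ids. Deterministic given the seed.
    """
    per_patient = cohort.drop_duplicates("patient_id")
    by_class = {
        lab: sorted(per_patient.loc[per_patient["label"] == lab, "patient_id"])
        for lab in (RC, NRC)
    }
    for lab, pats in by_class.items():
        if len(pats) < k:
            raise ValueError(f"class {lab} has {len(pats)} patients, fewer than k={k}")
    rng = np.random.default_rng(seed)
    class_folds = {lab: _stratified_folds(pats, k, rng) for lab, pats in by_class.items()}

    folds = []
    for f in range(k):
        test = sorted(class_folds[RC][f] + class_folds[NRC][f])
        train: list[str] = []
        val: list[str] = []
        for lab in (RC, NRC):
            rest = [p for i in range(k) if i != f for p in class_folds[lab][i]]
            rest = sorted(rest)
            rng_f = np.random.default_rng(
                np.random.SeedSequence([seed, f, CLASS_INDEX[lab]])
            )
            rng_f.shuffle(rest)
            n_val = max(1, round(val_fraction * len(rest)))
            val.extend(rest[:n_val])
            train.extend(rest[n_val:])
        folds.append(FoldSplit(train=sorted(train), validation=sorted(val), test=test))
    return SplitPlan(folds=folds)


def sample_weights(labels: list[str]) -> np.ndarray:
    """Inverse-class-frequency weights so expected class draws are equal."""
    labels_arr = np.asarray(labels)
    classes, counts = np.unique(labels_arr, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present to weight the sampler")
    freq = dict(zip(classes, counts))
    w = np.array([1.0 / freq[lab] for lab in labels_arr])
    return w / w.sum()


def _check_no_leakage(keyset: KeySet, bags: list[EmbeddingBag], role: str) -> None:
    leaked = keyset.slide_ids() & {b.slide_id for b in bags}
    if leaked:
        raise LeakageError(
            f"{role} slides found in key-set provenance: {sorted(leaked)[:5]}"
        )


def mean_loss(
    bags: list[EmbeddingBag], keyset: KeySet, params: DamilParams
) -> float:
    total = 0.0
    for bag in bags:
        out = forward(bag, keyset, params)
        total -= math.log(max(out.probs[CLASS_INDEX[bag.label]], 1e-300))
    return total / len(bags)


def train_fold(
    train_bags: list[EmbeddingBag],
    val_bags: list[EmbeddingBag],
    keyset: KeySet,
    model_config: DamilConfig,
    train_config: TrainConfig,
) -> tuple[DamilParams, TrainState]:
    """Train one fold; returns the best-validation checkpoint and trace."""
    if not train_bags or not val_bags:
        raise ValueError("need non-empty train and validation sets")
    _check_no_leakage(keyset, val_bags, "validation")

    params = init_params(model_config)
    best_params = params.copy()
    optimizer = Adam(train_config.learning_rate, train_config.weight_decay)
    stopper = EarlyStopping(train_config.min_epochs, train_config.patience)
    weights = sample_weights([b.label for b in train_bags])
    rng = np.random.default_rng(train_config.seed)
    state = TrainState()

    for epoch in range(1, train_config.max_epochs + 1):
        draws = rng.choice(len(train_bags), size=len(train_bags), p=weights)
        epoch_loss = 0.0
        for idx in draws:
            bag = train_bags[idx]
            loss, grads = loss_and_grads(bag, keyset, params, CLASS_INDEX[bag.label])
            optimizer.step(params, grads)
            epoch_loss += loss
        state.epoch = epoch
        state.train_losses.append(epoch_loss / len(draws))
        val_loss = mean_loss(val_bags, keyset, params)
        state.val_losses.append(val_loss)
        if val_loss < stopper.best:
            best_params = params.copy()
        if stopper.update(epoch, val_loss):
            state.stop_reason = "early_stop"
            break
    else:
        state.stop_reason = "max_epochs"
    state.best_epoch = stopper.best_epoch
    state.best_val_loss = stopper.best
    return best_params, state


def predict_bags(
    bags: list[EmbeddingBag], keyset: KeySet, params: DamilParams
) -> pd.DataFrame:
    rows = [
        {
            "slide_id": bag.slide_id,
            "patient_id": bag.patient_id,
            "p_RC": forward(bag, keyset, params).p_rc,
            "label": bag.label,
        }
        for bag in bags
    ]
    return pd.DataFrame(rows)


def run_crossval(
    bags: list[EmbeddingBag],
    cohort: pd.DataFrame,
    split_plan: SplitPlan,
    crl_config: CrlConfig,
    model_config: DamilConfig,
    train_config: TrainConfig,
) -> tuple[pd.DataFrame, list[TrainState]]:
    """Per-fold keyset + training + test predictions.

    Each slide receives exactly one test-fold prediction because the
    test folds partition the patients. Returns the stacked predictions
    (slide_id, patient_id, fold, p_RC, label) and per-fold train states.
    """
    by_patient: dict[str, list[EmbeddingBag]] = {}
    for bag in bags:
        by_patient.setdefault(bag.patient_id, []).append(bag)

    def collect(patients: list[str]) -> list[EmbeddingBag]:
        return [bag for pid in patients for bag in by_patient[pid]]

    all_preds = []
    states = []
    for f, fold in enumerate(split_plan.folds):
        train_bags = collect(fold.train)
        val_bags = collect(fold.validation)
        test_bags = collect(fold.test)
        keyset = build_keyset(train_bags, crl_config)
        _check_no_leakage(keyset, val_bags + test_bags, "validation/test")
        fold_train_cfg = TrainConfig(
            **{**train_config.__dict__, "seed": train_config.seed + f}
        )
        params, state = train_fold(
            train_bags, val_bags, keyset, model_config, fold_train_cfg
        )
        preds = predict_bags(test_bags, keyset, params)
        preds.insert(2, "fold", f)
        all_preds.append(preds)
        states.append(state)
    return pd.concat(all_preds, ignore_index=True), states
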