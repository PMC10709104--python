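"""Two-phase optimization: multi-task pretraining, then per-dataset fine-tuning.

Pretraining shares the two branch layers across datasets while each dataset
owns its scalar output head; every optimization step consumes a batch drawn
from a single dataset (defaults: 10 epochs, batch 256, lr 1e-5) so exactly
one head receives gradient. Fine-tuning uses two parameter groups with
differential learning rates (defaults: batch 8, lr 1e-4 for the output
head, 5e-6 for the shared branches). Both phases use Adam with canonical
moments (beta1=0.9, beta2=0.999, eps=1e-8) and mean-squared-error loss.

All randomness flows from explicit seeds through ``numpy`` generators; runs
are bit-reproducible for a fixed (seed, provider, config) on one platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .dms_data import DmsDataset, DmsRecord
from .embeddings import RepresentationProvider, pair_for_variant
from .head_model import (
    HeadConfig,
    MultiHeadModel,
    Gradients,
    backward_mse,
    forward_batch,
    init_model,
    _init_head,
)

ADAM_BETA1 = 0.9
ADAM_BETA2 = 0.999
ADAM_EPS = 1e-8


def mse(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Mean squared error (1/n) * sum (Y_i - Yhat_i)^2."""
    y = np.asarray(observed, dtype=np.float64)
    yhat = np.asarray(predicted, dtype=np.float64)
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {yhat.shape}")
    if y.size == 0:
        raise ValueError("empty input")
    return float(np.mean((y - yhat) ** 2))


@dataclass(frozen=True)
class ScoreTransform:
    """Affine standardization record: standardized = (raw - mean) / sd."""

    mean: float
    sd: float

    def apply(self, scores: np.ndarray) -> np.ndarray:
        return (np.asarray(scores, dtype=np.float64) - self.mean) / self.sd

    def invert(self, scores: np.ndarray) -> np.ndarray:
        return np.asarray(scores, dtype=np.float64) * self.sd + self.mean


def standardize_scores(dataset: DmsDataset) -> tuple[DmsDataset, ScoreTransform]:
    """Return a copy of *dataset* with zero-mean unit-variance scores."""
    scores = np.asarray(dataset.scores, dtype=np.float64)
    if scores.size < 2:
        raise ValueError("need >= 2 records to standardize")
    mean = float(scores.mean())
    sd = float(scores.std())
    if sd == 0.0:
        raise ValueError(f"{dataset.name}: constant scores cannot be standardized")
    transform = ScoreTransform(mean, sd)
    std = transform.apply(scores)
    records = [DmsRecord(r.mutation, float(s)) for r, s in zip(dataset.records, std)]
    out = DmsDataset(dataset.name, dataset.wt_sequence, records, dataset.measurement_label)
    return out, transform


@dataclass(frozen=True)
class PretrainConfig:
    epochs: int = 10
    batch_size: int = 256
    learning_rate: float = 1e-5
    standardize_scores: bool = True
    seed: int = 0
    shared_head: bool = False  # single output head across all datasets (zero-shot mode)
    shared_head_name: str = "shared"

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("epochs, batch_size and learning_rate must be positive")


@dataclass(frozen=True)
class FinetuneConfig:
    batch_size: int = 8
    lr_head: float = 1e-4
    lr_shared: float = 5e-6
    epochs: int = 20
    standardize_scores: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")
        if self.lr_head < 0 or self.lr_shared < 0:
            raise ValueError("learning rates must be non-negative")


@dataclass
class TrainingLog:
    """Per-epoch losses keyed by dataset, plus seed provenance."""

    seed: int
    entries: list[dict] = field(default_factory=list)

    def record(self, epoch: int, dataset: str, loss: float) -> None:
        if not np.isfinite(loss):
            raise FloatingPointError(f"non-finite loss at epoch {epoch} on {dataset}")
        self.entries.append({"epoch": epoch, "dataset": dataset, "loss": float(loss)})

    def to_rows(self) -> list[dict]:
        return list(self.entries)


class Adam:
    """Minimal Adam with a per-parameter learning rate map and update counts."""

    def __init__(self, lr: dict[str, float]):
        self.lr = lr
        self._m: dict[str, np.ndarray] = {}
        self._v: dict[str, np.ndarray] = {}
        self._t: dict[str, int] = {}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        for key, g in grads.items():
            lr = self.lr[key]
            if lr == 0.0:
                continue
            g = np.asarray(g, dtype=np.float64)
            if key not in self._m:
                self._m[key] = np.zeros_like(g)
                self._v[key] = np.zeros_like(g)
                self._t[key] = 0
            self._t[key] += 1
            t = self._t[key]
            m = self._m[key] = ADAM_BETA1 * self._m[key] + (1 - ADAM_BETA1) * g
            v = self._v[key] = ADAM_BETA2 * self._v[key] + (1 - ADAM_BETA2) * g * g
            mhat = m / (1 - ADAM_BETA1**t)
            vhat = v / (1 - ADAM_BETA2**t)
            p = params[key]
            p[...] = (p.astype(np.float64) - lr * mhat / (np.sqrt(vhat) + ADAM_EPS)).astype(p.dtype)


def _shared_params(model: MultiHeadModel) -> dict[str, np.ndarray]:
    return {
        "branch_wt.W": model.branch_wt.W,
        "branch_wt.b": model.branch_wt.b,
        "branch_wt.a": model.branch_wt.a,
        "branch_mt.W": model.branch_mt.W,
        "branch_mt.b": model.branch_mt.b,
        "branch_mt.a": model.branch_mt.a,
    }


def _head_params(model: MultiHeadModel, head_name: str) -> dict[str, np.ndarray]:
    head = model.heads[head_name]
    return {f"head:{head_name}.w": head.w, f"head:{head_name}.b": head.b}


def _grad_dict(g: Gradients) -> dict[str, np.ndarray]:
    return {
        "branch_wt.W": g.dW1,
        "branch_wt.b": g.db1,
        "branch_wt.a": g.da1,
        "branch_mt.W": g.dW2,
        "branch_mt.b": g.db2,
        "branch_mt.a": g.da2,
        f"head:{g.head_name}.w": g.dw_head,
        f"head:{g.head_name}.b": g.db_head,
    }


def variant_matrices(
    provider: RepresentationProvider,
    dataset: DmsDataset,
    records: Sequence[DmsRecord] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Stack wild-type and mutant vectors for *records* into (n, dim) arrays."""
    records = dataset.records if records is None else list(records)
    wt_rows, mt_rows = [], []
    for rec in records:
        pair = pair_for_variant(provider, dataset, rec.mutation)
        wt_rows.append(pair.wt_vector.values)
        mt_rows.append(pair.mt_vector.values)
    return np.asarray(wt_rows, dtype=np.float32), np.asarray(mt_rows, dtype=np.float32)


@dataclass
class PretrainResult:
    model: MultiHeadModel
    transforms: dict[str, ScoreTransform | None]
    log: TrainingLog


def pretrain(
    datasets: Sequence[DmsDataset],
    provider: RepresentationProvider,
    config: PretrainConfig,
    head_config: HeadConfig | None = None,
) -> PretrainResult:
    """Multi-task pretraining: shared branches, one output head per dataset.

    Each epoch is one pass over the union of all per-dataset batches in a
    seeded shuffled order; a batch is homogeneous in dataset, so its gradient
    touches the shared branches and that dataset's head only. With
    ``config.shared_head`` a single head is shared by the whole pool.
    """
    if not datasets:
        raise ValueError("need at least one dataset")
    names = [d.name for d in datasets]
    if len(set(names)) != len(names):
        raise ValueError("duplicate dataset names")
    if head_config is None:
        head_config = HeadConfig(input_dim=provider.dim)
    if head_config.input_dim != provider.dim:
        raise ValueError("head_config.input_dim disagrees with provider.dim")

    transforms: dict[str, ScoreTransform | None] = {}
    prepared: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for ds in datasets:
        if not ds.records:
            raise ValueError(f"empty dataset {ds.name}")
        if config.standardize_scores:
            ds_std, transforms[ds.name] = standardize_scores(ds)
        else:
            ds_std, transforms[ds.name] = ds, None
        V_wt, V_mt = variant_matrices(provider, ds_std)
        prepared[ds.name] = (V_wt, V_mt, np.asarray(ds_std.scores, dtype=np.float32))

    head_names = [config.shared_head_name] if config.shared_head else names
    model = init_model(head_config, head_names, seed=config.seed)
    head_of = {n: (config.shared_head_name if config.shared_head else n) for n in names}

    lr = {k: config.learning_rate for k in _shared_params(model)}
    for hn in head_names:
        lr.update({k: config.learning_rate for k in _head_params(model, hn)})
    opt = Adam(lr)
    log = TrainingLog(seed=config.seed)

    shuffle_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    dropout_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))

    for epoch in range(config.epochs):
        batches: list[tuple[str, np.ndarray]] = []
        for name in names:
            n = prepared[name][0].shape[0]
            order = shuffle_rng.permutation(n)
            for start in range(0, n, config.batch_size):
                batches.append((name, order[start : start + config.batch_size]))
        shuffle_rng.shuffle(batches)

        epoch_losses: dict[str, list[float]] = {n: [] for n in names}
        for name, idx in batches:
            V_wt, V_mt, y = prepared[name]
            preds, cache = forward_batch(
                model, V_wt[idx], V_mt[idx], head_of[name], training=True, rng=dropout_rng
            )
            grads = _grad_dict(backward_mse(model, cache, preds, y[idx]))
            params = {**_shared_params(model), **_head_params(model, head_of[name])}
            opt.step(params, grads)
            epoch_losses[name].append(mse(y[idx], preds))
        for name in names:
            log.record(epoch, name, float(np.mean(epoch_losses[name])))
    return PretrainResult(model, transforms, log)


@dataclass
class FinetuneResult:
    model: MultiHeadModel
    transform: ScoreTransform | None
    log: TrainingLog


def finetune(
    model: MultiHeadModel,
    target: DmsDataset,
    train_records: Sequence[DmsRecord],
    provider: RepresentationProvider,
    config: FinetuneConfig,
    head_name: str | None = None,
) -> FinetuneResult:
    """Fine-tune a copy of *model* on *train_records* of *target*.

    Two Adam parameter groups: the shared branches at ``lr_shared`` and the
    target's head at ``lr_head``. Heads of other datasets are frozen. A
    fresh seeded head is created when the target has none.
    """
    if not train_records:
        raise ValueError("empty training set")
    model = model.copy()
    head_name = head_name or target.name
    if head_name not in model.heads:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 303]))
        model.heads[head_name] = _init_head(model.config, head_name, rng)

    train_ds = DmsDataset(
        target.name, target.wt_sequence, list(train_records), target.measurement_label
    )
    if config.standardize_scores:
        train_ds, transform = standardize_scores(train_ds)
    else:
        transform = None
    V_wt, V_mt = variant_matrices(provider, train_ds)
    y = np.asarray(train_ds.scores, dtype=np.float32)

    lr = {k: config.lr_shared for k in _shared_params(model)}
    lr.update({k: config.lr_head for k in _head_params(model, head_name)})
    opt = Adam(lr)
    log = TrainingLog(seed=config.seed)

    shuffle_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 404]))
    dropout_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 505]))
    n = y.shape[0]
    for epoch in range(config.epochs):
        order = shuffle_rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            preds, cache = forward_batch(
                model, V_wt[idx], V_mt[idx], head_name, training=True, rng=dropout_rng
            )
            grads = _grad_dict(backward_mse(model, cache, preds, y[idx]))
            params = {**_shared_params(model), **_head_params(model, head_name)}
            opt.step(params, grads)
            losses.append(mse(y[idx], preds))
        log.record(epoch, target.name, float(np.mean(losses)))
    return FinetuneResult(model, transform, log)


def predict(
    model: MultiHeadModel,
    dataset: DmsDataset,
    records: Sequence[DmsRecord],
    provider: RepresentationProvider,
    head_name: str | None = None,
    transform: ScoreTransform | None = None,
) -> np.ndarray:
    """Training-off predictions, de-standardized through *transform* when given."""
    head_name = head_name or dataset.name
    if head_name not in model.heads:
        raise KeyError(f"unknown head {head_name!r}")
    V_wt, V_mt = variant_matrices(provider, dataset, records)
    preds, _ = forward_batch(model, V_wt, V_mt, head_name, training=False)
    preds = preds.astype(np.float64)
    if transform is not None:
        preds = transform.invert(preds)
    return preds
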