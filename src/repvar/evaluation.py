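"""Rank-correlation scoring and train/test split protocols.

Four split strategies: repeated k-fold cross-validation, leave-one-position-out
(all variants sharing a mutated position are held out together), repeated
fraction splits for few-shot transfer, and leave-one-dataset-out zero-shot.
Per-repeat correlation for k-fold protocols is computed over the concatenated
out-of-fold predictions of the repeat, and the aggregate is the unweighted
arithmetic mean of per-repeat values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .dms_data import DmsDataset, DmsRecord
from .embeddings import RepresentationProvider
from .head_model import HeadConfig, MultiHeadModel, init_model
from .training import (
    FinetuneConfig,
    PretrainConfig,
    PretrainResult,
    finetune,
    predict,
    pretrain,
)

STRATEGIES = ("kfold", "position", "fraction", "zero_shot")


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation: Pearson correlation of average-ranked values."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValueError("need at least two observations")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("degenerate (constant) input")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


@dataclass
class SplitPlan:
    strategy: str
    folds: list[tuple[np.ndarray, np.ndarray]]  # (train indices, test indices)
    seed: int | None = None
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")

    def validate(self, n: int | None = None) -> None:
        """Re-check disjointness (always) and partition structure (kfold/position)."""
        for train, test in self.folds:
            if np.intersect1d(train, test).size:
                raise ValueError("train and test overlap within a fold")
            if len(test) == 0 or len(train) == 0:
                raise ValueError("empty train or test side in a fold")
        if self.strategy in ("kfold", "position") and n is not None:
            all_test = np.concatenate([t for _, t in self.folds])
            if sorted(all_test.tolist()) != list(range(n)):
                raise ValueError("test folds do not partition the index range")


def kfold_split(n: int, k: int, seed: int) -> SplitPlan:
    """Seeded balanced k-fold partition; fold sizes differ by at most one."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError(f"cannot split {n} items into {k} folds")
    order = np.random.default_rng(seed).permutation(n)
    test_sets = np.array_split(order, k)
    folds = [(np.setdiff1d(np.arange(n), test), np.sort(test)) for test in test_sets]
    return SplitPlan("kfold", folds, seed=seed, parameters={"k": k, "n": n})


def position_split(dataset: DmsDataset) -> SplitPlan:
    """Leave-one-position-out: one fold per distinct mutated position."""
    positions = np.asarray([r.mutation.position for r in dataset.records])
    distinct = np.unique(positions)
    if distinct.size < 2:
        raise ValueError("need >= 2 distinct mutated positions")
    idx = np.arange(len(dataset.records))
    folds = [(idx[positions != p], idx[positions == p]) for p in distinct]
    return SplitPlan(
        "position", folds, parameters={"n_positions": int(distinct.size), "n": len(idx)}
    )


def fraction_split(n: int, train_fraction: float, seed: int, repeats: int = 1) -> SplitPlan:
    """Repeated random splits with train size ``round(train_fraction * n)``."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    n_train = round(train_fraction * n)
    if n_train == 0 or n_train == n:
        raise ValueError(f"fraction {train_fraction} leaves an empty side for n={n}")
    folds = []
    for r in range(repeats):
        order = np.random.default_rng(np.random.SeedSequence([seed, r])).permutation(n)
        folds.append((np.sort(order[:n_train]), np.sort(order[n_train:])))
    return SplitPlan(
        "fraction",
        folds,
        seed=seed,
        parameters={"train_fraction": train_fraction, "repeats": repeats, "n": n},
    )


@dataclass
class EvalResult:
    """Per-repeat rank correlations and their unweighted mean."""

    strategy: str
    dataset: str
    per_repeat_srcc: list[float]
    n_train: list[int]
    n_test: list[int]
    metadata: dict = field(default_factory=dict)
    rows: list[dict] = field(default_factory=list)  # per (repeat, fold) detail

    def __post_init__(self) -> None:
        for rho in self.per_repeat_srcc:
            if not -1.0 - 1e-12 <= rho <= 1.0 + 1e-12:
                raise ValueError(f"SRCC {rho} outside [-1, 1]")

    @property
    def mean_srcc(self) -> float:
        return float(np.mean(self.per_repeat_srcc))

    def summary(self) -> dict:
        return {
            "strategy": self.strategy,
            "dataset": self.dataset,
            "mean_srcc": self.mean_srcc,
            "sd_srcc": float(np.std(self.per_repeat_srcc)),
            "repeats": len(self.per_repeat_srcc),
            **self.metadata,
        }


def _records_at(dataset: DmsDataset, idx: np.ndarray) -> list[DmsRecord]:
    return [dataset.records[i] for i in idx]


def _cv_repeat(
    model: MultiHeadModel,
    target: DmsDataset,
    plan: SplitPlan,
    provider: RepresentationProvider,
    ft_config: FinetuneConfig,
    rows: list[dict],
    repeat: int,
) -> float:
    """Fine-tune per fold from the same starting model; SRCC over concatenated
    out-of-fold predictions."""
    all_pred: list[np.ndarray] = []
    all_obs: list[float] = []
    for fold_i, (train_idx, test_idx) in enumerate(plan.folds):
        train_recs = _records_at(target, train_idx)
        test_recs = _records_at(target, test_idx)
        ft = finetune(model, target, train_recs, provider, ft_config)
        preds = predict(ft.model, target, test_recs, provider, target.name, ft.transform)
        all_pred.append(preds)
        all_obs.extend(r.score for r in test_recs)
        rows.append(
            {
                "repeat": repeat,
                "fold": fold_i,
                "n_train": len(train_recs),
                "n_test": len(test_recs),
            }
        )
    return spearman(all_obs, np.concatenate(all_pred))


def run_tenfold(
    target: DmsDataset,
    pretrain_pool: Sequence[DmsDataset],
    provider: RepresentationProvider,
    pretrain_config: PretrainConfig,
    finetune_config: FinetuneConfig,
    repeats: int = 50,
    k: int = 10,
    seed: int = 0,
    pretrained: PretrainResult | None = None,
) -> EvalResult:
    """Leave-target-out pretraining, then repeated k-fold fine-tune/test cycles."""
    if any(d.name == target.name for d in pretrain_pool):
        raise ValueError("target must be excluded from the pretraining pool")
    if pretrained is None:
        pretrained = pretrain(pretrain_pool, provider, pretrain_config)
    rows: list[dict] = []
    srccs, n_train, n_test = [], [], []
    for r in range(repeats):
        plan = kfold_split(len(target.records), k, seed=seed + r)
        plan.validate(len(target.records))
        ft_cfg = FinetuneConfig(
            batch_size=finetune_config.batch_size,
            lr_head=finetune_config.lr_head,
            lr_shared=finetune_config.lr_shared,
            epochs=finetune_config.epochs,
            standardize_scores=finetune_config.standardize_scores,
            seed=finetune_config.seed + r,
        )
        srccs.append(_cv_repeat(pretrained.model, target, plan, provider, ft_cfg, rows, r))
        n_train.append(len(plan.folds[0][0]))
        n_test.append(len(target.records))
    return EvalResult(
        "kfold",
        target.name,
        srccs,
        n_train,
        n_test,
        metadata={"k": k, "repeats": repeats, "seed": seed},
        rows=rows,
    )


def run_fewshot(
    pool: Sequence[DmsDataset],
    target: DmsDataset,
    provider: RepresentationProvider,
    pretrain_config: PretrainConfig,
    finetune_config: FinetuneConfig,
    fraction: float = 0.3,
    repeats: int = 5,
    seed: int = 0,
    skip_pretraining: bool = False,
    head_config: HeadConfig | None = None,
) -> EvalResult:
    """Pretrain on the pool, then repeated fraction-split fine-tune/test.

    ``skip_pretraining`` starts each repeat from a fresh seeded model instead
    (the no-transfer control).
    """
    if any(d.name == target.name for d in pool):
        raise ValueError("target must not be in the pool")
    if skip_pretraining:
        if head_config is None:
            head_config = HeadConfig(input_dim=provider.dim)
        base_model = init_model(head_config, [target.name], seed=pretrain_config.seed)
    else:
        base_model = pretrain(pool, provider, pretrain_config, head_config).model
    plan = fraction_split(len(target.records), fraction, seed=seed, repeats=repeats)
    plan.validate()
    rows: list[dict] = []
    srccs, n_train, n_test = [], [], []
    for r, (train_idx, test_idx) in enumerate(plan.folds):
        train_recs = _records_at(target, train_idx)
        test_recs = _records_at(target, test_idx)
        ft_cfg = FinetuneConfig(
            batch_size=finetune_config.batch_size,
            lr_head=finetune_config.lr_head,
            lr_shared=finetune_config.lr_shared,
            epochs=finetune_config.epochs,
            standardize_scores=finetune_config.standardize_scores,
            seed=finetune_config.seed + r,
        )
        ft = finetune(base_model, target, train_recs, provider, ft_cfg)
        preds = predict(ft.model, target, test_recs, provider, target.name, ft.transform)
        srccs.append(spearman([rec.score for rec in test_recs], preds))
        n_train.append(len(train_recs))
        n_test.append(len(test_recs))
        rows.append({"repeat": r, "fold": 0, "n_train": len(train_recs), "n_test": len(test_recs)})
    return EvalResult(
        "fraction",
        target.name,
        srccs,
        n_train,
        n_test,
        metadata={
            "fraction": fraction,
            "repeats": repeats,
            "seed": seed,
            "pretrained": not skip_pretraining,
        },
        rows=rows,
    )


def run_zeroshot(
    pool: Sequence[DmsDataset],
    target: DmsDataset,
    provider: RepresentationProvider,
    pretrain_config: PretrainConfig,
    head_config: HeadConfig | None = None,
    head_strategy: str = "shared",
) -> EvalResult:
    """Train on the pool, apply unchanged to the target; single SRCC.

    ``head_strategy="shared"`` (default) trains one output head across the
    pool and applies it directly; ``"average"`` trains per-dataset heads and
    scores the target with their parameter average.
    """
    if any(d.name == target.name for d in pool):
        raise ValueError("target must not be in the pool")
    labels = {d.measurement_label for d in pool}
    if len(labels) > 1:
        raise ValueError(f"pool measurement labels disagree: {sorted(labels)}")
    if head_strategy not in ("shared", "average"):
        raise ValueError(f"unknown head strategy {head_strategy!r}")

    cfg = PretrainConfig(
        epochs=pretrain_config.epochs,
        batch_size=pretrain_config.batch_size,
        learning_rate=pretrain_config.learning_rate,
        standardize_scores=pretrain_config.standardize_scores,
        seed=pretrain_config.seed,
        shared_head=(head_strategy == "shared"),
    )
    result = pretrain(pool, provider, cfg, head_config)
    model = result.model
    if head_strategy == "shared":
        head_name = cfg.shared_head_name
    else:
        head_name = "averaged"
        heads = list(model.heads.values())
        avg = heads[0].copy()
        avg.w = np.mean([h.w for h in heads], axis=0).astype(avg.w.dtype)
        avg.b = np.asarray(np.mean([h.b for h in heads]), dtype=avg.b.dtype)
        avg.dataset_name = head_name
        model.heads[head_name] = avg

    preds = predict(model, target, target.records, provider, head_name)
    rho = spearman(target.scores, preds)
    return EvalResult(
        "zero_shot",
        target.name,
        [rho],
        [sum(len(d.records) for d in pool)],
        [len(target.records)],
        metadata={"head_strategy": head_strategy, "pool": [d.name for d in pool]},
        rows=[{"repeat": 0, "fold": 0, "n_train": sum(len(d.records) for d in pool), "n_test": len(target.records)}],
    )


def run_leave_position_out(
    target: DmsDataset,
    provider: RepresentationProvider,
    finetune_config: FinetuneConfig,
    pretrained: PretrainResult | None = None,
    head_config: HeadConfig | None = None,
    seed: int = 0,
) -> EvalResult:
    """Per-position hold-out; trains from random init when no pretrained model is given."""
    plan = position_split(target)
    plan.validate(len(target.records))
    if pretrained is not None:
        base_model = pretrained.model
    else:
        if head_config is None:
            head_config = HeadConfig(input_dim=provider.dim)
        base_model = init_model(head_config, [target.name], seed=seed)
    rows: list[dict] = []
    rho = _cv_repeat(base_model, target, plan, provider, finetune_config, rows, 0)
    return EvalResult(
        "position",
        target.name,
        [rho],
        [len(plan.folds[0][0])],
        [len(target.records)],
        metadata={"n_positions": plan.parameters["n_positions"], "transfer": pretrained is not None},
        rows=rows,
    )


def write_report(result: EvalResult, out_dir: str | Path) -> tuple[Path, Path]:
    """Emit the per-fold CSV and JSON summary; returns their paths."""
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    detail = pd.DataFrame(result.rows)
    detail.insert(0, "strategy", result.strategy)
    detail.insert(0, "dataset", result.dataset)
    srcc_by_repeat = {i: v for i, v in enumerate(result.per_repeat_srcc)}
    detail["srcc"] = detail["repeat"].map(srcc_by_repeat)
    csv_path = out_dir / f"eval_{result.dataset}_{result.strategy}.csv"
    detail.to_csv(csv_path, index=False)
    json_path = out_dir / f"eval_{result.dataset}_{result.strategy}.json"
    json_path.write_text(json.dumps(result.summary(), indent=1, sort_keys=True))
    return csv_path, json_path
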