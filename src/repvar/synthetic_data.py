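"""Planted-signal fixture generators.

Scores are produced by a hidden network of the same family the trainer fits
(a planted twin-branch head applied to the synthetic provider's vectors)
plus Gaussian noise, which makes recovery an identifiable oracle test of
the training code. A multi-task suite shares the planted branch parameters
across members so transfer between datasets carries real signal.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import yaml

from .dms_data import (
    CANONICAL_AA,
    DatasetManifest,
    DmsDataset,
    DmsRecord,
    Mutation,
    load_manifest,
)
from .embeddings import SyntheticProvider
from .head_model import HeadConfig, MultiHeadModel, forward_batch, init_model, _init_head
from .training import FinetuneConfig, PretrainConfig, variant_matrices

#: reduced default dimensions keep synthetic tests fast
DEFAULT_SYNTH_INPUT_DIM = 64
DEFAULT_SYNTH_HIDDEN_DIM = 8

_PLANTED_HEAD = "planted"

# Desk-scale training presets. The study-scale defaults (lr 1e-5 / 5e-6,
# 10-20 epochs) barely move the parameters on the small planted problems the
# tests use, so recovery checks train harder while keeping the protocol
# (Adam + MSE, two-group fine-tuning) identical.
RECOVERY_HEAD_CONFIG = HeadConfig(
    input_dim=DEFAULT_SYNTH_INPUT_DIM,
    hidden_dim=DEFAULT_SYNTH_HIDDEN_DIM,
    dropout_rate=0.05,
    rectifier_slope_init=1.0,
)
RECOVERY_FINETUNE_CONFIG = FinetuneConfig(
    epochs=500, batch_size=32, lr_head=3e-3, lr_shared=3e-3, seed=11
)
RECOVERY_PRETRAIN_CONFIG = PretrainConfig(
    epochs=60, batch_size=64, learning_rate=1e-3, seed=11
)


@dataclass(frozen=True)
class PlantedModelSpec:
    """Recipe for one planted dataset."""

    seed: int = 0
    n_variants: int = 500
    seq_length: int = 60
    input_dim: int = DEFAULT_SYNTH_INPUT_DIM
    hidden_dim: int = DEFAULT_SYNTH_HIDDEN_DIM
    noise_sd: float = 0.0
    noise_sd_relative: bool = False  # interpret noise_sd as a multiple of the score sd
    measurement_label: str = "planted"
    name: str = "planted"
    branch_seed: int | None = None  # None: derived from seed
    head_seed: int | None = None
    misspecified: bool = False  # scores from a random quadratic instead of the planted head
    #: slope of the planted rectifiers. 1.0 (the identity point of the
    #: learnable slope) keeps the planted map bilinear and recoverable at
    #: the sample sizes the fast tests use; generic slopes make recovery a
    #: much harder non-convex problem without changing the family.
    planted_slope: float = 1.0

    def __post_init__(self) -> None:
        if self.n_variants > 19 * self.seq_length:
            raise ValueError(
                f"{self.n_variants} variants exceed the {19 * self.seq_length} "
                f"distinct single substitutions of a length-{self.seq_length} sequence"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def planted_model(spec: PlantedModelSpec) -> MultiHeadModel:
    """The hidden network that generates a spec's ground-truth scores."""
    branch_seed = spec.seed if spec.branch_seed is None else spec.branch_seed
    config = HeadConfig(
        input_dim=spec.input_dim,
        hidden_dim=spec.hidden_dim,
        dropout_rate=0.0,
        rectifier_slope_init=spec.planted_slope,
    )
    model = init_model(config, [_PLANTED_HEAD], seed=branch_seed)
    if spec.head_seed is not None:
        rng = np.random.default_rng(np.random.SeedSequence([spec.head_seed, 7]))
        model.heads[_PLANTED_HEAD] = _init_head(config, _PLANTED_HEAD, rng)
    return model


def _random_wt_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(CANONICAL_AA), size=length))


def _sample_variants(
    rng: np.random.Generator, wt_sequence: str, n: int
) -> list[Mutation]:
    """Sample n distinct non-identity (position, mt) pairs without replacement."""
    length = len(wt_sequence)
    flat = rng.choice(19 * length, size=n, replace=False)
    muts = []
    for code in np.sort(flat):
        pos = int(code) // 19 + 1
        wt = wt_sequence[pos - 1]
        alternatives = [aa for aa in CANONICAL_AA if aa != wt]
        muts.append(Mutation(wt, pos, alternatives[int(code) % 19]))
    return muts


def make_planted_dataset(
    spec: PlantedModelSpec, provider_seed: int = 0
) -> tuple[DmsDataset, np.ndarray]:
    """Generate one dataset and its noise-free ground-truth score vector."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 11]))
    wt_sequence = _random_wt_sequence(rng, spec.seq_length)
    mutations = _sample_variants(rng, wt_sequence, spec.n_variants)
    provider = SyntheticProvider(provider_seed, dim=spec.input_dim)

    skeleton = DmsDataset(
        spec.name,
        wt_sequence,
        [DmsRecord(m, 0.0) for m in mutations],
        spec.measurement_label,
    )
    V_wt, V_mt = variant_matrices(provider, skeleton)
    if spec.misspecified:
        qrng = np.random.default_rng(np.random.SeedSequence([spec.seed, 13]))
        Q = qrng.standard_normal((spec.input_dim,)) / np.sqrt(spec.input_dim)
        truth = ((V_wt * V_mt) @ Q) ** 2
    else:
        truth, _ = forward_batch(planted_model(spec), V_wt, V_mt, _PLANTED_HEAD)
    truth = truth.astype(np.float64)

    noise_sd = spec.noise_sd * (truth.std() if spec.noise_sd_relative else 1.0)
    noise_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 17]))
    scores = truth + noise_rng.normal(0.0, noise_sd, size=truth.shape)
    records = [DmsRecord(m, float(s)) for m, s in zip(mutations, scores)]
    dataset = DmsDataset(spec.name, wt_sequence, records, spec.measurement_label)
    dataset.validate()
    return dataset, truth


def make_multitask_suite(
    n_datasets: int,
    shared_branch_seed: int,
    per_dataset_head_seeds: list[int] | None = None,
    template: PlantedModelSpec | None = None,
    provider_seed: int = 0,
) -> list[tuple[DmsDataset, np.ndarray]]:
    """Datasets sharing planted branch parameters but differing in heads and
    wild-type sequences.

    Passing identical head seeds plants the same output head everywhere,
    making zero-shot transfer exact in the noise-free limit.
    """
    if n_datasets < 2:
        raise ValueError("suite needs >= 2 datasets")
    if template is None:
        template = PlantedModelSpec()
    if per_dataset_head_seeds is None:
        per_dataset_head_seeds = [1000 + i for i in range(n_datasets)]
    if len(per_dataset_head_seeds) != n_datasets:
        raise ValueError("need one head seed per dataset")
    suite = []
    for i, head_seed in enumerate(per_dataset_head_seeds):
        spec = replace(
            template,
            name=f"{template.name}_{i}",
            seed=template.seed + 31 * (i + 1),  # distinct wt sequence and variants
            branch_seed=shared_branch_seed,
            head_seed=head_seed,
        )
        suite.append(make_planted_dataset(spec, provider_seed=provider_seed))
    return suite


def table1_manifest_fixture() -> DatasetManifest:
    """The packaged 38-row study manifest (names, short names, counts, lengths)."""
    return load_manifest()


def write_simulated(
    out_dir: str | Path,
    dataset: DmsDataset,
    truth: np.ndarray,
    spec: PlantedModelSpec,
) -> dict[str, Path]:
    """Write FASTA + variant CSV + truth CSV + spec YAML for one dataset."""
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out_dir / f"{dataset.name}.fasta",
        "dms": out_dir / f"{dataset.name}.csv",
        "truth": out_dir / f"{dataset.name}.truth.csv",
        "spec": out_dir / f"{dataset.name}.spec.yaml",
    }
    paths["fasta"].write_text(f">{dataset.name}\n{dataset.wt_sequence}\n")
    pd.DataFrame(
        {"mutant": [r.mutation.format() for r in dataset.records], "score": dataset.scores}
    ).to_csv(paths["dms"], index=False)
    pd.DataFrame(
        {"mutant": [r.mutation.format() for r in dataset.records], "truth": truth}
    ).to_csv(paths["truth"], index=False)
    paths["spec"].write_text(yaml.safe_dump(spec.__dict__, sort_keys=True))
    return paths
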