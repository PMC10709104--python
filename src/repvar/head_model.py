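"""Twin-branch regression head with per-dataset scalar output layers.

Architecture: two independent affine layers (one per input vector), each
followed by a parameterized rectifier with a single learnable negative-side
slope and inverted dropout, merged by an entry-wise product and read out by
a dataset-specific affine scalar head::

    yhat = w . ( drop(prelu(W1 v_wt + b1; a1)) * drop(prelu(W2 v_mt + b2; a2)) ) + b

At the default configuration (1280 -> 128, one output head) the network has
exactly 328,067 trainable scalars; this count pins the interpretation of
the architecture (untied branches, one slope scalar per branch, biased
scalar head) and is enforced by tests.

Implemented directly on NumPy: the network is small enough that explicit
forward/backward passes are simpler, dependency-free and bit-reproducible.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .embeddings import VariantRepresentationPair

CHECKPOINT_VERSION = 1
PARAM_DTYPE = np.float32


@dataclass(frozen=True)
class HeadConfig:
    input_dim: int = 1280
    hidden_dim: int = 128
    dropout_rate: float = 0.2
    rectifier_slope_init: float = 0.25

    def __post_init__(self) -> None:
        if self.input_dim < 1 or self.hidden_dim < 1:
            raise ValueError("dimensions must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")


@dataclass
class BranchParameters:
    """One branch: affine map to hidden_dim plus a scalar rectifier slope."""

    W: np.ndarray  # (hidden_dim, input_dim)
    b: np.ndarray  # (hidden_dim,)
    a: np.ndarray  # scalar slope, stored as shape-() array

    def copy(self) -> "BranchParameters":
        return BranchParameters(self.W.copy(), self.b.copy(), self.a.copy())

    def n_params(self) -> int:
        return self.W.size + self.b.size + 1


@dataclass
class OutputHead:
    w: np.ndarray  # (hidden_dim,)
    b: np.ndarray  # scalar
    dataset_name: str

    def copy(self) -> "OutputHead":
        return OutputHead(self.w.copy(), self.b.copy(), self.dataset_name)

    def n_params(self) -> int:
        return self.w.size + 1


def prelu(x: np.ndarray, a: float | np.ndarray) -> np.ndarray:
    """Rectifier with learnable negative-side slope: x if x >= 0 else a*x."""
    return np.where(x >= 0, x, a * x)


@dataclass
class MultiHeadModel:
    config: HeadConfig
    branch_wt: BranchParameters
    branch_mt: BranchParameters
    heads: dict[str, OutputHead] = field(default_factory=dict)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not self.heads:
            raise ValueError("model needs at least one output head")

    def copy(self) -> "MultiHeadModel":
        return MultiHeadModel(
            config=self.config,
            branch_wt=self.branch_wt.copy(),
            branch_mt=self.branch_mt.copy(),
            heads={k: h.copy() for k, h in self.heads.items()},
            rng_seed=self.rng_seed,
        )

    def add_head(self, name: str, seed: int | None = None) -> OutputHead:
        if name in self.heads:
            raise ValueError(f"head {name!r} already exists")
        rng = np.random.default_rng(self.rng_seed if seed is None else seed)
        self.heads[name] = _init_head(self.config, name, rng)
        return self.heads[name]


def _uniform_fan_in(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(PARAM_DTYPE)


def _init_branch(config: HeadConfig, rng: np.random.Generator) -> BranchParameters:
    return BranchParameters(
        W=_uniform_fan_in(rng, (config.hidden_dim, config.input_dim), config.input_dim),
        b=np.zeros(config.hidden_dim, dtype=PARAM_DTYPE),
        a=np.asarray(config.rectifier_slope_init, dtype=PARAM_DTYPE),
    )


def _init_head(config: HeadConfig, name: str, rng: np.random.Generator) -> OutputHead:
    return OutputHead(
        w=_uniform_fan_in(rng, (config.hidden_dim,), config.hidden_dim),
        b=np.zeros((), dtype=PARAM_DTYPE),
        dataset_name=name,
    )


def init_model(config: HeadConfig, head_names: list[str], seed: int) -> MultiHeadModel:
    """Deterministically initialize a model with one output head per name.

    Branch weights use a uniform fan-in scheme, biases start at zero and
    rectifier slopes at ``config.rectifier_slope_init``.
    """
    if not head_names:
        raise ValueError("head_names must be non-empty")
    if len(set(head_names)) != len(head_names):
        raise ValueError("duplicate head names")
    rng = np.random.default_rng(seed)
    branch_wt = _init_branch(config, rng)
    branch_mt = _init_branch(config, rng)
    heads = {name: _init_head(config, name, rng) for name in head_names}
    return MultiHeadModel(config, branch_wt, branch_mt, heads, rng_seed=seed)


def count_trainable_parameters(model: MultiHeadModel, n_heads: int | None = None) -> int:
    """Total trainable scalars for the branches plus *n_heads* output heads."""
    if n_heads is None:
        n_heads = len(model.heads)
    c = model.config
    per_branch = c.hidden_dim * c.input_dim + c.hidden_dim + 1
    per_head = c.hidden_dim + 1
    return 2 * per_branch + n_heads * per_head


@dataclass
class ForwardCache:
    """Intermediates of a batched forward pass, consumed by backward()."""

    V_wt: np.ndarray
    V_mt: np.ndarray
    z1: np.ndarray
    z2: np.ndarray
    d1: np.ndarray
    d2: np.ndarray
    mask1: np.ndarray | None
    mask2: np.ndarray | None
    keep: float
    head_name: str


def forward_batch(
    model: MultiHeadModel,
    V_wt: np.ndarray,
    V_mt: np.ndarray,
    head_name: str,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, ForwardCache]:
    """Predictions for a batch of (wild-type, mutant) vector rows.

    With ``training=True`` inverted dropout is applied after each branch
    rectifier using draws from *rng*; inference applies no scaling.
    """
    if head_name not in model.heads:
        raise KeyError(f"unknown head {head_name!r}")
    c = model.config
    V_wt = np.asarray(V_wt, dtype=PARAM_DTYPE)
    V_mt = np.asarray(V_mt, dtype=PARAM_DTYPE)
    if V_wt.shape != V_mt.shape or V_wt.ndim != 2 or V_wt.shape[1] != c.input_dim:
        raise ValueError(
            f"expected two (n, {c.input_dim}) arrays, got {V_wt.shape} and {V_mt.shape}"
        )
    b1, b2 = model.branch_wt, model.branch_mt
    z1 = V_wt @ b1.W.T + b1.b
    z2 = V_mt @ b2.W.T + b2.b
    h1 = prelu(z1, b1.a)
    h2 = prelu(z2, b2.a)
    keep = 1.0 - c.dropout_rate
    if training and c.dropout_rate > 0.0:
        if rng is None:
            raise ValueError("training-mode forward needs an rng for dropout")
        mask1 = (rng.random(h1.shape) < keep).astype(PARAM_DTYPE)
        mask2 = (rng.random(h2.shape) < keep).astype(PARAM_DTYPE)
        d1 = h1 * mask1 / keep
        d2 = h2 * mask2 / keep
    else:
        mask1 = mask2 = None
        d1, d2 = h1, h2
    head = model.heads[head_name]
    preds = (d1 * d2) @ head.w + head.b
    cache = ForwardCache(V_wt, V_mt, z1, z2, d1, d2, mask1, mask2, keep, head_name)
    return preds.astype(PARAM_DTYPE), cache


def forward(
    model: MultiHeadModel,
    pair: VariantRepresentationPair,
    head_name: str,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> float:
    """Predicted score for one variant pair; pure when training is off."""
    if pair.dim != model.config.input_dim:
        raise ValueError(f"pair dim {pair.dim} != model input dim {model.config.input_dim}")
    preds, _ = forward_batch(
        model,
        pair.wt_vector.values[None, :],
        pair.mt_vector.values[None, :],
        head_name,
        training=training,
        rng=rng,
    )
    return float(preds[0])


@dataclass
class Gradients:
    dW1: np.ndarray
    db1: np.ndarray
    da1: np.ndarray
    dW2: np.ndarray
    db2: np.ndarray
    da2: np.ndarray
    dw_head: np.ndarray
    db_head: np.ndarray
    head_name: str


def backward_mse(
    model: MultiHeadModel, cache: ForwardCache, preds: np.ndarray, targets: np.ndarray
) -> Gradients:
    """Gradients of mean squared error w.r.t. all parameters on the active path."""
    n = preds.shape[0]
    head = model.heads[cache.head_name]
    g = cache.d1 * cache.d2  # merged features (n, hidden)
    dpred = (2.0 / n) * (preds - targets)  # (n,)
    dw_head = g.T @ dpred
    db_head = dpred.sum()
    dg = np.outer(dpred, head.w)  # (n, hidden)
    dd1 = dg * cache.d2
    dd2 = dg * cache.d1
    if cache.mask1 is not None:
        dh1 = dd1 * cache.mask1 / cache.keep
        dh2 = dd2 * cache.mask2 / cache.keep
    else:
        dh1, dh2 = dd1, dd2
    b1, b2 = model.branch_wt, model.branch_mt
    neg1 = cache.z1 < 0
    neg2 = cache.z2 < 0
    dz1 = dh1 * np.where(neg1, b1.a, 1.0)
    dz2 = dh2 * np.where(neg2, b2.a, 1.0)
    da1 = float((dh1 * np.where(neg1, cache.z1, 0.0)).sum())
    da2 = float((dh2 * np.where(neg2, cache.z2, 0.0)).sum())
    return Gradients(
        dW1=dz1.T @ cache.V_wt,
        db1=dz1.sum(axis=0),
        da1=np.asarray(da1, dtype=PARAM_DTYPE),
        dW2=dz2.T @ cache.V_mt,
        db2=dz2.sum(axis=0),
        da2=np.asarray(da2, dtype=PARAM_DTYPE),
        dw_head=dw_head,
        db_head=np.asarray(db_head, dtype=PARAM_DTYPE),
        head_name=cache.head_name,
    )


def save_checkpoint(model: MultiHeadModel, path: str | Path) -> None:
    """Write config plus all parameter arrays (little-endian float32) to a zip archive."""
    path = Path(path)
    config = {
        "format_version": CHECKPOINT_VERSION,
        "config": asdict(model.config),
        "rng_seed": model.rng_seed,
        "heads": list(model.heads.keys()),
    }
    arrays: dict[str, np.ndarray] = {
        "branch_wt.W": model.branch_wt.W,
        "branch_wt.b": model.branch_wt.b,
        "branch_wt.a": model.branch_wt.a,
        "branch_mt.W": model.branch_mt.W,
        "branch_mt.b": model.branch_mt.b,
        "branch_mt.a": model.branch_mt.a,
    }
    for i, (name, head) in enumerate(model.heads.items()):
        arrays[f"head{i}.w"] = head.w
        arrays[f"head{i}.b"] = head.b
    def entry(name: str) -> zipfile.ZipInfo:
        # fixed timestamp so identical models produce byte-identical files
        return zipfile.ZipInfo(name, date_time=(1980, 1, 1, 0, 0, 0))

    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr(entry("config.json"), json.dumps(config, indent=1))
        for key, arr in arrays.items():
            buf = io.BytesIO()
            np.save(buf, np.ascontiguousarray(arr, dtype="<f4"))
            zf.writestr(entry(key + ".npy"), buf.getvalue())


def load_checkpoint(path: str | Path) -> MultiHeadModel:
    """Inverse of :func:`save_checkpoint`; bit-exact parameter round trip."""
    path = Path(path)
    try:
        with zipfile.ZipFile(path) as zf:
            config_meta = json.loads(zf.read("config.json"))
            if config_meta.get("format_version") != CHECKPOINT_VERSION:
                raise ValueError(
                    f"checkpoint version {config_meta.get('format_version')} "
                    f"!= supported {CHECKPOINT_VERSION}"
                )
            config = HeadConfig(**config_meta["config"])

            def arr(name: str) -> np.ndarray:
                return np.load(io.BytesIO(zf.read(name + ".npy")))

            def branch(prefix: str) -> BranchParameters:
                W = arr(f"{prefix}.W")
                if W.shape != (config.hidden_dim, config.input_dim):
                    raise ValueError(
                        f"{prefix}.W shape {W.shape} disagrees with declared config"
                    )
                return BranchParameters(W, arr(f"{prefix}.b"), arr(f"{prefix}.a"))

            heads = {}
            for i, name in enumerate(config_meta["heads"]):
                heads[name] = OutputHead(arr(f"head{i}.w"), arr(f"head{i}.b"), name)
            if not heads:
                raise ValueError("checkpoint has no head section")
            return MultiHeadModel(
                config,
                branch("branch_wt"),
                branch("branch_mt"),
                heads,
                rng_seed=config_meta["rng_seed"],
            )
    except (KeyError, zipfile.BadZipFile) as exc:
        raise ValueError(f"corrupted or incomplete checkpoint {path}: {exc}") from exc
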