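"""Per-position representation vectors behind a pluggable provider contract.

Every provider is a pure function of (configuration, sequence, position) and
yields one fixed-length vector per residue position. Three providers are
offered: a deterministic synthetic provider (no external assets), a
disk-backed cache wrapper, and an optional external backbone adapter that is
only imported on demand.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Protocol, runtime_checkable

import numpy as np

from .dms_data import CANONICAL_AA, DmsDataset, Mutation, apply_mutation

DEFAULT_DIM = 1280
DEFAULT_LAYER = 33
#: weight of the local-context component of the synthetic provider
DEFAULT_CONTEXT_WEIGHT = 0.1
#: residues on each side of the queried position that feed the context term
CONTEXT_RADIUS = 2


@dataclass(frozen=True)
class RepresentationVector:
    """One per-position vector plus provenance metadata."""

    values: np.ndarray
    backbone_id: str
    layer_index: int
    sequence_key: str
    position: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 1:
            raise ValueError("representation must be a 1-D vector")
        if not np.all(np.isfinite(v)):
            raise ValueError("representation contains non-finite values")

    @property
    def dim(self) -> int:
        return int(self.values.shape[0])


@dataclass(frozen=True)
class VariantRepresentationPair:
    """Wild-type and mutant vectors at the mutated position."""

    wt_vector: RepresentationVector
    mt_vector: RepresentationVector

    def __post_init__(self) -> None:
        if self.wt_vector.position != self.mt_vector.position:
            raise ValueError("pair positions disagree")
        if self.wt_vector.dim != self.mt_vector.dim:
            raise ValueError("pair dimensions disagree")

    @property
    def position(self) -> int:
        return self.wt_vector.position

    @property
    def dim(self) -> int:
        return self.wt_vector.dim


@runtime_checkable
class RepresentationProvider(Protocol):
    """Contract every representation backend satisfies."""

    backbone_id: str
    layer_index: int
    dim: int

    def vector(self, sequence: str, position: int) -> np.ndarray:
        """Return the per-position vector; pure in (sequence, position)."""
        ...


def _keyed_rng(*key_parts: int) -> np.random.Generator:
    # SeedSequence hashes the key tuple; keys must be non-negative ints
    return np.random.default_rng(np.random.SeedSequence(list(key_parts)))


class SyntheticProvider:
    """Deterministic stand-in for a frozen language-model backbone.

    The vector at a position is the sum of three seeded components::

        base(seed, position)
        + residue_effect(seed, residue at position)
        + context_weight * context(seed, flanking residues)

    The context window covers ``CONTEXT_RADIUS`` residues on each side of
    the queried position, excluding the position itself, so two sequences
    differing only at the queried position have vectors whose difference is
    exactly the difference of their residue effects.
    """

    def __init__(
        self,
        seed: int,
        dim: int = DEFAULT_DIM,
        context_weight: float = DEFAULT_CONTEXT_WEIGHT,
        base_weight: float = 1.0,
    ) -> None:
        self.seed = int(seed)
        self.dim = int(dim)
        self.context_weight = float(context_weight)
        # scaling the positional component lets tests construct regimes where
        # residue identity dominates the representation
        self.base_weight = float(base_weight)
        self.backbone_id = f"synthetic-{self.seed}-d{self.dim}"
        self.layer_index = 0
        # residue effects are few; precompute for speed
        self._residue_effect = {
            aa: _keyed_rng(self.seed, 1, idx).standard_normal(self.dim)
            for idx, aa in enumerate(CANONICAL_AA)
        }
        self._base_cache: dict[int, np.ndarray] = {}
        self._context_cache: dict[tuple[int, ...], np.ndarray] = {}

    def _base(self, position: int) -> np.ndarray:
        out = self._base_cache.get(position)
        if out is None:
            out = _keyed_rng(self.seed, 0, position).standard_normal(self.dim)
            self._base_cache[position] = out
        return out

    def _context(self, sequence: str, position: int) -> np.ndarray:
        i = position - 1
        lo, hi = max(0, i - CONTEXT_RADIUS), min(len(sequence), i + CONTEXT_RADIUS + 1)
        window = sequence[lo:i] + sequence[i + 1 : hi]
        key = tuple(CANONICAL_AA.index(aa) for aa in window)
        out = self._context_cache.get(key)
        if out is None:
            out = _keyed_rng(self.seed, 2, *key).standard_normal(self.dim)
            self._context_cache[key] = out
        return out

    def vector(self, sequence: str, position: int) -> np.ndarray:
        if not 1 <= position <= len(sequence):
            raise IndexError(f"position {position} outside sequence of length {len(sequence)}")
        aa = sequence[position - 1]
        if aa not in self._residue_effect:
            raise ValueError(f"non-canonical residue {aa!r} at position {position}")
        v = (
            self.base_weight * self._base(position)
            + self._residue_effect[aa]
            + self.context_weight * self._context(sequence, position)
        )
        return v.astype(np.float32)

    def residue_effect(self, aa: str) -> np.ndarray:
        """Expose the planted residue component (used by identifiability tests)."""
        return self._residue_effect[aa].astype(np.float32)


def synthetic_representation(seed: int, sequence: str, position: int, dim: int = DEFAULT_DIM) -> np.ndarray:
    """Functional form of :class:`SyntheticProvider` for one-off queries."""
    return SyntheticProvider(seed, dim=dim).vector(sequence, position)


def get_position_representation(
    provider: RepresentationProvider, sequence: str, position: int
) -> RepresentationVector:
    if not 1 <= position <= len(sequence):
        raise IndexError(f"position {position} outside sequence of length {len(sequence)}")
    values = np.asarray(provider.vector(sequence, position))
    return RepresentationVector(
        values=values,
        backbone_id=provider.backbone_id,
        layer_index=provider.layer_index,
        sequence_key=sequence,
        position=position,
    )


def pair_for_variant(
    provider: RepresentationProvider, dataset: DmsDataset, m: Mutation
) -> VariantRepresentationPair:
    """Wild-type and mutant vectors at the mutated position of one variant."""
    mt_seq = apply_mutation(dataset.wt_sequence, m)
    wt = get_position_representation(provider, dataset.wt_sequence, m.position)
    mt = get_position_representation(provider, mt_seq, m.position)
    return VariantRepresentationPair(wt, mt)


def window_sequence(sequence: str, position: int, max_len: int) -> tuple[str, int]:
    """Clip *sequence* to at most *max_len* residues centered on *position*.

    Sequences already within the limit pass through unchanged. Otherwise a
    window of exactly *max_len* residues centered on the position (shifted at
    the sequence ends) is returned together with the position re-indexed into
    the window. The residue at the re-indexed position is unchanged.
    """
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    n = len(sequence)
    if not 1 <= position <= n:
        raise IndexError(f"position {position} outside sequence of length {n}")
    if n <= max_len:
        return sequence, position
    start = position - max_len // 2  # 1-based window start
    start = max(1, min(start, n - max_len + 1))
    return sequence[start - 1 : start - 1 + max_len], position - start + 1


class EmbeddingStore:
    """Disk cache of per-position vectors, bit-exact across sessions.

    Layout: ``<root>/<backbone_id>/index.json`` plus one little-endian
    float32 binary file per sequence key; the index maps each key to the
    ordered list of positions stored in its file.
    """

    DTYPE = np.dtype("<f4")

    def __init__(self, root: str | Path, backbone_id: str, dim: int = DEFAULT_DIM) -> None:
        self.dir = Path(root) / backbone_id
        self.dir.mkdir(parents=True, exist_ok=True)
        self.dim = int(dim)
        self._index_path = self.dir / "index.json"
        if self._index_path.exists():
            meta = json.loads(self._index_path.read_text())
            if meta["dim"] != self.dim:
                raise ValueError(
                    f"store at {self.dir} has dim {meta['dim']}, expected {self.dim}"
                )
            self._index: dict[str, list[int]] = meta["keys"]
        else:
            self._index = {}
            self._flush()

    def _flush(self) -> None:
        payload = {"dim": self.dim, "dtype": "float32", "byteorder": "little", "keys": self._index}
        self._index_path.write_text(json.dumps(payload, indent=0, sort_keys=True))

    def _file(self, sequence_key: str) -> Path:
        import hashlib

        h = hashlib.sha1(sequence_key.encode()).hexdigest()[:16]
        return self.dir / f"{h}.f32"

    def __contains__(self, key: tuple[str, int]) -> bool:
        sequence_key, position = key
        return position in self._index.get(sequence_key, [])

    def write(self, sequence_key: str, position: int, vector: np.ndarray) -> None:
        vector = np.asarray(vector, dtype=self.DTYPE)
        if vector.shape != (self.dim,):
            raise ValueError(f"expected shape ({self.dim},), got {vector.shape}")
        positions = self._index.setdefault(sequence_key, [])
        if position in positions:
            return
        with open(self._file(sequence_key), "ab") as fh:
            fh.write(vector.tobytes())
        positions.append(position)
        self._flush()

    def read(self, sequence_key: str, position: int) -> np.ndarray:
        positions = self._index.get(sequence_key)
        if positions is None or position not in positions:
            raise KeyError(f"({sequence_key[:20]}..., {position}) not in store")
        row = positions.index(position)
        nbytes = self.dim * self.DTYPE.itemsize
        with open(self._file(sequence_key), "rb") as fh:
            fh.seek(row * nbytes)
            buf = fh.read(nbytes)
        return np.frombuffer(buf, dtype=self.DTYPE).copy()


def store_write(store: EmbeddingStore, key: tuple[str, int], vector: np.ndarray) -> None:
    store.write(key[0], key[1], vector)


def store_read(store: EmbeddingStore, key: tuple[str, int]) -> np.ndarray:
    return store.read(key[0], key[1])


class CachedProvider:
    """Wrap a provider with an :class:`EmbeddingStore`; cache hits skip compute."""

    def __init__(self, inner: RepresentationProvider, store: EmbeddingStore) -> None:
        if store.dim != inner.dim:
            raise ValueError("store and provider dimensions disagree")
        self.inner = inner
        self.store = store
        self.backbone_id = inner.backbone_id
        self.layer_index = inner.layer_index
        self.dim = inner.dim
        self.n_hits = 0
        self.n_misses = 0

    def vector(self, sequence: str, position: int) -> np.ndarray:
        try:
            v = self.store.read(sequence, position)
            self.n_hits += 1
            return v
        except KeyError:
            v = np.asarray(self.inner.vector(sequence, position), dtype=np.float32)
            self.store.write(sequence, position, v)
            self.n_misses += 1
            return v


class ExternalBackboneProvider:
    """Adapter for a real frozen transformer backbone (optional plugin).

    Requires the optional ``torch`` and ``esm`` packages; importing them is
    deferred so the core package works without the heavy dependencies.
    Sequences longer than ``max_len`` are windowed around the queried
    position before embedding.
    """

    def __init__(
        self,
        model_name: str = "esm1v_t33_650M_UR90S_1",
        layer_index: int = DEFAULT_LAYER,
        max_len: int = 1022,
    ) -> None:
        try:
            import esm  # type: ignore[import-not-found]
            import torch  # type: ignore[import-not-found]
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise RuntimeError(
                "external backbone requires the optional 'torch' and 'fair-esm' "
                "packages; install them or use --provider synthetic"
            ) from exc
        self._torch = torch
        model, alphabet = esm.pretrained.load_model_and_alphabet(model_name)
        self._model = model.eval()
        self._batch_converter = alphabet.get_batch_converter()
        self.backbone_id = model_name
        self.layer_index = int(layer_index)
        self.dim = int(model.embed_dim)
        self.max_len = int(max_len)

    def vector(self, sequence: str, position: int) -> np.ndarray:  # pragma: no cover
        sequence, position = window_sequence(sequence, position, self.max_len)
        _, _, tokens = self._batch_converter([("q", sequence)])
        with self._torch.no_grad():
            out = self._model(tokens, repr_layers=[self.layer_index])
        reps = out["representations"][self.layer_index][0]
        # token 0 is the begin-of-sequence marker, so residue i is row i
        return reps[position].cpu().numpy().astype(np.float32)
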