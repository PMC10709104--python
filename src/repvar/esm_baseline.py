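"""Masked-marginal log-ratio baseline score for variants.

The score of a variant is the sum, over its mutated positions, of
``log p(mutant residue) - log p(wild-type residue)`` under per-position
amino-acid probability vectors computed with the mutated position masked.
Natural logarithm throughout; rankings (hence rank correlations) are
base-invariant. Probability vectors come from any backend implementing
:class:`ProbabilitySource`, including an offline CSV dump.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Protocol, runtime_checkable

import numpy as np
import pandas as pd

from .dms_data import CANONICAL_AA, DmsDataset, Mutation

EPSILON_FLOOR = 1e-9
_PROB_TOL = 1e-6


@dataclass(frozen=True)
class PositionProbabilityVector:
    """Amino-acid probability distribution at one sequence position."""

    position: int
    probs: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = set(CANONICAL_AA) - set(self.probs)
        if missing:
            raise ValueError(f"alphabet incomplete at position {self.position}: missing {sorted(missing)}")
        vals = [self.probs[aa] for aa in CANONICAL_AA]
        if any(v < 0 for v in vals):
            raise ValueError(f"negative probability at position {self.position}")
        if abs(sum(vals) - 1.0) > _PROB_TOL:
            raise ValueError(f"probabilities at position {self.position} sum to {sum(vals)}")

    def __getitem__(self, aa: str) -> float:
        return float(self.probs[aa])


@dataclass(frozen=True)
class VariantSet:
    """The mutated positions of one variant with their (wt, mt) letters."""

    substitutions: tuple[Mutation, ...]

    def __post_init__(self) -> None:
        positions = [m.position for m in self.substitutions]
        if len(set(positions)) != len(positions):
            raise ValueError("duplicate positions in variant")

    @classmethod
    def single(cls, m: Mutation) -> "VariantSet":
        return cls((m,))

    def swapped(self) -> "VariantSet":
        return VariantSet(
            tuple(Mutation(m.mt_aa, m.position, m.wt_aa) for m in self.substitutions)
        )


def log_ratio_score(
    probabilities: Mapping[int, PositionProbabilityVector],
    variant: VariantSet,
    *,
    epsilon_floor: bool = False,
    allow_identity: bool = False,
) -> float:
    """Sum over mutated positions of log p(mt) - log p(wt).

    Zero probabilities are a strict error unless ``epsilon_floor`` replaces
    them with 1e-9.
    """
    total = 0.0
    for m in variant.substitutions:
        if m.is_identity and not allow_identity:
            raise ValueError(f"identity substitution {m.format()} (set allow_identity)")
        if m.position not in probabilities:
            raise KeyError(f"no probability vector for position {m.position}")
        vec = probabilities[m.position]
        p_mt, p_wt = vec[m.mt_aa], vec[m.wt_aa]
        if epsilon_floor:
            p_mt, p_wt = max(p_mt, EPSILON_FLOOR), max(p_wt, EPSILON_FLOOR)
        elif p_mt == 0.0 or p_wt == 0.0:
            raise ValueError(f"zero probability at position {m.position} in strict mode")
        total += math.log(p_mt) - math.log(p_wt)
    return total


@runtime_checkable
class ProbabilitySource(Protocol):
    """Backend yielding the masked-position probability vector.

    Implementations guarantee single-position masked semantics: the result
    must not depend on the residue present at the queried position.
    """

    def probabilities(self, sequence: str, position: int) -> PositionProbabilityVector:
        ...


class UniformProbabilitySource:
    """All 20 residues equally likely everywhere; every variant scores zero."""

    def probabilities(self, sequence: str, position: int) -> PositionProbabilityVector:
        p = 1.0 / len(CANONICAL_AA)
        return PositionProbabilityVector(position, {aa: p for aa in CANONICAL_AA})


class SoftmaxProbabilitySource:
    """Seeded synthetic backend: softmax of planted per-(position, residue) energies."""

    def __init__(self, seed: int, temperature: float = 1.0) -> None:
        self.seed = int(seed)
        self.temperature = float(temperature)

    def energies(self, position: int) -> np.ndarray:
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, position]))
        return rng.standard_normal(len(CANONICAL_AA))

    def probabilities(self, sequence: str, position: int) -> PositionProbabilityVector:
        e = self.energies(position) / self.temperature
        w = np.exp(e - e.max())
        p = w / w.sum()
        return PositionProbabilityVector(position, dict(zip(CANONICAL_AA, p.tolist())))


class DumpProbabilitySource:
    """Offline backend reading a per-sequence probability dump CSV."""

    def __init__(self, path: str | Path) -> None:
        self._table = read_probability_dump(path)

    def probabilities(self, sequence: str, position: int) -> PositionProbabilityVector:
        if position not in self._table:
            raise KeyError(f"dump has no row for position {position}")
        return self._table[position]


def score_dataset(
    probability_source: ProbabilitySource,
    dataset: DmsDataset,
    *,
    epsilon_floor: bool = False,
) -> np.ndarray:
    """One log-ratio score per record of *dataset*, in record order."""
    cache: dict[int, PositionProbabilityVector] = {}
    out = np.empty(len(dataset.records), dtype=np.float64)
    for i, rec in enumerate(dataset.records):
        pos = rec.mutation.position
        if pos not in cache:
            cache[pos] = probability_source.probabilities(dataset.wt_sequence, pos)
        out[i] = log_ratio_score(
            cache, VariantSet.single(rec.mutation), epsilon_floor=epsilon_floor,
            allow_identity=True,
        )
    return out


def write_probability_dump(
    path: str | Path, vectors: Mapping[int, PositionProbabilityVector]
) -> None:
    """CSV with columns (position, A..Y), one row per position."""
    rows = [
        {"position": pos, **{aa: vec[aa] for aa in CANONICAL_AA}}
        for pos, vec in sorted(vectors.items())
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_probability_dump(path: str | Path) -> dict[int, PositionProbabilityVector]:
    df = pd.read_csv(path)
    required = {"position", *CANONICAL_AA}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    out = {}
    for row in df.itertuples():
        pos = int(row.position)
        out[pos] = PositionProbabilityVector(
            pos, {aa: float(getattr(row, aa)) for aa in CANONICAL_AA}
        )
    return out
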