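"""Parsing, validation and containers for single amino acid variant datasets.

A variant table pairs a mutation code (e.g. ``"A24G"``: wild-type residue,
1-based position, mutant residue) with one real-valued functional measurement.
Tables are grouped per protein into a :class:`DmsDataset` carrying the
wild-type sequence they index into.
"""

from __future__ import annotations

import re
import statistics
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(CANONICAL_AA)

_MUTATION_RE = re.compile(r"^([A-Za-z])(\d+)([A-Za-z])$")


class MutationError(ValueError):
    """Malformed or inconsistent mutation code."""


@dataclass(frozen=True, order=True)
class Mutation:
    """A single amino acid substitution: wild-type residue, 1-based position, mutant residue."""

    wt_aa: str
    position: int
    mt_aa: str

    def __post_init__(self) -> None:
        if self.wt_aa not in _AA_SET:
            raise MutationError(f"non-canonical wild-type residue {self.wt_aa!r}")
        if self.mt_aa not in _AA_SET:
            raise MutationError(f"non-canonical mutant residue {self.mt_aa!r}")
        if self.position < 1:
            raise MutationError(f"position must be >= 1, got {self.position}")

    def format(self) -> str:
        return f"{self.wt_aa}{self.position}{self.mt_aa}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.format()

    @property
    def is_identity(self) -> bool:
        return self.wt_aa == self.mt_aa


def parse_mutation(code: str) -> Mutation:
    """Decode a ``<wt><position><mt>`` mutation code, case-insensitively.

    >>> parse_mutation("A24G")
    Mutation(wt_aa='A', position=24, mt_aa='G')
    """
    m = _MUTATION_RE.match(code.strip())
    if m is None:
        raise MutationError(f"malformed mutation code {code!r}")
    wt, pos, mt = m.group(1).upper(), int(m.group(2)), m.group(3).upper()
    if pos == 0:
        raise MutationError(f"position 0 in mutation code {code!r}")
    return Mutation(wt, pos, mt)


def format_mutation(m: Mutation) -> str:
    return m.format()


def apply_mutation(wt_sequence: str, m: Mutation) -> str:
    """Return *wt_sequence* with the substitution applied at ``m.position``.

    Raises :class:`MutationError` if the position is out of range or the
    sequence does not carry ``m.wt_aa`` there (corrupted table or off-by-one
    numbering convention).
    """
    if not 1 <= m.position <= len(wt_sequence):
        raise MutationError(
            f"position {m.position} outside sequence of length {len(wt_sequence)}"
        )
    found = wt_sequence[m.position - 1]
    if found != m.wt_aa:
        raise MutationError(
            f"wild-type mismatch at position {m.position}: "
            f"sequence has {found!r}, mutation says {m.wt_aa!r}"
        )
    return wt_sequence[: m.position - 1] + m.mt_aa + wt_sequence[m.position :]


@dataclass(frozen=True)
class DmsRecord:
    """One variant with its measured functional score (assay-specific units)."""

    mutation: Mutation
    score: float

    def __post_init__(self) -> None:
        s = float(self.score)
        if s != s or s in (float("inf"), float("-inf")):
            raise ValueError(f"non-finite score for {self.mutation.format()}")


@dataclass
class DmsDataset:
    """A named collection of variant records over one wild-type sequence."""

    name: str
    wt_sequence: str
    records: list[DmsRecord] = field(default_factory=list)
    measurement_label: str = "score"

    def __post_init__(self) -> None:
        self.wt_sequence = self.wt_sequence.upper()
        self.validate()

    def __len__(self) -> int:
        return len(self.records)

    @property
    def scores(self) -> list[float]:
        return [r.score for r in self.records]

    @property
    def mutations(self) -> list[Mutation]:
        return [r.mutation for r in self.records]

    def validate(self, allow_identity: bool = True) -> None:
        """Check records against the wild-type sequence; raise on violation."""
        seen: set[tuple[int, str]] = set()
        for rec in self.records:
            m = rec.mutation
            if m.position > len(self.wt_sequence):
                raise MutationError(
                    f"{self.name}: {m.format()} beyond sequence length "
                    f"{len(self.wt_sequence)}"
                )
            if self.wt_sequence[m.position - 1] != m.wt_aa:
                raise MutationError(
                    f"{self.name}: {m.format()} disagrees with wild-type residue "
                    f"{self.wt_sequence[m.position - 1]!r}"
                )
            if not allow_identity and m.is_identity:
                raise MutationError(f"{self.name}: identity substitution {m.format()}")
            key = (m.position, m.mt_aa)
            if key in seen:
                raise MutationError(f"{self.name}: duplicate variant {m.format()}")
            seen.add(key)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into ``{record id: upper-cased sequence}``.

    Ids are the first whitespace-delimited token of each header. Duplicate
    ids and empty files are errors.
    """
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        out[rec.id] = str(rec.seq).upper()
    if not out:
        raise ValueError(f"no FASTA records in {path}")
    return out


def read_dms_table(
    path: str | Path,
    wt_sequence: str,
    *,
    name: str | None = None,
    mutation_column: str = "mutant",
    score_column: str = "score",
    delimiter: str | None = None,
    measurement_label: str = "score",
    strict: bool = True,
    allow_identity: bool = False,
) -> DmsDataset:
    """Load a delimited variant table into a validated :class:`DmsDataset`.

    ``delimiter=None`` sniffs between comma and tab. Rows with non-finite
    scores are dropped (a count is warned); malformed mutation codes are a
    row-level error naming the line in strict mode and are skipped with a
    warning otherwise. Duplicate (position, mutant) rows follow the same
    strictness rule with first-wins semantics when permissive.
    """
    path = Path(path)
    if delimiter is None:
        with open(path, "r", encoding="utf-8") as fh:
            for line in fh:
                if line.strip() and not line.startswith("#"):
                    delimiter = "\t" if "\t" in line else ","
                    break
            else:
                raise ValueError(f"empty table {path}")
    df = pd.read_csv(path, sep=delimiter, comment="#", encoding="utf-8")
    for col in (mutation_column, score_column):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r} (have {list(df.columns)})")
    if df.empty:
        raise ValueError(f"{path}: empty dataset")

    records: list[DmsRecord] = []
    seen: set[tuple[int, str]] = set()
    n_nonfinite = 0
    for row_idx, (code, score) in enumerate(
        zip(df[mutation_column], df[score_column]), start=2
    ):
        score = float(score)
        if score != score or score in (float("inf"), float("-inf")):
            n_nonfinite += 1
            continue
        try:
            m = parse_mutation(str(code))
            if m.is_identity and not allow_identity:
                raise MutationError(f"identity substitution {m.format()}")
        except MutationError as exc:
            if strict:
                raise MutationError(f"{path} line {row_idx}: {exc}") from exc
            warnings.warn(f"{path} line {row_idx}: skipping ({exc})", stacklevel=2)
            continue
        key = (m.position, m.mt_aa)
        if key in seen:
            if strict:
                raise MutationError(f"{path} line {row_idx}: duplicate {m.format()}")
            warnings.warn(f"{path} line {row_idx}: duplicate {m.format()}, keeping first", stacklevel=2)
            continue
        seen.add(key)
        records.append(DmsRecord(m, score))
    if n_nonfinite:
        warnings.warn(f"{path}: dropped {n_nonfinite} rows with non-finite scores", stacklevel=2)
    if not records:
        raise ValueError(f"{path}: empty dataset after filtering")
    return DmsDataset(
        name=name or path.stem,
        wt_sequence=wt_sequence,
        records=records,
        measurement_label=measurement_label,
    )


@dataclass(frozen=True)
class ManifestRow:
    dataset_name: str
    short_name: str
    n_variants: int
    seq_length: int


@dataclass
class DatasetManifest:
    """Study-level listing: one row per dataset with its variant count and sequence length."""

    rows: list[ManifestRow]

    def __post_init__(self) -> None:
        shorts = [r.short_name for r in self.rows]
        if len(set(shorts)) != len(shorts):
            raise ValueError("short names in manifest are not unique")
        for r in self.rows:
            if r.n_variants < 1 or r.seq_length < 1:
                raise ValueError(f"manifest row {r.short_name}: non-positive count")

    def __len__(self) -> int:
        return len(self.rows)


def load_manifest(path: str | Path | None = None) -> DatasetManifest:
    """Load a manifest CSV; defaults to the packaged study fixture."""
    if path is None:
        source = resources.files("repvar").joinpath("data/dataset_manifest.csv")
        with resources.as_file(source) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    rows = [
        ManifestRow(str(r.dataset_name), str(r.short_name), int(r.n_variants), int(r.seq_length))
        for r in df.itertuples()
    ]
    return DatasetManifest(rows)


def manifest_summary(manifest: DatasetManifest) -> dict[str, float]:
    """Counts over the manifest: total/min/max/median variant counts and row count.

    Median uses the average of the two central order statistics for even row
    counts and is reported unrounded.
    """
    if not manifest.rows:
        raise ValueError("empty manifest")
    counts = [r.n_variants for r in manifest.rows]
    return {
        "n_datasets": len(counts),
        "total_variants": sum(counts),
        "min_variants": min(counts),
        "max_variants": max(counts),
        "median_variants": float(statistics.median(counts)),
    }
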