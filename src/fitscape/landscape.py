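"""Genotype -> fitness tables: reading, validation, transforms, splits.

A landscape table holds one row per DNA genotype of length ``3 * codon_count``
with a scalar fitness (log growth rate relative to wild type; wild type = 0).
Genotypes with raw fitness below the viability threshold (default -0.5) are
flagged inviable; viability is always decided on the raw, pre-offset scale.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

DNA_ALPHABET = frozenset("ACGT")
DEFAULT_VIABILITY_THRESHOLD = -0.5


class LandscapeError(Exception):
    """Base class for landscape-table errors."""


class MalformedSequenceError(LandscapeError):
    """A sequence contains non-ACGT characters or has an invalid length."""


class DuplicateSequenceError(LandscapeError):
    """The same DNA sequence appears more than once."""


class EmptyTableError(LandscapeError):
    """The input contains no records."""


class OffsetError(LandscapeError):
    """Invalid fitness-offset operation (e.g. applied twice)."""


@dataclass(frozen=True)
class FitnessRecord:
    """One DNA genotype with its measured fitness and viability flag."""

    sequence: str
    fitness: float
    viable: bool


@dataclass
class LandscapeTable:
    """Ordered collection of genotype->fitness records.

    Parameters
    ----------
    sequences, fitness
        Parallel arrays; order is preserved from the source.
    codon_count
        Number of codons C; all sequences have length 3*C.
    offset_applied
        Offset already added to the fitness column (0 if raw).
    viability_threshold
        Raw-scale threshold; fitness strictly below it is inviable.
    """

    sequences: np.ndarray
    fitness: np.ndarray
    viable: np.ndarray
    codon_count: int
    offset_applied: float = 0.0
    viability_threshold: float = DEFAULT_VIABILITY_THRESHOLD

    def __post_init__(self) -> None:
        self.sequences = np.asarray(self.sequences, dtype=object)
        self.fitness = np.asarray(self.fitness, dtype=float)
        self.viable = np.asarray(self.viable, dtype=bool)
        if not (len(self.sequences) == len(self.fitness) == len(self.viable)):
            raise LandscapeError("column lengths differ")

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self) -> Iterator[FitnessRecord]:
        for s, f, v in zip(self.sequences, self.fitness, self.viable):
            yield FitnessRecord(str(s), float(f), bool(v))

    @property
    def records(self) -> list[FitnessRecord]:
        return list(self)

    @property
    def sequence_length(self) -> int:
        return 3 * self.codon_count

    def subset(self, indices: Sequence[int] | np.ndarray) -> "LandscapeTable":
        idx = np.asarray(indices, dtype=int)
        return replace(
            self,
            sequences=self.sequences[idx],
            fitness=self.fitness[idx],
            viable=self.viable[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sequence": self.sequences.astype(str),
                "fitness": self.fitness,
                "viable": self.viable.astype(int),
            }
        )

    def fitness_of(self, sequence: str) -> float:
        hit = np.flatnonzero(self.sequences == sequence)
        if hit.size == 0:
            raise KeyError(sequence)
        return float(self.fitness[hit[0]])


def _flag_viable(fitness: np.ndarray, threshold: float) -> np.ndarray:
    # "below threshold" is read strictly: fitness == threshold is viable.
    return ~(np.asarray(fitness, dtype=float) < threshold)


def table_from_arrays(
    sequences: Sequence[str],
    fitness: Sequence[float],
    viability_threshold: float = DEFAULT_VIABILITY_THRESHOLD,
    offset_applied: float = 0.0,
    validate: bool = True,
) -> LandscapeTable:
    """Build a LandscapeTable from parallel sequence/fitness arrays."""
    seqs = np.asarray(list(sequences), dtype=object)
    fit = np.asarray(list(fitness), dtype=float)
    if len(seqs) == 0:
        raise EmptyTableError("no records")
    length = len(str(seqs[0]))
    if validate:
        for i, s in enumerate(seqs):
            s = str(s)
            if len(s) != length:
                raise MalformedSequenceError(
                    f"row {i}: length {len(s)} != {length}"
                )
            if not set(s) <= DNA_ALPHABET:
                bad = sorted(set(s) - DNA_ALPHABET)
                raise MalformedSequenceError(
                    f"row {i}: non-ACGT character(s) {bad} in {s!r}"
                )
        if length == 0 or length % 3 != 0:
            raise MalformedSequenceError(
                f"sequence length {length} is not a positive multiple of 3"
            )
        uniq, counts = np.unique(seqs.astype(str), return_counts=True)
        if (counts > 1).any():
            dup = uniq[counts > 1][0]
            raise DuplicateSequenceError(f"duplicate sequence {dup!r}")
    return LandscapeTable(
        sequences=seqs,
        fitness=fit,
        viable=_flag_viable(fit, viability_threshold),
        codon_count=length // 3,
        offset_applied=offset_applied,
        viability_threshold=viability_threshold,
    )


def _dialect(path: str | Path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def read_landscape_table(
    path: str | Path,
    sequence_column: str = "sequence",
    fitness_column: str = "fitness",
    viability_threshold: float = DEFAULT_VIABILITY_THRESHOLD,
) -> LandscapeTable:
    """Read a genotype->fitness CSV/TSV (delimiter inferred from extension).

    The file must have a header naming the sequence and fitness columns.
    Rows are kept in file order; viability flags are set from the threshold,
    offset_applied is 0.
    """
    df = pd.read_csv(
        path,
        sep=_dialect(path),
        dtype={sequence_column: str},
        float_precision="round_trip",
    )
    if df.empty:
        raise EmptyTableError(f"{path}: empty table")
    for col in (sequence_column, fitness_column):
        if col not in df.columns:
            raise LandscapeError(f"{path}: missing column {col!r}")
    fitness = pd.to_numeric(df[fitness_column], errors="coerce")
    if fitness.isna().any():
        row = int(fitness.isna().idxmax())
        raise LandscapeError(
            f"{path}: unparsable fitness {df[fitness_column][row]!r} at row {row}"
        )
    return table_from_arrays(
        df[sequence_column].tolist(),
        fitness.to_numpy(),
        viability_threshold=viability_threshold,
    )


def write_landscape_table(table: LandscapeTable, path: str | Path) -> None:
    """Write sequence,fitness,viable with full float precision (round-trip safe)."""
    frame = table.to_frame()
    # repr() emits the shortest string that parses back to the same double,
    # which pandas' default float formatting does not guarantee
    frame["fitness"] = [repr(float(f)) for f in table.fitness]
    frame.to_csv(path, sep=_dialect(path), index=False)


def write_fasta(table: LandscapeTable, path: str | Path) -> None:
    """Export as FASTA; record id = sequence, description = fitness."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(str(s)), id=str(s), description=repr(float(f)))
        for s, f in zip(table.sequences, table.fitness)
    ]
    seqio_write(records, str(path), "fasta")


def apply_offset(table: LandscapeTable, offset: float) -> LandscapeTable:
    """Add a constant offset to every fitness value (training-time transform).

    Viability flags are untouched: they were decided on the raw scale. A
    second application raises OffsetError.
    """
    if table.offset_applied != 0.0:
        raise OffsetError(
            f"offset {table.offset_applied} already applied; refusing a second"
        )
    return replace(
        table, fitness=table.fitness + offset, offset_applied=float(offset)
    )


def filter_viable(table: LandscapeTable) -> LandscapeTable:
    """Keep only viable records (idempotent)."""
    return table.subset(np.flatnonzero(table.viable))


def split_train_test(
    table: LandscapeTable, test_fraction: float, seed: int
) -> tuple[LandscapeTable, LandscapeTable]:
    """Seeded uniform split into (pool, test); test gets round(fraction * n) rows.

    Rounding is half-up so that e.g. 17774 * 0.5 gives exactly 8887.
    """
    if not 0.0 <= test_fraction <= 1.0:
        raise ValueError(f"test_fraction {test_fraction} outside [0, 1]")
    if len(table) == 0:
        raise EmptyTableError("cannot split an empty table")
    n = len(table)
    n_test = int(math.floor(test_fraction * n + 0.5))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    test_idx = np.sort(perm[:n_test])
    pool_idx = np.sort(perm[n_test:])
    return table.subset(pool_idx), table.subset(test_idx)


@dataclass
class RunManifest:
    """Provenance for a run: offset, threshold and the seeds used."""

    offset: float
    viability_threshold: float
    seeds: dict = field(default_factory=dict)
    extra: dict = field(default_factory=dict)

    def write(self, path: str | Path) -> None:
        payload = {
            "offset": self.offset,
            "viability_threshold": self.viability_threshold,
            "seeds": self.seeds,
            **self.extra,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def sequence_space_size(length_nt: int) -> float:
    """Number of DNA genotypes of the given length (4**L, as a float)."""
    return float(4) ** length_nt
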