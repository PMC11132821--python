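"""Sequence representations: translation, one-hot, codon tokens, CAI,
physicochemical protein embeddings.

Conventions fixed for reproducibility: nucleotide channel order is A,C,G,T;
codon tokens are the lexicographic index of the codon with A<C<G<T
(AAA -> 0, ..., TTT -> 63).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

NT_ORDER = "ACGT"
NT_INDEX = {c: i for i, c in enumerate(NT_ORDER)}
STOP = "*"

ALL_CODONS = tuple(a + b + c for a in NT_ORDER for b in NT_ORDER for c in NT_ORDER)


class EncodingError(ValueError):
    """Invalid sequence or table for an encoding operation."""


@dataclass(frozen=True)
class GeneticCode:
    """Total mapping from the 64 codons to amino-acid letters ('*' = stop)."""

    codon_to_aa: dict

    def __post_init__(self) -> None:
        if set(self.codon_to_aa) != set(ALL_CODONS):
            raise EncodingError("genetic code must cover all 64 codons")

    @classmethod
    def standard(cls) -> "GeneticCode":
        mapping = dict(standard_dna_table.forward_table)
        for stop in standard_dna_table.stop_codons:
            mapping[stop] = STOP
        return cls(codon_to_aa=mapping)

    def __getitem__(self, codon: str) -> str:
        return self.codon_to_aa[codon]


STANDARD_CODE = GeneticCode.standard()


def _check_dna(sequence: str, multiple_of_3: bool = False) -> str:
    bad = set(sequence) - set(NT_ORDER)
    if bad:
        raise EncodingError(f"non-ACGT character(s) {sorted(bad)} in {sequence!r}")
    if multiple_of_3 and (len(sequence) == 0 or len(sequence) % 3 != 0):
        raise EncodingError(
            f"length {len(sequence)} is not a positive multiple of 3"
        )
    return sequence


def codons_of(sequence: str) -> list[str]:
    _check_dna(sequence, multiple_of_3=True)
    return [sequence[i : i + 3] for i in range(0, len(sequence), 3)]


def translate(sequence: str, code: GeneticCode = STANDARD_CODE) -> str:
    """Translate DNA to amino acids; stop codons become '*'."""
    return "".join(code[c] for c in codons_of(sequence))


def onehot_encode(sequence: str, flatten: bool = True) -> np.ndarray:
    """One-hot encode over channels A,C,G,T; (L, 4) or flattened length 4L."""
    _check_dna(sequence)
    idx = np.fromiter((NT_INDEX[c] for c in sequence), dtype=np.int64)
    mat = np.zeros((len(sequence), 4))
    mat[np.arange(len(sequence)), idx] = 1.0
    return mat.reshape(-1) if flatten else mat


def nt_tokenize(sequence: str) -> np.ndarray:
    """Integer tokens in [0, 3], channel order A,C,G,T."""
    _check_dna(sequence)
    return np.fromiter((NT_INDEX[c] for c in sequence), dtype=np.int64)


def codon_tokenize(sequence: str) -> np.ndarray:
    """Integer codon tokens in [0, 63]: lexicographic index with A<C<G<T."""
    toks = nt_tokenize(_check_dna(sequence, multiple_of_3=True))
    return toks.reshape(-1, 3) @ np.array([16, 4, 1])


@dataclass(frozen=True)
class CodonUsageTable:
    """Per-codon relative adaptiveness w(c) in (0, 1].

    Weights are frequency(c) / max synonymous frequency within each family
    of codons encoding the same amino acid (stops are their own family), so
    every family has at least one codon with w = 1.
    """

    weights: dict

    @classmethod
    def from_frequencies(
        cls,
        frequencies: dict,
        code: GeneticCode = STANDARD_CODE,
        floor: float = 0.01,
    ) -> "CodonUsageTable":
        """Build w(c) from raw codon frequencies (any common scale).

        Zero (or missing) frequencies are floored at `floor` before the
        per-family normalization so every weight stays positive.
        """
        freqs = {c: max(float(frequencies.get(c, 0.0)), floor) for c in ALL_CODONS}
        families: dict[str, list[str]] = {}
        for c in ALL_CODONS:
            families.setdefault(code[c], []).append(c)
        weights = {}
        for fam in families.values():
            peak = max(freqs[c] for c in fam)
            for c in fam:
                weights[c] = freqs[c] / peak
        return cls(weights=weights)

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "CodonUsageTable":
        """Read a `codon,frequency` CSV and normalize per family."""
        df = pd.read_csv(path)
        freqs = dict(zip(df["codon"].str.upper().str.replace("U", "T"), df["frequency"]))
        return cls.from_frequencies(freqs, **kwargs)

    @classmethod
    def ecoli(cls) -> "CodonUsageTable":
        """Bundled reference E. coli K-12 usage (frequencies per thousand)."""
        ref = importlib.resources.files("fitscape.data") / "ecoli_codon_usage.csv"
        with importlib.resources.as_file(ref) as path:
            return cls.from_csv(path)

    def __getitem__(self, codon: str) -> float:
        return self.weights[codon]


def cai(
    sequence: str, usage: CodonUsageTable, allow_stop: bool = False
) -> float:
    """Codon adaptation index: geometric mean of relative adaptiveness.

    Stop codons raise unless `allow_stop`; a zero weight (which the floored
    usage-table constructors prevent) raises rather than yielding CAI = 0.
    """
    cods = codons_of(sequence)
    if not allow_stop:
        for c in cods:
            if STANDARD_CODE[c] == STOP:
                raise EncodingError(f"stop codon {c} in {sequence!r}")
    w = np.array([usage[c] for c in cods], dtype=float)
    if (w <= 0).any():
        raise EncodingError("zero relative-adaptiveness weight; floor the table")
    return float(np.exp(np.mean(np.log(w))))


# --- physicochemical amino-acid descriptors -------------------------------

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"

_AA_VOLUME = {  # van der Waals residue volumes, A^3 (Zamyatnin)
    "A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1, "C": 108.5,
    "Q": 143.8, "E": 138.4, "G": 60.1, "H": 153.2, "I": 166.7,
    "L": 166.7, "K": 168.6, "M": 162.9, "F": 189.9, "P": 112.7,
    "S": 89.0, "T": 116.1, "W": 227.8, "Y": 193.6, "V": 140.0,
}
_AA_CHARGE = {aa: 0.0 for aa in AA_ORDER} | {
    "D": -1.0, "E": -1.0, "K": 1.0, "R": 1.0, "H": 0.1,
}
_AA_PI = {
    "A": 6.00, "R": 10.76, "N": 5.41, "D": 2.77, "C": 5.07,
    "Q": 5.65, "E": 3.22, "G": 5.97, "H": 7.59, "I": 6.02,
    "L": 5.98, "K": 9.74, "M": 5.74, "F": 5.48, "P": 6.30,
    "S": 5.68, "T": 5.60, "W": 5.89, "Y": 5.66, "V": 5.96,
}
_AA_AROMATIC = {aa: float(aa in "FWYH") for aa in AA_ORDER}
_AA_POLAR = {aa: float(aa in "STNQCYHKRDE") for aa in AA_ORDER}


@dataclass(frozen=True)
class AminoAcidDescriptorSet:
    """20 x D numeric descriptor table for the proteinogenic amino acids.

    The default set stacks ten standard property scales (hydropathy,
    hydrophilicity, flexibility, surface accessibility, residue mass,
    volume, charge, pI, aromaticity, polarity), z-scored across the 20
    amino acids so no single scale dominates Euclidean distances. A
    different published set can be loaded from CSV (`aa,d1..dD`).
    """

    table: pd.DataFrame  # index: amino-acid letters; columns: descriptors

    def __post_init__(self) -> None:
        missing = set(AA_ORDER) - set(self.table.index)
        if missing:
            raise EncodingError(f"descriptor set missing amino acids {sorted(missing)}")

    @property
    def dimension(self) -> int:
        return self.table.shape[1]

    @classmethod
    def default(cls) -> "AminoAcidDescriptorSet":
        from Bio.Data.IUPACData import protein_weights
        from Bio.SeqUtils.ProtParamData import Flex, em, hw, kd

        scales = {
            "hydropathy_kd": kd,
            "hydrophilicity_hw": hw,
            "flexibility": Flex,
            "surface_accessibility": em,
            "residue_mass": protein_weights,
            "volume": _AA_VOLUME,
            "charge": _AA_CHARGE,
            "isoelectric_point": _AA_PI,
            "aromatic": _AA_AROMATIC,
            "polar": _AA_POLAR,
        }
        df = pd.DataFrame(
            {name: [scale[aa] for aa in AA_ORDER] for name, scale in scales.items()},
            index=list(AA_ORDER),
        )
        z = (df - df.mean()) / df.std(ddof=0)
        return cls(table=z)

    @classmethod
    def from_csv(cls, path: str | Path, standardize: bool = True) -> "AminoAcidDescriptorSet":
        df = pd.read_csv(path, index_col=0)
        if standardize:
            df = (df - df.mean()) / df.std(ddof=0)
        return cls(table=df)

    def vector(self, aa: str) -> np.ndarray:
        return self.table.loc[aa].to_numpy(dtype=float)


def protein_embed(
    protein: str, descriptors: AminoAcidDescriptorSet
) -> np.ndarray:
    """Concatenate per-residue descriptor vectors (dimension len(protein) * D)."""
    if STOP in protein:
        raise EncodingError(f"stop symbol in protein {protein!r}")
    try:
        rows = [descriptors.vector(aa) for aa in protein]
    except KeyError as exc:  # non-canonical residue
        raise EncodingError(f"unknown amino acid {exc} in {protein!r}") from exc
    return np.concatenate(rows) if rows else np.zeros(0)


# --- batch encoders used by the model zoo ---------------------------------

def encode_batch(sequences, kind: str) -> np.ndarray:
    """Encode a list of equal-length DNA sequences for a model input kind.

    kinds: onehot_flat (n, 4L); onehot_seq (n, L, 4); nt_tokens (n, L);
    codon_tokens (n, L/3).
    """
    seqs = list(sequences)
    if kind == "onehot_flat":
        return np.stack([onehot_encode(s, flatten=True) for s in seqs])
    if kind == "onehot_seq":
        return np.stack([onehot_encode(s, flatten=False) for s in seqs])
    if kind == "nt_tokens":
        return np.stack([nt_tokenize(s) for s in seqs])
    if kind == "codon_tokens":
        return np.stack([codon_tokenize(s) for s in seqs])
    raise EncodingError(f"unknown encoding kind {kind!r}")
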