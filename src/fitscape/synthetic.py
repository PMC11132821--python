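"""Combinatorially complete synthetic codon-level fitness landscapes.

The generator enumerates all 4**(3C) DNA sequences of C codons and assigns

    fitness(g) = sum_i a(i, AA_i) + sum_{i<j} e(i, j, AA_i, AA_j) * active(i, j)
               + sum_i s(i, codon_i) + noise,

with per-position additive amino-acid effects `a`, sparse pairwise
amino-acid epistasis `e`, small codon-level (synonymous) effects `s`, and
Gaussian measurement noise — the minimal structure behind the analyses this
package supports: non-additive amino-acid interactions, synonymous fitness
differences much weaker than non-synonymous ones, and stop-codon lethality.
Sequences containing a stop codon are pinned at a lethal fitness. The
landscape is shifted so the wild type sits at fitness 0 and rescaled (by
bisection on one global factor) so the viable fraction — fitness >= the
viability threshold — approximates a small target, emulating a landscape
where only a few percent of genotypes are viable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .encoding import ALL_CODONS, NT_ORDER, STANDARD_CODE, STOP
from .landscape import LandscapeTable, table_from_arrays

AA_SYMBOLS = "ACDEFGHIKLMNPQRSTVWY" + STOP  # index 20 = stop
_AA_INDEX = {aa: i for i, aa in enumerate(AA_SYMBOLS)}
AA_OF_CODON = np.array([_AA_INDEX[STANDARD_CODE[c]] for c in ALL_CODONS])
STOP_AA = _AA_INDEX[STOP]


class CalibrationError(RuntimeError):
    """The target viable fraction cannot be reached by rescaling."""


class LandscapeSizeError(ValueError):
    """Refusing to enumerate a landscape this large without an override."""


@dataclass
class SyntheticLandscapeConfig:
    """Generator parameters.

    sigma_additive, sigma_epistasis, sigma_synonymous, sigma_noise are the
    standard deviations (pre-calibration, fitness units) of the additive,
    pairwise-epistatic, codon-level and measurement-noise draws;
    epistasis_sparsity is the fraction of position pairs carrying an
    epistatic term. Defaults give a landscape whose synonymous fitness
    differences are an order of magnitude below amino-acid effects and
    whose viable fraction is a small minority of sequence space.
    """

    codon_count: int = 3
    sigma_additive: float = 0.3
    sigma_epistasis: float = 0.15
    epistasis_sparsity: float = 0.3
    sigma_synonymous: float = 0.02
    sigma_noise: float = 0.02
    stop_fitness: float = -1.2
    viability_threshold: float = -0.5
    target_viable_fraction: float = 0.07
    wild_type: Optional[str] = None  # default: additive-optimal genotype
    seed: int = 0
    allow_large: bool = False

    def __post_init__(self) -> None:
        if self.codon_count < 1:
            raise ValueError("codon_count must be >= 1")
        for name in ("sigma_additive", "sigma_epistasis", "sigma_synonymous", "sigma_noise"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.sigma_synonymous < self.sigma_additive:
            raise ValueError("synonymous effects must be weaker than additive ones")
        if not 0.0 <= self.epistasis_sparsity <= 1.0:
            raise ValueError("epistasis_sparsity must lie in [0, 1]")
        if self.codon_count > 5 and not self.allow_large:
            raise LandscapeSizeError(
                f"codon_count={self.codon_count} enumerates 4**{3 * self.codon_count} "
                "sequences; set allow_large=True to proceed"
            )


@dataclass
class EffectTables:
    """The generating effects, kept for parameter-recovery checks."""

    additive: np.ndarray     # (C, 21) per-position amino-acid effects
    epistasis: dict          # (i, j) -> (21, 21) matrix, active pairs only
    synonymous: np.ndarray   # (C, 64) per-position codon effects
    scale: float
    shift: float
    wild_type: str


def _enumerate_codon_indices(codon_count: int) -> np.ndarray:
    """(4**(3C), C) array of codon tokens covering sequence space."""
    n = 4 ** (3 * codon_count)
    idx = np.arange(n, dtype=np.int64)
    shifts = 6 * np.arange(codon_count - 1, -1, -1)
    return (idx[:, None] >> shifts[None, :]) & 63


def _sequences_from_codon_indices(codon_idx: np.ndarray) -> np.ndarray:
    codon_strs = np.array(ALL_CODONS, dtype=object)
    parts = codon_strs[codon_idx]
    out = parts[:, 0]
    for k in range(1, parts.shape[1]):
        out = out + parts[:, k]
    return out


def generate_landscape(
    config: SyntheticLandscapeConfig, return_effects: bool = False
):
    """Generate the full landscape; optionally also the generating effects."""
    C = config.codon_count
    rng = np.random.default_rng(config.seed)

    additive = rng.normal(0.0, config.sigma_additive, size=(C, 21))
    pairs = [(i, j) for i in range(C) for j in range(i + 1, C)]
    active = rng.random(len(pairs)) < config.epistasis_sparsity
    epistasis = {
        pair: rng.normal(0.0, config.sigma_epistasis, size=(21, 21))
        for pair, act in zip(pairs, active)
        if act
    }
    synonymous = rng.normal(0.0, config.sigma_synonymous, size=(C, 64))

    codon_idx = _enumerate_codon_indices(C)
    aa_idx = AA_OF_CODON[codon_idx]  # (n, C)
    is_stop = (aa_idx == STOP_AA).any(axis=1)

    core = np.zeros(len(codon_idx))
    for i in range(C):
        core += additive[i, aa_idx[:, i]]
        core += synonymous[i, codon_idx[:, i]]
    for (i, j), mat in epistasis.items():
        core += mat[aa_idx[:, i], aa_idx[:, j]]
    core += rng.normal(0.0, config.sigma_noise, size=len(core))

    if config.wild_type is None:
        # additive-optimal genotype: per position, best amino acid, then the
        # codon with the largest synonymous effect for that amino acid
        wt_codons = []
        for i in range(C):
            best_aa = int(np.argmax(additive[i, :20]))
            codons = np.flatnonzero(AA_OF_CODON == best_aa)
            wt_codons.append(int(codons[np.argmax(synonymous[i, codons])]))
        wt_seq = "".join(ALL_CODONS[c] for c in wt_codons)
    else:
        wt_seq = config.wild_type
        if len(wt_seq) != 3 * C or set(wt_seq) - set(NT_ORDER):
            raise ValueError(f"invalid wild-type sequence {wt_seq!r}")
        wt_codons = list(
            np.asarray(
                [ALL_CODONS.index(wt_seq[k : k + 3]) for k in range(0, 3 * C, 3)]
            )
        )
    wt_row = 0
    for c in wt_codons:
        wt_row = (wt_row << 6) | int(c)
    if is_stop[wt_row]:
        raise ValueError("wild-type sequence contains a stop codon")
    shift = core[wt_row]
    centered = core - shift

    # calibrate one global scale factor: viable fraction is monotone
    # decreasing in the scale (the wild type is at the top of the landscape)
    target = config.target_viable_fraction
    thr = config.viability_threshold

    def viable_fraction(scale: float) -> float:
        fit = centered * scale
        return float(np.mean(~is_stop & ~(fit < thr)))

    lo, hi = 1e-3, 1e3
    f_lo, f_hi = viable_fraction(lo), viable_fraction(hi)
    if not (f_hi <= target <= f_lo):
        raise CalibrationError(
            f"target viable fraction {target} outside reachable "
            f"range [{f_hi:.4f}, {f_lo:.4f}]"
        )
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if viable_fraction(mid) > target:
            lo = mid
        else:
            hi = mid
        if hi / lo < 1 + 1e-12:
            break
    scale = np.sqrt(lo * hi)
    realized = viable_fraction(scale)
    if abs(realized - target) > 0.2 * target:
        raise CalibrationError(
            f"calibrated viable fraction {realized:.4f} misses target "
            f"{target} by more than 20%"
        )

    fitness = centered * scale
    fitness[is_stop] = config.stop_fitness
    fitness[wt_row] = 0.0  # exact by construction; pin against roundoff

    sequences = _sequences_from_codon_indices(codon_idx)
    table = table_from_arrays(
        sequences,
        fitness,
        viability_threshold=thr,
        validate=False,
    )
    if return_effects:
        return table, EffectTables(
            additive=additive,
            epistasis=epistasis,
            synonymous=synonymous,
            scale=float(scale),
            shift=float(shift),
            wild_type=wt_seq,
        )
    return table


def shuffle_fitness(table: LandscapeTable, seed: int) -> LandscapeTable:
    """Permute fitness values among genotypes; viability flags recomputed."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(table))
    return table_from_arrays(
        [str(s) for s in table.sequences],
        table.fitness[perm],
        viability_threshold=table.viability_threshold,
        offset_applied=table.offset_applied,
        validate=False,
    )
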