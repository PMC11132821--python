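"""Training/validation genotype-sampling strategies.

Six strategies are compared: uniform random; one or two synonymous
sequences per protein ("one syn." / "two syn."); greedy max-min (farthest
point) nucleotide diversity; greedy max-min physicochemical protein
diversity; and high codon-usage-bias (top CAI). Every plan records
diagnostics — mean synonymous sequences per protein, minimum pairwise
Hamming distance, mean CAI, and the fitness standard deviation of the
sample — so strategy side-effects can be examined directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .encoding import (
    AminoAcidDescriptorSet,
    CodonUsageTable,
    cai,
    onehot_encode,
    protein_embed,
    translate,
)
from .landscape import LandscapeTable

STRATEGIES = ("random", "one_syn", "two_syn", "dna_div", "protein_div", "cub")


class SamplingError(ValueError):
    """Invalid sampling request (e.g. S larger than the pool)."""


@dataclass
class SampleDiagnostics:
    syn_per_protein: float
    min_pairwise_hamming: int
    mean_cai: float
    fitness_sd: float


@dataclass
class SamplePlan:
    """The S genotypes chosen by a named strategy, with diagnostics."""

    strategy: str
    size: int
    chosen: list
    seed: int
    diagnostics: SampleDiagnostics = field(default=None)

    def indices_in(self, table: LandscapeTable) -> np.ndarray:
        pos = {str(s): i for i, s in enumerate(table.sequences)}
        return np.array([pos[s] for s in self.chosen], dtype=int)


def _onehot_matrix(seqs: list) -> np.ndarray:
    return np.stack([onehot_encode(s) for s in seqs]).astype(np.float32)


def min_pairwise_hamming(seqs: list, block: int = 2000) -> int:
    """Minimum Hamming distance over all pairs (0 if fewer than 2 seqs).

    Uses the identity d(x, y) = L - <onehot x, onehot y>, computed blockwise.
    """
    n = len(seqs)
    if n < 2:
        return 0
    X = _onehot_matrix(seqs)
    L = len(seqs[0])
    best = L
    for a in range(0, n, block):
        xa = X[a : a + block]
        for b in range(a, n, block):
            sim = xa @ X[b : b + block].T
            d = L - sim
            if a == b:
                np.fill_diagonal(d, L)
            best = min(best, int(round(d.min())))
    return best


def compute_diagnostics(
    chosen: list,
    pool: LandscapeTable,
    usage: Optional[CodonUsageTable] = None,
) -> SampleDiagnostics:
    proteins = {translate(s) for s in chosen}
    syn_per_protein = len(chosen) / len(proteins) if proteins else float("nan")
    if usage is not None:
        mean_cai = float(np.mean([cai(s, usage, allow_stop=True) for s in chosen]))
    else:
        mean_cai = float("nan")
    fit_by_seq = {str(s): f for s, f in zip(pool.sequences, pool.fitness)}
    fit = np.array([fit_by_seq[s] for s in chosen]) if chosen else np.array([])
    fitness_sd = float(np.std(fit, ddof=1)) if len(fit) > 1 else 0.0
    return SampleDiagnostics(
        syn_per_protein=float(syn_per_protein),
        min_pairwise_hamming=min_pairwise_hamming(chosen),
        mean_cai=mean_cai,
        fitness_sd=fitness_sd,
    )


def _finalize(
    strategy: str,
    chosen: list,
    pool: LandscapeTable,
    size: int,
    seed: int,
    usage: Optional[CodonUsageTable],
    with_diagnostics: bool,
) -> SamplePlan:
    assert len(chosen) == size
    plan = SamplePlan(strategy=strategy, size=size, chosen=list(chosen), seed=seed)
    if with_diagnostics:
        plan.diagnostics = compute_diagnostics(chosen, pool, usage)
    return plan


def _check_size(pool: LandscapeTable, size: int) -> None:
    if size < 1:
        raise SamplingError(f"sample size {size} must be positive")
    if size > len(pool):
        raise SamplingError(f"sample size {size} exceeds pool size {len(pool)}")


def sample_random(
    pool: LandscapeTable,
    size: int,
    seed: int,
    usage: Optional[CodonUsageTable] = None,
    with_diagnostics: bool = True,
) -> SamplePlan:
    """Uniform sampling without replacement."""
    _check_size(pool, size)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=size, replace=False)
    chosen = [str(s) for s in pool.sequences[idx]]
    return _finalize("random", chosen, pool, size, seed, usage, with_diagnostics)


def sample_k_synonymous(
    pool: LandscapeTable,
    size: int,
    k: int,
    seed: int,
    usage: Optional[CodonUsageTable] = None,
    with_diagnostics: bool = True,
) -> SamplePlan:
    """At most k synonymous sequences per protein, topped up round-robin.

    Sequences are grouped by translated protein. Groups are visited in
    seeded random order, each contributing up to k seeded-random sequences;
    once every group has been visited, further rounds add one more sequence
    per group (groups smaller than the quota simply contribute all they
    have) until the sample reaches S — i.e. for large S, the smallest
    possible number of synonymous sequences beyond k per protein.
    """
    _check_size(pool, size)
    if k < 1:
        raise SamplingError("k must be >= 1")
    rng = np.random.default_rng(seed)
    groups: dict[str, list] = {}
    for s in pool.sequences:
        groups.setdefault(translate(str(s)), []).append(str(s))
    keys = sorted(groups)
    rng.shuffle(keys)
    shuffled = {key: rng.permutation(groups[key]).tolist() for key in keys}

    chosen: list = []
    quota = {key: 0 for key in keys}
    per_visit = k
    while len(chosen) < size:
        progressed = False
        for key in keys:
            take = min(per_visit, len(shuffled[key]) - quota[key], size - len(chosen))
            if take > 0:
                start = quota[key]
                chosen.extend(shuffled[key][start : start + take])
                quota[key] += take
                progressed = True
            if len(chosen) >= size:
                break
        per_visit = 1  # after the first pass, add one per group per round
        if not progressed:  # exhausted pool before reaching S (cannot happen: S <= |pool|)
            break
    return _finalize(f"{k}_syn" if k not in (1, 2) else ("one_syn" if k == 1 else "two_syn"),
                     chosen, pool, size, seed, usage, with_diagnostics)


def _farthest_point_indices(
    dist_fn, n: int, size: int, rng: np.random.Generator
) -> list:
    """Greedy max-min selection over items 0..n-1.

    dist_fn(i) returns the distance vector from item i to all items. Starts
    from one endpoint of a maximum-distance pair; at each step adds the item
    maximizing the minimum distance to the selected set. Ties anywhere are
    broken uniformly at random with the provided generator.
    """
    # maximum-distance pair (scan all rows; n is modest in practice)
    best_d = -1.0
    endpoints: list = []
    for i in range(n):
        d = dist_fn(i)
        j = int(np.argmax(d))
        di = float(d[j])
        if di > best_d + 1e-12:
            best_d = di
            endpoints = [i]
        elif abs(di - best_d) <= 1e-12:
            endpoints.append(i)
    first = int(rng.choice(endpoints))
    selected = [first]
    min_dist = dist_fn(first).astype(float)
    min_dist[first] = -np.inf
    while len(selected) < size:
        top = np.max(min_dist)
        ties = np.flatnonzero(min_dist >= top - 1e-12)
        nxt = int(rng.choice(ties))
        selected.append(nxt)
        d = dist_fn(nxt).astype(float)
        min_dist = np.minimum(min_dist, d)
        min_dist[nxt] = -np.inf
    return selected


def sample_max_div_dna(
    pool: LandscapeTable,
    size: int,
    seed: int,
    usage: Optional[CodonUsageTable] = None,
    with_diagnostics: bool = True,
) -> SamplePlan:
    """Greedy farthest-point selection under Hamming distance on DNA."""
    _check_size(pool, size)
    rng = np.random.default_rng(seed)
    seqs = [str(s) for s in pool.sequences]
    X = _onehot_matrix(seqs)
    L = pool.sequence_length

    def dist_fn(i: int) -> np.ndarray:
        return L - X @ X[i]

    idx = _farthest_point_indices(dist_fn, len(seqs), size, rng)
    chosen = [seqs[i] for i in idx]
    return _finalize("dna_div", chosen, pool, size, seed, usage, with_diagnostics)


def sample_max_div_protein(
    pool: LandscapeTable,
    size: int,
    descriptors: Optional[AminoAcidDescriptorSet] = None,
    seed: int = 0,
    usage: Optional[CodonUsageTable] = None,
    with_diagnostics: bool = True,
) -> SamplePlan:
    """Greedy farthest-point selection over unique proteins.

    Distances are Euclidean on concatenated physicochemical descriptors.
    Each selected protein contributes one seeded-random encoding sequence;
    if S exceeds the number of unique proteins, selection cycles over the
    selected proteins adding further random synonymous sequences.
    """
    _check_size(pool, size)
    if descriptors is None:
        descriptors = AminoAcidDescriptorSet.default()
    rng = np.random.default_rng(seed)
    groups: dict[str, list] = {}
    for s in pool.sequences:
        groups.setdefault(translate(str(s)), []).append(str(s))
    proteins = sorted(groups)
    E = np.stack([protein_embed(p, descriptors) for p in proteins])

    def dist_fn(i: int) -> np.ndarray:
        return np.sqrt(np.sum((E - E[i]) ** 2, axis=1))

    n_prot = len(proteins)
    order = _farthest_point_indices(dist_fn, n_prot, min(size, n_prot), rng)
    shuffled = {p: rng.permutation(groups[p]).tolist() for p in proteins}
    chosen = [shuffled[proteins[i]][0] for i in order]
    taken = {proteins[i]: 1 for i in order}
    while len(chosen) < size:
        progressed = False
        for i in order:
            p = proteins[i]
            if taken[p] < len(shuffled[p]):
                chosen.append(shuffled[p][taken[p]])
                taken[p] += 1
                progressed = True
                if len(chosen) >= size:
                    break
        if not progressed:
            raise SamplingError("pool exhausted before reaching S")
    return _finalize("protein_div", chosen, pool, size, seed, usage, with_diagnostics)


def sample_high_cub(
    pool: LandscapeTable,
    size: int,
    usage: Optional[CodonUsageTable] = None,
    seed: int = 0,
    with_diagnostics: bool = True,
) -> SamplePlan:
    """Top-S sequences by CAI, ties broken uniformly at random."""
    _check_size(pool, size)
    if usage is None:
        usage = CodonUsageTable.ecoli()
    rng = np.random.default_rng(seed)
    seqs = [str(s) for s in pool.sequences]
    scores = np.array([cai(s, usage, allow_stop=True) for s in seqs])
    tiebreak = rng.random(len(seqs))
    order = np.lexsort((tiebreak, -scores))
    chosen = [seqs[i] for i in order[:size]]
    return _finalize("cub", chosen, pool, size, seed, usage, with_diagnostics)


def sample(
    strategy: str,
    pool: LandscapeTable,
    size: int,
    seed: int,
    usage: Optional[CodonUsageTable] = None,
    descriptors: Optional[AminoAcidDescriptorSet] = None,
    with_diagnostics: bool = True,
) -> SamplePlan:
    """Dispatch on strategy name (see STRATEGIES)."""
    if strategy == "random":
        return sample_random(pool, size, seed, usage, with_diagnostics)
    if strategy == "one_syn":
        return sample_k_synonymous(pool, size, 1, seed, usage, with_diagnostics)
    if strategy == "two_syn":
        return sample_k_synonymous(pool, size, 2, seed, usage, with_diagnostics)
    if strategy == "dna_div":
        return sample_max_div_dna(pool, size, seed, usage, with_diagnostics)
    if strategy == "protein_div":
        return sample_max_div_protein(
            pool, size, descriptors, seed, usage, with_diagnostics
        )
    if strategy == "cub":
        return sample_high_cub(pool, size, usage, seed, with_diagnostics)
    raise SamplingError(f"unknown strategy {strategy!r}")
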