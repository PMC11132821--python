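import itertools

import numpy as np
import pytest

from fitscape.encoding import CodonUsageTable, cai, translate
from fitscape.landscape import table_from_arrays
from fitscape.sampling import (
    SamplingError,
    min_pairwise_hamming,
    sample,
    sample_high_cub,
    sample_k_synonymous,
    sample_max_div_dna,
    sample_max_div_protein,
    sample_random,
)
from tests.test_encoding import toy_descriptor_set


def hamming(a, b):
    return sum(x != y for x, y in zip(a, b))


def make_pool(seqs, fitness=None):
    fitness = fitness if fitness is not None else np.zeros(len(seqs))
    return table_from_arrays(seqs, fitness, validate=False)


class TestRandom:
    def test_exhaustive_sample_is_pool(self, random_pool):
        plan = sample_random(random_pool, len(random_pool), seed=1)
        assert set(plan.chosen) == set(random_pool.sequences)

    def test_same_seed_identical(self, random_pool):
        a = sample_random(random_pool, 10, seed=3)
        b = sample_random(random_pool, 10, seed=3)
        assert a.chosen == b.chosen

    def test_oversized_request_rejected(self, random_pool):
        with pytest.raises(SamplingError):
            sample_random(random_pool, len(random_pool) + 1, seed=0)


class TestKSynonymous:
    def test_one_per_protein_when_sample_fits(self):
        # 3 proteins x 2 synonymous each (K: AAA/AAG, N: AAT/AAC, Q: CAA/CAG)
        pool = make_pool(["AAA", "AAG", "AAT", "AAC", "CAA", "CAG"])
        plan = sample_k_synonymous(pool, 3, k=1, seed=0)
        proteins = {translate(s) for s in plan.chosen}
        assert len(proteins) == 3
        assert plan.diagnostics.syn_per_protein == pytest.approx(1.0)

    def test_exhaustive_two_syn(self):
        pool = make_pool(["AAA", "AAG", "AAT", "AAC", "CAA", "CAG"])
        plan = sample_k_synonymous(pool, 6, k=2, seed=0)
        assert set(plan.chosen) == set(pool.sequences)

    def test_allocation_with_group_sizes_3_3_1(self):
        # K has 2 codons + L has 6; build groups of sizes 3 (Leu), 3 (Arg), 1 (Met)
        pool = make_pool(["CTA", "CTC", "CTG", "CGA", "CGC", "CGG", "ATG"])
        plan = sample_k_synonymous(pool, 5, k=2, seed=4)
        counts = {}
        for s in plan.chosen:
            counts[translate(s)] = counts.get(translate(s), 0) + 1
        # brute-force constraint: no protein exceeds k=2 and the singleton
        # group contributes its only sequence
        assert sorted(counts.values(), reverse=True) == [2, 2, 1]
        assert counts["M"] == 1

    def test_round_robin_beyond_k(self):
        # S exceeding k * groups: extra picks spread one per group per round
        pool = make_pool(["CTA", "CTC", "CTG", "CTT", "AAA", "AAG"])
        plan = sample_k_synonymous(pool, 5, k=1, seed=0)
        counts = {}
        for s in plan.chosen:
            counts[translate(s)] = counts.get(translate(s), 0) + 1
        assert sorted(counts.values(), reverse=True) == [3, 2]


def brute_force_farthest_point_trace(seqs, size, chosen):
    """Re-evaluate the greedy arg-max at each step; the implementation's
    pick must always attain the step's optimal min-distance."""
    first_dists = {
        s: max(hamming(s, t) for t in seqs if t != s) for s in seqs
    }
    best_start = max(first_dists.values())
    assert first_dists[chosen[0]] == best_start
    selected = [chosen[0]]
    for pick in chosen[1:]:
        remaining = [s for s in seqs if s not in selected]
        scores = {s: min(hamming(s, t) for t in selected) for s in remaining}
        assert scores[pick] == max(scores.values())
        selected.append(pick)


class TestMaxDivDNA:
    def test_unique_maximum_distance_pair(self):
        pool = make_pool(["AAA", "AAT", "ATT", "TTT"])
        plan = sample_max_div_dna(pool, 2, seed=0)
        assert set(plan.chosen) == {"AAA", "TTT"}
        assert plan.diagnostics.min_pairwise_hamming == 3

    def test_exhaustive(self, random_pool):
        plan = sample_max_div_dna(random_pool, len(random_pool), seed=0)
        assert set(plan.chosen) == set(random_pool.sequences)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_greedy_trace_matches_brute_force(self, seed):
        rng = np.random.default_rng(100 + seed)
        seqs = list({"".join(rng.choice(list("ACGT"), 6)) for _ in range(10)})
        pool = make_pool(sorted(seqs))
        plan = sample_max_div_dna(pool, min(6, len(seqs)), seed=seed)
        brute_force_farthest_point_trace(list(pool.sequences), plan.size, plan.chosen)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_min_distance_at_least_random(self, seed):
        rng = np.random.default_rng(200 + seed)
        seqs = list({"".join(rng.choice(list("ACGT"), 9)) for _ in range(12)})
        pool = make_pool(sorted(seqs))
        S = 5
        div = sample_max_div_dna(pool, S, seed=seed)
        rnd = sample_random(pool, S, seed=seed)
        assert (
            div.diagnostics.min_pairwise_hamming
            >= rnd.diagnostics.min_pairwise_hamming
        )


class TestMaxDivProtein:
    def test_toy_protein_pair(self):
        # proteins AA, AV, VV under a 1-descriptor set {A: 0, V: 1}
        pool = make_pool(["GCAGCA", "GCAGTA", "GTAGTA"])
        plan = sample_max_div_protein(pool, 2, descriptors=toy_descriptor_set(), seed=0)
        assert {translate(s) for s in plan.chosen} == {"AA", "VV"}

    def test_single_sequence_min_distance_zero(self):
        pool = make_pool(["GCAGCA", "GTAGTA"])
        plan = sample_max_div_protein(pool, 1, descriptors=toy_descriptor_set(), seed=0)
        assert plan.size == 1
        assert plan.diagnostics.min_pairwise_hamming == 0

    def test_cycles_through_synonyms_when_S_exceeds_proteins(self):
        pool = make_pool(["GCAGCA", "GCCGCC", "GTAGTA", "GTCGTC"])
        plan = sample_max_div_protein(pool, 4, descriptors=toy_descriptor_set(), seed=0)
        assert set(plan.chosen) == set(pool.sequences)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_greedy_trace_matches_brute_force_on_proteins(self, seed):
        rng = np.random.default_rng(300 + seed)
        seqs = list({"".join(rng.choice(list("ACGT"), 6)) for _ in range(12)})
        seqs = [s for s in sorted(seqs) if "*" not in translate(s)][:9]
        pool = make_pool(seqs)
        desc = toy_descriptor_set()
        plan = sample_max_div_protein(pool, len({translate(s) for s in seqs}),
                                      descriptors=desc, seed=seed)
        # step-by-step oracle in protein-descriptor space
        from fitscape.encoding import protein_embed

        prots = sorted({translate(s) for s in seqs})
        vecs = {p: protein_embed(p, desc) for p in prots}

        def pdist(a, b):
            return float(np.linalg.norm(vecs[a] - vecs[b]))

        chosen_prots = [translate(s) for s in plan.chosen]
        first_best = max(
            max(pdist(a, b) for b in prots if b != a) for a in prots
        )
        assert max(pdist(chosen_prots[0], b) for b in prots if b != chosen_prots[0]) == pytest.approx(first_best)
        selected = [chosen_prots[0]]
        for pick in chosen_prots[1:]:
            remaining = [p for p in prots if p not in selected]
            scores = {p: min(pdist(p, q) for q in selected) for p in remaining}
            assert scores[pick] == pytest.approx(max(scores.values()))
            selected.append(pick)


class TestHighCUB:
    def test_top_one_attains_max_cai(self, random_pool):
        usage = CodonUsageTable.ecoli()
        plan = sample_high_cub(random_pool, 1, usage=usage, seed=0)
        best = max(cai(str(s), usage, allow_stop=True) for s in random_pool.sequences)
        assert cai(plan.chosen[0], usage, allow_stop=True) == pytest.approx(best)

    def test_all_ties_reduces_to_seeded_subset(self):
        from fitscape.encoding import ALL_CODONS

        usage = CodonUsageTable.from_frequencies({c: 1.0 for c in ALL_CODONS})
        pool = make_pool(["AAA", "AAC", "AAG", "AAT", "ACA", "ACC"])
        a = sample_high_cub(pool, 3, usage=usage, seed=9)
        b = sample_high_cub(pool, 3, usage=usage, seed=9)
        assert a.chosen == b.chosen
        assert len(set(a.chosen)) == 3

    def test_hand_computed_top_two(self):
        # two-family usage table: Lys AAA=1.0/AAG=0.5; Asn AAT=1.0/AAC=0.25
        freqs = {"AAA": 2.0, "AAG": 1.0, "AAT": 4.0, "AAC": 1.0}
        usage = CodonUsageTable.from_frequencies(freqs)
        pool = make_pool(["AAAAAG", "AAGAAC", "AATAAA"])
        # CAI: sqrt(1*0.5)=0.707, sqrt(0.5*0.25)=0.354, sqrt(1*1)=1.0
        plan = sample_high_cub(pool, 2, usage=usage, seed=0)
        assert plan.chosen[0] == "AATAAA"
        assert set(plan.chosen) == {"AATAAA", "AAAAAG"}

    def test_mean_cai_at_least_random(self, random_pool):
        usage = CodonUsageTable.ecoli()
        cub = sample_high_cub(random_pool, 8, usage=usage, seed=1)
        rnd = sample_random(random_pool, 8, seed=1, usage=usage)
        assert cub.diagnostics.mean_cai >= rnd.diagnostics.mean_cai


class TestPlanInvariants:
    @pytest.mark.parametrize(
        "strategy", ["random", "one_syn", "two_syn", "dna_div", "protein_div", "cub"]
    )
    def test_plans_are_valid_subsets(self, strategy, default_landscape):
        from fitscape.landscape import filter_viable, split_train_test

        viable = filter_viable(default_landscape)
        pool, test = split_train_test(viable, 0.5, seed=2)
        plan = sample(
            strategy,
            pool,
            60,
            seed=5,
            usage=CodonUsageTable.ecoli(),
            descriptors=toy_descriptor_set(),
        )
        assert len(plan.chosen) == 60
        assert len(set(plan.chosen)) == 60
        assert set(plan.chosen) <= set(map(str, pool.sequences))
        assert not set(plan.chosen) & set(map(str, test.sequences))

    def test_fitness_sd_diagnostic_matches_numpy(self, random_pool):
        plan = sample_random(random_pool, 10, seed=0)
        fit = {str(s): f for s, f in zip(random_pool.sequences, random_pool.fitness)}
        expected = np.std([fit[s] for s in plan.chosen], ddof=1)
        assert plan.diagnostics.fitness_sd == pytest.approx(expected)


def test_min_pairwise_hamming_matches_exhaustive():
    rng = np.random.default_rng(7)
    seqs = list({"".join(rng.choice(list("ACGT"), 9)) for _ in range(15)})
    expected = min(
        hamming(a, b) for a, b in itertools.combinations(seqs, 2)
    )
    assert min_pairwise_hamming(seqs) == expected
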