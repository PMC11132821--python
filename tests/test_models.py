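import numpy as np
import pytest

from fitscape import encoding
from fitscape.landscape import table_from_arrays
from fitscape.models import (
    ModelSpec,
    ModelSpecError,
    SearchSpace,
    baseline_random_predictor,
    build_model,
    count_params,
    default_spec,
    fit_linear_baseline,
    hyperband_brackets,
    tune_hyperband,
)
from fitscape.networks import BiRNNNet
from fitscape.train_eval import TrainConfig, train_network


class TestModelSpec:
    def test_incompatible_encoding_rejected(self):
        with pytest.raises(ModelSpecError):
            ModelSpec("mlp", encoding="codon_tokens")

    def test_default_encoding_inferred(self):
        assert ModelSpec("rnn_codon").encoding == "codon_tokens"

    def test_json_roundtrip(self):
        spec = ModelSpec("mlp", {"hidden_units": (32, 16)})
        back = ModelSpec.from_json(spec.to_json())
        assert back.architecture == "mlp"
        assert back.hyperparameters["hidden_units"] == (32, 16)

    def test_zero_transformer_blocks_rejected(self):
        with pytest.raises(ValueError):
            build_model(ModelSpec("transformer", {"blocks": 0}), 3, seed=0)


class TestBuild:
    def test_linear_onehot_dimensionality(self):
        # 9-nt input -> 36 one-hot coefficients + 1 intercept
        rng = np.random.default_rng(0)
        X = encoding.encode_batch(
            ["".join(rng.choice(list("ACGT"), 9)) for _ in range(20)], "onehot_flat"
        )
        lin = fit_linear_baseline(X, rng.normal(size=20))
        assert lin.coef_.shape == (36,)
        assert lin.parameter_count == 37

    def test_same_seed_identical_initial_predictions(self):
        rng = np.random.default_rng(1)
        X = encoding.encode_batch(
            ["".join(rng.choice(list("ACGT"), 9)) for _ in range(8)], "onehot_flat"
        )
        a = build_model(default_spec("mlp"), 3, seed=11).predict(X)
        b = build_model(default_spec("mlp"), 3, seed=11).predict(X)
        assert np.array_equal(a, b)

    @pytest.mark.parametrize(
        "arch", ["mlp", "rnn", "cnn", "transformer", "rnn_codon", "transformer_codon"]
    )
    def test_parameter_count_formula_matches_built_network(self, arch):
        spec = default_spec(arch)
        net = build_model(spec, 3, seed=0)
        assert net.parameter_count == count_params(spec, 3) == spec.parameter_count

    def test_parameter_count_monotone_in_units(self):
        small = count_params(ModelSpec("mlp", {"hidden_units": (16, 16)}), 3)
        large = count_params(ModelSpec("mlp", {"hidden_units": (64, 64)}), 3)
        assert large > small


class TestRandomBaseline:
    def test_single_record_predicts_own_fitness(self):
        table = table_from_arrays(["AAA"], [0.4])
        assert baseline_random_predictor(table, seed=0)[0] == 0.4

    def test_shuffle_preserves_multiset(self, random_pool):
        preds = baseline_random_predictor(random_pool, seed=3)
        assert sorted(preds) == sorted(random_pool.fitness)

    def test_mean_squared_correlation_near_zero_over_seeds(self):
        # Monte-Carlo over permutations on a 1000-record table: the squared
        # Pearson correlation of a random permutation with the truth has
        # expectation ~1/(n-1), essentially zero here
        rng = np.random.default_rng(0)
        n = 1000
        seqs = []
        seen = set()
        while len(seqs) < n:
            s = "".join(rng.choice(list("ACGT"), 9))
            if s not in seen:
                seen.add(s)
                seqs.append(s)
        fitness = rng.normal(2.0, 0.5, size=n)
        table = table_from_arrays(seqs, fitness, validate=False)
        corr2s = [
            np.corrcoef(fitness, baseline_random_predictor(table, seed=s))[0, 1] ** 2
            for s in range(100)
        ]
        assert np.mean(corr2s) < 0.05


class TestLinearBaseline:
    def test_recovers_additive_truth_exactly(self):
        # noise-free additive landscape over one-hot features
        rng = np.random.default_rng(2)
        seqs = list({"".join(rng.choice(list("ACGT"), 9)) for _ in range(60)})
        X = encoding.encode_batch(seqs, "onehot_flat")
        effects = rng.normal(size=36)
        y = X @ effects + 1.5
        lin = fit_linear_baseline(X, y)
        assert np.allclose(lin.predict(X), y, atol=1e-8)

    def test_constant_targets_zero_slopes(self):
        rng = np.random.default_rng(3)
        X = encoding.encode_batch(
            ["".join(rng.choice(list("ACGT"), 9)) for _ in range(10)], "onehot_flat"
        )
        lin = fit_linear_baseline(X, np.full(10, 0.7))
        assert np.allclose(lin.coef_, 0.0, atol=1e-10)
        assert lin.intercept_ == pytest.approx(0.7)

    def test_matches_lstsq_oracle(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(20, 7))
        y = rng.normal(size=20)
        lin = fit_linear_baseline(X, y)
        A = np.column_stack([X, np.ones(20)])
        theta = np.linalg.lstsq(A, y, rcond=None)[0]
        assert np.allclose(lin.predict(X), A @ theta, atol=1e-6)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            fit_linear_baseline(np.ones((1, 3)), np.ones(1))


class TestCapacity:
    @pytest.mark.parametrize(
        "arch,hp,lr",
        [
            ("mlp", {}, 3e-3),
            ("rnn", {}, 3e-3),
            ("cnn", {}, 3e-3),
            ("transformer", {"embed_dim": 32, "ff_units": 64}, 5e-3),
            ("rnn_codon", {}, 3e-3),
            ("transformer_codon", {"embed_dim": 32, "ff_units": 64}, 5e-3),
        ],
    )
    def test_overfits_20_sequences(self, arch, hp, lr):
        rng = np.random.default_rng(0)
        seqs = ["".join(rng.choice(list("ACGT"), 9)) for _ in range(20)]
        y = rng.normal(2.0, 0.3, size=20)
        spec = ModelSpec(arch, hp)
        X = encoding.encode_batch(seqs, spec.encoding)
        net = build_model(spec, 3, seed=2)
        cfg = TrainConfig(max_epochs=500, patience=499, batch_size=20)
        hist = train_network(net, X, y, None, None, cfg, seed=3, learning_rate=lr)
        assert min(hist["train_mse"]) < 1e-3


class TestDirectionSensitivity:
    def test_bidirectional_states_swap_only_with_tied_weights(self):
        rng = np.random.default_rng(5)
        X = encoding.encode_batch(
            ["".join(rng.choice(list("ACGT"), 9)) for _ in range(4)], "onehot_seq"
        )
        net = BiRNNNet(seq_len=9, input_dim=4, units=(6,), seed=8)
        rev = X[:, ::-1, :].copy()
        # independent weights: output changes under input reversal
        assert not np.allclose(net.predict(X), net.predict(rev))
        # tie backward weights to forward ones and symmetrize the readout:
        # reversal swaps the direction states, so the output is invariant
        for gate in ("Wz", "Uz", "Wr", "Ur", "Wh", "Uh"):
            net.params[f"gru0b_{gate}"].data[:] = net.params[f"gru0f_{gate}"].data
            bias = f"gru0b_{gate}_b"
            if bias in net.params:
                net.params[bias].data[:] = net.params[f"gru0f_{gate}_b"].data
        W = net.params["Wout"].data
        W[6:] = W[:6]
        assert np.allclose(net.predict(X), net.predict(rev))


class TestHyperband:
    def test_bracket_arithmetic_for_10_epochs_factor_3(self):
        # hand-computed from the published successive-halving schedule
        assert hyperband_brackets(10, 3) == [
            [(9, 1), (3, 3), (1, 10)],
            [(5, 3), (1, 10)],
            [(3, 10)],
        ]

    def test_single_point_space_returns_that_point(self):
        space = SearchSpace(choices={"hidden_units": [(8,)]}, iterations=1)
        template = default_spec("mlp")

        def evaluate_fn(spec, epochs):
            return 1.0

        best, log = tune_hyperband(space, template, evaluate_fn, seed=0)
        assert best.hyperparameters["hidden_units"] == (8,)
        assert len(log) == sum(n for b in hyperband_brackets(10, 3) for n, _ in b)

    def test_selects_strictly_better_configuration(self):
        # noise-free linear problem: the wider network fits it, width 1 cannot
        rng = np.random.default_rng(6)
        seqs = list({"".join(rng.choice(list("ACGT"), 9)) for _ in range(40)})
        X = encoding.encode_batch(seqs, "onehot_flat")
        y = X @ rng.normal(size=36)
        val_scores = {(1,): 0.5, (16,): 0.01}

        def evaluate_fn(spec, epochs):
            return val_scores[spec.hyperparameters["hidden_units"]]

        space = SearchSpace(
            choices={"hidden_units": [(1,), (16,)]}, iterations=1
        )
        best, _ = tune_hyperband(space, default_spec("mlp"), evaluate_fn, seed=0)
        assert best.hyperparameters["hidden_units"] == (16,)

    def test_empty_choice_list_rejected(self):
        with pytest.raises(ModelSpecError):
            SearchSpace(choices={"hidden_units": []})

    def test_end_to_end_tuning_on_tiny_problem(self):
        rng = np.random.default_rng(7)
        seqs = list({"".join(rng.choice(list("ACGT"), 9)) for _ in range(60)})
        X = encoding.encode_batch(seqs, "onehot_flat")
        y = X @ rng.normal(size=36) + 2.0
        Xtr, ytr, Xva, yva = X[:40], y[:40], X[40:], y[40:]
        space = SearchSpace(
            choices={"hidden_units": [(8,), (32,)]},
            max_epochs=3,
            patience=2,
            iterations=1,
        )
        cfg = TrainConfig(max_epochs=10, patience=2, batch_size=20)

        def evaluate_fn(spec, epochs):
            net = build_model(spec, 3, seed=1)
            train_network(
                net, Xtr, ytr, Xva, yva, cfg, seed=2, max_epochs=epochs,
                learning_rate=3e-3,
            )
            return float(np.mean((net.predict(Xva) - yva) ** 2))

        best, log = tune_hyperband(space, default_spec("mlp"), evaluate_fn, seed=3)
        assert best.hyperparameters["hidden_units"] in {(8,), (32,)}
        assert all(rec["val_mse"] >= 0 for rec in log)
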