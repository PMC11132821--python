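"""Model zoo: baselines, architecture specs, builders and hyperband tuning.

Architectures and their input encodings:

==================  =================  =========================================
architecture        input encoding     network
==================  =================  =========================================
random_baseline     (none)             shuffled-fitness predictor
linear              onehot_flat        minimum-norm least squares (pseudoinverse)
mlp                 onehot_flat        multilayer perceptron
rnn                 onehot_seq         bidirectional GRU over nucleotides
cnn                 onehot_seq         1D convolutional network
transformer         nt_tokens          transformer, nucleotide embedding
rnn_codon           codon_tokens      bidirectional GRU, codon embedding
transformer_codon   codon_tokens      transformer, codon embedding
==================  =================  =========================================
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np

from .landscape import LandscapeTable
from .networks import BiRNNNet, CNNNet, MLPNet, Network, TransformerNet

ARCHITECTURES = (
    "random_baseline",
    "linear",
    "mlp",
    "rnn",
    "cnn",
    "transformer",
    "rnn_codon",
    "transformer_codon",
)

ARCH_ENCODING = {
    "linear": "onehot_flat",
    "mlp": "onehot_flat",
    "rnn": "onehot_seq",
    "cnn": "onehot_seq",
    "transformer": "nt_tokens",
    "rnn_codon": "codon_tokens",
    "transformer_codon": "codon_tokens",
}

_DEFAULT_HPARAMS = {
    "mlp": {"hidden_units": (64, 64), "dropout": 0.0, "l2": 0.0, "learning_rate": 3e-3},
    "rnn": {"units": (32,), "recurrent_dropout": 0.0, "l2": 0.0, "learning_rate": 1e-3},
    "cnn": {
        "channels": (32,),
        "kernel_size": 3,
        "dense_units": (32,),
        "l2": 0.0,
        "learning_rate": 1e-3,
    },
    "transformer": {
        "embed_dim": 16,
        "heads": 2,
        "head_size": 8,
        "ff_units": 32,
        "blocks": 1,
        "dropout": 0.0,
        "l2": 0.0,
        "learning_rate": 1e-3,
    },
}
_DEFAULT_HPARAMS["rnn_codon"] = {**_DEFAULT_HPARAMS["rnn"], "embed_dim": 8}
_DEFAULT_HPARAMS["transformer_codon"] = dict(_DEFAULT_HPARAMS["transformer"])
_DEFAULT_HPARAMS["linear"] = {}
_DEFAULT_HPARAMS["random_baseline"] = {}


class ModelSpecError(ValueError):
    """Invalid architecture/encoding/hyperparameter combination."""


@dataclass
class ModelSpec:
    """Architecture name, hyperparameters and input encoding."""

    architecture: str
    hyperparameters: dict = field(default_factory=dict)
    encoding: Optional[str] = None
    parameter_count: Optional[int] = None  # filled by build_model

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ModelSpecError(f"unknown architecture {self.architecture!r}")
        expected = ARCH_ENCODING.get(self.architecture)
        if self.encoding is None:
            self.encoding = expected
        elif expected is not None and self.encoding != expected:
            raise ModelSpecError(
                f"{self.architecture} requires encoding {expected!r}, "
                f"got {self.encoding!r}"
            )
        merged = dict(_DEFAULT_HPARAMS.get(self.architecture, {}))
        merged.update(self.hyperparameters)
        self.hyperparameters = merged

    def to_json(self) -> str:
        d = {
            "architecture": self.architecture,
            "hyperparameters": {
                k: list(v) if isinstance(v, tuple) else v
                for k, v in self.hyperparameters.items()
            },
            "encoding": self.encoding,
            "parameter_count": self.parameter_count,
        }
        return json.dumps(d, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ModelSpec":
        d = json.loads(text)
        hp = {
            k: tuple(v) if isinstance(v, list) else v
            for k, v in d.get("hyperparameters", {}).items()
        }
        return cls(
            architecture=d["architecture"], hyperparameters=hp, encoding=d.get("encoding")
        )


def default_spec(architecture: str) -> ModelSpec:
    return ModelSpec(architecture=architecture)


class LinearModel:
    """Minimum-norm least squares on (one-hot) features.

    The intercept is fit separately (column means removed), so constant
    targets yield zero slopes; the slope system is solved with the
    Moore-Penrose pseudoinverse, giving the minimum-norm solution on the
    rank-deficient one-hot blocks.
    """

    def __init__(self) -> None:
        self.coef_: Optional[np.ndarray] = None
        self.intercept_: Optional[float] = None
        self._x_mean: Optional[np.ndarray] = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LinearModel":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or len(X) == 0:
            raise ValueError("need a non-empty 2D design matrix")
        if len(X) < 2:
            raise ValueError("need at least 2 training rows")
        self._x_mean = X.mean(axis=0)
        y_mean = y.mean()
        Xc = X - self._x_mean
        # rcond cuts the near-null block-constant directions of one-hot
        # designs; predictions are unchanged, coefficients stay bounded
        self.coef_ = np.linalg.pinv(Xc, rcond=1e-8) @ (y - y_mean)
        self.intercept_ = float(y_mean)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.coef_ is None:
            raise RuntimeError("model not fitted")
        return (np.asarray(X, dtype=float) - self._x_mean) @ self.coef_ + self.intercept_

    @property
    def parameter_count(self) -> int:
        return int(self.coef_.size + 1)


def fit_linear_baseline(X: np.ndarray, y: np.ndarray) -> LinearModel:
    """Least-squares linear regression on encoded features (pseudoinverse)."""
    return LinearModel().fit(X, y)


def baseline_random_predictor(table: LandscapeTable, seed: int) -> np.ndarray:
    """Fitness values randomly shuffled among genotypes, as predictions."""
    if len(table) == 0:
        raise ValueError("empty table")
    rng = np.random.default_rng(seed)
    return table.fitness[rng.permutation(len(table))]


def build_model(spec: ModelSpec, codon_count: int, seed: int) -> Network:
    """Instantiate a seeded, trainable network for the spec.

    Records the parameter count on the spec. `linear` and `random_baseline`
    are not gradient-trained networks; use fit_linear_baseline /
    baseline_random_predictor for those.
    """
    L = 3 * codon_count
    hp = spec.hyperparameters
    arch = spec.architecture
    if arch == "mlp":
        net: Network = MLPNet(
            input_dim=4 * L,
            hidden_units=tuple(hp["hidden_units"]),
            dropout=hp["dropout"],
            l2=hp["l2"],
            seed=seed,
        )
    elif arch == "rnn":
        net = BiRNNNet(
            seq_len=L,
            input_dim=4,
            units=tuple(hp["units"]),
            recurrent_dropout=hp["recurrent_dropout"],
            l2=hp["l2"],
            seed=seed,
        )
    elif arch == "rnn_codon":
        net = BiRNNNet(
            seq_len=codon_count,
            input_dim=0,
            units=tuple(hp["units"]),
            recurrent_dropout=hp["recurrent_dropout"],
            l2=hp["l2"],
            vocab=64,
            embed_dim=hp["embed_dim"],
            seed=seed,
        )
    elif arch == "cnn":
        net = CNNNet(
            seq_len=L,
            input_dim=4,
            channels=tuple(hp["channels"]),
            kernel_size=hp["kernel_size"],
            dense_units=tuple(hp["dense_units"]),
            l2=hp["l2"],
            seed=seed,
        )
    elif arch in ("transformer", "transformer_codon"):
        net = TransformerNet(
            seq_len=L if arch == "transformer" else codon_count,
            vocab=4 if arch == "transformer" else 64,
            embed_dim=hp["embed_dim"],
            heads=hp["heads"],
            head_size=hp["head_size"],
            ff_units=hp["ff_units"],
            blocks=hp["blocks"],
            dropout=hp["dropout"],
            l2=hp["l2"],
            seed=seed,
        )
    else:
        raise ModelSpecError(f"{arch} is not a buildable network")
    spec.parameter_count = net.parameter_count
    return net


def count_params(spec: ModelSpec, codon_count: int) -> int:
    """Parameter count from the spec alone (documented closed formulas)."""
    L = 3 * codon_count
    hp = spec.hyperparameters
    arch = spec.architecture
    if arch == "linear":
        return 4 * L + 1
    if arch == "mlp":
        total, prev = 0, 4 * L
        for h in hp["hidden_units"]:
            total += prev * h + h
            prev = h
        return total + prev + 1
    if arch in ("rnn", "rnn_codon"):
        if arch == "rnn":
            total, prev = 0, 4
        else:
            e = hp["embed_dim"]
            total, prev = 64 * e + codon_count * e, e
        for u in hp["units"]:
            total += 2 * 3 * (prev * u + u * u + u)  # 2 directions x {z, r, h}
            prev = 2 * u
        return total + prev + 1
    if arch == "cnn":
        total, prev, length = 0, 4, L
        k = hp["kernel_size"]
        for ch in hp["channels"]:
            total += k * prev * ch + ch
            prev, length = ch, length - k + 1
        prev = prev * length
        for u in hp["dense_units"]:
            total += prev * u + u
            prev = u
        return total + prev + 1
    if arch in ("transformer", "transformer_codon"):
        length = L if arch == "transformer" else codon_count
        vocab = 4 if arch == "transformer" else 64
        e, hd = hp["embed_dim"], hp["heads"] * hp["head_size"]
        f = hp["ff_units"]
        per_block = 3 * e * hd + hd * e + (e * f + f) + (f * e + e) + 4 * e
        return vocab * e + length * e + hp["blocks"] * per_block + e + 1
    raise ModelSpecError(f"no parameter formula for {arch}")


# --- hyperband ------------------------------------------------------------


@dataclass
class SearchSpace:
    """Hyperparameter choices plus the hyperband budget.

    `choices` maps a hyperparameter name to a list of candidate values;
    `log_uniform` maps a name to (low, high) sampled log-uniformly.
    """

    choices: dict = field(default_factory=dict)
    log_uniform: dict = field(default_factory=dict)
    factor: int = 3
    iterations: int = 3
    max_epochs: int = 10
    patience: int = 5

    def __post_init__(self) -> None:
        for name, opts in self.choices.items():
            if not opts:
                raise ModelSpecError(f"empty choice list for {name!r}")
        if self.factor < 2 or self.max_epochs < 1 or self.iterations < 1:
            raise ModelSpecError("invalid hyperband budget")

    def sample(self, rng: np.random.Generator) -> dict:
        hp = {name: opts[rng.integers(len(opts))] for name, opts in self.choices.items()}
        for name, (lo, hi) in self.log_uniform.items():
            hp[name] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        return hp

    @classmethod
    def default_for(cls, architecture: str) -> "SearchSpace":
        lr = {"learning_rate": (1e-4, 1e-2)}
        l2 = {"l2": [0.0, 1e-4, 1e-3]}
        if architecture == "mlp":
            grids = {
                "hidden_units": [
                    (u,) * depth for depth in (1, 2, 3) for u in (16, 32, 64, 128, 256)
                ],
                **l2,
            }
        elif architecture in ("rnn", "rnn_codon"):
            grids = {
                "units": [(u,) * d for d in (1, 2) for u in (8, 16, 32, 64)],
                "recurrent_dropout": [0.0, 0.1, 0.3],
                **l2,
            }
            if architecture == "rnn_codon":
                grids["embed_dim"] = [4, 8, 16]
        elif architecture == "cnn":
            grids = {
                "channels": [(c,) * d for d in (1, 2) for c in (16, 32, 64, 128)],
                "dense_units": [(u,) * d for d in (1, 2) for u in (16, 32, 64)],
                **l2,
            }
        elif architecture in ("transformer", "transformer_codon"):
            grids = {
                "embed_dim": [8, 16, 32, 64],
                "heads": [1, 2, 4],
                "blocks": [1, 2, 3],
                **l2,
            }
        else:
            raise ModelSpecError(f"no default search space for {architecture}")
        return cls(choices=grids, log_uniform=lr)


def hyperband_brackets(max_epochs: int, factor: int) -> list:
    """Successive-halving bracket schedule: list of [(n_configs, epochs), ...].

    s_max = floor(log_factor(max_epochs)); bracket s starts with
    n = ceil((s_max + 1) / (s + 1) * factor**s) configurations at
    r = max_epochs * factor**(-s) epochs, then keeps the top 1/factor at
    factor-times the epochs, down to full-epoch training.
    """
    s_max = int(math.floor(math.log(max_epochs) / math.log(factor)))
    brackets = []
    for s in range(s_max, -1, -1):
        n = int(math.ceil((s_max + 1) / (s + 1) * factor**s))
        rungs = []
        for i in range(s + 1):
            n_i = int(math.floor(n * factor**-i))
            r_i = max(int(math.floor(max_epochs * factor ** (i - s))), 1)
            rungs.append((n_i, r_i))
        brackets.append(rungs)
    return brackets


def tune_hyperband(
    space: SearchSpace,
    template: ModelSpec,
    evaluate_fn: Callable[[ModelSpec, int], float],
    seed: int,
) -> tuple:
    """Hyperband search; returns (best ModelSpec, trial log).

    evaluate_fn(spec, epochs) trains the spec for the given epoch budget
    (honoring the space's patience) and returns the validation mse.
    Each rung retrains from scratch with a larger epoch budget, keeping the
    top 1/factor configurations of the previous rung.
    """
    rng = np.random.default_rng(seed)
    brackets = hyperband_brackets(space.max_epochs, space.factor)
    total_trials = space.iterations * sum(r[0][0] for r in brackets)
    if total_trials == 0:
        raise ModelSpecError("hyperband budget allows zero trials")
    log: list[dict] = []
    best_spec, best_val = None, np.inf
    for it in range(space.iterations):
        for bi, rungs in enumerate(brackets):
            n0 = rungs[0][0]
            configs = [
                replace(template, hyperparameters={**template.hyperparameters, **space.sample(rng)},
                        parameter_count=None)
                for _ in range(n0)
            ]
            for ri, (n_i, r_i) in enumerate(rungs):
                configs = configs[:n_i]
                scored = []
                for spec in configs:
                    val = float(evaluate_fn(spec, r_i))
                    scored.append((val, spec))
                    log.append(
                        {
                            "iteration": it,
                            "bracket": bi,
                            "rung": ri,
                            "epochs": r_i,
                            "val_mse": val,
                            "hyperparameters": json.dumps(
                                {k: list(v) if isinstance(v, tuple) else v
                                 for k, v in spec.hyperparameters.items()},
                                sort_keys=True,
                            ),
                        }
                    )
                    if val < best_val:
                        best_val, best_spec = val, spec
                scored.sort(key=lambda t: t[0])
                configs = [s for _, s in scored]
    return best_spec, log
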