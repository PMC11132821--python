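"""Training protocol (4-fold cross-validation, minibatch rmsprop, early
stopping on training loss) and the evaluation metric suite.

The protocol trains one network per fold on 75% of the sample, monitors the
training mse each epoch, and stops a fold early once the training mse has
failed to improve for `patience` consecutive epochs. Test-set predictions
are the mean of the fold models' predictions (per-fold predictions are
retained so either convention can be reported).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.stats import spearmanr
from sklearn.metrics import mean_absolute_error, mean_squared_error, r2_score

from . import encoding
from .autograd import mse_loss
from .landscape import LandscapeTable
from .models import ModelSpec, build_model
from .networks import Network, RMSProp
from .sampling import SamplePlan


@dataclass
class TrainConfig:
    """Protocol constants: batch 128, rmsprop, <=100 epochs, patience 5,
    4 folds of 75/25 train/validation, 3 replicates."""

    batch_size: int = 128
    optimizer: str = "rmsprop"
    max_epochs: int = 100
    patience: int = 5
    folds: int = 4
    validation_fraction: float = 0.25
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.folds * self.validation_fraction - 1.0) > 1e-9:
            raise ValueError(
                "folds x validation_fraction must equal 1 "
                f"({self.folds} x {self.validation_fraction})"
            )
        if not self.patience < self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")
        if self.optimizer != "rmsprop":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")


@dataclass
class MetricsReport:
    """Metric bundle for one evaluation."""

    r_squared: float
    mae: float
    mape: float  # percent
    mse: float
    spearman_r: float
    n: int

    def as_dict(self) -> dict:
        return {
            "r_squared": self.r_squared,
            "mae": self.mae,
            "mape": self.mape,
            "mse": self.mse,
            "spearman_r": self.spearman_r,
            "n": self.n,
        }


def make_folds(
    sample_size: int, folds: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded (train, validation) index pairs.

    Validation sets partition 0..S-1 into `folds` blocks whose sizes differ
    by at most one; each train set is the complement.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if sample_size < folds:
        raise ValueError(f"sample size {sample_size} < folds {folds}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(sample_size)
    val_blocks = np.array_split(perm, folds)
    out = []
    for k in range(folds):
        val = np.sort(val_blocks[k])
        train = np.sort(np.concatenate([v for i, v in enumerate(val_blocks) if i != k]))
        out.append((train, val))
    return out


class EarlyStopper:
    """Stop after `patience` consecutive epochs without a strictly lower
    training loss."""

    def __init__(self, patience: int):
        self.patience = patience
        self.best = np.inf
        self.stale = 0

    def update(self, loss: float) -> bool:
        """Record an epoch loss; return True if training should stop now."""
        if loss < self.best:
            self.best = loss
            self.stale = 0
        else:
            self.stale += 1
        return self.stale >= self.patience


def epochs_run(losses: list, patience: int, max_epochs: int) -> int:
    """Number of epochs a run with this training-loss trajectory executes."""
    stopper = EarlyStopper(patience)
    for i, loss in enumerate(losses[:max_epochs], start=1):
        if stopper.update(loss):
            return i
    return min(len(losses), max_epochs)


def train_network(
    net: Network,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: Optional[np.ndarray],
    y_val: Optional[np.ndarray],
    config: TrainConfig,
    seed: int,
    max_epochs: Optional[int] = None,
    learning_rate: float = 1e-3,
) -> dict:
    """Minibatch rmsprop with early stopping on the training mse.

    Returns a history dict with per-epoch full-sample train mse and (if a
    validation set is given) validation mse.
    """
    if len(X_train) == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(seed)
    if "Wout_b" in net.params:
        # start the output bias at the target mean so early epochs fit
        # structure rather than the constant offset of the fitness scale
        net.params["Wout_b"].data[:] = float(np.mean(y_train))
    opt = RMSProp(net.params.values(), lr=learning_rate)
    cap = max_epochs if max_epochs is not None else config.max_epochs
    stopper = EarlyStopper(config.patience)
    history = {"train_mse": [], "val_mse": []}
    n = len(X_train)
    for _ in range(cap):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            opt.zero_grad()
            pred = net.forward(X_train[idx], train=True)
            loss = mse_loss(pred, y_train[idx])
            pen = net.l2_penalty()
            if not isinstance(pen, float):
                loss = loss + pen
            loss.backward()
            opt.step()
        train_mse = float(np.mean((net.predict(X_train) - y_train) ** 2))
        history["train_mse"].append(train_mse)
        if X_val is not None and len(X_val):
            history["val_mse"].append(
                float(np.mean((net.predict(X_val) - y_val) ** 2))
            )
        if stopper.update(train_mse):
            break
    return history


@dataclass
class CVEnsemble:
    """The four fold models plus their loss histories and fold indices."""

    spec: ModelSpec
    models: list
    histories: list
    fold_indices: list
    codon_count: int

    @property
    def trained(self) -> bool:
        return bool(self.models)

    def averaged_curves(self) -> dict:
        """Mean train/val mse per epoch across folds.

        Folds stopped early are right-padded with their final loss so the
        average at late epochs reflects the loss those folds ended at.
        """
        out = {}
        for key in ("train_mse", "val_mse"):
            curves = [h[key] for h in self.histories if h[key]]
            if not curves:
                out[key] = []
                continue
            longest = max(len(c) for c in curves)
            padded = np.array(
                [c + [c[-1]] * (longest - len(c)) for c in curves], dtype=float
            )
            out[key] = padded.mean(axis=0).tolist()
        return out


def crossval_train(
    spec: ModelSpec,
    sequences: list,
    fitness: np.ndarray,
    config: TrainConfig,
    codon_count: int,
) -> CVEnsemble:
    """Train one model per CV fold on an encoded genotype sample."""
    X = encoding.encode_batch(sequences, spec.encoding)
    y = np.asarray(fitness, dtype=float)
    folds = make_folds(len(X), config.folds, config.seed)
    models, histories = [], []
    lr = spec.hyperparameters.get("learning_rate", 1e-3)
    for k, (tr, va) in enumerate(folds):
        if len(tr) == 0 or len(va) == 0:
            raise ValueError(f"fold {k} is empty")
        net = build_model(spec, codon_count, seed=config.seed * 1000 + k)
        hist = train_network(
            net,
            X[tr],
            y[tr],
            X[va],
            y[va],
            config,
            seed=config.seed * 1000 + 500 + k,
            learning_rate=lr,
        )
        models.append(net)
        histories.append(hist)
    return CVEnsemble(
        spec=spec,
        models=models,
        histories=histories,
        fold_indices=folds,
        codon_count=codon_count,
    )


def crossval_train_plan(
    spec: ModelSpec, plan: SamplePlan, pool: LandscapeTable, config: TrainConfig
) -> CVEnsemble:
    fit_by_seq = {str(s): f for s, f in zip(pool.sequences, pool.fitness)}
    y = np.array([fit_by_seq[s] for s in plan.chosen])
    return crossval_train(spec, plan.chosen, y, config, pool.codon_count)


def predict_test(ensemble: CVEnsemble, sequences: list) -> tuple[np.ndarray, np.ndarray]:
    """(ensemble-mean predictions, per-fold prediction matrix) for a test set."""
    if not ensemble.trained:
        raise RuntimeError("ensemble has no trained models")
    X = encoding.encode_batch(sequences, ensemble.spec.encoding)
    per_fold = np.stack([m.predict(X) for m in ensemble.models])
    return per_fold.mean(axis=0), per_fold


def evaluate(predictions: np.ndarray, truth: np.ndarray) -> MetricsReport:
    """R^2, mae, mape (percent), mse and Spearman r (average ranks for ties).

    mape diverges for truth values near zero, which is why fitness is
    shifted to a strictly positive scale before training. Constant truth
    makes R^2 and Spearman undefined; they are reported as NaN.
    """
    pred = np.asarray(predictions, dtype=float)
    y = np.asarray(truth, dtype=float)
    if pred.shape != y.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {y.shape}")
    if y.size < 2:
        raise ValueError("need at least 2 values")
    if np.allclose(y, y[0]):
        r2 = float("nan")
        rho = float("nan")
    else:
        r2 = float(r2_score(y, pred))
        # rank correlation is undefined when one input is constant
        if np.allclose(pred, pred[0]):
            rho = float("nan")
        else:
            rho = float(spearmanr(y, pred).statistic)
    with np.errstate(divide="ignore", invalid="ignore"):
        # mape legitimately diverges when truth contains zeros (raw scale)
        mape = float(100.0 * np.mean(np.abs(y - pred) / np.abs(y)))
    return MetricsReport(
        r_squared=r2,
        mae=float(mean_absolute_error(y, pred)),
        mape=mape,
        mse=float(mean_squared_error(y, pred)),
        spearman_r=rho,
        n=int(y.size),
    )


def percent_change(value: float, reference: float) -> float:
    """100 * (value - reference) / reference, to one decimal."""
    if reference == 0:
        raise ZeroDivisionError("percent change against a zero reference")
    return round(100.0 * (value - reference) / reference, 1)
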