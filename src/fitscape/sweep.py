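"""The strategy x architecture x sample-size x replicate experiment grid.

Every grid cell draws a fresh 50% test split, a fresh training/validation
sample by its strategy, runs the cross-validated training protocol, and
scores the held-out test set. Per-cell seeds are derived deterministically
from the master seed and the cell key, so any cell can be recomputed in
isolation and two runs with the same master seed produce byte-identical
output tables.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .encoding import AminoAcidDescriptorSet, CodonUsageTable
from .landscape import LandscapeTable, split_train_test
from .models import ModelSpec, default_spec
from .sampling import SamplePlan, sample
from .train_eval import (
    MetricsReport,
    TrainConfig,
    crossval_train_plan,
    evaluate,
    percent_change,
    predict_test,
)

DEFAULT_SIZES = (200, 400, 600, 800, 1000, 1200, 1400, 1600, 2000, 3000, 4000, 6000, 8000)


@dataclass
class SweepConfig:
    sample_sizes: tuple = DEFAULT_SIZES
    strategies: tuple = ("random",)
    architectures: tuple = ("mlp",)
    replicates: int = 3
    master_seed: int = 0
    test_fraction: float = 0.5
    reference_size: int = 1400  # where strategy contrasts are summarized

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if any(s < 1 for s in self.sample_sizes):
            raise ValueError("sample sizes must be positive")


def cell_seed(master_seed: int, strategy: str, arch: str, size: int, replicate: int) -> int:
    """Stable per-cell seed below 2**31."""
    key = f"{master_seed}|{strategy}|{arch}|{size}|{replicate}".encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "big") % (2**31)


@dataclass
class SweepCell:
    strategy: str
    architecture: str
    size: int
    replicate: int
    seed: int
    metrics: MetricsReport
    plan: SamplePlan


@dataclass
class SweepResult:
    config: SweepConfig
    cells: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.cells:
            d = c.plan.diagnostics
            rows.append(
                {
                    "strategy": c.strategy,
                    "arch": c.architecture,
                    "sample_size": c.size,
                    "replicate": c.replicate,
                    "seed": c.seed,
                    **c.metrics.as_dict(),
                    "syn_per_protein": d.syn_per_protein if d else np.nan,
                    "min_pairwise_hamming": d.min_pairwise_hamming if d else np.nan,
                    "mean_cai": d.mean_cai if d else np.nan,
                    "fitness_sd": d.fitness_sd if d else np.nan,
                }
            )
        return pd.DataFrame(rows)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def is_complete(self) -> bool:
        want = (
            len(self.config.strategies)
            * len(self.config.architectures)
            * len(self.config.sample_sizes)
            * self.config.replicates
        )
        return len(self.cells) == want


def run_sweep(
    table: LandscapeTable,
    config: SweepConfig,
    train_config: TrainConfig,
    specs: Optional[dict] = None,
    usage: Optional[CodonUsageTable] = None,
    descriptors: Optional[AminoAcidDescriptorSet] = None,
) -> SweepResult:
    """Run the full grid on a (viable-only) landscape table.

    `specs` optionally maps architecture name -> ModelSpec (tuned
    hyperparameters); defaults are used otherwise. The largest sample size
    must fit into the non-test half of the table.
    """
    pool_size = len(table) - int(np.floor(config.test_fraction * len(table) + 0.5))
    needs_usage = "cub" in config.strategies or usage is not None
    if needs_usage and usage is None:
        usage = CodonUsageTable.ecoli()
    if "protein_div" in config.strategies and descriptors is None:
        descriptors = AminoAcidDescriptorSet.default()
    result = SweepResult(config=config)
    for strategy in config.strategies:
        for arch in config.architectures:
            spec_template = (specs or {}).get(arch) or default_spec(arch)
            for size in config.sample_sizes:
                if size > pool_size:
                    raise ValueError(
                        f"cell ({strategy}, {arch}, S={size}): sample size "
                        f"exceeds pool of {pool_size}"
                    )
                for rep in range(config.replicates):
                    seed = cell_seed(config.master_seed, strategy, arch, size, rep)
                    pool, test = split_train_test(table, config.test_fraction, seed)
                    plan = sample(
                        strategy,
                        pool,
                        size,
                        seed=seed + 1,
                        usage=usage,
                        descriptors=descriptors,
                    )
                    tc = TrainConfig(
                        batch_size=train_config.batch_size,
                        max_epochs=train_config.max_epochs,
                        patience=train_config.patience,
                        folds=train_config.folds,
                        validation_fraction=train_config.validation_fraction,
                        replicates=train_config.replicates,
                        seed=seed + 2,
                    )
                    spec = ModelSpec(
                        architecture=spec_template.architecture,
                        hyperparameters=dict(spec_template.hyperparameters),
                    )
                    ensemble = crossval_train_plan(spec, plan, pool, tc)
                    preds, _ = predict_test(ensemble, [str(s) for s in test.sequences])
                    metrics = evaluate(preds, test.fitness)
                    result.cells.append(
                        SweepCell(
                            strategy=strategy,
                            architecture=arch,
                            size=size,
                            replicate=rep,
                            seed=seed,
                            metrics=metrics,
                            plan=plan,
                        )
                    )
    return result


@dataclass
class SweepSummary:
    curves: pd.DataFrame          # mean +/- SEM per (strategy, arch, S)
    size_to_90pct: pd.DataFrame   # smallest S reaching 90% of peak mean R^2
    deltas_at_reference: pd.DataFrame  # strategy contrasts vs random
    fitness_sd: pd.DataFrame      # per-cell sample fitness SD summary


def summarize(result: SweepResult) -> SweepSummary:
    """Mean +/- SEM curves, 90%-of-peak sample sizes, strategy contrasts."""
    if not result.is_complete():
        raise ValueError("sweep grid is incomplete")
    df = result.to_frame()
    group = df.groupby(["strategy", "arch", "sample_size"])
    curves = group.agg(
        r_squared_mean=("r_squared", "mean"),
        r_squared_sem=("r_squared", "sem"),
        mape_mean=("mape", "mean"),
        mape_sem=("mape", "sem"),
        mae_mean=("mae", "mean"),
        mse_mean=("mse", "mean"),
        spearman_mean=("spearman_r", "mean"),
    ).reset_index()

    rows = []
    for (strategy, arch), sub in curves.groupby(["strategy", "arch"]):
        sub = sub.sort_values("sample_size")
        peak = sub.loc[sub["sample_size"].idxmax(), "r_squared_mean"]
        ok = sub[sub["r_squared_mean"] >= 0.9 * peak]
        rows.append(
            {
                "strategy": strategy,
                "arch": arch,
                "peak_r_squared": peak,
                "size_90pct": int(ok["sample_size"].min()),
            }
        )
    size90 = pd.DataFrame(rows)

    ref = result.config.reference_size
    sizes = np.array(sorted(set(curves["sample_size"])))
    ref_size = int(sizes[np.argmin(np.abs(sizes - ref))])
    at_ref = curves[curves["sample_size"] == ref_size]
    deltas = []
    for arch, sub in at_ref.groupby("arch"):
        base = sub[sub["strategy"] == "random"]
        if base.empty:
            continue
        base_r2 = float(base["r_squared_mean"].iloc[0])
        base_mape = float(base["mape_mean"].iloc[0])
        for _, row in sub.iterrows():
            if row["strategy"] == "random":
                continue
            deltas.append(
                {
                    "arch": arch,
                    "strategy": row["strategy"],
                    "reference_size": ref_size,
                    "r_squared_change_pct": percent_change(
                        float(row["r_squared_mean"]), base_r2
                    ),
                    "mape_change_pct": percent_change(
                        float(row["mape_mean"]), base_mape
                    ),
                }
            )
    fitness_sd = (
        df.groupby(["strategy", "sample_size"])
        .agg(fitness_sd_mean=("fitness_sd", "mean"), fitness_sd_sem=("fitness_sd", "sem"))
        .reset_index()
    )
    return SweepSummary(
        curves=curves,
        size_to_90pct=size90,
        deltas_at_reference=pd.DataFrame(deltas),
        fitness_sd=fitness_sd,
    )


def plot_curves(summary: SweepSummary, metric: str, path: str | Path) -> None:
    """Line plot of a metric vs sample size per (strategy, arch)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for (strategy, arch), sub in summary.curves.groupby(["strategy", "arch"]):
        sub = sub.sort_values("sample_size")
        ax.errorbar(
            sub["sample_size"],
            sub[f"{metric}_mean"],
            yerr=sub.get(f"{metric}_sem"),
            marker="o",
            capsize=3,
            label=f"{strategy}/{arch}",
        )
    ax.set_xlabel("sample size S")
    ax.set_ylabel(metric)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
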