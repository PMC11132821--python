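# fitscape

Genotype sampling and deep-learning regression on combinatorially complete
fitness landscapes.

## The problem

A combinatorially complete fitness landscape assigns a fitness value to every
DNA sequence of a short coding region — for a 9-nucleotide region, all
4^9 = 262,144 genotypes. Measuring such landscapes experimentally is
expensive, so a practical question is: **how many genotypes must be assayed,
and which ones, for a regression model to predict the fitness of the rest?**

`fitscape` provides the full pipeline for studying that question at desk
scale:

- **Synthetic landscape generator** — a combinatorially complete landscape
  with additive amino-acid effects, pairwise amino-acid epistasis, weak
  synonymous (codon-level) effects, measurement noise, lethal stop codons,
  and a calibrated viable fraction (~7%, matching the regime where only a
  small minority of genotypes is viable). Since most genotypes are inviable,
  models are trained and evaluated on the viable subset only.
- **Six sampling strategies** for choosing the training genotypes: uniform
  random, one or two synonymous variants per protein (`one_syn`, `two_syn`),
  greedy maximal nucleotide diversity (`dna_div`), greedy maximal
  physicochemical protein diversity (`protein_div`), and preference for high
  codon usage bias (`cub`).
- **A model zoo** — linear regression baseline, multilayer perceptron,
  bidirectional GRU, 1-D convolutional network, and transformer encoder, the
  last two also with learned codon embeddings. The networks run on a compact
  numpy reverse-mode autodiff engine included in the package (no external
  deep-learning framework required); gradients are verified against finite
  differences in the test suite.
- **A fixed training protocol** — 4-fold cross-validation with a 75/25
  split, minibatches of 128, rmsprop, early stopping after 5 epochs without
  training-loss improvement, fold-ensembled prediction on a held-out 50%
  test split, and a hyperband hyperparameter tuner (factor 3, 3 iterations).
- **Sweep orchestration** — the full strategy × architecture × sample-size ×
  replicate grid with deterministic per-cell seeding, tabular output, and
  learning-curve summaries (sample size to reach 90% of peak R², percent
  change between strategies at a reference sample size).

## Worked example

Generate a landscape, train a perceptron on a random sample of 1400 viable
genotypes, and evaluate on an untouched 50% test split:

```python
import numpy as np

from fitscape.landscape import apply_offset, filter_viable, split_train_test
from fitscape.models import default_spec
from fitscape.sampling import sample
from fitscape.synthetic import SyntheticLandscapeConfig, generate_landscape
from fitscape.train_eval import TrainConfig, crossval_train, evaluate, predict_test

# a combinatorially complete 9-nt landscape (4^9 = 262144 genotypes)
table = generate_landscape(SyntheticLandscapeConfig(seed=1))
print(f"genotypes: {len(table)}, viable: {int(table.viable.sum())}")

# keep viable genotypes, shift fitness to a positive scale, hold out 50%
viable = apply_offset(filter_viable(table), 2.0)
pool, test = split_train_test(viable, 0.5, seed=0)

# train a multilayer perceptron on a random sample of 1400 genotypes
plan = sample("random", pool, 1400, seed=1, with_diagnostics=False)
fitness = {str(s): f for s, f in zip(pool.sequences, pool.fitness)}
y = np.array([fitness[s] for s in plan.chosen])
ensemble = crossval_train(
    default_spec("mlp"), plan.chosen, y, TrainConfig(seed=3), pool.codon_count
)

# evaluate the fold-averaged predictions on the held-out half
preds, _ = predict_test(ensemble, [str(s) for s in test.sequences])
m = evaluate(preds, test.fitness)
print(f"test R^2 = {m.r_squared:.3f}, mae = {m.mae:.3f}, mape = {m.mape:.1f}%")
```

Output (about 9 seconds on one CPU core):

```
genotypes: 262144, viable: 18351
test R^2 = 0.482, mae = 0.085, mape = 5.0%
```

A command-line interface covers the same ground: `fitscape simulate`,
`fitscape sample` and `fitscape sweep` (see `fitscape --help`).

## Layout

| Module | Contents |
| --- | --- |
| `fitscape.landscape` | fitness tables, I/O, offsets, viability, splits |
| `fitscape.encoding` | one-hot/token encodings, translation, CAI, descriptors |
| `fitscape.synthetic` | calibrated synthetic landscape generator |
| `fitscape.sampling` | the six sampling strategies + diagnostics |
| `fitscape.autograd` / `fitscape.networks` | numpy autodiff engine and model zoo |
| `fitscape.models` | model specs, baselines, hyperband tuner |
| `fitscape.train_eval` | CV training protocol, metrics, early stopping |
| `fitscape.sweep` | grid orchestration, summaries, plots |
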