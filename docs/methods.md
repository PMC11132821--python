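# Methods

This note records the generative model behind the synthetic landscapes, the
training and evaluation protocol, and the numerical choices that affect
reproducibility.

## Synthetic landscape model

Every DNA sequence of `C` codons (default `C = 3`, i.e. all 4^9 = 262,144
genotypes) receives a fitness

```
f(g) = scale · [ Σ_p a(p, aa_p)                    additive amino-acid effects
               + Σ_(i<j) active  e(i, j, aa_i, aa_j)   pairwise epistasis
               + Σ_p s(p, codon_p) ]               synonymous codon effects
       + ε                                          measurement noise
       + shift
```

with every effect drawn once per landscape from zero-mean normals
(`a ~ N(0, σ_a²)`, `e ~ N(0, σ_e²)`, `s ~ N(0, σ_s²)`, `ε ~ N(0, σ_n²)`).
Each position pair is epistatically *active* with probability `p_e`;
inactive pairs contribute nothing. Any sequence containing a stop codon is
pinned to a fixed lethal fitness and is never viable.

Two global constants are then solved for, in this order:

1. **shift** — the wild type, defined as the genotype that maximizes the
   additive part (per-position argmax amino acid, then argmax synonymous
   codon), is assigned fitness exactly 0. All other fitness values are
   relative to it, so the landscape spans negative and positive values
   around the wild type.
2. **scale** — bisection on a multiplicative scale (geometric midpoint,
   search interval [1e-3, 1e3]) until the fraction of genotypes at or above
   the viability threshold hits the target viable fraction within ±20%.
   Calibration failure raises an error rather than returning a miscalibrated
   landscape.

Viability is decided on the raw scale: a genotype is inviable iff its
fitness is strictly below the threshold. Training happens after adding a
constant offset (+2 by default) so all fitness values are strictly positive
and the mean absolute percentage error stays finite; viability flags are
never recomputed on the offset scale.

### Default parameters

| Parameter | Symbol | Default | Role |
| --- | --- | --- | --- |
| codons | `C` | 3 | 4^(3C) genotypes, combinatorially complete |
| additive sd | `σ_a` | 0.3 | main fitness determinant |
| epistasis sd | `σ_e` | 0.15 | pairwise amino-acid interactions |
| active-pair probability | `p_e` | 0.3 | sparsity of epistasis |
| synonymous sd | `σ_s` | 0.02 | weak codon-level effects (must be < `σ_a`) |
| noise sd | `σ_n` | 0.02 | measurement error |
| stop fitness | — | −1.2 | lethal, below the viability threshold |
| viability threshold | — | −0.5 | strictly-below is inviable |
| target viable fraction | — | 0.07 ± 20% | calibrated via the global scale |

### What the generator emulates — and what it does not

The generator reproduces the qualitative premises of experimentally
mapped protein fitness landscapes: a small viable minority, additive effects
dominating, sparse pairwise epistasis, synonymous variation much weaker
than nonsynonymous variation, lethal stops, and noisy measurement. One
emergent consequence worth noting: restricting to the top ~7% of genotypes
induces a selection (collider) anticorrelation between the additive and
epistatic components among viable genotypes, which caps linear-regression
performance well below the noise ceiling — deep models recover a large part
of the gap. The generator does **not** emulate higher-order (>2-way)
epistasis, position-dependent structural constraints, or any particular
empirical protein; its parameters were fixed from the premises above, not
fitted to data.

## Sampling strategies

All strategies draw from the viable training pool only and are fully
deterministic given a seed:

- `random` — uniform without replacement.
- `one_syn` / `two_syn` — at most k = 1 (resp. 2) synonymous sequences per
  protein, allocated round-robin over proteins in seeded order; once every
  protein is covered k times, further rounds add one more per protein.
- `dna_div` — greedy farthest-point selection under Hamming distance,
  initialized at a maximum-distance pair; ties broken by seeded draw.
- `protein_div` — greedy farthest-point over *unique proteins* under
  Euclidean distance between concatenated per-residue physicochemical
  descriptor vectors (20 amino acids × 10 z-scored descriptors bundled;
  replaceable via CSV). If the request exceeds the number of proteins, it
  cycles through synonymous variants.
- `cub` — the top-S sequences by codon adaptation index (geometric mean of
  per-codon relative adaptiveness; bundled E. coli K-12 usage frequencies,
  floored at 0.01 before per-family normalization; replaceable via CSV).

## Training and evaluation protocol

- Fresh 50% train-pool / test split per sweep cell; the sample is drawn from
  the pool, the test half is never sampled or touched during training.
- 4-fold cross-validation (75/25) on the sample; one network per fold;
  test predictions are the mean over the four fold models.
- Minibatch gradient descent, batch size 128, rmsprop (ρ = 0.9, ε = 1e-7).
- Up to 100 epochs with early stopping after 5 consecutive epochs without a
  strict improvement in full-training-set mse.
- 3 replicates per cell; per-cell seeds derive from
  sha256(master | strategy | architecture | S | replicate), so any cell can
  be recomputed in isolation and reruns are byte-identical.
- Metrics on the test half: R² = 1 − SS_res/SS_tot, mae, mape (percent, on
  the offset scale), mse, and Spearman rank correlation with average ranks.
  Strategy contrasts are reported as percent change rounded to one decimal.
- The shuffled-fitness baseline is reported as squared Pearson correlation
  (expectation ≈ 1/(n−1) for a random permutation); its residual-based R²
  is ≈ −1 by construction and is not a useful null summary.
- Hyperband tuner: factor 3, 3 iterations, 10-epoch ceiling — bracket
  schedule [(9,1),(3,3),(1,10)], [(5,3),(1,10)], [(3,10)].

## Numerical choices

- **Networks** run on an in-package numpy reverse-mode autodiff engine
  (float64). Gradients of every architecture are checked against central
  finite differences in the test suite.
- **Output-bias initialization**: each network's output bias starts at the
  training-fold target mean, so early epochs fit structure rather than the
  +2 offset constant.
- **Learning rates**: 3e-3 for the perceptron (chosen by a pre-registered
  scan over the tuner's learning-rate range on a synthetic landscape at
  S = 1400), 1e-3 elsewhere; all tunable per model spec.
- **Linear baseline**: pseudo-inverse with `rcond = 1e-8` on centered
  one-hot features; this drops the near-null block-constant directions of
  one-hot encodings instead of amplifying them.
- **Tie-breaking** in greedy samplers uses a tolerance of 1e-12 and a seeded
  draw among tied candidates; `cub` breaks CAI ties by seeded permutation.
- **Fold averaging** of loss curves right-pads shorter folds with their
  final loss before averaging.
- **Splits** round the test size half-up; splits and fold assignments come
  from `numpy.random.default_rng` with explicit seeds throughout.

## Problem sizes used in the checks

Recovery and benchmark checks run on the full C = 3 landscape (262,144
genotypes, ~18k viable): linear recovery of additive effects on an
epistasis-free landscape, linear-vs-perceptron comparison at S = 1400, and
the strategy comparison at S ∈ {400, 1400} with 3 replicates. Protocol
invariants run on a C = 2 landscape (4,096 genotypes) for speed.

## Limitations

- Passing these checks on synthetic landscapes does not certify performance
  on any empirical landscape; real data have higher-order epistasis,
  structured measurement error, and different synonymous architecture.
- The synthetic landscape is protein-blocky: each viable protein keeps many
  synonymous variants carrying almost no fitness information. Consequently
  maximal-nucleotide-diversity sampling — which mainly avoids synonymous
  near-duplicates — is roughly neutral here rather than clearly harmful,
  and the acceptance check asserting a clear deficit for `dna_div` fails at
  default parameters. On landscapes whose informative variation lies at the
  nucleotide level, or with samples smaller than the number of viable
  proteins, the contrast is expected to be stronger.
- Networks are trained at fixed default hyperparameters in the sweep; the
  hyperband tuner is provided but not run inside the acceptance path for
  budget reasons.
- mape is only meaningful on the strictly positive offset scale; on the raw
  scale it diverges near zero fitness.
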