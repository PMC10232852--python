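# Methods

## Task and data model

The unit of analysis is a 41-nt RNA window over {A,C,G,U} whose centre
(1-based position 21) is the queried uridine; the label says whether that U
carries the m⁵U modification. Windows are one-hot encoded in the fixed
channel order (A, C, G, U). T is treated as an alias of U on input because
site lists are routinely deposited in DNA coordinates. A non-U centre raises
a warning rather than an error so the toolkit can be reused for other
single-nucleotide marks; the m⁵U semantics are otherwise unchanged.

Splits are stratified by class: each class is permuted with a seeded
generator and cut at cumulative-rounded fractions, which guarantees
per-class counts within ±1 of the exact fractions and byte-identical
partitions for identical `(records, fractions, seed)`.

## Synthetic benchmark

Real m⁵U benchmarks pair experimentally mapped sites with unmodified
uridines drawn from the same transcripts; both classes therefore share the
centre U and a broadly similar background composition, and the
discriminative signal lives in short context motifs — a G-rich patch
immediately upstream and a C-rich patch downstream of the site. The
simulator reproduces exactly that structure and nothing more:

- negatives: i.i.d. draws from a background distribution (default uniform
  0.25×4) at all 40 non-centre positions, centre fixed to U;
- positives: the same background, with each motif — `GGU` at 1-based 18–20
  and `CXAXCCC` at 23–29 (`X` = wildcard) — independently written with
  probability `plant_prob` (default 0.9).

Penetrance 0.9 is deliberate: ~1% of positives carry neither motif and are
indistinguishable from background, so confusion tables are non-degenerate
and both false positives and false negatives occur. Penetrance in real data
is unknown; `plant_prob` is a free parameter, not an estimate. Defaults of
2,000+2,000 sequences give a training scale at which the full ensemble
trains in minutes on one CPU while leaving ~800 held-out test windows.

What the simulator does **not** model: read-level sequencing noise,
transcript structure (exon/intron context), positional composition gradients,
or correlated backgrounds. Passing the recovery tests therefore shows that
the pipeline can learn and faithfully report planted, position-fixed motifs —
it does not certify performance on real transcriptomic data.

A `PAPER_FLAVORED_BACKGROUND` preset (G/C-enriched) exists for logo-rendering
demos only; all quantitative defaults use the uniform background.

## Architectures

Five stacks on (41, 4) input, each ending in dense(256) → dropout(0.2) →
ReLU → dense(1, sigmoid):

| family | feature extractor |
|---|---|
| CNN | conv(250, k11)×2 → maxpool(10/10) |
| BiLSTM | bilstm(256)×2 |
| BiGRU | bigru(256) |
| CNN-BiLSTM | conv(250, k7)×2 → maxpool(4/4) → bilstm(64) |
| CNN-BiGRU | conv(250, k11) → maxpool(10/10) → bigru(256) |

Conventions, fixed where the published descriptions are silent:

- Convolutions are *valid* (no padding), stride 1, fused ReLU; the time-axis
  traces are CNN 41→31→21→(pool)2 and CNN-BiLSTM 41→35→29→(pool)7. Max
  pooling drops remainder positions (21 pooled by 10 gives 2).
- Recurrent "units" are **per direction**; a bidirectional block emits
  2×units channels. Stacked recurrent layers return full sequences except
  the last, which emits the concatenated final hidden states.
- A flatten (time-major) is inserted wherever a dense layer receives
  sequence-shaped input.
- Grid search (conv layers {1,2,3}, kernels {3,5,7,9,11}, filters
  {50,150,250}, pools {2,4,6,8,10}, recurrent layers {1,2,3}, units
  {32,64,128,256}) selects by validation accuracy, ties broken toward fewer
  parameters; infeasible shape chains are recorded and skipped.

## The numerical engine

No deep-learning framework is used: layers, backpropagation and Adam are
implemented directly in numpy, with every heavy operation phrased as a BLAS
matmul (convolution as a sum of K shifted-slice matmuls; LSTM/GRU as
per-step gate matmuls). LSTM gates follow the standard (i, f, g, o)
formulation with forget-gate bias 1; the GRU uses the classic
reset-before-matmul candidate, `h = (1−z)·h̃ + z·h_prev`. Initialisation is
Glorot-uniform for input kernels and orthogonal for recurrent kernels.
Training fuses the output sigmoid with binary cross-entropy, so the gradient
entering the output pre-activation is `(p − y)/B` — numerically exact at
saturated probabilities. Weights are float32 (~127 GFLOPS single-core
matmul throughput); gradient-correctness tests run the same code in float64
against central finite differences (max error ~1e-10). All randomness flows
through seeded `numpy.random.Generator`s, so training is bit-reproducible on
a given BLAS build, and saved ensembles reload with bit-identical
predictions.

## Training protocol

Adam (lr 0.001, β₁ 0.9, β₂ 0.999, ε 1e-7), batch 64, exactly 20 epochs — no
early stopping, no schedule. Validation loss is recorded after each epoch
but never influences the weights. The predictor is the arithmetic mean of 5
members; member *i* uses seed `seed+i` and re-draws its train/validation
partition from the pooled train+validation records so members differ through
initialisation, dropout and data order. The test fraction is drawn once and
never re-entered, which keeps the ensemble's held-out evaluation leak-free
(a full re-split per member would put one member's training data in another
member's test set). Class weighting is available (`class_weighting=True`)
but off by default, including at 1:10 imbalance — imbalance effects are
reported, not corrected. Classification threshold is 0.5 with ties to the
positive class.

## Metrics

ACC, PRE, Recall, F-value and MCC are computed from the 2×2 confusion table
by their standard closed forms. Degenerate denominators return 0 with a
warning so imbalanced evaluations never crash. ROC/PR curves and areas are
delegated to scikit-learn: full threshold sweep (no intermediate dropping),
trapezoidal auROC, and the step-interpolation (average-precision) auPR,
chosen over trapezoidal PR interpolation because the latter is optimistically
biased.

## Shapley attribution

The value function behind all estimators is
`v(S) = E_b[f(x_S, b_{\bar S})]`: features in S taken from the explained
window, the rest from a background reference (default: a seeded 100-sequence
subsample of the training set — which also makes the constant centre U a
null player). Three estimators:

- **exact** — weighted subset enumeration of the defining sum, players =
  axis-0 entries of the input; O(2^M), refused beyond 16 players. Additivity
  `f(x) = φ₀ + Σφᵢ` holds to machine precision.
- **sampling** — marginal contributions along random player permutations
  (unbiased, 1/√n error).
- **expected gradients** (default for the 41×4 sequence model, where
  enumeration over positions is intractable) — Monte-Carlo average of
  `(x−b) ⊙ ∇f(b + α(x−b))` over background draws and uniform path positions,
  using the engine's exact input gradients; the ensemble is explained as its
  mean-probability function (the deployed predictor), with gradients
  averaged across members. The additivity residual is recorded on every
  attribution rather than assumed.

Logo presentation: each window's 41×4 attribution matrix is rescaled so its
largest magnitude is 0.25 (zero matrices untouched; signs never change),
then scaled values are accumulated position-by-observed-base across windows.
Per-sequence sums of observed-base scaled values outside [−1, 1] — possible
when attributions are dense rather than motif-sparse — are flagged with a
warning, not clipped.

## Layer-wise UMAP

Any layer's activations (multi-dimensional outputs flattened time-major) are
projected to 2-D with seeded UMAP (defaults n_neighbors 15, min_dist 0.1).
For an ensemble the first member is dissected — members are exchangeable by
construction, and mixing activations across members would blur the geometry.
Class separation is quantified by the silhouette score of the embedding
under the true labels; on a well-trained model it rises from ≈0 at the
one-hot input to strongly positive in the last hidden layer.

## Saturation mutagenesis

All 41×3 = 123 single-base mutants of a window are scored together with the
wild type in one forward batch; the effect of mutation (i, b) is
`Δp = p(mutant) − p(wild type)` (positive = pushes toward the modified
class), wild-type cells fixed at 0. The centre U is mutated like any other
position — the model's response there is informative — but summaries accept
`mask_center=True` since a non-U centre is definitionally not an m⁵U site,
and the motif-recovery analyses use that mask.

## Problem sizes used in the checked runs

The standard study configuration (2,000+2,000 windows, 5-member CNN-BiLSTM,
20 epochs) is what the acceptance script and the end-to-end tests run;
attribution summaries use 80 held-out positives at 64 Monte-Carlo samples
each, mutagenesis 20 held-out motif-carrying positives, and UMAP the full
~800-window test set. These sizes give stable recovery statistics while the
whole pipeline stays in the tens of minutes on a single CPU core.

## Known limitations

- Conclusions from the synthetic benchmark transfer to real data only to the
  extent that real discriminative signal is motif-like and position-stable.
- Expected gradients is a path-integral Shapley approximation; its residuals
  are Monte-Carlo noise, reported per attribution rather than bounded a
  priori.
- Bit-level training reproducibility holds per BLAS build/threading
  configuration, not across different numerical libraries.
- The GRU uses the classic gate equations, which differ slightly from some
  frameworks' `reset_after` variant; trained weights are not interchangeable
  with such implementations.
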