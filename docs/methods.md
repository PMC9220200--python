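# Methods

## Model

One predictor is trained per MHC allele. A peptide of length *L* over the
20 canonical amino acids is one-hot encoded as a 20×*L* matrix (rows in the
fixed alphabetical ordering `ACDEFGHIKLMNPQRSTVWY`, used project-wide for
every residue-indexed matrix). A learnable 20×20 matrix *W* — twenty 1×20
convolution kernels of window size 1, initialized from BLOSUM62 — maps each
position to the 20-vector `Evo(X)[i,·] = W · x_i`. With one-hot input this
is exactly the BLOSUM similarity profile of the residue at position *i*
before training, and a data-adapted substitution matrix after training
(`extract_learned_matrix` reads it back out). No bias term is used in this
layer.

Two independent LSTM chains (forget/input/output gates, tanh cell
candidate; zero initial state) consume the *L*×20 feature matrix
left-to-right and right-to-left. Their final hidden states are concatenated
into a fixed-size vector regardless of *L* — this is the mechanism behind
length independence. The vector passes through dropout, a ReLU
fully-connected layer, a second affine layer, and a sigmoid that outputs
the binding probability.

Assumptions worth stating: binding signal is assumed to be expressible from
the peptide sequence alone (no MHC protein features); one model per allele
(no pan-allele parameter sharing); the final-state summary assumes the
recurrences can carry anchor information across the peptide, which holds at
peptide scale (8–25 residues).

## Dataset conventions

* Dichotomization: binder ⇔ IC50 < 500 nM; 500 nM itself is a non-binder.
* Standardized affinity: `1 − log(IC50)/log(50000)` (base-invariant;
  natural log used), clamped to [0, 1] for IC50 outside [1, 50000] nM so
  soft targets remain valid for cross-entropy.
* Curation, within an (allele, sequence) group: identical IC50s collapse to
  one record; differing IC50s remove the whole group; cross-allele repeats
  are kept (separate predictors per allele). Records with non-canonical
  residues (X, B, Z, U, …) are dropped and counted — the 20-letter encoding
  has no column for them. Curation is idempotent.
* Fold assignment: label-stratified shuffled k-fold (scikit-learn
  `StratifiedKFold`) under an explicit seed; a round-robin fallback handles
  strata smaller than k (with a warning). Fold sizes per stratum differ by
  at most one.

## Tunable parameters

| parameter | default | notes |
|---|---|---|
| hidden size / direction | 64 | concatenated encoding = 128 |
| fully-connected bottleneck | 32 | 128 → 32 → 1 |
| dropout rate | 0.8, read as **keep** probability | dropping 80% of a 128-unit encoding would be destructive; the complementary reading is available via `dropout_rate_is_keep_prob = false` |
| dropout placement | between biLSTM vector and first FC layer | training mode only; inference is deterministic |
| learning rate | 1e−4 (Adam) | |
| loss | binary cross-entropy | hard labels by default; `target_mode = affinity` trains against standardized affinity |
| classification threshold | 0.5 | the standardized-500 nM value (≈ 0.4256) is used automatically in soft-target mode; stored in the model file |
| epochs / batch / early stop | 100 / 64 / patience 10 on a 10% validation split | all recorded in the model archive |
| substitution matrix | BLOSUM62 | any Biopython built-in or NCBI-format file |

## Numerical choices

* All arithmetic is float64. Gradients (backpropagation through time,
  including the dropout mask and the kernel-bank layer) are closed-form and
  verified against central finite differences in the test suite.
* Variable-length batches are padded and masked: at padded positions the
  recurrent state is carried unchanged, making per-peptide outputs
  invariant to batch composition (tested to ≤ 1e−5; observed ≈ 1e−16).
* LSTM weights initialize Uniform(±1/√H) with forget-gate bias +1; the
  head uses Glorot-uniform limits. BCE clamps probabilities at 1e−12.
* Confusion matrices count `score ≥ threshold` as a predicted positive.
  Any metric with a zero denominator is reported as NA (never coerced to
  0), including F1 when precision + sensitivity = 0 and AUC/AUPR when a
  class is absent. Presentation rounding is half-up at 3 decimals; full
  precision is kept internally.
* AUC is the Mann–Whitney rank statistic with midranks (ties credit 1/2);
  AUPR is the descending-score step sweep with tie groups processed
  atomically, so an all-tied score vector scores the positive prevalence.
  Both are cross-checked against scikit-learn and against exhaustive pair
  counting / hand-computed step curves in the tests.

## Synthetic benchmark generator

The generator emulates allele-specific binding data: anchor positions
(default: position 2 and the C-terminus, the classic class-I pockets) carry
preferred residues in binders, planted with probability `1 − e^(−strength)`;
remaining positions are background (uniform by default). Lengths are drawn
from class-appropriate distributions — class I weights 8:0.10, 9:0.60,
10:0.20, 11:0.10 (9-mer-dominated, as in real class-I data), class II over
13–20. IC50 is lognormal (sd 0.5 log-units) around
`500·e^∓(0.5 + strength·n_matched)` nM, so labels derived by
dichotomization carry sequence-independent noise: with the default noise
scale, about 16% of motif-free peptides drawn as non-binders still land
below 500 nM. Negative anchor indices count from the C-terminus so a single
motif applies across lengths. Exact duplicates and conflicting-IC50 pairs
are injected at configurable Bernoulli rates to exercise the curation
rules.

What it does *not* emulate: real allele chemistry, position couplings,
length-dependent anchor shifts, assay batch effects, or database-scale
class imbalance. Passing the recovery benchmarks therefore demonstrates
that the pipeline can learn planted positional preferences from noisy
variable-length data — not that it matches any published per-allele
accuracy on real extracts.

## Benchmark experiments and problem sizes

`mhclstm.benchmarks` fixes the recovery experiments: strong-motif five-fold
CV at n = 2000, strength 3.0, 60 training epochs (pooled AUC 0.906–0.920
across seeds, against a label-noise ceiling of ≈ 0.93 for this generator);
null-generator CV at n = 2000 (AUC ≈ 0.5; 40 epochs, since the chance-level
outcome does not depend on training length); and a strength sweep
{0, 1, 3} × 3 seeds at n = 800 with a single 75/25 held-out split and 12
epochs. These sizes keep the full benchmark suite in the minutes range on
one CPU while leaving the conclusions unchanged at larger n.

## Known limitations

* Training is single-threaded NumPy; database-scale datasets (10⁵ peptides
  per allele) would need hours, not minutes.
* The comparison threshold used by published tools for their confusion
  counts is not always recoverable; worked examples therefore reconstruct
  confusion matrices from printed class counts and sensitivity/specificity
  rather than re-running those tools.
* Soft-target mode shares the sigmoid head with hard-label mode; it is a
  calibration convenience, not a regression model of IC50.
* Motif comparison requires length-stratified inputs; pooling across
  lengths is deliberately not defaulted because column alignment across
  lengths is ill-defined.
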