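# Methods

`hitgen` implements a de novo hit-generation framework for a protein
target (the motivating case is USP7 inhibition in oncology): a
recurrent SMILES language model proposes molecules, a recurrent
attention-equipped regressor predicts their inhibitory potency
(pIC50), and the generator is fine-tuned by policy gradient against a
self-adaptive weighted sum of potency and synthetic-accessibility
rewards. This note records the model, the numerical choices, and what
the synthetic benchmark does and does not demonstrate.

## Neural-network substrate

All networks run on `hitgen.nn`, a compact reverse-mode automatic
differentiation core over NumPy arrays with fused LSTM/GRU sequence
kernels (hand-derived backpropagation through time, one large input
projection per layer). Gradient correctness is established by central
finite differences in the test suite. Recurrent weight blocks use
orthogonal initialization per gate; input blocks use Glorot uniform.
Heavy training runs use float32 arithmetic (`nn.default_dtype`);
closed-form unit tests run in float64. Optional sequence masks hold
recurrent state constant across padded steps so batch composition
cannot change a molecule's representation (verified by a
batch-equals-single-item prediction test).

## Generator

Embedding → two stacked LSTM layers → softmax dense head over a fixed
chemistry-aware token vocabulary (multi-character tokens: `Cl`, `Br`,
bracket atoms, `@@`, `%nn` ring closures; greedy longest-match
tokenizer). Pretraining is teacher-forced next-token prediction under
categorical cross-entropy, averaged per token then per sequence.
Sampling is autoregressive with logits divided by a softmax
temperature before normalization; generation stops at EOS or the
length cap (sequences hitting the cap are kept and judged by the
validity oracle). Temperature 0 reduces to greedy argmax decoding.

Default pretraining recipe (desk scale): batch 128, Adam with
gradient-norm clipping at 5, staged learning rate 2.5e-3 (30 epochs) →
1e-3 (15) → 5e-4 (10). On the 2,000-molecule synthetic corpus this
reaches a per-token loss close to the corpus entropy floor and ≥ 90 %
syntactic validity of 500 samples at temperature 0.8.

## Predictor

Ten configurations (A–J) pair descriptors with architectures:
ECFP4/ECFP6/RDKit path fingerprints feed a feed-forward network; raw
SMILES feed GRU stacks (unidirectional, bidirectional, bidirectional +
stacked, or two separated directional streams), optionally pooled by
additive attention. The default (configuration I) is embedding →
bidirectional GRU → GRU → attention pool → dropout 0.3 → linear
output. Reference widths are embedding 256 and 128 recurrent units;
the desk-scale defaults used by the workflows module are 48/48, which
recover the synthetic signal in seconds per epoch.

Attention: a dense alignment layer scores each hidden state against a
learned output query, scores pass through tanh and a masked softmax,
and the context vector is the weight-averaged hidden state sequence
(α ≥ 0, Σα = 1 by construction). The tanh bound means attention
ratios cannot exceed e² between positions; this is an accepted
property of the additive form. The "separated bidirectional"
configuration (J) admits more than one reading; it is realized here as
independently attention-pooled forward and backward streams whose
context vectors are concatenated.

Labels are standardized as z = (y − median)/IQR with linearly
interpolated (type-7) quartiles; the transform is inverted for
reporting so predictions are in pIC50 units. Training: Adam, ≤ 50
epochs, early stopping with patience 15 and best-checkpoint
restoration, five shuffled 85/15 train/validation splits for
cross-validation, and a 10 % hold-out carved off before any training.
Duplicate molecules are collapsed on canonical SMILES before splitting
so folds cannot leak. Metrics: MSE, RMSE, Q² = 1 − SSres/SStot, and
Lin's concordance correlation coefficient. Fine-tuning on a focused
subset continues training at 0.1× the base learning rate with the
label scaler frozen.

## Rewards and self-adaptive scalarization

Each property maps onto [0, 1] through a clipped logistic: pIC50
rises 0→1 across [4, 9]; SAS falls 1→0 across [1, 6] (SAS is the
fragment-contribution/complexity synthetic-accessibility score, 1 =
easy to 10 = practically impossible; computed with RDKit's
contributed scorer). The logistic scale is set so the curve reaches
0.01/0.99 at the saturation points, with hard clipping outside.
Invalid molecules receive reward 0 on both objectives — without this
the policy gradient has no pressure to stay syntactically valid.

The scalar reward is f = w₁·r₁ + w₂·r₂ with w₁ + w₂ = 1, initial
weights (0.6, 0.4) favoring potency. After each batch the weights
adapt: if one weighted objective dominates while the other objective's
batch-mean reward has plateaued — variation ratio (max−min)/max over
the last five batch means below 0.05 — the dominant weight is
decremented by the step and the other incremented, then clipped and
re-coupled to the simplex. The (max−min)/max variation-ratio formula
is the package's convention; a std/mean (coefficient of variation)
alternative is available via configuration. The update step defaults
to 0.05; 0.1 is also a supported choice. A numerical tie guard (|w₁f₁ − w₂f₂| ≤ 1e-9 treated as
equality) prevents floating-point oscillation at the exact-balance
fixed point where the exact-arithmetic rule extinguishes.

## REINFORCE optimization

Each sampled SMILES is one episode; its tokens are the actions and the
scalarized reward is terminal. Per-step returns follow
R_t = Σ_k γ^k r_{t+k+1} (γ defaults to 1, undiscounted — terminal-only
rewards make discounting a pure length penalty, which we do not want).
The surrogate loss
−(1/B) Σ_molecules Σ_t γ^t R_t ln π(A_t|S_t) is minimized with Adam
(gradient clipping at norm 5), realizing the policy-gradient ascent.
The weight update runs once per batch, before the gradient step.
Vanilla REINFORCE is the default; the desk-scale driver enables an
exponential moving-average baseline (decay 0.9) for variance
reduction, which changes no expected gradient direction. Correctness
is anchored by two bandit oracles: exact agreement (≤ 1e-4 relative)
between the enumerated score-function gradient and a finite-difference
derivative of expected reward, and convergence of a 3-armed bandit to
the best arm.

The framework's standard operating point is softmax temperature 0.80
during optimization, initial weights (0.6, 0.4), weight step 0.05 and
90 epochs at full scale; the desk-scale runs use 30 epochs with batch
64, which already saturate the shaped rewards on the synthetic task.

## Hit selection

Pareto partition (maximize pIC50, minimize SAS) uses weak dominance
with at least one strict inequality; exact ties on both axes are all
retained. The production path is an O(n log n) sort-and-sweep,
verified against the O(n²) pairwise oracle. Stereoisomer expansion
enumerates assignments of unassigned tetrahedral centers and double
bonds (≤ 2^c isomers for c centers, with duplicate/meso collapse),
ranks isomers by predicted pIC50 (descending, stable), and reports SAS
alongside rather than folding it into a composite score — the
affinity/synthesizability trade-off is left to the analyst.
Similarity uses ECFP4 Tanimoto plus an MCS Tanimoto on atom counts,
t_mcs = |MCS| / (|A| + |B| − |MCS|), with element matching and
order-compatible bonds (single matches aromatic) and a 10 s timeout
per pair reported as missing. Attention atom maps project token
weights onto atoms: atom tokens keep their weight, non-atom tokens
split theirs between the nearest preceding and following atom tokens.

## Evaluation metrics

Validity, uniqueness (distinct canonical / valid) and novelty
(distinct not in corpus / distinct) follow the standard
distribution-learning benchmark definitions. Internal diversity is
1 − mean pairwise ECFP4 Tanimoto; external diversity is 1 − mean
nearest-reference-neighbor similarity. The KLD score computes
per-descriptor KL divergence (sample‖reference, direction fixed and
tested) over MW, logP, Bertz complexity, fraction sp³ carbons, ring
count, aromatic-ring count, heavy-atom count and H-bond donors —
histograms with 50 equal-width bins over the reference's 0.1–99.9
percentile span for continuous descriptors, categorical for discrete —
aggregated as mean(exp(−KL)); the mean-KL alternative is exposed. The
Fréchet ChemNet Distance field is present but null: it requires an
externally trained reference network whose weights are not part of
this package.

## Synthetic data

The fixture generator decorates five drug-like scaffold templates
(benzamide, anilide, aryl sulfonamide, aryl urea, aryloxy-acetamide)
with substituent fragments, guaranteeing valid SMILES inside the MW
200–600 g/mol and logP −2–6 corpus bands; about two thirds of the
molecules carry at least one unassigned stereocenter. The affinity
oracle is linear in substructure counts — a·(N atoms) + b·(aromatic
rings) − c·(halogens) + d·(amides), defaults (0.5, 0.4, 0.3, 0.6) —
affinely rescaled to span pIC50 4–10, plus Gaussian noise (sd 0.3
pIC50 units) truncated to the band. The default table has 1,453 rows,
matching the scale of the kind of augmented target-affinity set the
framework is designed for.

Because the signal is substructure-linear, recovery is achievable by
construction and attention has a known ground truth (nitrogen tokens
for a nitrogen-count label). Passing these checks demonstrates that
the machinery — tokenization, recurrent regression, attention,
policy-gradient optimization, selection — works end to end; it does
not demonstrate performance on real bioactivity data, whose
structure–activity landscape is nonlinear, noisier, and far more
diverse than five decorated scaffolds. Novelty and diversity numbers
on the fixture corpus are likewise bounded by the small combinatorial
library and are not comparable to values obtained on a
million-molecule corpus.

## Problem sizes and determinism

Desk-scale defaults: 2,000-molecule corpus, 55 pretraining epochs,
1,453-row affinity table, 30 RL epochs with batch 64, 200–500-molecule
evaluation samples. Every stochastic step (initialization, shuffling,
sampling, noise) is driven by an explicit integer seed; identical
seeds reproduce identical outputs bit-for-bit on a fixed platform.
Checkpoints are NumPy archives with an embedded JSON header (config,
vocabulary, label scaler).

## Known limitations

- The autodiff core is single-threaded NumPy; full-scale
  (million-molecule, 128–256-unit) training is out of reach — the
  package targets method correctness and desk-scale studies.
- Reward shapes are fixed logistics; per-batch min-max normalization
  was rejected because it makes rewards non-stationary across batches.
- MCS similarity can time out on large molecules (reported as missing).
- No docking stage: binding-pose validation requires external
  proprietary software and is out of scope.
- Configuration J's "separated bidirectional" realization is an
  interpretation (flagged above).
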