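# Methods

## Problem and model

The package treats drug-combination synergy as a regression problem: a trio
(drug A, drug B, cell line) carries a continuous score — a Loewe-additivity
value computed from a four-parameter sigmoid dose-response
(R_min, R_max, midpoint dose m > 0, shape λ > 0) evaluated at the combined
dose, or a Bliss-derived ComboScore, the sum over a concentration grid of
observed minus expected growth fractions. Both label functions are
implemented in `synergy_scores` and are used by the synthetic generator and
the command-line `score` tool; the model itself is agnostic to which score
the labels came from.

The predictor is a three-branch network. Each branch (fingerprint-specific
subnetwork, FSN) consumes one fingerprint view of the drug pair — MACCS
keys, hashed topological torsions, or MinHashed atom pairs — together with
the cell line's expression and mutation vectors. Within a branch, drugs
share one convolutional encoder (both inputs are the same fingerprint kind,
and sharing halves the parameter count); expression and mutation each get
their own encoder of the same architecture. The four encoded views are
stacked into a 4 × D tensor and fused by two Permute-MLP blocks — a
residual MLP along the feature axis, a transpose, a residual MLP along the
view axis, and a transpose back — so information mixes across both channels
and views without attention or graph structure. A flatten-project-GELU-
project pipeline produces the branch's synergy feature, a two-layer head
its scalar score, and the model prediction is the arithmetic mean of the
three branch scores. Training minimizes the MSE of the averaged prediction.

Assumptions worth stating explicitly: fingerprints are treated as plain 0/1
sequences whose *positions* are meaningful only through what the
convolution can learn locally; the pair is *ordered* at the input level
(stack rows drug-i, drug-j) and no symmetry is enforced — an optional
training flag (`TrainConfig.augment_swap`) adds the swapped copy of every
training pair as a soft symmetrization; cell lines are fully described by
the two profile vectors.

## Parameters and defaults

| parameter | default | notes |
|---|---|---|
| HashTT / MAP4 length | 1024 bits | common toolkit default; configurable (≥ 64) |
| MACCS length | 166 | fixed; the toolkit's unused leading bit is dropped |
| conv channels | (8, 16, 32) | three layers, GELU after each |
| kernel width h | 3 | smallest nontrivial window; any width works with the padding rule below |
| feature width D | 128 | encoder output and fusion feature width |
| projection hidden D̂ | 512 | fusion projection bottleneck |
| synergy feature D̃ | 128 | head input width |
| head hidden | 64 | D̃ / 2 |
| Permute-MLP blocks | 2 | fixed by the fusion design |
| views N | 4 | drug i, drug j, expression, mutation — fixed |
| LayerNorm ε | 1e-5 | |
| optimizer | Adam, lr 1e-3, batch 128 | up to 200 epochs, early stopping patience 20 on an inner 10% validation split |
| parameter dtype | float32 | float64 available (used by the gradient-check tests) |

The training schedule favours a larger learning rate and fewer epochs than
a GPU-era default because the backend is pure NumPy on CPU; every value is
a `TrainConfig`/`ModelConfig` field and is recorded in the checkpoint's
JSON sidecar.

## Numerical and design choices

* **Convolution padding.** The feature map keeps length L at every layer:
  stride 1 with zero padding of (h−1)/2 on the left and h/2 on the right,
  so the flatten-projection input is always L·32.
* **R².** The coefficient of determination is computed as 1 − SSE/SST (the
  universally comparable definition). Identical prediction and label
  vectors short-circuit the Pearson correlation to exactly 1.0, avoiding a
  one-ulp sqrt artifact.
* **ComboScore sign.** Observed minus expected, summed; a boolean mask can
  exclude unmeasured grid cells (real HTS grids are ragged).
* **MACCS.** RDKit emits 167 bits with bit 0 conventionally unused; bit 0
  is dropped to give the canonical 166-bit string.
* **MAP4.** The reference construction (circular substructures of radius 1
  and 2 around each atom of a pair, joined with the topological distance,
  MinHashed) natively yields an integer signature. To feed the same binary
  convolutional pathway as the other fingerprints, the signature is folded
  modulo `dims` into presence/absence buckets. MinHash permutations are
  affine maps over a 61-bit prime field drawn once from a fixed internal
  seed, so the fingerprint is identical across runs and processes.
* **HashTT** is used as a binary (not count) vector, matching the other
  views. Molecules with fewer than 4 heavy atoms have no torsion path and
  produce an all-zero vector plus a `DegenerateMoleculeWarning`.
* **Salts.** Multi-fragment SMILES keep the largest fragment (by heavy-atom
  count) before canonicalization.
* **Expression normalization** is a per-gene z-score fit on the training
  matrix only (train/apply separation prevents leakage); sd-0 genes map to
  0. Gene panels are sorted sets, so feature positions are a pure function
  of the panel.
* **Noise operators.** Multiplicative x·N(1, σ) and additive x + N(0, σ)
  noise, i.i.d. per entry. A master seed spawns one substream per cell-line
  row, so extending the panel never changes existing draws. Mutation
  vectors are noised as real vectors (no re-binarization) — the robustness
  study perturbs both profiles.
* **Splits.** Leave-cell-out partitions the *cell-line set*; leave-
  combination-out partitions the set of *unordered* drug pairs, so both
  orderings of a pair share a fold. Duplicate trio rows (either ordering)
  are deduplicated by score averaging with a warning. The 90/10 hold-out is
  simple seeded sampling, not stratified.
* **Aggregation.** Cross-validation reports the mean of per-fold metrics
  and additionally pooled-prediction metrics.
* **Ablations** (`run_ablation`) score each variant on a seeded 80/20
  random split rather than full 5-fold CV — a desk-scale analogue; full CV
  is available through `run_cv` with a variant config. Fingerprint-subset
  variants average the remaining heads; `wo_permute_mlp` feeds the raw
  stack's flatten directly into the projection; `permutedds_L` replaces
  every convolutional encoder with an affine-GELU-affine stack of matched
  output width.
* **Noise study protocol.** For each σ the model is retrained on noisy
  profiles (same seed) and its predictions on a common clean test split are
  Pearson-correlated with the noiseless-trained model's. At σ = 0 the
  trainings are bit-identical, so the correlation is exactly 1. The σ grid
  is a required argument; no default grid is asserted.
* **Autograd.** The in-package reverse-mode engine covers exactly the ops
  the network needs; every vector-Jacobian product and the assembled FSN
  are checked against central finite differences (relative error < 1e-4 in
  float64). Checkpoints restore bit-identical predictions.
* **Biases.** The fusion equations are written without bias terms; linear
  layers nevertheless carry biases initialized to zero (harmless at
  initialization, useful capacity later). With residual-branch weights and
  biases zeroed, LayerNorm of the zero vector is zero and each Permute-MLP
  block is the exact identity — a property the tests assert bit-for-bit.
* **Initialization** is fan-in uniform U(±1/√fan_in) from a seeded PCG64
  stream; a model is a pure function of its config (including the seed).

## Synthetic data: what it does and does not show

The generator emulates a combination screen at desk scale. Drugs are drawn
from a packaged vocabulary of 62 hand-curated, RDKit-validated small
molecules (each ≥ 4 heavy atoms with at least one torsion path, so no
fingerprint view is degenerate). Cell lines get i.i.d. N(0,1) expression
and Bernoulli(0.1) mutations over synthetic gene symbols. Labels are a
planted function — drug main effects ⟨u, f_i + f_j⟩, cell effects
⟨v, e_c⟩, and pair interactions ⟨r, f_i ⊙ f_j⟩ on MACCS vectors — whose
noiseless value is standardized to mean 0 / sd 20 (the magnitude range of
real synergy scores) before adding N(0, σ_label²) noise. Standardizing the
signal *before* adding noise keeps σ_label interpretable against the fixed
score scale; with the default σ_label = 5 the attainable test correlation
is ≈ 0.97. Labels are symmetric in the drug order by construction.

Default study conditions: 20 drugs, 10 cells, 500 records, σ_label = 5,
64 expression and 64 mutation genes (a desk-scale panel chosen once;
real screens use hundreds of landmark genes, which the same code handles).

What passing tests show: the architecture can represent and recover a
structured signal through all three fingerprint views; the protocol
(splits, metrics, hold-outs) is leak-free; the noise study behaves as
designed. What they do not show: performance on real screens — synthetic
expression has no covariance structure, the planted function is far simpler
than biology, the drug vocabulary is tiny, and chemically similar drugs do
not imply similar effects the way a learned model would need to exploit.

## Problem sizes used by the automated checks

The acceptance script and system tests run the default model (about 10 M
parameters) at the default synthetic conditions: overfit capacity on 64
trios (stopping once the epoch loss is below 0.2% of the initial MSE),
planted-signal recovery on an 80/20 split with a 15-epoch schedule, and the
noise study on a 200-record subset with an 8-epoch schedule at
σ ∈ {0, 1}. These sizes were chosen as the smallest at which the studied
effects are unambiguous.

## Known limitations

* No GPU path; training scales to thousands of records, not the 10^5-row
  real screens (the vectorized unique-entity encoding helps only while the
  drug/cell panels are small relative to the batch).
* The MAP4 folding is a faithful but non-standard binarization; bit values
  are not comparable with the reference MinHash signature implementation.
* Dose-response fitting (estimating R_min, R_max, m, λ from raw viability)
  is out of scope; the Loewe score assumes the parameters are given.
* One-hot cell descriptors are provided for the descriptor-sensitivity
  experiment but the default pipeline always uses expression + mutation.
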