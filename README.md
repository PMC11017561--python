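# permutedds

Regression of anti-cancer **drug-drug synergy** from molecular fingerprints
and cell-line omics, built around a permutable feature-fusion network.

High-throughput combination screens (e.g. the O'Neil and NCI-ALMANAC
panels) label each *(drug A, drug B, cell line)* trio with a continuous
synergy score — a Loewe-additivity score or the Bliss-derived ComboScore.
The combinatorial space of pairs × cell lines is far too large to screen
exhaustively, so the practical question is: given fingerprints of two drugs
and the molecular profile of a cell line, predict the synergy score of the
untested trio. This package is aimed at computational chemists and
bioinformaticians who want such a model plus its full evaluation protocol —
entity-held-out cross-validation, ablations, robustness analysis — runnable
offline on synthetic or their own data.

## Model

Each drug is encoded three ways: MACCS keys (166 predefined structural
bits), hashed topological torsions (4-heavy-atom paths, 1024 bits) and
MinHashed atom pairs with radius-1/2 circular substructures (1024 bits). A
cell line contributes a z-scored expression vector X_e and a binary
mutation vector X_m over fixed gene panels.

One **fingerprint-specific subnetwork** (FSN) per fingerprint kind:

1. a shared three-layer 1-D convolutional encoder (channels 8 → 16 → 32,
   GELU, stride 1, length-preserving) followed by flatten and an affine
   projection maps each drug's fingerprint X_d ∈ R^{L×1} to Z_d ∈ R^D;
   two analogous encoders map X_e and X_m to Z_e, Z_m;
2. the four views are stacked into H = Stack(Z_di, Z_dj, Z_e, Z_m) ∈ R^{N×D},
   N = 4;
3. two **Permute-MLP blocks** fuse the views. Each block applies a residual
   MLP along the feature axis,
   Ĥ = H + LN(Swish(H W¹_D) W²_D),
   transposes (the N-D permutation), applies a residual MLP along the view
   axis, H̄ = Ĥᵀ + LN(Swish(Ĥᵀ W¹_N) W²_N), and transposes back;
4. flatten, affine to D̂, GELU, affine to D̃ gives the synergy feature M_d,
   and a two-layer GELU head yields a scalar ŷ_d.

The model prediction is the average of the three heads,
ŷ = (ŷ_t + ŷ_p + ŷ_s)/3, trained with mean squared error. Evaluation
follows the screen protocol: a 90/10 independent hold-out, then 5-fold CV
under three split strategies (random, leave-cell-out,
leave-combination-out), scored by RMSE, R² = 1 − SSE/SST and Pearson r.

The network runs on a small NumPy reverse-mode autodiff engine included in
the package (`permutedds.autograd`), verified against finite differences in
the test suite; no deep-learning framework is required.

## Worked example

Train on a synthetic benchmark with planted structure (drug main effects,
cell-line effects and pair interactions on an sd-20 synergy scale, label
noise sd 5):

```python
from permutedds import (
    SyntheticConfig, FeatureStore, TrainConfig, SynergyRecord,
    featurize_drug_table, normalize_expression, train_model,
    compute_metrics, holdout_split,
)
from permutedds import experiments as ex
from permutedds import synthetic_data as sd

cfg = SyntheticConfig(n_drugs=12, n_cells=6, n_records=200, seed=0)
drugs = sd.generate_drugs(cfg.n_drugs, cfg.seed)
expr, mut, panel = sd.generate_cell_panel(cfg.n_cells, cfg.g_expr, cfg.g_mut, cfg.seed + 1)
fps = featurize_drug_table(drugs)
trios = sd.generate_trios(cfg.n_records, [d for d, _ in drugs], list(expr.index), cfg.seed + 2)
scores = sd.generate_labels(trios, fps, expr, cfg)
records = [SynergyRecord(a, b, c, float(s)) for (a, b, c), s in zip(trios, scores)]

store = FeatureStore(fps, normalize_expression(expr, expr), mut)
train, test = holdout_split(records, frac=0.2, seed=0)
model, log = train_model(train, store, store.model_config(),
                         TrainConfig(max_epochs=15, val_frac=0.0), seed=0)
frame = ex.predict_records(model, test, store)
report = compute_metrics(frame["y_true"], frame["y_hat"])
print(f"test RMSE {report.rmse:.2f}  R2 {report.r2:.3f}  PCC {report.pcc:.3f}")
print(frame.head(3).round(2).to_string(index=False))
```

Output:

```
test RMSE 5.77  R2 0.926  PCC 0.970
drug_a drug_b cell_line  y_true  y_hat   y_t   y_p   y_s
  D007   D010     CL001   21.51  11.32 -9.13 20.02 23.07
  D005   D010     CL002   21.33  16.66 -8.55 17.49 41.03
  D006   D011     CL002   11.55  12.60 -3.55 20.35 21.00
```

The model recovers most of the planted signal on held-out trios (PCC 0.97
against a noise ceiling of ≈0.97 at label-noise sd 5 on an sd-20 scale);
`y_t`, `y_p`, `y_s` are the per-fingerprint head scores whose average is
`y_hat`.

A `permutedds` console command exposes the same pipeline from the shell
(`simulate`, `featurize`, `score`, `split`, `train`, `evaluate`, `ablate`,
`noise-study`, `rank`); run `permutedds --help`.

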