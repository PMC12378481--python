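# dam — dynamic-aware modelling of longitudinal liquid biopsies

Predicting whether a gastric-cancer patient will respond to treatment
(RECIST CR/PR = responder, SD/PD = non-responder) from **longitudinal
liquid-biopsy data**: per-visit crops of tumor-related aneuploid cells
(circulating tumor cells, CTCs, and circulating endothelial cells,
CECs, imaged as multi-channel fluorescence composites) together with a
six-marker serum panel (AFP, CEA, CA19-9, CA72-4, CA125, NSE). The two
streams are sampled on *different, irregular* time grids — patients
have 1–5 visits per modality (median 3), and cell draws rarely
coincide with marker draws.

The package is for computational researchers who want to study this
class of model end-to-end: it ships a seeded synthetic-cohort
generator that emulates the data's statistical structure, so every
component can be exercised without access to clinical data.

## The model

Five components operate on a patient record `x = ({(t_i, {I_ij})},
{(s_k, m_k)})` of time-stamped cell-image sets and marker panels:

1. **Cellular aggregator** — an 18-layer residual CNN maps each crop
   `I_ij` to a feature vector; a learnable aggregation token attends
   over the cell set of each visit (permutation-invariant set
   pooling); continuous sinusoidal encodings of `t_i` (days since
   baseline) are added and a self-attention stage refines the sequence
   across visits.
2. **Tumor-marker aggregator** — `log1p` + z-scored panels pass a
   two-layer perceptron, then the same two-stage attention recipe.
3. **Temporal interaction module (TIM)** — cross-attention with the
   cellular sequence as queries and the marker sequence as keys/values
   aligns the mismatched grids; the attended marker context is added
   residually, preserving the cellular time axis.
4. **Temporal aggregator** — a learnable patient token plus four
   stacked self-attention layers collapse the fused sequence into one
   patient vector.
5. **Predictor** — a three-layer MLP (`D → D/2 → D/4 → 2`) with
   softmax gives `P(responder)`.

Training follows the study protocol: stratified 17/91-style test
holdout, threefold cross-validation (three models, ensembled by mean
probability), class-weighted cross-entropy, per-step **dynamic
longitudinal elimination** (each modality independently thinned to a
random 80% of its timepoints — a data-level dropout that teaches the
model to predict from partial follow-up). Evaluation always uses full
sequences; AUC comes with stratified-bootstrap 95% CIs. Ablation
variants (`tci_only`, `tm_only`, `concat`, `sum`), a gradient-boosted
cell-counting baseline, windowed early-prediction evaluation
(≤45 d/3 m/6 m/1 y/all), Grad-CAM focus-area statistics
(AvgFA/VarFA/MinFA/MaxFA/MedFA/DisFA) and permutation importance are
included. All neural components run on a small NumPy reverse-mode
autodiff core (`dam.nn`) — no deep-learning framework required.

## Worked example

```python
from dam import DynamicAwareModel, SynthConfig, generate_cohort

cohort = generate_cohort(SynthConfig(n_patients=90, image_size=32,
                                     effect_size=2.0, seed=11))
from dam.encoders import ModelConfig
from dam.training import TrainConfig
res = DynamicAwareModel(
    cohort, mode="tim",
    model_config=ModelConfig(embed_dim=32, n_heads=4, cnn_width=8,
                             marker_hidden=32, seed=5),
    train_config=TrainConfig(epochs=30, seed=5, image_out_size=32),
).fit()
print(res.summary())
```

prints (exact numbers for these seeds):

```
Dynamic-aware treatment-response model
======================================================
mode: tim    patients: 90    embed dim: 32
folds: F1: n=25, F2: n=23, F3: n=25, test: n=17
------------------------------------------------------
val AUC F1: 0.851  (95% CI 0.675-0.974)
val AUC F2: 0.885  (95% CI 0.708-1.000)
val AUC F3: 0.812  (95% CI 0.623-0.968)
CV AUC: 0.849 ± 0.030
test AUC (ensemble): 0.871  (95% CI 0.671-1.000, n=17)
```

The synthetic cohort carries its response signal **only in the
dynamics** (responders' nuclei shrink and marker levels fall over
treatment; baselines are label-independent), so the cell-counting
baseline hovers near chance while the dynamic model recovers the
signal — the package-level analogue of the headline claim that dynamic
modelling beats baseline counting. `res.windowed()` reports the
early-prediction AUC ladder and `res.baseline()` the counting
comparator under the identical split.

A thin CLI mirrors the library: `dam simulate`, `dam segment`,
`dam train`, `dam evaluate`, `dam baseline`, `dam interpret`.

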