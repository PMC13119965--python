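# histofuse

Self-supervised feature fusion, mRMR selection and graph-attention
classification for histopathology-style image data.

## The problem

Histopathology classification (e.g. lung adenocarcinoma vs. squamous cell
carcinoma vs. normal tissue on H&E-stained slides) typically has few labeled
patients, strong class imbalance, and patient-level correlation between
images. `histofuse` implements a full pipeline for this setting:

1. **Feature extraction** — a compact CNN (three 3×3/32-filter conv blocks,
   max-pool to 112×112, two 64-filter blocks, max-pool to 56×56, a 128-filter
   tail, global average pooling) maps each 224×224 RGB image to a 128-d
   feature vector.
2. **Self-supervised refinement** — three complementary heads, trained on the
   training split only with Gaussian-noise augmentation (σ = 0.05):
   * *SimCLR*: NT-Xent contrastive loss
     L_ij = −log [exp(sim(z_i,z_j)/T) / Σ_{k≠i} exp(sim(z_i,z_k)/T)], T = 0.5;
   * *BYOL*: an online projector + predictor regresses onto a target network
     updated only by EMA, ε ← τε + (1−τ)θ with τ = 0.99; the loss is
     ‖q/‖q‖ − z′/‖z′‖‖² = 2 − 2·cos(q, z′);
   * *DeepCluster*: alternating k-means pseudo-labels (k = 10) and
     cross-entropy training of an encoder + cluster head.
3. **Fusion + selection** — the three 128-d outputs are concatenated (384
   columns) and filtered by greedy **mRMR**: maximize mutual-information
   relevance I(f; c) while penalizing mean redundancy I(f; s) over the
   selected set — quotient form (MIQ, default) or difference form (MID) —
   keeping the top 100 columns (fit on train, applied to every split).
4. **Graph classification** — samples become nodes of a top-K (K = 15) cosine
   similarity graph (same-class training edges get a small additive cohesion
   boost before neighbor selection); a two-layer graph-attention network
   (2 heads × 128 → 256, then 1 head → 64, batch-norm, dropout 0.4, affine
   readout) is trained with focal loss −α(1−p_t)^γ log p_t (α = 1, γ = 2),
   Adam (lr = 0.003), and early stopping (patience 35) on validation
   **balanced accuracy** — the mean of per-class recalls.

Splits are patient-aware and stratified (70/15/15): all images from one
patient stay in one partition. Evaluation includes group-aware stratified
5-fold cross-validation, paired t-tests between pipelines, and
class-separability diagnostics (Fisher ratio, silhouette, t-SNE).

All neural components run on a small NumPy reverse-mode autodiff engine
shipped with the package, so there is no deep-learning framework
dependency; training is CPU-sized and bit-reproducible from a single seed.

A synthetic-data module generates both H&E-like images (pink stroma, purple
elliptical nuclei whose density/elongation/tint vary by class) and
Gaussian-mixture feature tables with informative, redundant and pure-noise
columns, so the whole pipeline is testable without external data. Adapters
read the standard image-folder layout (`<root>/<class>/<img>.png` plus an
optional `manifest.csv` with patient IDs) used by public H&E datasets.

## Worked example

```python
import histofuse as hf
from histofuse.pipeline import PipelineConfig, run_feature_variant, split_features

fm = hf.gen_features(hf.SyntheticFeatureSpec(
    n_per_class=60, n_classes=3, d_informative=20, d_redundant=60,
    d_noise=304, class_sep=3.0, seed=1))
cfg = PipelineConfig(seed=1, variant="fused_mrmr",
                     ssl=hf.SSLConfig(epochs=30),
                     vgcn=hf.VGCNConfig(epochs=100))
train, val, test = split_features(fm, cfg)
res = run_feature_variant(train, val, test, cfg)
m = res["metrics"]
print("splits:", train.n, val.n, test.n)
print(f"test BAC: {m.bac:.4f}")
print(m.confusion_matrix)
```

Output:

```
splits: 120 30 30
test BAC: 1.0000
[[10  0  0]
 [ 0 10  0]
 [ 0  0 10]]
```

The 384 fused self-supervised columns are reduced to 100 by mRMR; on this
separable three-class mixture the graph-attention classifier then labels
every held-out sample correctly (balanced accuracy 1.0 — the mean of the
three per-class recalls on the diagonal confusion matrix). The `plain`
variant (raw features straight into the classifier, no refinement or
selection) scores lower on the same splits because its cosine graph is built
over 304 noise columns.

## Command line

```bash
histofuse simulate --images --out data/imgs --n-per-class 20 --side 64
histofuse run-all --input data/imgs --out runs/full --seed 7 --toy
histofuse run-all --input features.csv --out runs/plain --variant plain
histofuse grid-search --input features.csv --out runs/grid --toy
histofuse cross-validate --input features.csv --out cv.json --k 5
```

Every stage is also exposed as its own subcommand (`train-extractor`,
`extract`, `refine`, `select`, `build-graph`, `train-vgcn`, `evaluate`),
composable through the documented CSV/JSON/TSV artifacts. Ablation variants:
`plain`, `simclr`, `deepcluster`, `byol`, `fused`, `fused_mrmr`.

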