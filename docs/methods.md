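# Methods

## Pipeline model

`histofuse` classifies labeled images (or precomputed feature tables) by
composing five stages, each fit strictly on the training partition and then
applied unchanged to validation and test data:

CNN features → per-branch self-supervised refinement → concatenation →
mRMR selection → per-split cosine top-K graph → two-layer graph-attention
classifier.

The guiding assumptions are (a) a compact 128-d representation per image is
sufficient for tissue-class discrimination; (b) contrastive (SimCLR),
bootstrap (BYOL) and clustering (DeepCluster) objectives learn complementary
views of that representation, so their concatenation is richer than any one
of them; (c) mutual-information-based selection can strip the redundant and
uninformative columns the fusion introduces; and (d) sample-to-sample
similarity carries label information that neighborhood attention can
exploit.

## Numerical substrate

No deep-learning framework is used. All networks run on a small tape-based
reverse-mode autodiff engine over NumPy float64 arrays
(`histofuse._autodiff`): broadcasting arithmetic, matmul, rectifiers, axis
reductions, gathers (which also implement convolution via im2col indices),
segment sums (which implement neighborhood softmax attention) and 2×2 max
pooling. Gradients of every op are verified against central differences;
float64 makes the loss closed forms exact to ~1e-12 and training
bit-reproducible from a seed on any platform. Adam (β₁ = 0.9, β₂ = 0.999,
ε = 1e-8) is the only optimizer.

## Defaults that matter

| parameter | default | notes |
|---|---|---|
| input side | 224 px | images resized, [0,1] range |
| CNN widths | 32,32,32 / 64,64 / 128 tail | spatial funnel 224→112→56→28 |
| feature dim | 128 | penultimate dense layer, post-ReLU |
| CNN training | Adam lr 1e-3, batch 32, 100 epochs, cross-entropy | |
| SSL dims | 128→128→128 | input/hidden/output of all heads |
| SSL training | Adam lr 1e-3, 100 epochs, Gaussian noise σ 0.05, two views | train split only |
| SimCLR T | 0.5 | NT-Xent temperature; per-anchor losses averaged over 2N |
| BYOL τ | 0.99 | EMA decay; target never receives gradients |
| DeepCluster k | 10 | k-means++ seeding, per-epoch re-assignment |
| mRMR | MIQ, m = 100, 10 equal-frequency bins, ε = 1e-12 | fit on train |
| graph | top-K 15, cohesion boost +0.05 (clipped at 1), union symmetrization | boost before neighbor selection, train graph only |
| GAT | 2 heads×128 concat → 256, then 1 head → 64; dropout 0.4; LeakyReLU 0.2 | affine readout 64 → classes |
| classifier loss | focal, α 1, γ 2 | γ = 0 reduces exactly to cross-entropy |
| training | Adam lr 0.003, ≤100 epochs, patience 35 on validation balanced accuracy | best-epoch weights *and* batch-norm statistics restored |
| splits | 70/15/15, stratified, group(patient)-aware | greedy relative-deficit assignment of whole groups |
| grid search | lr {1e-4,3e-4,5e-4,1e-3,3e-3} × K {5,10,15,20,25,30} | validation BAC, ties → first in scan order |

## Design choices where the design was open

* **CNN tail.** The funnel is completed past 56×56×64 with one 128-filter
  conv block + pool, global average pooling, a 128-unit dense feature layer
  (ReLU) and a softmax head. Features are read from the 128-unit layer
  post-activation so the refinement heads see the advertised 128 inputs.
* **SSL heads consume 128-d features, not raw images.** The refinement
  stage is a feature-space operation; its augmentation is additive Gaussian
  noise rather than image transforms.
* **BYOL refine map** is the online projector output (not the predictor);
  the target's batch-norm runs with frozen evaluation-mode statistics,
  copied from the online network at each EMA step.
* **DeepCluster k-means**: Lloyd's algorithm with k-means++ seeding from the
  module RNG; an emptied cluster is re-seeded to the farthest point;
  assignment ties break to the lowest centroid index. The per-iteration
  objective is non-increasing by construction and is cross-checked against
  scikit-learn's KMeans on blob data in the tests.
* **mRMR forms.** The incremental greedy algorithm implements both the
  quotient (MIQ) and difference (MID) objectives; MIQ is the default. The
  MI estimator is the plug-in formula on 10 equal-frequency bins; it is
  positively biased at small n (≈(B−1)²/2n nats for two continuous
  variables), which is why desk-scale selection fixtures use a few hundred
  samples.
* **Attention formulation.** Additive attention per head
  (e_ij = LeakyReLU(a_l·Wh_i + a_r·Wh_j) over j ∈ N(i)∪{i}, softmax over the
  neighborhood) with exponentiated scores multiplied by the edge weight
  before normalization, so the cohesion-boosted weights influence the
  message passing. Negative cosine weights are floored at zero in this
  product; the unit self-loop keeps every denominator positive. A plain
  graph-convolution layer (symmetric or row-stochastic normalization) is
  retained for ablation.
* **Per-split graphs.** Train, validation and test each get their own graph;
  no edges cross splits, so evaluation is leakage-free and the classifier is
  applied inductively. The cohesion boost is added to same-class
  similarities of the training graph *before* top-K selection, so it shapes
  topology, not just weights.
* **Early stopping** tracks validation balanced accuracy, and restoring the
  best epoch restores batch-norm running statistics along with the weights —
  restoring weights alone pairs early parameters with late normalization
  statistics and silently corrupts inference.
* **Stage seeding.** One global seed determines every stage seed through
  SHA-256 of `"{seed}:{stage}"` (mod 2³¹), so any stage can be re-run in
  isolation, reproducibly.

## Synthetic data

The image generator paints an eosin-pink background with hematoxylin-purple
elliptical nuclei; class identity controls nuclear areal density (the
`blob_density` fraction of tile area), elongation, and a background tint.
Nuclei are rejection-sampled to avoid overlap, so connected-component
counting is a valid oracle for density. Synthetic patients own
`images_per_patient` consecutive tiles and never straddle classes.

The feature-table generator draws class centroids so the expected pairwise
class separation per informative column is `class_sep` within-class SDs
(within-class SD 1), adds redundant columns as affine images of informative
ones plus N(0, σ²) noise, and pure N(0,1) noise columns.

What this does *not* emulate: stain variability, scanner/domain shift,
magnification mixtures, spatial correlation inside a slide, label noise, or
non-Gaussian within-class structure. Passing tests therefore demonstrate
correctness of the pipeline's mechanics and the *direction* of its ablation
effects under controlled conditions — not clinical-grade accuracy on real
slides.

## Desk-scale study conditions

Tests and the acceptance script run the post-extraction pipeline on tables
of 60 samples per class × 3 classes (20 informative / 60 redundant / 304
noise columns, class separation 3), with the self-supervised heads trained
for 30 epochs and the classifier for up to 100; CNN training tests use the
halved-width toy profile (side 64, widths 16/16/16 + 32/32, tail 64). These
sizes keep a full multi-seed comparison to a few CPU-minutes while leaving
every split larger than the graph's K, so the top-K graph is never complete.
Ablation comparisons are reported as medians over 5 seeds.

## Known limitations

* The plug-in MI estimator's small-sample bias can reorder near-tied mRMR
  candidates; rankings are exactly reproducible but not bias-corrected.
* The cohesion boost makes training-graph neighborhoods much purer than
  validation/test neighborhoods (a train/test topology shift inherent to
  boosting only where labels exist); large boosts can hurt generalization.
* Single-initialization k-means may land in local optima on unstructured
  data; DeepCluster re-seeds every epoch, which mitigates but does not
  eliminate this.
* The NumPy engine is single-process and CPU-bound; it is sized for
  hundreds-to-thousands of samples and toy-scale CNNs, not for
  slide-archive-scale training.
* With coarse patient groups, the greedy splitter trades exact 70/15/15
  fractions for the hard constraint that no patient straddles partitions.
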