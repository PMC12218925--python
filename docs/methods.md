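# Methods

This note documents the models implemented in `cytohgnn`, the choices
made where the design was genuinely open, what the synthetic fixtures
emulate, and the known limitations.

## Feature-extraction backbone

The backbone is a 17-layer compound-scaled CNN: a 3×3 stride-2 stem
(32 channels), fifteen mobile-inverted-bottleneck (MBConv) blocks, and a
1×1 head convolution to 2304 channels, followed by global average
pooling. The stage layout is

| layers | kind | kernel | stage stride | channels | expansion |
|---|---|---|---|---|---|
| 1 | stem conv | 3 | 2 | 32 | – |
| 2 | MBConv | 3 | 1 | 16 | 1 |
| 3–4 | MBConv | 3 | 2 | 24 | 6 |
| 5–6 | MBConv | 5 | 2 | 40 | 6 |
| 7–9 | MBConv | 3 | 2 | 80 | 6 |
| 10–12 | MBConv | 5 | 1 | 112 | 6 |
| 13–16 | MBConv | 5 | 2 | 192 | 6 |
| 17 | head conv | 1 | 1 | 2304 | – |

Within a stage only the first block carries the stage stride. This table
is a reconstruction constrained by the published facts (exactly 17
layers, MBConv internals, a 2304-dimensional GAP output) and follows the
standard stage pattern of the compound-scaling model family; it is not
guaranteed to be the original authors' exact network.

Conventions and open choices, fixed as follows:

- **Compound scaling.** The table above is the network at the default
  compound coefficient (φ = 1). φ scales the input resolution
  (`base_resolution · γ^φ`, rounded to the nearest multiple of 32 so all
  five stride-2 stages divide evenly: 224 · 1.15 = 257.6 → 256) and is
  reported through the depth/width multipliers α^φ and β^φ.
- **Sizing rules.** Same padding `(f−1)/2` for odd kernels; spatial
  output `ceil(n/s)` (so stride 1 preserves dimensions); the
  squeeze-excitation bottleneck has `max(1, floor(c_in/ω))` channels
  with ω = 4 applied to the block input channels; SE uses swish on the
  reduction and sigmoid gating on the expansion.
- **Batch normalisation.** `y = (x−μ)/√(σ²+δ)·γ + β` with δ = 1e−5,
  biased batch variance during training, running statistics
  (momentum 0.1) at inference. Feature extraction always runs in
  inference mode so a sample's feature vector does not depend on batch
  composition.
- **MBConv residuals** only when stride 1 and equal in/out channels.
- **Input normalisation**: per-channel scaling to [0, 1]; images are
  resized bilinearly to the input resolution. No dataset-mean
  subtraction, no augmentation, no pretrained weights — parameters are
  seeded He-normal draws.
- **Supervised fitting.** The package has no autodifferentiation
  framework; the backbone is used as a seeded random-projection feature
  extractor, and `fit` trains a temporary multinomial-logistic head on
  the (standardised) GAP features with Adam. The head is kept for
  inspection but excluded from exported features. Random convolutional
  features preserve the coarse colour/morphology statistics that the
  toy fixtures encode, which is what makes the end-to-end path testable
  at desk scale; on real stained imagery a trained trunk would be
  needed for competitive accuracy.

## Hypergraph construction

Samples are vertices. Each vertex contributes one hyperedge: itself plus
its k nearest neighbours by Euclidean distance (defaults: k = 10).
Including the centroid vertex guarantees every vertex degree is positive
and gives incidence columns of exactly k+1 entries. Weights are
initialised to 1. Distances are computed in double precision; neighbour
ties break by ascending vertex index, so construction is deterministic;
duplicate points (distance 0) rank first. All N hyperedges are kept even
when neighbour sets coincide. The incidence matrix is stored sparse
(CSR); the propagation operator

    P = Dv^(−1/2) H W De^(−1) Hᵀ Dv^(−1/2)

is symmetric, entrywise non-negative, has spectral radius ≤ 1, and fixes
Dv^(1/2)·1 (degree-weighted mass is conserved). These properties, and
entrywise agreement with a brute-force triple-loop evaluation, are
asserted in the test suite.

## Classifier

Two hypergraph convolutions `X' = σ(P X Θ)` (hidden width 32) each
followed by batch normalisation → ReLU → dropout 0.5, then a fully
connected softmax head: three learnable layers in total. Training is
transductive and full-batch: the loss is cross-entropy on the training
vertices only, optimised with Adam (lr 0.01, β₁ = 0.9, β₂ = 0.999,
ε = 1e−8) with weight decay 5e−4 applied as an L2 gradient term on the
three weight matrices (not on biases or batch-norm affine parameters)
for 200 epochs. The parameters of the epoch with the best validation
accuracy are retained; ties keep the earliest epoch. Batch normalisation
in the classifier is per-feature over vertices (the natural choice in a
full-batch transductive setting). Gradients are derived analytically and
checked against central finite differences (≤ 1e−4 relative error).

The **propagation ablation** replaces P by the identity in both
convolutions, preserving every width and training setting; on a k = 0
hypergraph (H = I) the two arms are exactly equivalent, which is tested.
The **GCN baseline** substitutes the symmetrically normalised kNN-graph
adjacency with self-loops, `D^(−1/2)(A+I)D^(−1/2)`, where A symmetrises
the directed kNN relation; widths, optimiser and protocol are shared so
reports are comparable row for row.

## Evaluation protocols and metrics

Stratified 70/15/15 hold-out and stratified 5-fold cross-validation with
an inner 20% validation split. Per-class counts use largest-remainder
rounding (deterministic, per-class deviation at most one sample; ties
favour train over val over test). Metrics are one-vs-rest per class —
specificity, precision, recall, F1 — with unweighted macro averages as
headline values, accuracy = trace/sum of the confusion matrix, and
one-vs-rest AUC by the tie-corrected Mann–Whitney rank statistic (the
independent cross-check in the tests is scikit-learn). Ratios with a
zero denominator are reported as 0 and flagged in the report rather than
silently dropped.

## Synthetic fixtures: what they emulate and what they do not

- **Gaussian clusters** place the C class means at mutually equal
  distance (a scaled simplex), `separation × noise_sd` apart, with
  isotropic noise. Defaults: 5 classes, 100 per class, 64 dimensions,
  separation 8 (essentially separable). They emulate the geometry of a
  well-trained feature extractor's output; they do not reproduce the
  anisotropy, heavy tails or manifold structure of real CNN features.
- **Ablation fixture.** Diffusion through the hypergraph helps only in
  the regime the method assumes: neighbourhoods that are locally
  class-coherent yet classes that still overlap. In a high-dimensional
  low-separation mixture (e.g. separation 3 in 64 dims) the noise radius
  (√dim · σ) swamps the mean separation, kNN purity falls toward
  chance, and propagation mixes classes — the opposite regime from
  trained cytology features, whose neighbour distances are tightly
  clustered. The ablation experiments therefore use separation 5 in 32
  dimensions (kNN purity ≈ 0.85, per-arm accuracy ≈ 0.95), where the
  paired comparison over 5 seeds shows the with-propagation arm at or
  slightly above the without-propagation arm.
- **Toy cell images** are ellipse cytoplasm + concentric nucleus with
  class-specific nucleus/cytoplasm area ratio (0.10 … 0.58, strictly
  increasing with class index), ellipse shape, stain hue, and additive
  Gaussian texture noise; 64×64 pixels, 20 per class by default.
  Class identity is recoverable from morphology by construction. They
  are not photorealistic cytology: no staining artifacts, overlapping
  cells, debris, or intra-class morphology variation. Passing the
  end-to-end test shows the plumbing and the learning dynamics are
  correct, not that the pipeline reaches any particular accuracy on
  real Pap-smear imagery.

## Numerical choices

- Classifier arithmetic in float64; backbone in float32 (im2col +
  einsum convolutions), features exported as float64.
- Softmax is max-shifted; log-probabilities are clamped at 1e−300
  (classifier) / 1e−12 (backbone head) before the log.
- Argmax prediction ties resolve to the lowest class index.
- Resolution rounding is half-up to the nearest multiple of 32.
- Problem sizes in the test suite (500-sample cluster tables, 100
  toy images, brute-force oracles at N ≤ 20) were chosen so the whole
  suite runs in about a minute on one CPU core.

## Known limitations

- The backbone trunk is not trained end-to-end (see above); `fit`
  optimises only the GAP head.
- The 17-layer table is a reconstruction; the original per-stage
  channel/repeat configuration is not published.
- Transductive training stores a dense-ish N×N operator product per
  epoch; the implementation targets N up to a few thousand vertices,
  not whole-slide-scale collections.
- Hyperedge weights are fixed at 1; learned or adaptive weights are out
  of scope.
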