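# cytohgnn

Multi-class classification of single-cell cytology images (Pap-smear
subtypes) by combining a **compound-scaled convolutional feature
extractor** with a **k-nearest-neighbour hypergraph neural network**.
The package is aimed at computational-pathology researchers who want a
fully reproducible, dependency-light reference implementation of this
pipeline — every stage runs on synthetic fixtures, so no external image
collection is required to build, test or study it.

## The method

**Feature extraction.** A 17-layer CNN (one stem convolution, fifteen
mobile-inverted-bottleneck blocks with squeeze-excitation and swish
activation, and a 1×1 head convolution) ends in global average pooling,
turning each RGB cell image into a 2304-dimensional feature vector. The
network's scale follows the compound-scaling rule

```
depth: d = α^φ,   width: w = β^φ,   resolution: r = γ^φ
```

with α = 1.2, β = 1.1, γ = 1.15, so at φ = 1 the network is 1.2× deeper
and 1.1× wider and operates on 1.15× larger inputs (224 → 256 pixels)
than the unscaled baseline.

**Classification.** Each sample is a vertex of a hypergraph; vertex *i*
spawns a hyperedge containing *i* and its *k* nearest neighbours under
Euclidean distance (incidence matrix **H**, unit hyperedge weights
**W**). With vertex degrees **Dv** and hyperedge degrees **De**, features
diffuse through the normalised operator

```
P = Dv^(−1/2) H W De^(−1) Hᵀ Dv^(−1/2)
```

in two hypergraph-convolution layers, `X' = σ(P X Θ)`, each followed by
batch normalisation, ReLU and dropout (0.5), then a softmax head (hidden
width 32). Training is transductive full-batch cross-entropy with Adam
(learning rate 0.01, weight decay 5·10⁻⁴, 200 epochs), keeping the
parameters of the best validation epoch. Setting `propagation=False`
replaces **P** with the identity — the ablation that isolates the
hypergraph's contribution — and a conventional GCN on the symmetrised
kNN graph (`D^(−1/2)(A+I)D^(−1/2)`) is provided as a pairwise baseline.

All neural components are implemented in numpy/scipy with analytic
gradients (finite-difference-checked in the test suite); there is no
deep-learning-framework dependency.

## Worked example

```python
import cytohgnn as c

# 5-class Gaussian feature clusters (overlapping: 5 sigma in 32 dims)
table = c.gen_feature_clusters(c.ClusterSpec(dim=32, class_mean_separation=5.0, seed=0))
plan = c.stratified_holdout(table.labels, seed=0)          # 70/15/15
model = c.HypergraphClassifier.from_feature_table(table, k=10)
result = model.fit(plan.train_idx, plan.val_idx)
print(result.summary())
print(result.evaluate(plan.test_idx).summary())
```

prints

```
HypergraphClassifier fit
==============================================
vertices:           500
input dim:          32
hidden dim:         32
classes:            5
propagation:        True
epochs:             200
...
best epoch:         10
best val accuracy:  0.9867
==============================================
Evaluation report
============================================================
                          specificity  precision  recall     f1
Dyskeratotic                   1.0000     1.0000  0.9333 0.9655
Koilocytotic                   0.9833     0.9375  1.0000 0.9677
Metaplastic                    0.9833     0.9333  0.9333 0.9333
Parabasal                      1.0000     1.0000  1.0000 1.0000
Superficial_intermediate       1.0000     1.0000  1.0000 1.0000
------------------------------------------------------------
macro: specificity=0.9933  precision=0.9742  recall=0.9733  f1=0.9733
accuracy: 0.9733
macro AUC: 0.9962
```

i.e. on 500 synthetic samples the model classifies the 75 held-out test
samples with 97.3% accuracy; the per-class rows are the one-vs-rest
specificity/precision/recall/F1 of each cytological subtype, and the
macro line is their unweighted mean. On well-separated clusters
(8 sigma) the same pipeline reaches 100% held-out accuracy, and the full
image path (toy cell images → CNN features → hypergraph → classifier)
reaches ≥ 0.93 on a 5 × 20 image fixture.

A command-line interface covers the same stages
(`cytohgnn synth-features | synth-images | extract-features |
build-hypergraph | train | evaluate | crossval | ablate | run`); see
`cytohgnn --help`.

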