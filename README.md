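# asgnn

Adaptive spatial graph neural networks for predicting spot-level gene
expression from histology-derived features.

Sequencing-based spatial transcriptomics (ST) profiles the transcriptome on
a barcoded spot array aligned to an H&E image, but remains expensive;
histology itself is cheap and routine. This package predicts the spatial
expression of a panel of highly expressed genes directly from per-spot
image feature vectors (nuclei-morphology statistics, pretrained-CNN
embeddings, or synthetic stand-ins), for computational biologists studying
tissue architecture — and, as a by-product of how it learns, detects
spatial domains (tumor, stroma, infiltrate, …) within each section.

## The model

Spots of one section form an 8-connected grid graph G = (X, E). A learned
linear projection W₀ maps image features to meta-features Z = XW₀, spots
are clustered by affinity propagation on the distance

d(n₁, n₂) = α‖z_{n₁} − z_{n₂}‖₂ + β·hops(n₁, n₂),

and every edge crossing a cluster boundary is pruned: E′ = {(n,m) ∈ E |
C_n = C_m}. A graph-convolutional regressor then passes messages only
within these putative spatial domains,

x_n^l = ReLU( Σ_{m:(m,n)∈E′} x_m^{l−1} W_l / √(deg n · deg m) ),

followed by a per-spot linear read-out, trained with the loss
MSE − λ·Σ_j PCC_j (per-gene Pearson correlation across spots). Because W₀
changes the pruned graph discontinuously, it is optimized by
smoothing-based variational updates of a Gaussian N(μ, σI) over vec(W₀):
sample S projections per meta-epoch, train the regressor for each, score
samples by F_s = max(−L_s + c, 0), and move (μ, σ) to the score-weighted
mean and variance. The clusters of the best sample's refined graphs double
as detected spatial domains, evaluated by adjusted Rand index (ARI)
against annotations; domains pooled across sections are grouped into
k-means prototype clusters on nuclei-type composition, with Wilcoxon
rank-sum marker genes and bootstrap stability scores.

See `docs/methods.md` for assumptions, defaults, and numerical details.

## Worked example

```python
import numpy as np
from asgnn import (SyntheticSpec, simulate_dataset, AdaptiveSpatialGNN,
                   GTNRegressor, evaluate_predictions, detect_domains)

sections = simulate_dataset(SyntheticSpec(seed=7))   # 15x15 grid, 3 domains
train, val, test = sections[:2], [sections[2]], sections[3]

model = AdaptiveSpatialGNN(lam=0.0, n_samples=8, meta_epochs=6, random_state=7)
model.fit(train, val)

baseline = GTNRegressor(lam=0.0, random_state=7)
baseline.fit(train, [s.graph for s in train], val, [s.graph for s in val])

adaptive = evaluate_predictions(model.predict(test), test.expression)
full = evaluate_predictions(baseline.predict(test, test.graph), test.expression)
domains = detect_domains(test, model._refinement_config(), mode="cc",
                         feature_source="meta", projection=model.projection_)

print(f"adaptive  held-out MSE {adaptive['mse']:.3f}  mean per-gene PCC {adaptive['pcc']:.3f}")
print(f"full graph held-out MSE {full['mse']:.3f}  mean per-gene PCC {full['pcc']:.3f}")
print(f"domain recovery ARI {domains.ari:.3f}")
```

Output:

```
adaptive  held-out MSE 0.238  mean per-gene PCC 0.782
full graph held-out MSE 0.278  mean per-gene PCC 0.749
domain recovery ARI 0.980
```

The adaptive model predicts the held-out section's expression better than
the same regressor on the full (unpruned) grid — pruning edges that cross
expression-domain boundaries stops message passing from smearing signal
across tissue compartments — and the connected components of its refined
graph, hierarchically merged, recover the planted domains almost exactly
(ARI 0.98; 1.0 would be perfect agreement).

The same workflow is available from the shell via the `asgnn` CLI
(`simulate`, `preprocess`, `train`, `predict`, `evaluate`, `domains`,
`prototypes`); every run writes a config snapshot and master seed that
reproduce it byte-for-byte.

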