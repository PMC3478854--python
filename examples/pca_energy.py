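"""Energy-based PCA selection on the hybrid descriptor.

Extracts features from a small synthetic dataset, standardizes them,
fits PCA, and shows how many leading components are needed to hold 95%
of the total variance.
"""

import numpy as np

from fruitvision import pipeline, reduction, synthetic

ds = synthetic.generate_dataset(synthetic.preset("color6"), 6, seed=2, size=160)
X = pipeline.compute_features(ds.images, None, pipeline.PipelineConfig(seed=2))

model = reduction.fit_reduction(X, energy=0.95)
cum = np.cumsum(model.pca.explained)

print("cumulative explained variance (%):")
for k in (1, 2, 5, 10, model.k, 30):
    if k <= len(cum):
        print(f"  {k:3d} components: {100 * cum[k - 1]:6.2f}")
print(f"\nselected k at 95% energy: {model.k} of {X.shape[1]} features")
print("\nEach transformed sample keeps only these k scores; the held-out")
print("data of a cross-validation fold is projected with the training fit.")
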