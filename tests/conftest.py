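import numpy as np
import pytest

from fruitvision import evaluation, pipeline, synthetic


@pytest.fixture(scope="session")
def color6_dataset():
    """The six-class color preset at its study size (20 images per class)."""
    return synthetic.generate_dataset(synthetic.preset("color6"), 20, 7)


@pytest.fixture(scope="session")
def color6_features(color6_dataset):
    """End-to-end features of the color6 dataset (own segmentation)."""
    X = pipeline.compute_features(
        color6_dataset.images, None, pipeline.PipelineConfig(seed=7)
    )
    return X, color6_dataset.labels


@pytest.fixture(scope="session")
def color6_cv_plan(color6_dataset):
    return evaluation.stratified_kfold(color6_dataset.labels, K=5, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
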