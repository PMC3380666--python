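import numpy as np
import pytest

from gaborseg.dataset import LabeledDataset, split_dataset
from gaborseg.features import PixelFeatureMatrix, standardize
from gaborseg.phantom import PhantomConfig, generate_benchmark_set
from gaborseg.pipeline import RunConfig, _build_dataset


SMALL_PHANTOM = PhantomConfig(height=128, width=128)


def make_free_dataset(X, y, split=None):
    """LabeledDataset around a free-form (layout-unconstrained) matrix."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    fm = PixelFeatureMatrix(
        features=X, coords=np.column_stack([np.arange(n), np.zeros(n, dtype=int)]),
        image_ids=np.array([f"p{i}" for i in range(n)], dtype=object), layout=None,
    )
    return LabeledDataset(features=fm, labels=np.asarray(y, dtype=int), split=split)


@pytest.fixture(scope="session")
def bench4():
    """Four 128×128 phantoms shared across tests."""
    return generate_benchmark_set(4, SMALL_PHANTOM, seed=7)


@pytest.fixture(scope="session")
def small_cfg():
    return RunConfig(phantom=SMALL_PHANTOM, n_images=4, n_vessel=900, n_nonvessel=900,
                     seed=7, segment_images=False)


@pytest.fixture(scope="session")
def small_splits(bench4, small_cfg):
    """Standardized train/val/test partitions from the 4-phantom benchmark."""
    ds = _build_dataset(bench4, small_cfg)
    ds = split_dataset(ds, seed=3)
    train, val, test = (ds.partition(p) for p in ("train", "val", "test"))
    train.features, stats = standardize(train.features, "fit")
    val.features, _ = standardize(val.features, stats)
    test.features, _ = standardize(test.features, stats)
    return train, val, test
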