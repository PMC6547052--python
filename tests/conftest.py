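import numpy as np
import pytest

from easymklfs.io_data import FeatureSource, LabeledDataset, assemble_dataset
from easymklfs import synthetic


def make_dataset(X, y, *, n_image_cols=None, age=None):
    """Wrap a raw matrix as a LabeledDataset, splitting columns into an
    image block and a clinical block (all-image by default)."""
    X = np.asarray(X, dtype=float)
    m = X.shape[1]
    if n_image_cols is None:
        n_image_cols = m
    blocks = []
    if n_image_cols > 0:
        blocks.append(
            (
                X[:, :n_image_cols],
                FeatureSource("img", "image", (0, n_image_cols)),
            )
        )
    if m - n_image_cols > 0:
        blocks.append(
            (
                X[:, n_image_cols:],
                FeatureSource(
                    "clin",
                    "clinical",
                    (0, m - n_image_cols),
                    column_names=[f"c{i}" for i in range(m - n_image_cols)],
                ),
            )
        )
    return assemble_dataset(blocks, y, age=age)


@pytest.fixture
def separable_toy():
    """Two features: column 0 separates the classes, column 1 is noise."""
    rng = np.random.default_rng(7)
    n = 20
    y = np.array([1] * (n // 2) + [-1] * (n // 2))
    x_sig = y * 2.0 + rng.normal(0, 0.1, n)
    x_noise = rng.normal(0, 1.0, n)
    return make_dataset(np.column_stack([x_sig, x_noise]), y)


@pytest.fixture(scope="session")
def planted_synth():
    """Small planted-signal study reused across tests (seeded)."""
    spec = synthetic.SimulationSpec(
        n_per_class=20, grid_dims=(8, 8, 8), n_clinical=10,
        n_informative_clinical=2, seed=11,
    )
    return synthetic.generate(spec)


@pytest.fixture
def random_dataset():
    def _make(n=15, m=40, seed=0, n_image_cols=None):
        rng = np.random.default_rng(seed)
        y = np.array([1] * (n // 2) + [-1] * (n - n // 2))
        X = rng.standard_normal((n, m))
        return make_dataset(X, y, n_image_cols=n_image_cols)

    return _make
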