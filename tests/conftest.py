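import warnings

import numpy as np
import pytest

from rhythmmap.gtm import GTM
from rhythmmap.synthetic import BlobSpec, simulate_feature_blobs


def random_gtm_results(seed, n=40, d=3, grid=(4, 4), rbf=(2, 2), max_iter=30):
    """Small fitted GTM on random Gaussian data (helper, not a fixture)."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, d))
    X = (X - X.mean(0)) / X.std(0)
    model = GTM(X, grid_shape=grid, rbf_shape=rbf)
    return model.fit(max_iter=max_iter)


@pytest.fixture(scope="session")
def blob_default_fit():
    """Study-configuration GTM fitted to the default 5-blob fixture."""
    table, labels = simulate_feature_blobs(BlobSpec(n_clusters=5))
    feats = [c for c in table.columns if c.startswith("f")]
    X = table[feats].to_numpy()
    X = (X - X.mean(0)) / X.std(0)
    results = GTM(X, grid_shape=(8, 8), rbf_shape=(3, 3), width=0.8, alpha=1.0).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        results.attach_magnification()
    return results, labels
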