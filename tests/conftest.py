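import numpy as np
import pandas as pd
import pytest

from mcrkin.dataset import SpectralDataset


def make_dataset(wavenumbers, absorbance, **meta):
    """Small SpectralDataset with auto-filled metadata."""
    absorbance = np.atleast_2d(np.asarray(absorbance, dtype=float))
    n = absorbance.shape[0]
    defaults = {
        "sample_id": [f"s{i}" for i in range(n)],
        "material_kind": ["substance"] * n,
        "age_months": [0.0] * n,
    }
    defaults.update(meta)
    return SpectralDataset(np.asarray(wavenumbers, float), absorbance,
                           pd.DataFrame(defaults))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_ds():
    """3 samples x 5 wavenumbers with replicate structure."""
    wn = np.array([4000.0, 4500.0, 5000.0, 5500.0, 6000.0])
    ab = np.arange(15, dtype=float).reshape(3, 5) / 10.0
    return make_dataset(
        wn, ab,
        sample_id=["a", "a", "b"],
        age_months=[3.0, 3.0, 7.0],
        batch=["B1", "B1", "B1"],
        replicate=[0, 1, 0],
    )
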