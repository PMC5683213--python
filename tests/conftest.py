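import numpy as np
import pandas as pd
import pytest

from fermspec import (
    AcquisitionConfig,
    default_library,
    default_profiles,
    synthesize_dataset,
)


@pytest.fixture(scope="session")
def library():
    return default_library()


@pytest.fixture(scope="session")
def profiles():
    return default_profiles()


@pytest.fixture(scope="session")
def hts_benchmark(library, profiles):
    """Default dry-film benchmark: full screening design, 666 raw spectra."""
    return synthesize_dataset(library, profiles, AcquisitionConfig.hts(seed=0))


@pytest.fixture(scope="session")
def atr_benchmark(library, profiles):
    """Default liquid-ATR benchmark (water bands included, no dilution)."""
    return synthesize_dataset(library, profiles, AcquisitionConfig.atr(seed=0))


@pytest.fixture()
def tiny_dataset():
    """A 6-spectrum, 2-sample dataset on a short uniform grid."""
    from fermspec import SpectralDataset

    grid = np.arange(1000.0, 1101.0, 10.0)
    rng = np.random.default_rng(7)
    absorbance = rng.uniform(0.1, 1.0, (6, grid.size))
    meta = pd.DataFrame(
        {
            "spectrum_id": [f"s{i}_t{t}" for i in (1, 2) for t in (1, 2, 3)],
            "sample_id": ["s1"] * 3 + ["s2"] * 3,
            "strain": ["A"] * 6,
            "temperature": [20.0] * 6,
            "day": [1] * 6,
            "well_replicate": [1] * 6,
            "technical_replicate": [1, 2, 3, 1, 2, 3],
            "sample_type": ["supernatant"] * 6,
        }
    )
    return SpectralDataset(grid=grid, absorbance=absorbance, metadata=meta)
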