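import numpy as np
import pytest

from hsiband import (
    BandSubset,
    LabeledDataset,
    SpectralGrid,
    SyntheticSceneSpec,
    generate_dataset,
    preprocess_dataset,
)


@pytest.fixture(scope="session")
def grid128() -> SpectralGrid:
    return SpectralGrid.linear(440.0, 902.0, 128)


@pytest.fixture(scope="session")
def small_scene() -> SyntheticSceneSpec:
    """Small max-contrast cohort: 3 patients, 80 px per class per patient."""
    return SyntheticSceneSpec(n_patients=3, pixels_per_class_per_patient=80, seed=42)


@pytest.fixture(scope="session")
def small_dataset(small_scene) -> LabeledDataset:
    return preprocess_dataset(generate_dataset(small_scene))


@pytest.fixture(scope="session")
def all_bands(small_dataset) -> BandSubset:
    return BandSubset(np.arange(small_dataset.n_bands), small_dataset.grid)
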