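import numpy as np
import pytest

from msiclust.lipid_annot import default_lipid_library
from msiclust.phantom import (
    NOISELESS,
    GroundTruth,
    Molecule,
    make_ground_truth,
    make_region_masks,
    render_dataset,
)


@pytest.fixture(scope="session")
def masks():
    """Standard 64×48 phantom geometry."""
    return make_region_masks(64, 48)


@pytest.fixture(scope="session")
def small_masks():
    """Small 32×24 geometry for fast rendering tests."""
    return make_region_masks(32, 24)


@pytest.fixture(scope="session")
def library():
    return default_lipid_library()


@pytest.fixture(scope="session")
def single_molecule_truth():
    """One PS(39:0) molecule, protonated, planted in the cerebellar cortex."""
    return GroundTruth(
        [Molecule("PS(39:0)", "III", ("[M+H]+",), 1000.0)], seed=0
    )


@pytest.fixture(scope="session")
def noiseless_dataset(small_masks, library):
    """Noiseless render of 12 molecules, one per archetype slot on average."""
    truth = make_ground_truth(12, None, library, seed=5)
    return truth, render_dataset(truth, small_masks, NOISELESS)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
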