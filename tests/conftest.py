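import numpy as np
import pytest

from hgtscan.model import MAMMAL, NON_MAMMAL, ChromSizes, SpeciesPanel


@pytest.fixture
def small_panel() -> SpeciesPanel:
    clades = {f"m{i}": MAMMAL for i in range(1, 11)}
    clades.update({f"nm{i}": NON_MAMMAL for i in range(1, 5)})
    return SpeciesPanel(clades)


@pytest.fixture
def toy_sizes() -> ChromSizes:
    return ChromSizes({"chr1": 50_000, "chr2": 50_000})


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
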