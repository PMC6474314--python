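import numpy as np
import pytest

from sedmix.profiles import DepthProfile, OtuTable
from sedmix.synthetic import ScenarioConfig


@pytest.fixture()
def toy_profile() -> DepthProfile:
    return DepthProfile(bin_top=[0, 1, 2], bin_bottom=[1, 2, 3],
                        value=[10.0, 5.0, 1.0], sigma=[1.0, 0.5, 0.1],
                        units="Bq kg-1")


@pytest.fixture()
def toy_otus() -> OtuTable:
    # 4 samples x 6 OTUs; otu_a..otu_c present everywhere, otu_d missing at depth
    counts = np.array([
        [50, 30, 10, 8, 2, 0],
        [40, 25, 15, 5, 0, 15],
        [20, 10, 30, 0, 1, 39],
        [10, 5, 45, 0, 0, 40],
    ])
    return OtuTable(
        counts=counts,
        otu_ids=("otu_a", "otu_b", "otu_c", "otu_d", "otu_e", "otu_f"),
        taxonomy=("Proteobacteria", "Proteobacteria", "Chloroflexi",
                  "Gammaproteobacteria", "unclassified", "Atribacteria"),
        sample_ids=("s3", "s7", "s20", "s50"),
        sample_depth=np.array([3.0, 7.0, 20.0, 50.0]),
    )


@pytest.fixture()
def scenario() -> ScenarioConfig:
    return ScenarioConfig(seed=7)


@pytest.fixture()
def sample_depths() -> np.ndarray:
    return np.arange(0.5, 50.0, 1.0)
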