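import numpy as np
import pandas as pd
import pytest

from edtia import synthetic


@pytest.fixture(scope="session")
def default_design():
    return synthetic.make_design()


@pytest.fixture(scope="session")
def small_design():
    """One region, two elevations, full nutrient gradient: 60 samples."""
    return synthetic.make_design({
        "regions": ({"name": "testreg", "elevations": (500, 100),
                     "sea_level_temp": 20.0},),
        "replicates": 3,
    })


@pytest.fixture(scope="session")
def library():
    return synthetic.gen_formula_library(200, seed=1)


@pytest.fixture(scope="session")
def strong_signal(default_design, library):
    """Full-design dataset with strongly planted molecule-taxon links."""
    effects = synthetic.PeakEffects(
        noise_sd=0.3, link_strength=1.2,
        n_consumer_links=10, n_producer_links=10,
        links_per_taxon=3, taxa_per_molecule=1,
    )
    peaks, gt = synthetic.gen_peak_table(default_design, library,
                                         effects=effects, seed=2)
    otus = synthetic.gen_otu_table(default_design, 100, coupling=gt,
                                   seed=3, coupling_strength=1.2)
    return peaks, otus, gt


@pytest.fixture
def rng():
    return np.random.default_rng(0)
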