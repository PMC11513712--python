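import numpy as np
import pytest

from moakit import synthdata as sd


@pytest.fixture
def dose_grid():
    """Seven-point geometric dose grid spanning 1/8x to 8x the EC50."""
    return np.geomspace(0.125, 8.0, 7)


@pytest.fixture
def flick_timepoints():
    return np.arange(0.0, 73.0, 3.0)


@pytest.fixture
def toy_screen():
    """Tiny noiseless screen: 4 genes x 4 guides + 4 non-targeting guides."""
    truth = sd.ScreenTruth(
        n_genes=4,
        n_nontargeting=4,
        depth=1000.0,
        dispersion=0.0,
        essential_fraction=0.0,
        death_modifier_genes={"GENE1": 2.0},
        seed=0,
    )
    library = sd.gen_crispr_library(truth)
    gcm = sd.gen_screen_counts(
        library, truth, sd.default_screen_samples(("drug",))
    )
    return truth, library, gcm
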