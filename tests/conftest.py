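import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from birdmix import (
    COEF_NAMES,
    ClassHyperparams,
    DesignSpec,
    URBAN_CLASSES,
    generate_design,
)


@pytest.fixture(scope="session")
def tiny_design():
    """2 blocks x 4 site types x 2 visits."""
    return generate_design(DesignSpec(n_blocks=2, n_visits=2,
                                      weed_block_dropout=0, seed=7))


@pytest.fixture(scope="session")
def small_design():
    """5 blocks x 4 site types x 3 visits with one weed-dropout block."""
    return generate_design(DesignSpec(n_blocks=5, n_visits=3,
                                      weed_block_dropout=1, seed=11))


@pytest.fixture
def flat_hyper():
    """Hyperparameters with all means 0 and sd 0.3."""
    return {
        c: ClassHyperparams(urban_class=c, mu={},
                            sigma={k: 0.3 for k in COEF_NAMES})
        for c in URBAN_CLASSES
    }


@pytest.fixture
def small_roster():
    rows = []
    for i, cls in enumerate(
            ["sensitive"] * 4 + ["adaptable"] * 3 + ["exploitative"] * 3):
        rows.append({"species_id": f"sp{i + 1:02d}", "urban_class": cls})
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)
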