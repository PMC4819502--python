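import numpy as np
import pandas as pd
import pytest

from rhizotransfer.simulate import (
    FieldDesign,
    SoilTruth,
    SpeciesProfile,
    default_design,
    default_profiles,
    default_soil_truth,
    generate,
)


def zero_noise_design(**kw) -> FieldDesign:
    base = dict(
        plant_noise_sd_delta=0.0,
        plant_noise_sd_n=0.0,
        block_sd_delta=0.0,
        block_sd_n=0.0,
        seed=0,
    )
    base.update(kw)
    return FieldDesign(**base)


def zero_noise_soil(**kw) -> SoilTruth:
    base = dict(soil_noise_sd_delta=0.0, soil_noise_sd_n=0.0)
    base.update(kw)
    return SoilTruth(**base)


def zero_noise_profiles():
    return [
        SpeciesProfile("LC", "constant", 0.47, d_ref_mean=4.0, d_ref_sd=0.0, n_ref_sd=0.0),
        SpeciesProfile("SG", "step_at_zero", 0.19, d_ref_mean=2.0, d_ref_sd=0.0, n_ref_sd=0.0),
        SpeciesProfile("AS", "none", 0.0, d_ref_mean=1.0, d_ref_sd=0.0, n_ref_sd=0.0),
    ]


@pytest.fixture
def noisefree_tables():
    """Plant/soil/truth tables generated with every noise source at zero."""
    return generate(zero_noise_design(), zero_noise_soil(), zero_noise_profiles())


@pytest.fixture
def noisy_tables():
    """One realisation at the default noise level."""
    rng = np.random.default_rng(42)
    return generate(default_design(), default_soil_truth(), default_profiles(), rng=rng)


@pytest.fixture
def plant_table_3rows():
    return pd.DataFrame(
        {
            "species": ["LC", "SG", "AS"],
            "block": [1, 1, 2],
            "distance": [0, 20, "REF"],
            "n_pct": [1.5, 1.2, 1.8],
            "d15n": [0.7, 1.9, 1.0],
        }
    )
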