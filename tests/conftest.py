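import numpy as np
import pytest

import canegait as cg


@pytest.fixture(scope="session")
def layout():
    return cg.load_default_layout()


@pytest.fixture(scope="session")
def clean_sim():
    """Noiseless 12-stride recording with one planted CoMZ maximum."""
    cfg = cg.GaitSimConfig(
        n_strides=12,
        noise_sd_fsr=0.0,
        noise_sd_kin=0.0,
        noise_sd_cane=0.0,
        planted_events=(cg.PlantedEvent("CoMZ", "max", 0.45),),
        seed=11,
    )
    return cfg, cg.simulate(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
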