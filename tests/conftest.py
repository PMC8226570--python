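import numpy as np
import pandas as pd
import pytest

from porinperm import GeneratorConfig, PoreModel, ScoringCoefficients


@pytest.fixture
def pore():
    return PoreModel(
        name="OmpF",
        v_pore=-30.0,
        e_pore=6.0,
        pore_area_mean=50.0,
        pore_area_sd=9.0,
    )


@pytest.fixture
def coefficients():
    return ScoringCoefficients(alpha=1.0, beta=-0.03, gamma=0.008, delta=0.0)


@pytest.fixture
def generator_config():
    return GeneratorConfig()


def random_descriptor_frame(n, seed=0):
    """Random but valid descriptor table in the canonical schema."""
    rng = np.random.default_rng(seed)
    total = rng.lognormal(np.log(9.0), 0.5, size=n)
    return pd.DataFrame(
        {
            "id": [f"c{i}" for i in range(n)],
            "net_charge": rng.integers(-2, 3, size=n),
            "total_dipole": total,
            "transversal_dipole": total * rng.beta(5, 2, size=n),
            "mpa_mean": rng.uniform(40, 75, size=n),
            "mpa_sd": rng.uniform(0.5, 4.0, size=n),
            "alogp": rng.normal(0.9, 1.1, size=n),
        }
    )
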