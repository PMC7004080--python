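import numpy as np
import pytest

from divmig import DemographicModelSpec, SimulationConfig


@pytest.fixture(scope="session")
def si_spec():
    return DemographicModelSpec("SI", nu1=1.0, nu2=1.0, T_s=1.0)


@pytest.fixture(scope="session")
def im_spec():
    return DemographicModelSpec("IM", nu1=1.0, nu2=1.0, M12=1.0, M21=1.0, T_s=0.5)


@pytest.fixture(scope="session")
def small_sim_config(si_spec):
    return SimulationConfig(
        model_spec=si_spec, n1=4, n2=4, num_snp_sites=300, num_loci=2,
        locus_length=60, theta_site=0.01, seed=123,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
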