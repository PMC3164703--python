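import numpy as np
import pytest

from melgrn.core import Genotype
from melgrn.dynamics import integrate
from melgrn.reference import reference_parameters
from melgrn.scenarios import run_panel


@pytest.fixture(scope="session")
def ref_params():
    return reference_parameters()


@pytest.fixture(scope="session")
def wt_traj(ref_params):
    """Wild-type full-model reference run at the default step."""
    return integrate("C", ref_params)


@pytest.fixture(scope="session")
def panel_coarse(ref_params):
    """Four-genotype panel at a coarser step (sufficient for metrics)."""
    return run_panel("C", ref_params, dt=0.02)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20110901)
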