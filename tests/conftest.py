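import numpy as np
import pytest
from hypothesis import settings

import spatialcircuits as sc

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def logistic():
    return sc.logistic_density()


@pytest.fixture(scope="session")
def xgrid():
    return np.linspace(0.0, 1.0, 1001)


@pytest.fixture(scope="session")
def case1_model():
    """Case I binding pair (large mRNA-like + ribosome-like species)."""
    return sc.CircuitModel(
        species=[sc.SpeciesSpec("E", r_rel=0.88), sc.SpeciesSpec("S", r_rel=0.44)],
        reactions=[sc.BindingReaction("E", "S", a=1.0, d=5.0, kappa=1.0)],
        productions={"E": sc.Production(alpha_bar=1.0), "S": sc.Production(alpha_bar=1.0)},
        epsilon=1e-2,
        name="case1-binding",
    )


@pytest.fixture(scope="session")
def txtl_pde_run():
    """One full transcription/translation PDE solve at eps=1e-3 (shared: it is
    the expensive fixture behind the model-reduction and field-profile checks)."""
    from spatialcircuits.circuits import TxTlParams, txtl_model

    p = TxTlParams()
    model = txtl_model(p)
    traj = sc.simulate_pde(model, grid=200, t_end=8.0)
    return p, model, traj
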