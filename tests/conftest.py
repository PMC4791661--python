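import numpy as np
import pytest

from oligorient.structures import (PentamerBlueprint, ReplicaEnsemble,
                                   build_ideal_pentamer, perturb_ensemble)


@pytest.fixture(scope="session")
def tm_blueprint():
    """Domain-II-only pentamer blueprint at the published mean TM tilt."""
    return PentamerBlueprint.tm_only(tau_deg=12.8)


@pytest.fixture(scope="session")
def full_blueprint():
    """Full-length pinwheel pentamer blueprint (TM + cytoplasmic helix)."""
    return PentamerBlueprint()


@pytest.fixture(scope="session")
def tm_pentamer(tm_blueprint):
    return build_ideal_pentamer(tm_blueprint)


@pytest.fixture(scope="session")
def full_pentamer(full_blueprint):
    return build_ideal_pentamer(full_blueprint)


@pytest.fixture(scope="session")
def perturbed_ensemble(tm_pentamer):
    """Two heterogeneous replicas of the TM pentamer (tilt + jitter noise)."""
    ens = ReplicaEnsemble(replicas=[tm_pentamer, tm_pentamer])
    return perturb_ensemble(ens, tilt_sigma=3.0, jitter_sigma=0.05, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
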