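import numpy as np
import pytest

from cranioscan.morphometrics import LandmarkConfig
from cranioscan.simulate import (SimConfig, simulate_genotypes_and_trait,
                                 simulate_resequencing_panel)


def make_config(coords, specimen_id="s1", breed="B", sex="M", view="merged",
                ids=None):
    coords = np.asarray(coords, float)
    ids = ids if ids is not None else range(1, len(coords) + 1)
    return LandmarkConfig(specimen_id, breed, sex, view,
                          {int(i): c for i, c in zip(ids, coords)})


def random_rotation(rng):
    Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    return Q


@pytest.fixture(scope="session")
def study():
    """One default synthetic study shared across tests (seed fixed)."""
    return simulate_genotypes_and_trait(SimConfig(seed=3))


@pytest.fixture(scope="session")
def panel():
    return simulate_resequencing_panel(SimConfig(seed=3))
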