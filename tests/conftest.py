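import numpy as np
import pytest

import dockoverlap as d


@pytest.fixture(scope="session")
def default_study():
    """The default 19-compound synthetic docking study (seed 42)."""
    return d.make_study()


@pytest.fixture(scope="session")
def default_features(default_study):
    """LDA features (overlap-with-reference, Eb) of the default study."""
    return d.study_features(default_study)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def random_pose(rng, n_atoms=10, id="pose", spread=2.0):
    """A random radius-assigned pose for estimator tests (not necessarily
    connected; volumes don't care)."""
    from dockoverlap.structures import AtomRecord, MoleculePose

    elements = ["C", "N", "O", "H", "Fe"]
    atoms = [
        AtomRecord(
            element=rng.choice(elements),
            position=rng.normal(0, spread, 3),
            radius=float(rng.uniform(1.2, 2.0)),
        )
        for _ in range(n_atoms)
    ]
    return MoleculePose(id=id, atoms=atoms)
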