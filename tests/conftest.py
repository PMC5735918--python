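import numpy as np
import pytest

from nmsgen.calculators import Calculator
from nmsgen.errors import SinglePointFailure
from nmsgen.sampling import SamplingSchedule
from nmsgen.toys import make_toy_library


class AlwaysFailsCalculator(Calculator):
    """Every single-point evaluation fails, like a hopeless SCF."""

    name = "always-fails"

    def supports(self, species):
        return True

    def evaluate(self, species, coordinates):
        raise SinglePointFailure("synthetic SCF failure")


@pytest.fixture(scope="session")
def library():
    return make_toy_library()


@pytest.fixture(scope="session")
def small_schedule():
    """Desk-scale schedule covering every toy's heavy-atom count."""
    return SamplingSchedule(rows={1: (3, 300.0), 2: (3, 300.0), 3: (3, 300.0)})


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def nms_dataset(tmp_path_factory):
    """A harmonic-surface NMS dataset (40 draws per dof) written once per session."""
    from nmsgen.toys import build_synthetic_dataset

    schedule = SamplingSchedule(rows={1: (40, 300.0), 2: (40, 300.0), 3: (40, 300.0)})
    path = tmp_path_factory.mktemp("data") / "nms.h5"
    summary = build_synthetic_dataset(path, seed=11, schedule=schedule)
    return path, summary


@pytest.fixture(scope="session")
def equilibrium_dataset(tmp_path_factory):
    from nmsgen.toys import make_equilibrium_only_dataset

    path = tmp_path_factory.mktemp("data") / "eq.h5"
    make_equilibrium_only_dataset(path)
    return path
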