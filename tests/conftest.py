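import numpy as np
import pytest

from bcaccum.dose import BeamConfig, compute_fraction_dose
from bcaccum.hu_red import apply_curve, build_curve
from bcaccum.synthetic import PhantomSpec, generate_fraction, generate_planning_phantom


@pytest.fixture(scope="session")
def spec():
    return PhantomSpec()


@pytest.fixture(scope="session")
def planning(spec):
    """Planning HU grid + labels (seed 11)."""
    return generate_planning_phantom(spec, seed=11)


@pytest.fixture(scope="session")
def curve():
    return build_curve()


@pytest.fixture(scope="session")
def beams():
    return BeamConfig()


@pytest.fixture(scope="session")
def planning_dose(planning, curve, beams):
    """Planning per-fraction dose, normalized to 2 Gy median PTV."""
    hu, labels = planning
    red = apply_curve(curve, hu)
    return compute_fraction_dose(red, beams, labels["ptv"])


@pytest.fixture(scope="session")
def fraction_plus30(spec):
    """A fraction anatomy with +30% bowel-gas volume."""
    return generate_fraction(spec, 30.0, seed=12)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
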