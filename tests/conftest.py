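import numpy as np
import pytest

from skiturn.dynamics import SkierSystem


@pytest.fixture(scope="session")
def system():
    return SkierSystem("reduced_planar")


@pytest.fixture(scope="session")
def fixture_turn(system):
    """The synthetic single-turn reference (shared; expensive to build)."""
    from skiturn.synthetic import generate_reference_turn

    return generate_reference_turn(system, seed=1)


@pytest.fixture(scope="session")
def crouch_state(system):
    """A statically balanced crouch state on the slope with glide velocity."""
    from skiturn.synthetic import ReferenceScheduler, TurnOverlay

    sched = ReferenceScheduler(system, TurnOverlay())
    return sched.initial_state()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
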