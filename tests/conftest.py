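import numpy as np
import pytest

from colomech import MaterialParameters, published_parameters


@pytest.fixture(scope="session")
def table3() -> MaterialParameters:
    """The packaged published coefficient set."""
    return published_parameters()


def random_parameters(rng: np.random.Generator) -> MaterialParameters:
    """A random but physically plausible coefficient set (Pa, degrees)."""
    return MaterialParameters(
        a1=rng.uniform(1e4, 5e5),
        a2=rng.uniform(-1e5, 1e5),
        a3=rng.uniform(-1e4, 1e4),
        c2=rng.uniform(-5e5, 5e5),
        c3=rng.uniform(-3e5, 3e5),
        c4=rng.uniform(-1e4, 1e4),
        e2=rng.uniform(-5e5, 5e5),
        e3=rng.uniform(-3e5, 3e5),
        e4=rng.uniform(-1e4, 1e4),
        beta1=rng.uniform(0.0, 180.0),
        beta2=rng.uniform(0.0, 180.0),
    )
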