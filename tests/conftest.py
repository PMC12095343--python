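import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def small_cfg():
    from sparrowalloc import OptimizerConfig

    return OptimizerConfig(pop_size=20, max_iter=50, seed=3)


@pytest.fixture
def sphere_problem():
    """Sphere objective on a symmetric 5-dimensional box."""
    from sparrowalloc import SearchSpace, make_test_objective

    return make_test_objective("sphere", 5), SearchSpace.symmetric(5, 10.0)


@pytest.fixture
def linear_problem():
    """A fixed 4-target linear allocation problem with a binding cap."""
    from sparrowalloc import AllocationProblem

    return AllocationProblem(
        efficiency=np.array([1.8, 1.2, 0.7, 0.5]),
        delta_sq=0.5,
    )
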