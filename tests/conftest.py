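import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import statebridge as sb

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def random_instance(rng: np.random.Generator, k: int, zero_frac: float = 0.0):
    """A random feasible bridge instance (pi, pi_target, Q) of size k.

    Q comes from a random initial law times a random kernel; optionally some
    kernel entries are zeroed (rows re-normalized) to exercise sparse support,
    with the target restricted to reachable states.
    """
    kernel = rng.dirichlet(np.ones(k), size=k)
    if zero_frac > 0:
        mask = rng.random((k, k)) < zero_frac
        mask[np.arange(k), rng.integers(0, k, k)] = False  # keep every row alive
        kernel[mask] = 0.0
        kernel = kernel / kernel.sum(axis=1, keepdims=True)
    pi = rng.dirichlet(np.ones(k))
    # target = column marginal of a random coupling absolutely continuous
    # w.r.t. Q with row marginals pi, so the instance is always feasible even
    # under sparse support
    weights = rng.lognormal(0.0, 1.0, size=k)
    tilted = kernel * weights[None, :]
    tilted = tilted / tilted.sum(axis=1, keepdims=True)
    tgt = pi @ tilted
    pi_v = sb.ProbabilityVector(pi)
    kernel_v = sb.TransitionMatrix(kernel)
    return pi_v, sb.ProbabilityVector(tgt), sb.uncontrolled_joint(pi_v, kernel_v, 1), kernel_v


@pytest.fixture(scope="session")
def planted_spec():
    """Default-size planted rest/easy/hard study (shared across tests)."""
    return sb.make_planted_hierarchy(k=8, seed=7)


@pytest.fixture(scope="session")
def planted_sequences(planted_spec):
    return sb.simulate_state_sequences(planted_spec)
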