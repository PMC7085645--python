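import numpy as np
import pytest

from olivesort.rce import NetworkProfile, RceNetwork


@pytest.fixture
def tiny_profile() -> NetworkProfile:
    """Small network for unit tests: 8-byte vectors, 4-neuron capacity."""
    return NetworkProfile("tiny", vector_len=8, max_neurons=4)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260923)


def make_random_network(rng, n_neurons, dim, n_categories=3,
                        min_if=2, max_if=400) -> RceNetwork:
    """Directly committed random neurons (bypasses the learn rule)."""
    from olivesort.rce import Neuron

    profile = NetworkProfile("rand", vector_len=dim, max_neurons=max(n_neurons, 1),
                             min_if=min_if, max_if=max_if)
    neurons = [
        Neuron(
            prototype=rng.integers(0, 256, size=dim),
            category=f"c{rng.integers(n_categories)}",
            aif=int(rng.integers(min_if, max_if + 1)),
            commit_index=i,
        )
        for i in range(n_neurons)
    ]
    return RceNetwork.from_neurons(profile, neurons)
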