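import random

import pytest

from recyclesim import SimulationConfig
from recyclesim.simulation import initialize_run


@pytest.fixture
def rng():
    return random.Random(12345)


@pytest.fixture
def base_config():
    """A small, fast configuration for unit scenarios."""
    return SimulationConfig(n_agents=5, seed=99)


class SequenceRng:
    """Deterministic stand-in for the run RNG in hand-built scenarios.

    ``random()`` yields the given values in order (cycling); integer
    draws delegate to a seeded real generator.
    """

    def __init__(self, values, seed=0):
        self.values = list(values)
        self.i = 0
        self._real = random.Random(seed)

    def random(self):
        v = self.values[self.i % len(self.values)]
        self.i += 1
        return v

    def randint(self, a, b):
        return self._real.randint(a, b)

    def randrange(self, n):
        return self._real.randrange(n)

    def shuffle(self, x):
        self._real.shuffle(x)


def make_state(config, hand=None, rng_values=None):
    """A run state with the first agent placed and an optional forced hand."""
    state = initialize_run(config)
    if hand is not None:
        state.active_agent.hand = list(hand)
    if rng_values is not None:
        state.rng = SequenceRng(rng_values)
    return state
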