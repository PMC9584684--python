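import numpy as np
import pytest

from slimeopt.benchmarks import make_classical_suite


class ScriptedRNG:
    """Stand-in RNG returning a scripted queue of arrays.

    Used to hand-trace update equations: each draw method pops the next
    scripted value (reshaped if needed) regardless of the requested
    distribution, so tests can force exact random values.
    """

    def __init__(self, values):
        self.queue = [np.asarray(v, dtype=float) for v in values]

    def _pop(self, shape):
        v = self.queue.pop(0)
        if shape is None:
            return float(v)
        return np.broadcast_to(v, shape).astype(float).copy()

    def random(self, size=None):
        return self._pop(size if size is None or isinstance(size, tuple) else (size,))

    def standard_normal(self, size=None):
        return self.random(size)

    def uniform(self, low=0.0, high=1.0, size=None):
        return self.random(size)

    def integers(self, low, high=None, size=None):
        v = self.queue.pop(0)
        if size is None:
            return int(v)
        return np.broadcast_to(v, size if isinstance(size, tuple) else (size,)).astype(int).copy()


@pytest.fixture(scope="session")
def suite():
    return make_classical_suite()


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
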