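import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def feasible_delta(p_a: float, p_b: float, rng, margin: float = 0.85) -> float:
    """A random LD coefficient inside the frequency-feasible range."""
    q_a, q_b = 1.0 - p_a, 1.0 - p_b
    hi = min(p_a * q_b, q_a * p_b)
    lo = -min(p_a * p_b, q_a * q_b)
    return float(rng.uniform(lo * margin, hi * margin))
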