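import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def finite_difference_grad(f, t, indices, eps=1e-6):
    """Central-difference gradient of scalar-valued f at selected entries."""
    out = []
    for i in indices:
        orig = t.data[i]
        t.data[i] = orig + eps
        fp = f().item()
        t.data[i] = orig - eps
        fm = f().item()
        t.data[i] = orig
        out.append((fp - fm) / (2.0 * eps))
    return np.array(out)
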