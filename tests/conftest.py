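import math

import numpy as np
import pytest

from ringexciton.geometry import EmitterArray, RingSpec, StackSpec, build_ring, build_stack


@pytest.fixture
def rng():
    return np.random.default_rng(20230851)


@pytest.fixture
def small_ring():
    """N=9 Dicke-regime ring with transverse polarization."""
    return build_ring(RingSpec(N=9, R=0.05))


@pytest.fixture
def double_ring_transverse():
    """Two identical N=9 rings, R=0.05 lambda, Z=0.5R, transverse dipoles."""
    r1 = RingSpec(N=9, R=0.05)
    r2 = RingSpec(N=9, R=0.05, z=0.025)
    return build_stack(StackSpec(rings=(r1, r2)))


def random_symmetric_array(rng) -> EmitterArray:
    """Random N-fold symmetric single or multi-ring geometry."""
    N = int(rng.integers(3, 11))
    n_cell = int(rng.integers(1, 4))
    rings = []
    for _ in range(n_cell):
        rings.append(
            RingSpec(
                N=N,
                R=float(rng.uniform(0.05, 0.5)),
                z=float(rng.uniform(-0.3, 0.3)),
                delta=float(rng.uniform(0.0, 2 * math.pi / N)) % (2 * math.pi / N),
                theta=float(rng.uniform(0.0, math.pi)),
                phi=float(rng.uniform(0.0, 2 * math.pi)),
                detuning=float(rng.uniform(-2.0, 2.0)),
            )
        )
    return build_stack(StackSpec(rings=tuple(rings)))
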