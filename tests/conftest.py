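import numpy as np
import pytest

from puffmd.engine import HarmonicBond, ParticleSystem


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def random_chain(rng):
    """A 6-bead harmonic chain in a mildly perturbed configuration."""
    n = 6
    masses = rng.uniform(20.0, 150.0, size=n)
    positions = np.zeros((n, 3))
    positions[:, 0] = 3.0 * np.arange(n)
    positions += rng.normal(scale=0.3, size=(n, 3))
    velocities = rng.normal(scale=1.0, size=(n, 3))
    bonds = [HarmonicBond(i=k, j=k + 1, k=rng.uniform(500, 5000), r0=3.0) for k in range(n - 1)]
    return ParticleSystem(masses=masses, positions=positions, velocities=velocities, bonds=bonds)
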