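import numpy as np
import pytest

from mutsphere import synthetic
from mutsphere.geometry import load_structure, write_pdb


@pytest.fixture(scope="session")
def linear10():
    """Ten-residue straight chain, Cα at (3.8·i, 0, 0)."""
    spec = synthetic.FixtureSpec(geometry="linear", N=10, seed=1)
    model, text = synthetic.make_structure(spec)
    return model, text


@pytest.fixture(scope="session")
def worked_example():
    """Five residues, mutually 20 Å apart, counts 50/40/30/20/10.

    At any radius r <= 10 the spheres around distinct residues cannot
    overlap (2r <= 20), and each sphere covers exactly its center residue
    when r < 20.
    """
    spec = synthetic.FixtureSpec(geometry="linear", N=5, spacing=20.0, seed=2)
    model, _ = synthetic.make_structure(spec)
    counts = np.array([50, 40, 30, 20, 10], dtype=np.int64)
    return model, counts


@pytest.fixture(scope="session")
def coil30():
    """Compact self-avoiding 30-residue coil for randomized tests."""
    spec = synthetic.FixtureSpec(geometry="random_coil", N=30, seed=3)
    model, _ = synthetic.make_structure(spec)
    return model


def random_instance(rng, n_min=8, n_max=30):
    """A random small structure + counts + radius, for oracle comparisons."""
    n = int(rng.integers(n_min, n_max + 1))
    spec = synthetic.FixtureSpec(
        geometry="random_coil", N=n, seed=int(rng.integers(2**31))
    )
    model, _ = synthetic.make_structure(spec)
    counts = rng.integers(0, 6, size=n)
    r = float(rng.uniform(1.0, 10.0))
    return model, counts, r


@pytest.fixture()
def two_chain_pdb():
    """PDB text with chains A and B (A first in ATOM record order)."""
    a = write_pdb("AG", [(0, 0, 0), (3.8, 0, 0)], chain_id="A")
    b = write_pdb("VL", [(0, 9, 0), (3.8, 9, 0)], chain_id="B")
    # strip A's END/TER so both chains sit in one file
    return "\n".join(a.splitlines()[:-2] + b.splitlines()) + "\n"
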