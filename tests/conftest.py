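import numpy as np
import pytest

from regulonkit import SimConfig, simulate
from regulonkit.motif_scanning import MotifModel
from regulonkit.synthetic_data import default_motif_counts


@pytest.fixture(scope="session")
def default_model() -> MotifModel:
    """The palindromic TTGAT-N4-ATCAA model with the default pseudocount."""
    return MotifModel(
        counts=default_motif_counts(),
        background=np.array([0.25] * 4),
        pseudocount=0.5,
        n_sites=40.0,
    )


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated data set shared by read-only tests."""
    return simulate(SimConfig(
        seed=11, n_species=8, n_regulators=2, n_target_groups=6,
        n_background_genes=30,
    ))


def random_model(rng: np.random.Generator, width: int | None = None) -> MotifModel:
    """A random count-matrix model for oracle comparisons."""
    w = width or int(rng.integers(4, 16))
    n = int(rng.integers(5, 40))
    counts = rng.multinomial(n, [0.25] * 4, size=w).astype(float)
    bg = rng.dirichlet([5.0] * 4)
    return MotifModel(counts=counts, background=bg, pseudocount=0.5, n_sites=n)


def random_dna(rng: np.random.Generator, length: int, alphabet: str = "ACGT") -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=length))
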