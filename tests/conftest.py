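import numpy as np
import pandas as pd
import pytest

from glpop.gl import GLMatrix
from glpop.simdata import simulate_dataset


def certain_gl(genotypes: np.ndarray) -> np.ndarray:
    """GL block with probability-1 triples from a (sites, inds) genotype array."""
    S, N = genotypes.shape
    L = np.zeros((S, N, 3))
    for g in range(3):
        L[:, :, g] = genotypes == g
    return L


def make_gl(genotypes, chrom="chr1", chrom_len=None, spacing=1000,
            colonies=None, start=1):
    """GLMatrix with certain genotypes at evenly spaced positions."""
    S, N = genotypes.shape
    pos = start + spacing * np.arange(S)
    sites = pd.DataFrame({"chrom": chrom, "pos": pos, "major": "A", "minor": "C"})
    inds = [f"ind{i}" for i in range(N)]
    return GLMatrix(
        sites=sites, individuals=inds,
        colonies=colonies or ["pop"] * N,
        L=certain_gl(np.asarray(genotypes)),
        chrom_lengths={chrom: chrom_len or int(pos[-1] + spacing)},
    )


@pytest.fixture(scope="session")
def default_dataset():
    """One simulation of the default twelve-colony study (seed 1)."""
    return simulate_dataset(seed=1)


@pytest.fixture(scope="session")
def default_panel(default_dataset):
    """The default panel without the outgroup individuals."""
    gl = default_dataset.gl
    keep = [i for i, c in enumerate(gl.colonies) if c != "Outgroup"]
    return gl.subset_individuals(keep)
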