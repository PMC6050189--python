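import numpy as np
import pytest

from hierdiv import AbundanceTable, HierarchySpec, decompose
from hierdiv.datasets import shared_allele_example, toy_ecosystem


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def sixty_percent():
    """Two equal populations, 10 equally frequent alleles each, 4 shared."""
    return shared_allele_example()


@pytest.fixture
def toy3():
    """Three-level toy ecosystem: 4 communities, 2 regions, 5 species."""
    return toy_ecosystem()


def random_vector(rng, s=None, allow_zero=True):
    """Random relative-abundance vector (Dirichlet-ish, optional zeros)."""
    if s is None:
        s = int(rng.integers(2, 12))
    p = rng.gamma(0.7, size=s)
    if allow_zero and s > 2 and rng.random() < 0.3:
        p[rng.integers(0, s)] = 0.0
    return p / p.sum()


def random_instance(rng, n_levels=3):
    """Random nested hierarchy plus matching positive abundance table."""
    shape = [int(rng.integers(2, 4)) for _ in range(n_levels - 1)]
    labels, mapping = [], {}
    units = []

    def build(prefix, depth):
        if depth == len(shape):
            units.append(prefix)
            mapping[prefix] = tuple(prefix.rsplit("/", k)[0] for k in range(1, len(shape))) + ("eco",)
            return
        for i in range(shape[depth]):
            build(f"{prefix}/{i}" if prefix else str(i), depth + 1)

    for i in range(shape[0]):
        build(str(i), 1)
    level_names = [f"L{k}" for k in range(1, n_levels + 1)]
    hierarchy = HierarchySpec.from_mapping(level_names, mapping)
    s = int(rng.integers(3, 9))
    counts = rng.integers(0, 30, size=(s, len(units))).astype(float)
    counts[rng.integers(0, s, size=len(units)), np.arange(len(units))] += 1.0
    table = AbundanceTable.from_arrays(
        counts, [f"e{i}" for i in range(s)], units
    )
    return table, hierarchy


def two_pop_delta(counts):
    """Differentiation of a two-population, two-level system."""
    table = AbundanceTable.from_arrays(
        counts, [f"a{i}" for i in range(np.shape(counts)[0])], ["p1", "p2"]
    )
    hierarchy = HierarchySpec.from_mapping(
        ["population", "total"], {"p1": ("T",), "p2": ("T",)}
    )
    return float(decompose(table, hierarchy).differentiation[0])
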