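import numpy as np
import pytest

from moses import (
    AnnotationDatabase,
    BenchmarkSpec,
    Interactome,
    RunConfig,
    generate_benchmark,
)


@pytest.fixture
def path12():
    """Path graph g1-g2-...-g12."""
    edges = [(f"G{i}", f"G{i+1}") for i in range(1, 12)]
    return Interactome(edges)


@pytest.fixture
def toy_db():
    return AnnotationDatabase(
        "TOY",
        {"T1": frozenset({"A", "B"}), "T2": frozenset({"B", "C"}), "T3": frozenset({"D"})},
        {"T1": "one", "T2": "two", "T3": "three"},
    )


@pytest.fixture(scope="session")
def small_benchmark():
    """One strong-signal instance shared by slower integration tests."""
    return generate_benchmark(BenchmarkSpec(rng_seed=7))


def random_interactome(rng: np.random.Generator, n: int, p: float) -> Interactome:
    """Small Erdős–Rényi interactome for oracle comparisons."""
    names = [f"N{i:02d}" for i in range(n)]
    edges = [
        (names[i], names[j])
        for i in range(n)
        for j in range(i + 1, n)
        if rng.random() < p
    ]
    if not edges:
        edges = [(names[0], names[1])]
    return Interactome(edges, nodes=names)
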