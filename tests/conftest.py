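"""Shared fixtures: hand-built motif webs and one synthetic study."""

import numpy as np
import pytest

from microweb import (
    FoodWeb,
    FoodWebStudy,
    TaxonNode,
    generate_seasonal_dataset,
)


def make_web(edges, nodes=None, label="test", guilds=None, compartments=None):
    """Build a web from (prey, predator) pairs; nodes inferred if omitted."""
    if nodes is None:
        seen = []
        for a, b in edges:
            for x in (a, b):
                if x not in seen:
                    seen.append(x)
        nodes = seen
    guilds = guilds or {}
    compartments = compartments or {}
    registry = []
    for n in nodes:
        comp = compartments.get(n, "protist")
        kind = "genus" if comp == "protist" else "aggregate"
        registry.append(
            TaxonNode(n, kind=kind, compartment=comp,
                      guilds=frozenset(guilds.get(n, ())))
        )
    index = {n: k for k, n in enumerate(nodes)}
    A = np.zeros((len(nodes), len(nodes)), dtype=np.int8)
    for prey, pred in edges:
        A[index[prey], index[pred]] = 1
    return FoodWeb(registry, A, label=label)


def web_with(S, L, rng):
    """Random web with exactly S nodes and L links (node 0 kept basal)."""
    cells = [(i, j) for i in range(S) for j in range(1, S) if i != j]
    if L > len(cells):
        raise ValueError("too many links requested")
    picks = rng.choice(len(cells), size=L, replace=False)
    A = np.zeros((S, S), dtype=np.int8)
    for p in picks:
        i, j = cells[int(p)]
        A[i, j] = 1
    nodes = [TaxonNode(f"n{k}") for k in range(S)]
    return FoodWeb(nodes, A)


@pytest.fixture
def chain_web():
    """basal -> herbivore -> carnivore."""
    return make_web([("a", "b"), ("b", "c")])


@pytest.fixture
def igp_web():
    """Intraguild predation: c eats {a, b}, b eats a, a basal."""
    return make_web([("a", "b"), ("a", "c"), ("b", "c")])


@pytest.fixture(scope="session")
def dataset():
    return generate_seasonal_dataset(0)


@pytest.fixture(scope="session")
def study(dataset):
    return FoodWebStudy.from_dataset(dataset)


@pytest.fixture(scope="session")
def season_webs(study):
    return study.webs()
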