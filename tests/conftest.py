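import numpy as np
import pytest

from mirloc.datamodel import DiseaseDAG
from mirloc.embedding import Node2vecParams
from mirloc.features import FeatureParams, build_features
from mirloc.synth import SynthConfig, generate


@pytest.fixture(scope="session")
def chain_dag() -> DiseaseDAG:
    """A -> B -> C (child -> parent)."""
    return DiseaseDAG(frozenset("ABC"), frozenset({("A", "B"), ("B", "C")}))


@pytest.fixture(scope="session")
def diamond_dag() -> DiseaseDAG:
    """A -> {B, C} -> D."""
    return DiseaseDAG(
        frozenset("ABCD"),
        frozenset({("A", "B"), ("A", "C"), ("B", "D"), ("C", "D")}),
    )


def small_synth_config(seed: int = 1) -> SynthConfig:
    return SynthConfig(n_mirna=60, n_disease=30, n_drug=10, n_mrna=60, seed=seed)


def fast_feature_params(seed: int = 0) -> FeatureParams:
    """Reduced walk/embedding budget for quick unit-level training runs."""
    return FeatureParams(
        node2vec=Node2vecParams(dim=32, num_walks=4, walk_length=20, window=5,
                                epochs=2, seed=seed)
    )


@pytest.fixture(scope="session")
def tiny_bundle():
    """A 60-miRNA synthetic dataset with its feature bundle (shared, read-only)."""
    synth = generate(small_synth_config())
    bundle = build_features(synth.dataset, fast_feature_params())
    return synth, bundle


def random_hypergraph(rng: np.random.Generator, max_nodes: int = 20):
    """Random valid hypergraph: n nodes, random >=2-member hyperedges."""
    from mirloc.hypergraph import Hypergraph

    n = int(rng.integers(3, max_nodes + 1))
    m = int(rng.integers(1, 8))
    h = np.zeros((n, m))
    for e in range(m):
        size = int(rng.integers(2, n + 1))
        members = rng.choice(n, size=size, replace=False)
        h[members, e] = 1
    w = rng.uniform(0.5, 2.0, size=m)
    labels = tuple(f"e{j}" for j in range(m))
    return Hypergraph(tuple(f"n{i}" for i in range(n)), h, w, labels)
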