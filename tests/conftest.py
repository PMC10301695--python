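import numpy as np
import pytest

import pathvae as pv


@pytest.fixture
def toy_graph() -> pv.OntologyGraph:
    """A parent of B, C; D child of both B and C; five genes."""
    return pv.OntologyGraph(
        term_ids=["A", "B", "C", "D"],
        edges={("A", "B"), ("A", "C"), ("B", "D"), ("C", "D")},
        direct_annotations={"A": {"g1"}, "B": {"g2", "g3"}, "C": {"g3", "g4"}, "D": {"g5"}},
    )


def random_trimmed(seed: int, n_terms: int = 30, k: int = 2) -> pv.TrimmedOntology:
    spec = pv.SyntheticSpec(n_terms=n_terms, n_genes=5 * n_terms, max_depth=4, seed=seed)
    graph = pv.generate_dag(spec)
    onto = pv.trim_ontology(graph, 0, 10 ** 9)
    pv.compile_ontology(onto, k)
    return onto


@pytest.fixture(scope="session")
def branch_model():
    """Trained model on the branch-driver scenario, shared across tests.

    One gene (``gstar``) exclusively carries branch A's signal; the model is
    trained to convergence so perturbation readouts are meaningful.
    """
    graph, X, meta = pv.branch_driver_scenario(seed=100)
    onto = pv.trim_ontology(graph, 1, 30)  # removes the root term R
    pv.compile_ontology(onto, 3)
    res = pv.OntologyVAE(X, onto).fit(seed=0, max_epochs=3000)
    return res, X, meta


@pytest.fixture(scope="session")
def small_training_setup():
    """Small synthetic ontology + data for quick training runs (untrained)."""
    spec = pv.SyntheticSpec(n_terms=15, n_genes=80, n_samples=80, max_depth=3, seed=3)
    graph = pv.generate_dag(spec)
    data = pv.generate_expression(graph, spec)
    onto = pv.trim_ontology(graph, 0, 10 ** 9)
    pv.compile_ontology(onto, 2)
    return onto, data


def zeroed_decoder(results: pv.OntologyVAEResults) -> pv.OntologyVAEResults:
    """Set every parameter to zero (in place); decode output becomes bias-only."""
    for k in results.net.params:
        results.net.params[k] = np.zeros_like(results.net.params[k])
    return results
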