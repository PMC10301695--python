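"""Synthetic ontologies and expression data with known ground truth.

The generator emulates the model's own generative assumption: each sample has a
non-negative latent activity per root term, activities propagate down the DAG
through fixed positive edge weights, and a gene's expression is a noisy positive
combination of the activities of the terms it is annotated to.  Because the true
per-term activities are returned alongside the expression matrix, every other
module can be tested for recovery of a known signal without downloading any real
ontology or dataset.

Group structure is optional: each non-reference group receives an additive shift
``effect_size`` on the latent activity of one designated root term ("signal
term"), which then propagates to that term's whole branch.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .ontology import OntologyGraph, TrimmedOntology, compile_ontology, trim_ontology

__all__ = ["SyntheticSpec", "generate_dag", "generate_expression", "write_fixture_files",
           "synthetic_trimmed", "branch_driver_scenario"]


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic ontology + expression generator.

    Defaults describe a small but structured study: a 50-term DAG over a pool of
    300 genes, 500 samples, half-normal root activities (scale 1), gene-level
    Gaussian noise with standard deviation 0.5, and a two-group design with an
    additive shift of 2 on one root branch.
    """

    n_terms: int = 50
    max_depth: int = 4
    n_genes: int = 300
    genes_per_term_range: tuple[int, int] = (3, 10)
    n_samples: int = 500
    n_groups: int = 1
    effect_size: float = 2.0
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_terms, self.n_genes, self.n_samples, self.n_groups) < 1:
            raise ValueError("all counts must be positive")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        lo, hi = self.genes_per_term_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid genes_per_term_range")
        if self.n_terms < self.max_depth + 1:
            raise ValueError("need n_terms >= max_depth + 1")


def generate_dag(spec: SyntheticSpec) -> OntologyGraph:
    """Random single-root DAG with per-term gene annotations.

    Term ``T000`` is the root; every later term receives 1–2 parents among the
    previously created terms, keeping realized depths within ``max_depth``.
    Genes are drawn uniformly (without replacement per term) from a pool of
    ``n_genes`` identifiers, so genes may annotate several terms.
    """
    rng = np.random.default_rng(spec.seed)
    terms = [f"T{i:03d}" for i in range(spec.n_terms)]
    gene_pool = [f"G{i:04d}" for i in range(spec.n_genes)]

    edges: set[tuple[str, str]] = set()
    depth = {terms[0]: 0}
    for i, t in enumerate(terms[1:], start=1):
        # candidate parents: existing terms with depth < max_depth
        candidates = [u for u in terms[:i] if depth[u] < spec.max_depth]
        n_parents = int(rng.integers(1, 3)) if len(candidates) > 1 else 1
        parents = rng.choice(len(candidates), size=min(n_parents, len(candidates)), replace=False)
        ps = [candidates[j] for j in parents]
        for p in ps:
            edges.add((p, t))
        depth[t] = max(depth[p] for p in ps) + 1

    lo, hi = spec.genes_per_term_range
    annotations: dict[str, set[str]] = {}
    for t in terms:
        n = int(rng.integers(lo, hi + 1))
        idx = rng.choice(spec.n_genes, size=min(n, spec.n_genes), replace=False)
        annotations[t] = {gene_pool[j] for j in idx}

    return OntologyGraph(term_ids=terms, edges=edges, direct_annotations=annotations)


@dataclass
class SyntheticData:
    """Expression matrix plus the ground truth that generated it."""

    expression: pd.DataFrame  # samples x genes
    activities: pd.DataFrame  # samples x terms (true latent activities)
    labels: pd.Series  # group label per sample
    signal_terms: dict[str, str]  # group label -> shifted root term
    edge_weights: dict[tuple[str, str], float] = field(default_factory=dict)
    gene_weights: dict[tuple[str, str], float] = field(default_factory=dict)


def generate_expression(graph: OntologyGraph, spec: SyntheticSpec) -> SyntheticData:
    """Sample expression whose genes are noisy positive mixes of term activities.

    Root activities are half-normal (|N(0,1)|) per sample; a non-root term's
    activity is the parent-weight average ``mean_p(v_{p,t} * a_p)`` with fixed
    ``v ~ U(0.5, 1)``.  A gene's value is ``sum_t w_{t,g} * a_t`` over the terms
    annotating it, with fixed ``w ~ U(0.5, 1.5)``, plus N(0, noise_sd) noise,
    truncated at zero.  Groups beyond the first get ``effect_size`` added to the
    activity of one root term before propagation.
    """
    import networkx as nx

    rng = np.random.default_rng(spec.seed + 1)
    g = graph.to_networkx()
    order = list(nx.topological_sort(g))
    roots = [t for t in order if g.in_degree(t) == 0]

    n = spec.n_samples
    labels = pd.Series(
        [f"group{(i * spec.n_groups) // n}" for i in range(n)], name="group"
    )

    # fixed positive weights
    vw = {(p, c): float(rng.uniform(0.5, 1.0)) for p, c in graph.edges}
    gw = {
        (t, gene): float(rng.uniform(0.5, 1.5))
        for t in graph.term_ids
        for gene in sorted(graph.direct_annotations.get(t, set()))
    }

    # choose one signal root per non-reference group (deterministic in the seed)
    signal_terms: dict[str, str] = {}
    if spec.n_groups > 1:
        picks = rng.choice(len(roots), size=min(spec.n_groups - 1, len(roots)), replace=False)
        for gi, pi in enumerate(picks, start=1):
            signal_terms[f"group{gi}"] = roots[int(pi)]

    act = pd.DataFrame(0.0, index=range(n), columns=graph.term_ids)
    for t in roots:
        a = np.abs(rng.standard_normal(n))
        for grp, st in signal_terms.items():
            if st == t:
                a = a + np.where(labels.values == grp, spec.effect_size, 0.0)
        act[t] = a
    for t in order:
        parents = list(g.predecessors(t))
        if parents:
            act[t] = np.mean([vw[(p, t)] * act[p].values for p in parents], axis=0)

    genes = sorted({gene for s in graph.direct_annotations.values() for gene in s})
    expr = np.zeros((n, len(genes)))
    for j, gene in enumerate(genes):
        for t in graph.term_ids:
            if gene in graph.direct_annotations.get(t, set()):
                expr[:, j] += gw[(t, gene)] * act[t].values
    expr += rng.normal(0.0, spec.noise_sd, size=expr.shape)
    np.maximum(expr, 0.0, out=expr)

    expression = pd.DataFrame(expr, index=range(n), columns=genes)
    return SyntheticData(
        expression=expression,
        activities=act,
        labels=labels,
        signal_terms=signal_terms,
        edge_weights=vw,
        gene_weights=gw,
    )


def synthetic_trimmed(spec: SyntheticSpec, neurons_per_term: int = 3,
                      bottom: int = 0, top: int | None = None) -> tuple[TrimmedOntology, SyntheticData]:
    """Convenience: DAG + expression + compiled trimmed ontology in one call.

    By default no term is trimmed away (``bottom=0``, ``top=inf``), so ground
    truth activities align one-to-one with model terms; the single synthetic
    root then forms the latent space alone unless thresholds remove it.
    """
    graph = generate_dag(spec)
    data = generate_expression(graph, spec)
    if top is None:
        top = 10 ** 9
    onto = trim_ontology(graph, bottom, top)
    compile_ontology(onto, neurons_per_term)
    return onto, data


def branch_driver_scenario(seed: int, n_samples: int = 150, noise_sd: float = 0.5
                           ) -> tuple[OntologyGraph, pd.DataFrame, dict]:
    """Three-branch ontology in which a single gene carries one branch's signal.

    The DAG is a root ``R`` over branches ``A``, ``B``, ``C``, each with two
    child terms.  Every term has genes annotated to it, but branch ``A`` is
    special: its latent activity reaches the expression matrix only through the
    driver gene ``gstar`` (weight 2); all other A-branch genes are pure noise.
    Branches B and C behave normally (gene weight 0.8).  A model trained on this
    data can therefore read branch-A activity only from ``gstar``, making the
    scenario a ground-truthed benchmark for knockout screening: knocking out
    ``gstar`` must depress the A-branch terms, and no other gene can.

    Returns the ontology graph, the expression table, and a metadata dict with
    the driver gene, its branch node, and the branch's term set.
    """
    rng = np.random.default_rng(seed)
    branches = ["A", "B", "C"]
    terms = ["R"] + branches + [f"{b}{i}" for b in branches for i in (1, 2)]
    edges = {("R", b) for b in branches} | {(b, f"{b}{i}") for b in branches for i in (1, 2)}
    genes: dict[str, set[str]] = {"R": set()}
    for b in branches:
        genes[b] = {f"g{b}{i}" for i in range(4)}
        for i in (1, 2):
            genes[f"{b}{i}"] = {f"g{b}{i}{j}" for j in range(4)}
    genes["A"].add("gstar")
    graph = OntologyGraph(term_ids=terms, edges=edges, direct_annotations=genes)

    a = {b: np.abs(rng.standard_normal(n_samples)) for b in branches}
    act = {}
    for b in branches:
        act[b] = a[b]
        act[f"{b}1"] = 0.8 * a[b]
        act[f"{b}2"] = 0.7 * a[b]
    cols = sorted({x for s in genes.values() for x in s})
    X = np.zeros((n_samples, len(cols)))
    for j, c in enumerate(cols):
        for t, gs in genes.items():
            if c in gs:
                w = 2.0 if c == "gstar" else (0.0 if c.startswith("gA") else 0.8)
                X[:, j] += w * act[t]
    X += rng.normal(0.0, noise_sd, X.shape)
    np.maximum(X, 0.0, out=X)
    meta = {"driver": "gstar", "branch_node": "A",
            "branch_terms": {"A", "A1", "A2"}, "true_activities": act}
    return graph, pd.DataFrame(X, columns=cols), meta


def write_fixture_files(graph: OntologyGraph, data: SyntheticData, outdir) -> dict[str, str]:
    """Emit OBO, two-column TSV annotations, and expression/label TSVs.

    These files exercise the same readers used for real ontologies and datasets.
    """
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "obo": os.path.join(outdir, "ontology.obo"),
        "annotations": os.path.join(outdir, "annotations.tsv"),
        "expression": os.path.join(outdir, "expression.tsv"),
        "labels": os.path.join(outdir, "labels.tsv"),
    }
    parents: dict[str, list[str]] = {t: [] for t in graph.term_ids}
    for p, c in sorted(graph.edges):
        parents[c].append(p)
    with open(paths["obo"], "w") as fh:
        fh.write("format-version: 1.2\nontology: synthetic\n")
        for t in graph.term_ids:
            fh.write(f"\n[Term]\nid: {t}\nname: {graph.term_names.get(t, t)}\n")
            fh.write("namespace: synthetic_process\n")
            for p in parents[t]:
                fh.write(f"is_a: {p} ! {p}\n")
    with open(paths["annotations"], "w") as fh:
        for t in graph.term_ids:
            for gene in sorted(graph.direct_annotations.get(t, set())):
                fh.write(f"{t}\t{gene}\n")
    data.expression.to_csv(paths["expression"], sep="\t", index_label="sample")
    data.labels.to_frame().assign(sample=data.expression.index).set_index("sample").to_csv(
        paths["labels"], sep="\t"
    )
    return paths
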