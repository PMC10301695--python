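"""Ontology handling: parsing, trimming, depth layering, and decoder connectivity masks.

A biological ontology (GO, HPO, ...) restricted to its ``is_a`` relationships is a
directed acyclic graph of terms, each optionally carrying direct gene annotations.
The model consumes a *trimmed* version of this DAG in which overly generic terms
(too many descendant genes) and overly specific terms (too few) have been removed,
with children of removed terms rewired to their parents so that ancestry among the
surviving terms is preserved.  Terms are then layered by *depth* — the length of
the longest directed path from any parentless term — and compiled into one binary
connectivity mask per decoder layer plus one mask for the gene reconstruction
layer.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import obonet

logger = logging.getLogger(__name__)

__all__ = [
    "OntologyGraph",
    "TrimmedOntology",
    "parse_obo",
    "parse_annotations",
    "descendant_genes",
    "compute_depths",
    "trim_ontology",
    "build_masks",
]


class OntologyError(ValueError):
    """Raised for structurally invalid ontologies (cycles, dangling edges...)."""


@dataclass
class OntologyGraph:
    """A raw ontology DAG with ``is_a`` edges and direct gene annotations.

    Edges are stored as ``(parent, child)`` pairs; information flows from parent
    (more generic) to child (more specific).
    """

    term_ids: list[str]
    edges: set[tuple[str, str]]
    direct_annotations: dict[str, set[str]] = field(default_factory=dict)
    term_names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        terms = set(self.term_ids)
        for p, c in self.edges:
            if p not in terms or c not in terms:
                raise OntologyError(f"edge ({p}, {c}) references unknown term")
        for t in self.direct_annotations:
            if t not in terms:
                raise OntologyError(f"annotation references unknown term {t}")
        cycle = _find_cycle(self.term_ids, self.edges)
        if cycle is not None:
            raise OntologyError(f"ontology contains a cycle through {cycle}")

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.term_ids)
        g.add_edges_from(self.edges)
        return g

    def children(self, term: str) -> set[str]:
        return {c for p, c in self.edges if p == term}

    def annotations_for(self, term: str) -> set[str]:
        return set(self.direct_annotations.get(term, set()))


def _find_cycle(terms: Sequence[str], edges: set[tuple[str, str]]) -> str | None:
    g = nx.DiGraph()
    g.add_nodes_from(terms)
    g.add_edges_from(edges)
    try:
        cyc = nx.find_cycle(g)
    except nx.NetworkXNoCycle:
        return None
    return cyc[0][0]


def parse_obo(path, namespace_filter: str | None = None) -> OntologyGraph:
    """Parse an OBO file keeping only ``is_a`` edges between retained terms.

    Parameters
    ----------
    path
        OBO 1.2/1.4 flat file.
    namespace_filter
        If given, only terms whose ``namespace`` matches are retained
        (e.g. ``"biological_process"``).

    Obsolete terms are dropped (the OBO reader skips them).  Relationship types
    other than ``is_a`` (``part_of``, ``regulates``, ...) are discarded.
    """
    multigraph = obonet.read_obo(path, ignore_obsolete=True)

    keep: list[str] = []
    names: dict[str, str] = {}
    for node, data in multigraph.nodes(data=True):
        if namespace_filter is not None and data.get("namespace") != namespace_filter:
            continue
        keep.append(node)
        names[node] = data.get("name", node)
    keep_set = set(keep)

    # obonet edges point child -> parent with the relationship as the key
    edges: set[tuple[str, str]] = set()
    for child, parent, rel in multigraph.edges(keys=True):
        if rel != "is_a":
            continue
        if child in keep_set and parent in keep_set:
            edges.add((parent, child))

    return OntologyGraph(term_ids=sorted(keep), edges=edges, term_names=names)


def parse_annotations(path, id_space: str = "symbol") -> dict[str, set[str]]:
    """Read term→gene annotations from a GAF 2.x file or a two-column TSV.

    A file is treated as GAF when it has ``!``-prefixed header lines or rows with
    15+ tab-separated columns; otherwise each row must be ``term<TAB>gene``.
    GAF rows with a ``NOT`` qualifier are excluded.  ``id_space`` selects the GAF
    gene column: ``"symbol"`` uses the DB object symbol, ``"ensembl"`` the DB
    object ID (assumed pre-mapped upstream).

    Raises
    ------
    ValueError
        If no parsable rows are found.
    """
    if id_space not in ("symbol", "ensembl"):
        raise ValueError(f"id_space must be 'symbol' or 'ensembl', got {id_space!r}")
    gene_col = 2 if id_space == "symbol" else 1  # 0-based GAF column

    annotations: dict[str, set[str]] = {}
    n_rows = 0
    n_rejected = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("!") or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) >= 15:  # GAF
                qualifier = fields[3]
                if "NOT" in qualifier.split("|"):
                    n_rejected += 1
                    continue
                gene, term = fields[gene_col], fields[4]
            elif len(fields) == 2:  # term<TAB>gene
                term, gene = fields
            else:
                n_rejected += 1
                continue
            if not gene or not term:
                n_rejected += 1
                continue
            annotations.setdefault(term, set()).add(gene)
            n_rows += 1
    if n_rejected:
        logger.info("parse_annotations: rejected %d rows", n_rejected)
    if n_rows == 0:
        raise ValueError(f"no parsable annotation rows in {path}")
    return annotations


def descendant_genes(graph: OntologyGraph, term: str) -> set[str]:
    """Genes annotated directly to ``term`` or to any term reachable below it."""
    if term not in set(graph.term_ids):
        raise KeyError(f"unknown term {term}")
    g = graph.to_networkx()
    reach = {term} | nx.descendants(g, term)
    out: set[str] = set()
    for t in reach:
        out |= graph.direct_annotations.get(t, set())
    return out


def _all_descendant_genes(graph: OntologyGraph) -> dict[str, set[str]]:
    """Descendant gene sets for every term in one reverse-topological pass."""
    g = graph.to_networkx()
    result: dict[str, set[str]] = {}
    for t in reversed(list(nx.topological_sort(g))):
        s = set(graph.direct_annotations.get(t, set()))
        for c in g.successors(t):
            s |= result[c]
        result[t] = s
    return result


def compute_depths(edges: Iterable[tuple[str, str]], kept_terms: Sequence[str]) -> dict[str, int]:
    """Longest-path depth of every term from the parentless (depth-0) terms.

    ``depth(t)`` is the length of the longest directed path ending at ``t`` that
    starts at any term without parents.  Computed by dynamic programming over a
    topological order; a cycle raises :class:`OntologyError`.
    """
    g = nx.DiGraph()
    g.add_nodes_from(kept_terms)
    g.add_edges_from(edges)
    try:
        order = list(nx.topological_sort(g))
    except nx.NetworkXUnfeasible as exc:
        raise OntologyError("cycle detected while computing depths") from exc
    depth: dict[str, int] = {}
    for t in order:
        preds = list(g.predecessors(t))
        depth[t] = 0 if not preds else max(depth[p] for p in preds) + 1
    return depth


@dataclass
class TrimmedOntology:
    """A trimmed, layered ontology compiled into decoder connectivity masks.

    ``kept_terms`` are ordered by ascending depth, lexicographically within a
    depth; this ordering defines the neuron layout of the model and the row /
    column order of all masks.  ``masks`` holds one binary matrix per decoder
    depth ``1..D`` followed by the reconstruction mask (see :func:`build_masks`).
    """

    kept_terms: list[str]
    edges: set[tuple[str, str]]
    depth: dict[str, int]
    direct_annotations: dict[str, set[str]]
    genes: list[str]
    descendant_genes: dict[str, set[str]]
    trim_thresholds: tuple[int, int]
    term_names: dict[str, str] = field(default_factory=dict)
    masks: list[np.ndarray] = field(default_factory=list)
    neurons_per_term: int = 0

    @property
    def n_layers(self) -> int:
        return self.max_depth + 1

    @property
    def max_depth(self) -> int:
        return max(self.depth.values()) if self.depth else 0

    @property
    def layer_terms(self) -> dict[int, list[str]]:
        layers: dict[int, list[str]] = {d: [] for d in range(self.n_layers)}
        for t in self.kept_terms:
            layers[self.depth[t]].append(t)
        return layers

    @property
    def root_terms(self) -> list[str]:
        return [t for t in self.kept_terms if self.depth[t] == 0]

    def term_index(self, term: str) -> int:
        try:
            return self.kept_terms.index(term)
        except ValueError:
            raise KeyError(f"unknown term {term}") from None

    def content_hash(self) -> str:
        payload = json.dumps(
            {
                "terms": self.kept_terms,
                "edges": sorted(self.edges),
                "genes": self.genes,
                "annotations": {t: sorted(g) for t, g in sorted(self.direct_annotations.items())},
                "thresholds": list(self.trim_thresholds),
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()

    # ---- persistence ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "format": "pathvae-trimmed-ontology",
            "version": 1,
            "kept_terms": self.kept_terms,
            "edges": sorted(self.edges),
            "depth": self.depth,
            "direct_annotations": {t: sorted(g) for t, g in self.direct_annotations.items()},
            "genes": self.genes,
            "descendant_genes": {t: sorted(g) for t, g in self.descendant_genes.items()},
            "trim_thresholds": list(self.trim_thresholds),
            "term_names": self.term_names,
            "neurons_per_term": self.neurons_per_term,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, d: Mapping) -> "TrimmedOntology":
        if d.get("format") != "pathvae-trimmed-ontology":
            raise ValueError("not a trimmed-ontology artifact")
        onto = cls(
            kept_terms=list(d["kept_terms"]),
            edges={tuple(e) for e in d["edges"]},
            depth={t: int(v) for t, v in d["depth"].items()},
            direct_annotations={t: set(g) for t, g in d["direct_annotations"].items()},
            genes=list(d["genes"]),
            descendant_genes={t: set(g) for t, g in d["descendant_genes"].items()},
            trim_thresholds=tuple(d["trim_thresholds"]),
            term_names=dict(d.get("term_names", {})),
        )
        k = int(d.get("neurons_per_term", 0))
        if k:
            onto.masks = build_masks(onto, k)
            onto.neurons_per_term = k
        return onto

    @classmethod
    def load(cls, path) -> "TrimmedOntology":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def save_masks(self, path) -> None:
        """Write masks in a sparse coordinate text format (one block per mask)."""
        with open(path, "w") as fh:
            fh.write(f"# pathvae masks k={self.neurons_per_term} n={len(self.masks)}\n")
            for i, m in enumerate(self.masks):
                rows, cols = np.nonzero(m)
                fh.write(f"# mask {i} shape {m.shape[0]} {m.shape[1]} nnz {len(rows)}\n")
                for r, c in zip(rows, cols):
                    fh.write(f"{i}\t{r}\t{c}\n")


def trim_ontology(graph: OntologyGraph, bottom: int, top: int) -> TrimmedOntology:
    """Remove terms with descendant-gene counts outside ``[bottom, top]``.

    Counts are evaluated on the *untrimmed* graph in a single pass.  Each removed
    term is edge-contracted: its children are rewired to its parents, so any
    ancestry path between two kept terms survives trimming.  Depths are then
    recomputed on the contracted graph and the gene list rebuilt from the direct
    annotations of the kept terms.
    """
    if bottom < 0 or top <= bottom:
        raise ValueError(f"need 0 <= bottom < top, got bottom={bottom}, top={top}")

    desc = _all_descendant_genes(graph)
    counts = {t: len(desc[t]) for t in graph.term_ids}
    kept = [t for t in graph.term_ids if bottom <= counts[t] <= top]
    if not kept:
        from collections import Counter

        dist = Counter(counts.values())
        raise OntologyError(
            f"no terms survive trimming with [{bottom}, {top}]; "
            f"descendant-count distribution: {dict(sorted(dist.items()))}"
        )
    kept_set = set(kept)

    g = graph.to_networkx()
    for t in graph.term_ids:
        if t in kept_set:
            continue
        parents = list(g.predecessors(t))
        children = list(g.successors(t))
        g.remove_node(t)
        g.add_edges_from((p, c) for p in parents for c in children if p != c)

    edges = {(p, c) for p, c in g.edges()}
    depth = compute_depths(edges, kept)
    order = sorted(kept, key=lambda t: (depth[t], t))

    annotations = {t: set(graph.direct_annotations.get(t, set())) for t in order}
    genes = sorted({g_ for t in order for g_ in annotations[t]})
    return TrimmedOntology(
        kept_terms=order,
        edges=edges,
        depth=depth,
        direct_annotations=annotations,
        genes=genes,
        descendant_genes={t: desc[t] for t in order},
        trim_thresholds=(bottom, top),
        term_names={t: graph.term_names.get(t, t) for t in order},
    )


def build_masks(onto: TrimmedOntology, neurons_per_term: int) -> list[np.ndarray]:
    """Compile the layered DAG into binary connectivity masks.

    With ``k = neurons_per_term`` and decoder depths ``1..D``, mask ``d-1`` has
    shape ``(k*|layer d|, k*|layers < d|)`` with a ``k x k`` all-ones block where
    a parent→child edge exists; columns cover all terms of depth ``< d`` in
    ``kept_terms`` order.  The final mask has shape ``(|genes|, k*|terms|)`` with
    a ``1 x k`` block where a gene is *directly* annotated to a term.
    """
    k = neurons_per_term
    if k < 1:
        raise ValueError("neurons_per_term must be >= 1")
    depth = onto.depth
    for p, c in onto.edges:
        if depth[p] >= depth[c]:
            raise OntologyError(f"edge ({p}, {c}) violates depth({p}) < depth({c})")

    terms = onto.kept_terms  # ordered by (depth, id)
    col_of = {t: i for i, t in enumerate(terms)}
    layers = onto.layer_terms
    masks: list[np.ndarray] = []
    for d in range(1, onto.n_layers):
        rows = layers[d]
        prev = [t for t in terms if depth[t] < d]
        m = np.zeros((k * len(rows), k * len(prev)), dtype=np.float64)
        prev_of = {t: i for i, t in enumerate(prev)}
        for i, child in enumerate(rows):
            for p, c in onto.edges:
                if c == child:
                    j = prev_of[p]
                    m[i * k : (i + 1) * k, j * k : (j + 1) * k] = 1.0
        masks.append(m)

    gene_of = {g: i for i, g in enumerate(onto.genes)}
    recon = np.zeros((len(onto.genes), k * len(terms)), dtype=np.float64)
    for t in terms:
        j = col_of[t]
        for g_ in onto.direct_annotations.get(t, set()):
            recon[gene_of[g_], j * k : (j + 1) * k] = 1.0
    masks.append(recon)
    return masks


def compile_ontology(onto: TrimmedOntology, neurons_per_term: int) -> TrimmedOntology:
    """Attach masks for ``neurons_per_term`` to the ontology (in place) and return it."""
    onto.masks = build_masks(onto, neurons_per_term)
    onto.neurons_per_term = neurons_per_term
    return onto
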