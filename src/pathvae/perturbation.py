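"""In-silico gene perturbations: knockouts, stimulations, and screens.

A *knockout* sets a gene's input value to zero for every sample; a *stimulation*
raises it to a constant above the observed expression range (default: the data
maximum rounded up to the next integer).  The perturbed samples are run through
the trained model and the activity at a chosen ontology term — or the readout of
a reconstruction gene — is compared pre vs post with a one-tailed paired
Wilcoxon signed-rank test.  Screens repeat this for many genes one at a time and
rank them by p-value; pre-perturbation activities are computed once and reused.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import OntologyVAEResults, align_genes
from .stats import bh_fdr, hypergeom_ora, signed_rank_test

logger = logging.getLogger(__name__)

__all__ = [
    "Perturbation",
    "PerturbationResult",
    "apply_perturbation",
    "compare_node",
    "screen_genes",
    "term_and_gene_level_analysis",
    "default_stimulation_value",
]


@dataclass
class Perturbation:
    """A single-gene input perturbation."""

    gene: str
    mode: str = "knockout"  # "knockout" | "stimulate"
    value: float | None = None  # 0 for knockout; target value for stimulation

    def __post_init__(self) -> None:
        if self.mode not in ("knockout", "stimulate"):
            raise ValueError("mode must be 'knockout' or 'stimulate'")
        if self.mode == "knockout":
            if self.value is None:
                self.value = 0.0
            if self.value != 0.0:
                raise ValueError("knockout requires value 0")
        elif self.value is not None and self.value <= 0:
            raise ValueError("stimulation value must be > 0")


@dataclass
class PerturbationResult:
    """Paired-test outcome at one node for one perturbation."""

    target: str
    statistic: float
    p_value: float
    direction: str
    n_used: int
    gene: str
    mode: str
    rank: int | None = None

    @property
    def untestable(self) -> bool:
        return not np.isfinite(self.p_value)


def default_stimulation_value(data: np.ndarray) -> float:
    """Max expression in the data rounded up to the next integer."""
    return float(np.ceil(np.max(data)))


def _as_matrix(results: OntologyVAEResults, data) -> np.ndarray:
    return align_genes(data, results.ontology.genes)


def apply_perturbation(data, p: Perturbation, genes: list[str] | None = None) -> np.ndarray:
    """Copy of ``data`` with the perturbed gene's column set to ``p.value``.

    ``data`` is a DataFrame with gene columns or an array whose columns follow
    ``genes`` (required for arrays).  All other columns are untouched.
    """
    if isinstance(data, pd.DataFrame):
        genes = list(data.columns)
        X = data.to_numpy(dtype=float).copy()
    else:
        if genes is None:
            raise ValueError("gene order required for array input")
        X = np.array(data, dtype=float, copy=True)
    try:
        j = genes.index(p.gene)
    except ValueError:
        raise KeyError(f"gene {p.gene} not in input genes") from None
    value = p.value if p.value is not None else default_stimulation_value(X)
    X[:, j] = value
    return X


def _node_column(results: OntologyVAEResults, node: str) -> tuple[str, int]:
    onto = results.ontology
    if node in onto.depth:
        return "term", onto.kept_terms.index(node)
    if node in onto.genes:
        return "gene", onto.genes.index(node)
    raise KeyError(f"node {node} is neither a kept term nor a model gene")


def _node_values(results: OntologyVAEResults, X: np.ndarray, kind: str, col: int) -> np.ndarray:
    from .activity import get_activities, get_reconstruction
    if kind == "term":
        return get_activities(results, X).values[:, col]
    return get_reconstruction(results, X).values[:, col]


def compare_node(results: OntologyVAEResults, data, p: Perturbation, node: str,
                 alternative: str = "less", exclude_zero_cells: bool = False,
                 _pre: np.ndarray | None = None) -> PerturbationResult:
    """Paired pre/post comparison of one node's activity under a perturbation.

    With ``exclude_zero_cells`` and a stimulation, samples whose unperturbed
    expression of the gene is zero are dropped before testing (they carry no
    evidence about raising an expressed gene).  Fewer than 2 usable pairs, or
    all-zero differences, yield an untestable result (p = NaN) rather than an
    error.
    """
    X = _as_matrix(results, data)
    if X.shape[0] == 0:
        raise ValueError("empty data")
    kind, col = _node_column(results, node)
    value = p.value
    if p.mode == "stimulate" and value is None:
        value = Perturbation(p.gene, "stimulate", default_stimulation_value(X)).value
    pert = Perturbation(p.gene, p.mode, value)

    genes = results.ontology.genes
    j = genes.index(pert.gene) if pert.gene in genes else None
    if j is None:
        raise KeyError(f"gene {pert.gene} not in model input genes")

    mask = np.ones(X.shape[0], dtype=bool)
    if exclude_zero_cells and pert.mode == "stimulate":
        mask = X[:, j] != 0
    Xs = X[mask]

    pre = _node_values(results, Xs, kind, col) if _pre is None else np.asarray(_pre)[mask]
    Xp = apply_perturbation(Xs, pert, genes=genes)
    post = _node_values(results, Xp, kind, col)

    r = signed_rank_test(pre, post, alternative=alternative)
    n_used = int(mask.sum()) if not r.untestable else int(r.n_pairs)
    return PerturbationResult(
        target=node, statistic=r.statistic, p_value=r.p_value,
        direction=alternative, n_used=int(mask.sum()), gene=pert.gene, mode=pert.mode,
    )


def _rank_results(results_list: list[PerturbationResult]) -> pd.DataFrame:
    def key(r: PerturbationResult):
        p = r.p_value if np.isfinite(r.p_value) else np.inf
        mag = abs(r.statistic) if np.isfinite(r.statistic) else -np.inf
        return (r.untestable, p, -mag, r.gene, r.target)

    ordered = sorted(results_list, key=key)
    rows = []
    for i, r in enumerate(ordered, start=1):
        r.rank = i
        rows.append({
            "gene": r.gene, "target": r.target, "mode": r.mode,
            "statistic": r.statistic, "p_value": r.p_value,
            "direction": r.direction, "n_used": r.n_used, "rank": i,
        })
    return pd.DataFrame(rows)


def screen_genes(results: OntologyVAEResults, data, genes: list[str], node: str,
                 mode: str = "knockout", value: float | None = None,
                 alternative: str = "less", exclude_zero_cells: bool = False) -> pd.DataFrame:
    """One-by-one perturbation screen of ``genes`` at a single node.

    Returns a table sorted by ascending p-value (ties: larger |statistic|, then
    gene ID; untestable genes last) with a 1-based ``rank`` column.
    """
    if not genes:
        raise ValueError("empty gene list")
    X = _as_matrix(results, data)
    model_genes = results.ontology.genes
    unknown = [g for g in genes if g not in model_genes]
    if unknown:
        raise KeyError(f"genes not in model input: {unknown[:5]}")
    if mode == "stimulate" and value is None:
        value = default_stimulation_value(X)
    kind, col = _node_column(results, node)
    pre = _node_values(results, X, kind, col)

    out = []
    for g in genes:
        p = Perturbation(g, mode, value)
        out.append(compare_node(results, X, p, node, alternative=alternative,
                                exclude_zero_cells=exclude_zero_cells, _pre=pre))
    return _rank_results(out)


def term_and_gene_level_analysis(results: OntologyVAEResults, data, p: Perturbation,
                                 alternative: str = "less", top_k: int = 100,
                                 exclude_zero_cells: bool = False
                                 ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Full single-perturbation analysis: every term, every gene, plus ORA.

    Term-level: one-tailed paired signed-rank tests at every kept term.
    Gene-level: the same at every reconstruction gene.  ORA: hypergeometric
    over-representation of each term's descendant gene set within the ``top_k``
    most significant genes of the gene-level ranking (background = all model
    genes), BH-FDR corrected.  All three tables are ranked by significance.
    """
    from .activity import get_activities, get_reconstruction

    onto = results.ontology
    X = _as_matrix(results, data)
    value = p.value
    if p.mode == "stimulate" and value is None:
        value = default_stimulation_value(X)
    pert = Perturbation(p.gene, p.mode, value)

    j = onto.genes.index(pert.gene)
    mask = np.ones(X.shape[0], dtype=bool)
    if exclude_zero_cells and pert.mode == "stimulate":
        mask = X[:, j] != 0
    Xs = X[mask]
    Xp = apply_perturbation(Xs, pert, genes=onto.genes)

    act_pre = get_activities(results, Xs).values
    act_post = get_activities(results, Xp).values
    rec_pre = get_reconstruction(results, Xs).values
    rec_post = get_reconstruction(results, Xp).values

    term_results = []
    for i, t in enumerate(onto.kept_terms):
        r = signed_rank_test(act_pre[:, i], act_post[:, i], alternative=alternative)
        term_results.append(PerturbationResult(t, r.statistic, r.p_value, alternative,
                                               int(mask.sum()), pert.gene, pert.mode))
    gene_results = []
    for i, g in enumerate(onto.genes):
        r = signed_rank_test(rec_pre[:, i], rec_post[:, i], alternative=alternative)
        gene_results.append(PerturbationResult(g, r.statistic, r.p_value, alternative,
                                               int(mask.sum()), pert.gene, pert.mode))
    term_table = _rank_results(term_results)
    gene_table = _rank_results(gene_results)

    if top_k > len(onto.genes):
        warnings.warn(f"top_k={top_k} exceeds gene count; capped at {len(onto.genes)}")
        top_k = len(onto.genes)
    top_genes = set(gene_table.head(top_k)["target"])
    background = set(onto.genes)
    ora_rows = []
    for t in onto.kept_terms:
        term_genes = onto.descendant_genes[t] & background
        pv = hypergeom_ora(top_genes, term_genes, background)
        ora_rows.append({"term": t, "n_term_genes": len(term_genes),
                         "n_overlap": len(top_genes & term_genes), "p_value": pv})
    ora = pd.DataFrame(ora_rows)
    ora["fdr"] = bh_fdr(ora["p_value"].to_numpy())
    ora = ora.sort_values(["p_value", "term"], kind="mergesort").reset_index(drop=True)
    ora["rank"] = np.arange(1, len(ora) + 1)
    return term_table, gene_table, ora
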