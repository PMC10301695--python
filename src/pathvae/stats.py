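"""Statistical primitives: rank tests, FDR, hypergeometric ORA, Jaccard, term ranking.

Thin, contract-checked wrappers around scipy/statsmodels.  Small tie-free
samples use exact null distributions; larger or tied samples fall back to the
tie-corrected normal approximation (scipy's ``method="auto"`` policy), matching
how these tests are conventionally run on expression data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import fdrcorrection

logger = logging.getLogger(__name__)

__all__ = [
    "RankTestResult",
    "rank_sum_test",
    "signed_rank_test",
    "bh_fdr",
    "hypergeom_ora",
    "jaccard",
    "jaccard_class",
    "TermRanking",
    "rank_terms_for_groups",
]


@dataclass
class RankTestResult:
    """Outcome of a rank test; ``statistic`` is centered (0 under H0)."""

    statistic: float
    p_value: float
    alternative: str
    n1: int = 0
    n2: int = 0
    n_pairs: int = 0
    untestable: bool = False


_ALTERNATIVES = ("two-sided", "greater", "less")


def rank_sum_test(x, y, alternative: str = "two-sided") -> RankTestResult:
    """Wilcoxon–Mann–Whitney rank-sum comparison of two independent samples.

    ``statistic`` is the centered U statistic ``U - n1*n2/2`` (positive when
    ``x`` tends to exceed ``y``).  Identical constant samples give p = 1.
    """
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"alternative must be one of {_ALTERNATIVES}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both samples must be non-empty")
    if np.ptp(np.concatenate([x, y])) == 0:
        return RankTestResult(0.0, 1.0, alternative, x.size, y.size)
    res = sps.mannwhitneyu(x, y, alternative=alternative, method="auto")
    stat = float(res.statistic) - x.size * y.size / 2.0
    return RankTestResult(stat, float(res.pvalue), alternative, x.size, y.size)


def signed_rank_test(pre, post, alternative: str = "two-sided") -> RankTestResult:
    """Paired Wilcoxon signed-rank test of ``post`` against ``pre``.

    Zero differences are dropped; midranks are used for tied magnitudes; the
    null distribution is exact for small zero/tie-free samples and a normal
    approximation (with continuity correction) otherwise.  ``statistic`` is the
    centered positive-rank sum ``W+ - m(m+1)/4`` over the m nonzero differences
    (positive when ``post`` tends to exceed ``pre``).  ``alternative="greater"``
    tests post > pre.  All-zero differences are untestable (p = NaN).
    """
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"alternative must be one of {_ALTERNATIVES}")
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre and post must have equal length")
    if pre.size < 2:
        return RankTestResult(np.nan, np.nan, alternative, n_pairs=pre.size, untestable=True)
    diff = post - pre
    nz = diff[diff != 0]
    if nz.size == 0:
        return RankTestResult(np.nan, np.nan, alternative, n_pairs=0, untestable=True)
    ranks = sps.rankdata(np.abs(nz))
    w_plus = float(ranks[nz > 0].sum())
    centered = w_plus - nz.size * (nz.size + 1) / 4.0
    res = sps.wilcoxon(post, pre, zero_method="wilcox", alternative=alternative,
                       correction=True, method="auto")
    return RankTestResult(centered, float(res.pvalue), alternative, n_pairs=int(nz.size))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return fdrcorrection(p, method="indep")[1]


def hypergeom_ora(hits: set, term_genes: set, background: set) -> float:
    """Upper-tail hypergeometric p-value for over-representation.

    Probability of drawing at least ``|hits ∩ term_genes|`` term genes when
    sampling ``|hits|`` genes without replacement from ``background``.
    """
    background = set(background)
    if not background:
        raise ValueError("empty background")
    hits = set(hits) & background
    term_genes = set(term_genes) & background
    overlap = len(hits & term_genes)
    if overlap == 0:
        return 1.0
    return float(sps.hypergeom.sf(overlap - 1, len(background), len(term_genes), len(hits)))


def jaccard(term_a: str, term_b: str, graph) -> float:
    """Jaccard similarity of two terms' descendant gene sets (0 if both empty).

    ``graph`` may be an :class:`~pathvae.ontology.OntologyGraph` or a
    :class:`~pathvae.ontology.TrimmedOntology`.
    """
    if hasattr(graph, "descendant_genes") and isinstance(graph.descendant_genes, dict):
        sets = graph.descendant_genes
        a, b = sets[term_a], sets[term_b]
    else:
        from .ontology import descendant_genes
        a = descendant_genes(graph, term_a)
        b = descendant_genes(graph, term_b)
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


def jaccard_class(js: float) -> str:
    """Similarity band: low (js <= 0.25), medium (0.25 < js <= 0.75), high (js > 0.75)."""
    if js <= 0.25:
        return "low"
    if js <= 0.75:
        return "medium"
    return "high"


@dataclass
class TermRanking:
    """Pairwise-hit ranking of groups per term and top-term tables per group.

    ``table`` has one row per (term, group) with columns ``hits`` (number of
    pairwise wins at p <= alpha), ``rank`` (1 = most hits for that term) and
    ``median_statistic`` (median pairwise centered rank-sum statistic).
    ``top_terms(group)`` sorts that group's terms by (rank asc, hits desc,
    median statistic desc).
    """

    table: pd.DataFrame
    alpha: float

    def top_terms(self, group: str, n: int | None = None) -> pd.DataFrame:
        sub = self.table[self.table["group"] == group].sort_values(
            by=["rank", "hits", "median_statistic"],
            ascending=[True, False, False],
            kind="mergesort",
        ).reset_index(drop=True)
        return sub.head(n) if n is not None else sub


def rank_terms_for_groups(activities: pd.DataFrame, labels, alpha: float = 0.05) -> TermRanking:
    """Rank sample groups at every term by pairwise one-sided rank-sum wins.

    For each term and each ordered pair of groups (A, B), a one-sided rank-sum
    test asks whether the term is more active in A than in B; a win at
    p <= ``alpha`` counts as a *hit* for A.  Per term, groups are ranked by hit
    count (most hits = rank 1, ties broken by group label order).  Groups with
    fewer than 2 samples are excluded with a warning.
    """
    labels = pd.Series(labels).reset_index(drop=True)
    act = activities.reset_index(drop=True)
    groups = []
    for g in labels.unique():
        if (labels == g).sum() < 2:
            logger.warning("group %s has < 2 samples; excluded from ranking", g)
        else:
            groups.append(g)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups with >= 2 samples")
    groups = sorted(groups, key=str)

    rows = []
    for term in act.columns:
        values = {g: act.loc[(labels == g).values, term].to_numpy() for g in groups}
        hits = {g: 0 for g in groups}
        stats_by_group = {g: [] for g in groups}
        for a in groups:
            for b in groups:
                if a == b:
                    continue
                r = rank_sum_test(values[a], values[b], alternative="greater")
                stats_by_group[a].append(r.statistic)
                if r.p_value <= alpha:
                    hits[a] += 1
        order = sorted(groups, key=lambda g: (-hits[g], str(g)))
        rank = {g: i + 1 for i, g in enumerate(order)}
        for g in groups:
            rows.append({
                "term": term,
                "group": g,
                "hits": hits[g],
                "rank": rank[g],
                "median_statistic": float(np.median(stats_by_group[g])),
            })
    return TermRanking(pd.DataFrame(rows), alpha)
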