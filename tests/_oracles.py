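"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive — exhaustive enumeration, dense linear
algebra, Monte-Carlo — and shares no code with the package internals it checks.
"""

from __future__ import annotations

import itertools
import math

import networkx as nx
import numpy as np
from scipy.stats import rankdata


def longest_path_depths(edges, terms) -> dict[str, int]:
    """Depth by exhaustive enumeration of all simple paths from all roots."""
    g = nx.DiGraph()
    g.add_nodes_from(terms)
    g.add_edges_from(edges)
    roots = [t for t in terms if g.in_degree(t) == 0]
    depth = {t: 0 for t in terms}
    for r in roots:
        for t in terms:
            if t == r:
                continue
            for path in nx.all_simple_paths(g, r, t):
                depth[t] = max(depth[t], len(path) - 1)
    return depth


def reachable_pairs(edges, terms) -> set[tuple[str, str]]:
    """All ordered pairs (u, v), u != v, with a directed path u -> v."""
    g = nx.DiGraph()
    g.add_nodes_from(terms)
    g.add_edges_from(edges)
    closure = nx.transitive_closure(g)
    return {(u, v) for u, v in closure.edges()}


def expanded_adjacency_masks(onto, k: int) -> list[np.ndarray]:
    """Masks rebuilt from a plain edge-list scan, independent of build_masks."""
    depth = onto.depth
    terms = sorted(onto.kept_terms, key=lambda t: (depth[t], t))
    max_depth = max(depth.values()) if depth else 0
    masks = []
    for d in range(1, max_depth + 1):
        rows = [t for t in terms if depth[t] == d]
        cols = [t for t in terms if depth[t] < d]
        m = np.zeros((k * len(rows), k * len(cols)))
        for (p, c) in onto.edges:
            if c in rows:
                i, j = rows.index(c), cols.index(p)
                m[i * k:(i + 1) * k, j * k:(j + 1) * k] = 1
        masks.append(m)
    genes = sorted({g for t in terms for g in onto.direct_annotations.get(t, set())})
    recon = np.zeros((len(genes), k * len(terms)))
    for t in terms:
        for g in onto.direct_annotations.get(t, set()):
            recon[genes.index(g), terms.index(t) * k:(terms.index(t) + 1) * k] = 1
    masks.append(recon)
    return masks


def dense_decoder_forward(net, z: np.ndarray) -> np.ndarray:
    """Reconstruction via one dense block-lower-triangular solve.

    Assembles the full (n_total x n_total) masked weight matrix A mapping the
    concatenated activation vector to itself (strictly block-lower-triangular),
    then solves (I - A) c = injection(z) + biases and applies the reconstruction
    map — an algebraic reformulation of the skip-concatenation pass.
    """
    widths = net.layer_widths
    n_total = sum(widths)
    offsets = np.cumsum([0] + widths)
    A = np.zeros((n_total, n_total))
    b = np.zeros(n_total)
    for d, m in enumerate(net.dec_masks, start=1):
        W = net.params[f"Wd{d}"] * m
        A[offsets[d]:offsets[d + 1], :offsets[d]] = W
        b[offsets[d]:offsets[d + 1]] = net.params[f"bd{d}"]
    z = np.atleast_2d(z)
    C = np.zeros((z.shape[0], n_total))
    for i in range(z.shape[0]):
        rhs = b.copy()
        rhs[:widths[0]] += z[i]
        C[i] = np.linalg.solve(np.eye(n_total) - A, rhs)
    Wr = net.params["Wr"] * net.recon_mask
    return C @ Wr.T + net.params["br"]


def exact_rank_sum_p(x, y, alternative: str) -> float:
    """Exact rank-sum p by enumeration of all assignments of ranks to x."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = len(x), len(y)
    ranks = rankdata(np.concatenate([x, y]))
    t_obs = ranks[:n1].sum() - n1 * (n1 + n2 + 1) / 2.0  # centered rank sum of x
    stats = []
    for comb in itertools.combinations(range(n1 + n2), n1):
        t = ranks[list(comb)].sum() - n1 * (n1 + n2 + 1) / 2.0
        stats.append(t)
    stats = np.asarray(stats)
    eps = 1e-9
    if alternative == "greater":
        return float(np.mean(stats >= t_obs - eps))
    if alternative == "less":
        return float(np.mean(stats <= t_obs + eps))
    return float(np.mean(np.abs(stats) >= abs(t_obs) - eps))


def exact_signed_rank_p(pre, post, alternative: str) -> float:
    """Exact signed-rank p by enumeration of all 2^m sign assignments."""
    d = np.asarray(post, float) - np.asarray(pre, float)
    d = d[d != 0]
    m = len(d)
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    total = m * (m + 1) / 2.0
    ws = []
    for signs in itertools.product([0, 1], repeat=m):
        ws.append(sum(r for r, s in zip(ranks, signs) if s))
    ws = np.asarray(ws)
    eps = 1e-9
    if alternative == "greater":
        return float(np.mean(ws >= w_obs - eps))
    if alternative == "less":
        return float(np.mean(ws <= w_obs + eps))
    dev = np.abs(ws - total / 2.0)
    return float(np.mean(dev >= abs(w_obs - total / 2.0) - eps))


def exact_hypergeom_upper(n_background: int, n_term: int, n_hits: int, overlap: int) -> float:
    """P(X >= overlap) by direct combinatorial summation."""
    total = math.comb(n_background, n_hits)
    acc = 0
    for k in range(overlap, min(n_term, n_hits) + 1):
        acc += math.comb(n_term, k) * math.comb(n_background - n_term, n_hits - k)
    return acc / total


def monte_carlo_kl(mu, log_var, n_draws: int, seed: int) -> tuple[float, float]:
    """MC estimate (and its standard error) of KL(q || N(0, I)) via reparameterized draws."""
    rng = np.random.default_rng(seed)
    mu = np.asarray(mu, float)
    lv = np.asarray(log_var, float)
    sd = np.exp(0.5 * lv)
    eps = rng.standard_normal((n_draws, mu.size))
    z = mu + sd * eps
    log_q = -0.5 * (((z - mu) / sd) ** 2 + np.log(2 * np.pi) + lv).sum(axis=1)
    log_p = -0.5 * (z ** 2 + np.log(2 * np.pi)).sum(axis=1)
    diff = log_q - log_p
    return float(diff.mean()), float(diff.std(ddof=1) / np.sqrt(n_draws))
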