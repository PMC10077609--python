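"""Independent brute-force oracles used by the tests.

These deliberately avoid the code paths they check: shortest paths by
exhaustive simple-path enumeration, logistic likelihood by direct summation
and grid search, BH by the step-up formula written out, Welch by the textbook
formula.
"""

from __future__ import annotations

import itertools
import math

import networkx as nx
import numpy as np


def brute_force_min_time(graph: nx.Graph, sources, target, weight: str = "time") -> float:
    """Min over sources of the cheapest simple path, by full enumeration."""
    best = math.inf
    for s in sources:
        if s == target:
            return 0.0
        for path in nx.all_simple_paths(graph, s, target):
            cost = sum(graph[u][v][weight] for u, v in zip(path, path[1:]))
            best = min(best, cost)
    return best


def bh_step_up(p_values) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values by the step-up formula."""
    p = np.asarray(p_values, float)
    m = len(p)
    order = np.argsort(p)
    adjusted = np.empty(m)
    running_min = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        running_min = min(running_min, p[idx] * m / rank)
        adjusted[idx] = running_min
    return np.minimum(adjusted, 1.0)


def welch_statistic(a, b) -> tuple[float, float]:
    """Welch t statistic and Welch–Satterthwaite df, textbook formulas."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    return t, df


def pearson_chi2(table) -> float:
    table = np.asarray(table, float)
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row @ col / table.sum()
    return float(((table - expected) ** 2 / expected).sum())


def logistic_log_likelihood(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    """Direct log-likelihood summation for a logistic model."""
    eta = X @ beta
    # log(p) = -log(1 + e^-eta), log(1-p) = -eta - log(1 + e^-eta)
    ll = 0.0
    for e, yi in zip(eta, y):
        log_p = -np.log1p(math.exp(-e))
        log_q = -e + log_p
        ll += yi * log_p + (1 - yi) * log_q
    return float(ll)


def grid_search_max_loglik(
    X: np.ndarray, y: np.ndarray, lo: float = -4.0, hi: float = 4.0, step: float = 0.2
) -> float:
    """Exhaustive grid evaluation of the logistic log-likelihood maximum."""
    grid = np.arange(lo, hi + step / 2, step)
    best = -math.inf
    for beta in itertools.product(grid, repeat=X.shape[1]):
        best = max(best, logistic_log_likelihood(X, y, np.asarray(beta)))
    return best


def random_connected_graph(rng: np.random.Generator, n_nodes: int) -> nx.Graph:
    """Small random connected weighted graph (for exact-path comparisons)."""
    g = nx.Graph()
    g.add_nodes_from(range(n_nodes))
    nodes = list(range(n_nodes))
    rng.shuffle(nodes)
    for a, b in zip(nodes, nodes[1:]):  # random spanning tree backbone
        g.add_edge(a, b, time=float(rng.uniform(1, 20)))
    n_extra = int(rng.integers(0, n_nodes))
    for _ in range(n_extra):
        u, v = rng.integers(0, n_nodes, size=2)
        if u != v and not g.has_edge(int(u), int(v)):
            g.add_edge(int(u), int(v), time=float(rng.uniform(1, 20)))
    return g
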