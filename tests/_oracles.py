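"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by exhaustive enumeration or direct
definition, sharing no code path with the implementation it checks.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np


def exhaustive_pfp(R: np.ndarray) -> np.ndarray:
    """Exact pfp by enumerating every joint rank permutation.

    ``R`` is a k x g matrix of observed within-study ranks (each row a
    permutation of 1..g).  The null enumerates all (g!)^k joint
    permutations; each contributes g null rank products.  For the gene at
    1-based position x of the observed ranking with product r:
    pfp = (#null products <= r) / (n_joint * x), then made monotone
    non-decreasing down the ranking and capped at 1.  Products are
    compared as exact integers.
    """
    k, g = R.shape
    obs_prod = np.prod(R.astype(np.int64), axis=0)
    base = list(itertools.permutations(range(1, g + 1)))
    null_prods = []
    for rows in itertools.product(base, repeat=k):
        null_prods.extend(np.prod(np.array(rows, dtype=np.int64), axis=0))
    null_prods = np.sort(np.array(null_prods))
    n_joint = len(base) ** k

    order = np.argsort(obs_prod, kind="stable")
    vals = np.empty(g)
    for pos, gi in enumerate(order, start=1):
        cnt = int(np.searchsorted(null_prods, obs_prod[gi], side="right"))
        vals[pos - 1] = cnt / (n_joint * pos)
    vals = np.minimum(np.maximum.accumulate(vals), 1.0)
    pfp = np.empty(g)
    pfp[order] = vals
    return pfp


def steiner_optimum(G: nx.Graph, terminals: set) -> int:
    """Exact minimum Steiner tree cost (unit weights) by subset search.

    With unit weights the optimal tree over node set S has |S| - 1 edges,
    so the optimum is the smallest connected superset of the terminals.
    """
    others = sorted(set(G.nodes) - set(terminals))
    for r in range(len(others) + 1):
        for extra in itertools.combinations(others, r):
            S = set(terminals) | set(extra)
            if nx.is_connected(G.subgraph(S)):
                return len(S) - 1
    raise ValueError("terminals not connected in G")


def best_growth_objective(
    G: nx.Graph, seed_node: str, penalty: float = 2.0
) -> float:
    """Exhaustive maximum of the per-node-penalty cohesiveness over every
    subset of the seed's connected component that contains the seed."""
    comp = sorted(nx.node_connected_component(G, seed_node))
    others = [n for n in comp if n != seed_node]
    best = 0.0
    for r in range(len(others) + 1):
        for extra in itertools.combinations(others, r):
            V = {seed_node, *extra}
            w_in = sum(1 for u, v in G.edges if u in V and v in V)
            w_bound = sum(
                1 for u, v in G.edges if (u in V) != (v in V)
            )
            denom = w_in + w_bound + penalty * len(V)
            f = w_in / denom if denom > 0 else 0.0
            best = max(best, f)
    return best


def bfs_avg_distances(G: nx.Graph, targets: set) -> dict:
    """Average distance from every node to the reachable targets by a
    plain queue BFS (the node itself excluded when it is a target)."""
    out = {}
    for src in G.nodes:
        dist = {src: 0}
        queue = [src]
        while queue:
            u = queue.pop(0)
            for v in G[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    queue.append(v)
        ds = [d for t, d in dist.items() if t in targets and t != src]
        n_targets = len([t for t in targets if t != src])
        out[src] = sum(ds) / len(ds) if ds else float("nan")
    return out


def hypergeom_exact(N: int, K: int, n: int, k: int):
    """Upper-tail hypergeometric probability as an exact Fraction."""
    from fractions import Fraction
    from math import comb

    total = comb(N, n)
    hits = sum(
        comb(K, j) * comb(N - K, n - j) for j in range(k, min(K, n) + 1)
    )
    return Fraction(hits, total)
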