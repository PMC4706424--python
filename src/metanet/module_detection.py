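"""Overlapping dense-module detection by greedy cohesiveness growth.

The cohesiveness of a node set V is

    f(V) = w_in(V) / (w_in(V) + w_bound(V) + p)

with w_in the number of edges inside V, w_bound the number crossing its
boundary and p a penalty term modelling unobserved interactions (unit
edge weights throughout).  Modules are grown greedily from seeds in
decreasing-degree order, highly overlapping candidates are merged, and
the survivors are filtered on minimum size, minimum density
2m/(n(n-1)) and a separation p-value.

The separation test compares, per member node, its in-module edge count
against its out-of-module edge count with a one-sided Mann-Whitney U
(a binomial edge-count test against the global density is available via
``pvalue_method="binomial"``).

Two penalty conventions coexist deliberately.  ``cohesiveness`` exposes
the plain additive form above (a fixed scalar p added to the
denominator).  The greedy growth itself maximizes the per-node-penalty
variant f_p(V) = w_in / (w_in + w_bound + p|V|), the reference
ClusterONE objective: charging p per member models each protein's
unobserved interactions, and without it the scalar form makes absorbing
every stray degree-1 neighbor profitable, which dissolves planted dense
modules into their pendant fringe.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats

DEFAULT_PENALTY = 2.0


def _win_wbound(V: set, G: nx.Graph) -> tuple[int, int]:
    w_in = 0
    w_bound = 0
    for u in V:
        for v in G[u]:
            if v in V:
                w_in += 1
            else:
                w_bound += 1
    return w_in // 2, w_bound


def cohesiveness(V: set, G: nx.Graph, penalty: float = DEFAULT_PENALTY) -> float:
    """f(V) = w_in / (w_in + w_bound + penalty); 0 for a set with no
    internal edges, 1 for an isolated cluster at zero penalty."""
    if not V:
        raise ValueError("cohesiveness of the empty set is undefined")
    w_in, w_bound = _win_wbound(V, G)
    denom = w_in + w_bound + penalty
    return w_in / denom if denom > 0 else 0.0


def growth_objective(
    w_in: float, w_bound: float, n: int, penalty: float = DEFAULT_PENALTY
) -> float:
    """Per-node-penalty cohesiveness f_p = w_in / (w_in + w_bound + p*n)."""
    denom = w_in + w_bound + penalty * n
    return w_in / denom if denom > 0 else 0.0


def grow_module(
    seed_node: str,
    G: nx.Graph,
    penalty: float = DEFAULT_PENALTY,
    min_affinity: float = 0.0,
) -> set:
    """Greedy local search from a seed: repeatedly apply the single best
    add-external-neighbor or remove-member step that strictly increases
    the growth objective, stopping at a local maximum.

    ``min_affinity`` gates additions: a candidate node must already be
    adjacent to at least ``min_affinity * |V|`` current members.  Tying
    this floor to the downstream density threshold keeps single-edge
    pendants and loosely bridged neighbor clusters out of the module
    even when annexing them would nudge the cohesiveness up.

    Deterministic: among equally good moves, additions beat removals and
    the lexicographically smallest node wins.
    """
    if seed_node not in G:
        raise ValueError(f"seed {seed_node!r} not in network")
    V = {seed_node}
    w_in, w_bound = _win_wbound(V, G)

    def f(wi: int, wb: int, n: int) -> float:
        return growth_objective(wi, wb, n, penalty)

    current = f(w_in, w_bound, 1)
    while True:
        best: tuple[float, int, str, str] | None = None
        # candidate additions: external boundary nodes
        boundary = {v for u in V for v in G[u] if v not in V}
        for u in sorted(boundary):
            din = sum(1 for v in G[u] if v in V)
            if din < min_affinity * len(V):
                continue
            wi = w_in + din
            wb = w_bound - din + (G.degree(u) - din)
            cand = (-f(wi, wb, len(V) + 1), 0, u, "add")
            if best is None or cand < best:
                best = cand
        # candidate removals (never empty the set)
        if len(V) > 1:
            for u in sorted(V):
                din = sum(1 for v in G[u] if v in V)
                wi = w_in - din
                wb = w_bound + din - (G.degree(u) - din)
                cand = (-f(wi, wb, len(V) - 1), 1, u, "remove")
                if best is None or cand < best:
                    best = cand
        if best is None or -best[0] <= current + 1e-12:
            return V
        _, _, node, action = best
        din = sum(1 for v in G[node] if v in V)
        if action == "add":
            V.add(node)
            w_in += din
            w_bound += G.degree(node) - 2 * din
        else:
            V.remove(node)
            w_in -= din
            w_bound += 2 * din - G.degree(node)
        current = -best[0]


def overlap_score(A: set, B: set) -> float:
    """omega(A, B) = |A n B|^2 / (|A| |B|)."""
    inter = len(A & B)
    return inter * inter / (len(A) * len(B))


def density(V: set, G: nx.Graph) -> float:
    n = len(V)
    if n < 2:
        return 0.0
    m, _ = _win_wbound(V, G)
    return 2.0 * m / (n * (n - 1))


def module_pvalue(V: set, G: nx.Graph, method: str = "mannwhitney") -> float:
    """Separation quality of V from the rest of the network.

    ``"mannwhitney"``: one-sided Mann-Whitney U comparing each member's
    in-module edge count against its out-of-module edge count (greater).
    ``"binomial"``: upper tail of Binomial(n(n-1)/2, global density) at
    the observed internal edge count.
    """
    members = sorted(V)
    din = np.array([sum(1 for v in G[u] if v in V) for u in members])
    dout = np.array([G.degree(u) - d for u, d in zip(members, din)])
    if method == "mannwhitney":
        if np.all(din == dout):
            return 1.0
        res = stats.mannwhitneyu(din, dout, alternative="greater")
        return float(res.pvalue)
    if method == "binomial":
        n = len(V)
        n_possible = n * (n - 1) // 2
        N = G.number_of_nodes()
        global_density = (
            2.0 * G.number_of_edges() / (N * (N - 1)) if N > 1 else 0.0
        )
        w_in, _ = _win_wbound(V, G)
        return float(stats.binom.sf(w_in - 1, n_possible, global_density))
    raise ValueError(f"unknown p-value method {method!r}")


@dataclass
class ModuleResult:
    """One dense subnetwork passing every filter."""

    id: str
    nodes: frozenset
    density: float
    cohesiveness: float
    p_value: float

    def as_dict(self) -> dict:
        return {
            "id": self.id,
            "nodes": sorted(self.nodes),
            "density": self.density,
            "cohesiveness": self.cohesiveness,
            "p_value": self.p_value,
        }


def detect_modules(
    G: nx.Graph,
    min_size: int = 7,
    min_density: float = 0.3,
    alpha: float = 0.05,
    overlap_merge: float = 0.8,
    penalty: float = DEFAULT_PENALTY,
    pvalue_method: str = "mannwhitney",
) -> list[ModuleResult]:
    """Grow-from-every-seed overlapping module detection.

    Seeds are visited in decreasing-degree order (ties lexicographic);
    nodes already covered by a grown module are skipped as seeds.  Pairs
    of candidates with overlap score >= ``overlap_merge`` are merged
    (union) until stable, then candidates are filtered on size, density
    and separation p-value and sorted by cohesiveness descending.
    """
    if G.number_of_nodes() == 0:
        raise ValueError("empty network")
    seeds = sorted(G.nodes, key=lambda n: (-G.degree(n), n))
    covered: set = set()
    candidates: list[set] = []
    for seed in seeds:
        if seed in covered:
            continue
        V = grow_module(seed, G, penalty, min_affinity=min_density)
        covered |= V
        if V not in candidates:
            candidates.append(V)

    # merge highly overlapping candidates until fixed point
    merged = True
    while merged:
        merged = False
        for i in range(len(candidates)):
            for j in range(i + 1, len(candidates)):
                if overlap_score(candidates[i], candidates[j]) >= overlap_merge:
                    candidates[i] = candidates[i] | candidates[j]
                    del candidates[j]
                    merged = True
                    break
            if merged:
                break

    results = []
    for V in candidates:
        if len(V) < min_size:
            continue
        dens = density(V, G)
        if dens < min_density:
            continue
        p = module_pvalue(V, G, method=pvalue_method)
        if p >= alpha:
            continue
        results.append((V, dens, cohesiveness(V, G, penalty), p))
    results.sort(key=lambda r: (-r[2], sorted(r[0])))
    return [
        ModuleResult(
            id=f"M{i + 1}",
            nodes=frozenset(V),
            density=dens,
            cohesiveness=coh,
            p_value=p,
        )
        for i, (V, dens, coh, p) in enumerate(results)
    ]
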