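"""Background interaction network assembly and Steiner-tree reduction.

Edge lists from several interaction databases are unioned into one
simple undirected background graph; the DEG set is mapped onto it as
terminals; and a minimal connecting subnetwork is extracted with the
Kou-Markowsky-Berman (KMB) 2-approximation of the Steiner minimal tree
(metric closure over terminals -> minimum spanning tree -> shortest-path
expansion -> prune non-terminal leaves), with lexicographic tie-breaking
throughout so results are exactly reproducible.

The subnetwork handed to module detection is the Steiner tree edges plus
all background edges induced among the Steiner nodes, the terminals and
the "one-intermediary" candidates (non-terminals adjacent to at least
two terminals): a bare tree would make density-based clustering
degenerate, while the induced edges restore the local interaction
structure around the DEGs.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx

from .deg_meta import DEGSet
from .io_formats import canonicalize


def integrate_background(*edge_lists: Sequence[tuple[str, str]]) -> nx.Graph:
    """Union of interaction pair lists into one simple undirected graph.

    (A, B) and (B, A) merge into one edge; self-loops are dropped; the
    ``source_count`` edge attribute records how many input pairs support
    the edge.  Idempotent: integrating a graph's edge list with itself
    only doubles source counts, never the structure.
    """
    if not edge_lists:
        raise ValueError("at least one edge list required")
    G = nx.Graph()
    n_pairs = 0
    for pairs in edge_lists:
        for a, b in pairs:
            a, b = canonicalize(a), canonicalize(b)
            if a == b:
                continue
            n_pairs += 1
            if G.has_edge(a, b):
                G[a][b]["source_count"] += 1
            else:
                G.add_edge(a, b, source_count=1)
    if G.number_of_edges() == 0:
        raise ValueError("empty edge union: no usable interaction pairs")
    return G


def annotate_degs(G: nx.Graph, degs: DEGSet) -> None:
    """Attach is_deg / direction node attributes in place."""
    direction = degs.direction_of()
    for node in G.nodes:
        d = direction.get(node)
        G.nodes[node]["is_deg"] = d is not None
        G.nodes[node]["direction"] = d if d is not None else "none"


def map_terminals(G: nx.Graph, degs: DEGSet) -> tuple[set[str], set[str]]:
    """DEG symbols present in the network (terminals) and those absent.

    Unmapped genes are returned, never silently dropped; zero mapped
    terminals is an error because every downstream stage would be empty.
    """
    if G.number_of_nodes() == 0:
        raise ValueError("empty network")
    symbols = {canonicalize(g) for g in (degs.up | degs.down)}
    terminals = {s for s in symbols if s in G}
    unmapped = symbols - terminals
    if not terminals:
        raise ValueError("no DEG mapped to the background network")
    return terminals, unmapped


def one_intermediary_candidates(G: nx.Graph, terminals: set[str]) -> set[str]:
    """Non-terminal nodes adjacent to at least two distinct terminals:
    the single-intermediary linkers between DEG pairs."""
    out = set()
    for node in G.nodes:
        if node in terminals:
            continue
        if sum(1 for nb in G[node] if nb in terminals) >= 2:
            out.add(node)
    return out


def _bfs_parents(G: nx.Graph, root: str) -> tuple[dict[str, int], dict[str, str]]:
    """BFS distances and lexicographically-smallest parents from root."""
    dist = {root: 0}
    parent: dict[str, str] = {}
    queue = deque([root])
    while queue:
        u = queue.popleft()
        for v in sorted(G[u]):
            if v not in dist:
                dist[v] = dist[u] + 1
                parent[v] = u
                queue.append(v)
            elif dist[v] == dist[u] + 1 and parent.get(v, u) > u:
                parent[v] = u  # keep the smallest predecessor at equal depth
    return dist, parent


def _path_from_parents(parent: dict[str, str], root: str, target: str) -> list[str]:
    path = [target]
    while path[-1] != root:
        path.append(parent[path[-1]])
    return path[::-1]


def _mst_edges_kruskal(
    edges: Iterable[tuple[float, str, str]], nodes: Iterable[str]
) -> list[tuple[str, str]]:
    """Deterministic Kruskal MST: edges sorted by (weight, endpoints)."""
    parent = {n: n for n in nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    out = []
    for w, a, b in sorted(edges):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
            out.append((a, b))
    return out


@dataclass
class SteinerSubnetwork:
    """KMB Steiner forest: tree per terminal-connected component."""

    graph: nx.Graph
    terminals: set[str] = field(default_factory=set)
    singleton_terminals: set[str] = field(default_factory=set)

    @property
    def total_cost(self) -> int:
        return self.graph.number_of_edges()


def steiner_subnetwork(G: nx.Graph, terminals: set[str]) -> SteinerSubnetwork:
    """KMB 2-approximate Steiner tree per terminal component, unit weights.

    For each connected component of ``G`` holding >=2 terminals: build the
    terminal metric closure by BFS, take its minimum spanning tree, expand
    every MST edge back to one (lexicographically deterministic) shortest
    path, re-extract a spanning tree of the union, and prune non-terminal
    leaves.  The resulting cost is at most 2(1 - 1/l) times the optimum,
    l being the number of terminal leaves in an optimal tree.  Terminals
    alone in their component are returned as singletons with a warning.
    """
    missing = {t for t in terminals if t not in G}
    if missing:
        raise ValueError(f"terminals absent from network: {sorted(missing)}")
    forest = nx.Graph()
    singletons: set[str] = set()
    for comp in nx.connected_components(G):
        comp_terms = sorted(terminals & comp)
        if not comp_terms:
            continue
        if len(comp_terms) == 1:
            singletons.add(comp_terms[0])
            forest.add_node(comp_terms[0])
            continue
        # metric closure restricted to terminals
        bfs = {t: _bfs_parents(G, t) for t in comp_terms}
        closure_edges = [
            (float(bfs[a][0][b]), a, b)
            for i, a in enumerate(comp_terms)
            for b in comp_terms[i + 1 :]
        ]
        mst = _mst_edges_kruskal(closure_edges, comp_terms)
        # expand each closure edge via the BFS tree rooted at its smaller end
        sub = nx.Graph()
        for a, b in mst:
            root, target = min(a, b), max(a, b)
            path = _path_from_parents(bfs[root][1], root, target)
            nx.add_path(sub, path)
        # the union of paths may contain cycles: re-extract a spanning tree
        tree_edges = _mst_edges_kruskal(
            ((1.0, min(u, v), max(u, v)) for u, v in sub.edges), sub.nodes
        )
        tree = nx.Graph(tree_edges)
        tree.add_nodes_from(comp_terms)
        # prune non-terminal leaves until fixed point
        while True:
            leaves = [
                n for n in tree if tree.degree(n) <= 1 and n not in terminals
            ]
            if not leaves:
                break
            tree.remove_nodes_from(leaves)
        forest.add_edges_from(tree.edges)
        forest.add_nodes_from(tree.nodes)
    if singletons:
        warnings.warn(
            f"terminal(s) with no companion in their component: "
            f"{sorted(singletons)}",
            stacklevel=2,
        )
    return SteinerSubnetwork(
        graph=forest, terminals=set(terminals), singleton_terminals=singletons
    )


def analysis_subnetwork(G: nx.Graph, degs: DEGSet) -> nx.Graph:
    """Subnetwork handed to module detection and hub scoring.

    Steiner tree edges unioned with all background edges induced among
    terminals, Steiner nodes and one-intermediary candidates.  Node
    attributes: ``is_deg``, ``direction``, ``steiner`` (member of the
    Steiner forest).
    """
    terminals, _unmapped = map_terminals(G, degs)
    steiner = steiner_subnetwork(G, terminals)
    candidates = one_intermediary_candidates(G, terminals)
    keep = set(steiner.graph.nodes) | terminals | candidates
    sub = nx.Graph(G.subgraph(keep))
    sub.add_edges_from(steiner.graph.edges)
    direction = degs.direction_of()
    for node in sub.nodes:
        sub.nodes[node]["is_deg"] = node in terminals
        sub.nodes[node]["direction"] = direction.get(node, "none")
        sub.nodes[node]["steiner"] = node in steiner.graph.nodes
    return sub
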