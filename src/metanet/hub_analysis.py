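"""Hub-gene scoring: average shortest-path distance to DEGs plus degree.

Within the analysis subnetwork, every module member is scored by the
mean unweighted shortest-path length to the DEG nodes (a DEG's distance
to itself is excluded from its own average; unreachable DEGs are
excluded and counted).  A node is flagged as a hub when its average
distance falls strictly below the module's lower quartile of average
distances AND its subnetwork degree reaches the degree cutoff.

The degree cutoff defaults to an inclusive >= 6; a strict > mode is
available (``strict_degree=True``) for the literal "more than"
reading, which however excludes known degree-6 hubs.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

DEFAULT_DEGREE_MIN = 6


def avg_distance_to_degs(
    node: str, subnet: nx.Graph, deg_nodes: set
) -> tuple[float, int, int]:
    """Mean shortest-path distance from ``node`` to the reachable DEGs.

    Returns (average, n_reachable, n_unreachable); average is NaN when no
    DEG is reachable.  The node itself, if a DEG, is excluded.
    """
    if node not in subnet:
        raise ValueError(f"node {node!r} not in subnetwork")
    targets = {d for d in deg_nodes if d in subnet and d != node}
    if not targets:
        raise ValueError("no DEG node in subnetwork to measure distance to")
    lengths = nx.single_source_shortest_path_length(subnet, node)
    dists = [lengths[t] for t in targets if t in lengths]
    n_unreachable = len(targets) - len(dists)
    if not dists:
        return float("nan"), 0, n_unreachable
    return float(np.mean(dists)), len(dists), n_unreachable


@dataclass
class HubReport:
    """Per-node hub scoring for one module."""

    module_id: str
    table: pd.DataFrame  # index node; avg_dist, sum_dist, degree, is_hub, ...
    quartile_cutoff: float
    degree_min: int

    @property
    def hubs(self) -> list[str]:
        return sorted(self.table.index[self.table["is_hub"]])


def select_hubs(
    module_nodes,
    subnet: nx.Graph,
    deg_nodes: set,
    degree_min: int = DEFAULT_DEGREE_MIN,
    *,
    strict_degree: bool = False,
    module_id: str = "M",
    quartile_method: str = "linear",
) -> HubReport:
    """Flag module members below the lower-quartile average DEG distance
    with degree at or above the cutoff.

    The quartile cutoff is the 25th percentile (linear interpolation by
    default) of the module members' average distances; the distance
    comparison is strict (<), so a module where everyone is equidistant
    has no hubs.  Nodes with no reachable DEG are never hubs.  Modules
    with fewer than 4 members make the quartile ill-defined and raise.
    """
    nodes = sorted(module_nodes)
    if len(nodes) < 4:
        raise ValueError(
            f"module of size {len(nodes)} too small for a lower quartile (need >=4)"
        )
    rows = []
    for n in nodes:
        avg, n_reach, n_unreach = avg_distance_to_degs(n, subnet, deg_nodes)
        rows.append(
            {
                "avg_dist": avg,
                "sum_dist": avg * n_reach if n_reach else float("nan"),
                "n_reachable_degs": n_reach,
                "n_unreachable_degs": n_unreach,
                "degree": subnet.degree(n),
            }
        )
    table = pd.DataFrame(rows, index=nodes)
    finite = table["avg_dist"].dropna()
    cutoff = float(np.percentile(finite, 25, method=quartile_method))
    deg_ok = (
        table["degree"] > degree_min
        if strict_degree
        else table["degree"] >= degree_min
    )
    table["is_hub"] = (table["avg_dist"] < cutoff) & deg_ok & finite.reindex(
        table.index
    ).notna()
    return HubReport(
        module_id=module_id,
        table=table,
        quartile_cutoff=cutoff,
        degree_min=degree_min,
    )
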