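"""Synthetic multi-study expression data, interaction networks and IHC
cohorts with the statistical structure the analysis pipeline assumes.

The expression generator emulates a multi-cohort microarray design:
several independent studies per platform group, each a log2 intensity
matrix with its own additive batch offset, a partially overlapping gene
panel, and a shared set of planted up/down-regulated genes whose log2
effect is added to tumor samples only.  Per-study batch offsets are the
hazard that motivates rank-based meta-analysis over naive cross-study
merging: they cancel inside a study's tumor-control contrast but would
dominate a pooled matrix.

The network generator plants dense near-cliques (and optionally a hub
wired to many differentially expressed genes) inside an Erdos-Renyi
background, so that density/cohesiveness thresholds and the hub distance
criterion have a known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .io_formats import CONTROL, TUMOR, ExpressionStudy

#: log2-scale baseline distribution of gene means, typical of RMA output
BASELINE_LOG2_MEAN = 7.0
BASELINE_LOG2_SD = 1.5


@dataclass
class SimulationConfig:
    """Configuration of the multi-study expression simulator.

    Planted effect sizes are log2 fold changes added to tumor samples;
    the same planted sets are used in every study (they are the
    meta-analysis target).  ``panel_overlap`` is the fraction of the gene
    universe measured by each study; planted genes are always on-panel.
    """

    n_genes: int = 500
    n_studies_per_group: int = 3
    samples_per_study: tuple[int, int] = (20, 10)  # (n_tumor, n_control)
    planted_up: dict[int, float] = field(default_factory=dict)
    planted_down: dict[int, float] = field(default_factory=dict)
    batch_sd: float = 1.0
    noise_sd: float = 0.7
    panel_overlap: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        n_tumor, n_control = self.samples_per_study
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if n_tumor <= 0 or n_control <= 0:
            raise ValueError("samples_per_study counts must be positive")
        if not (0.0 < self.panel_overlap <= 1.0):
            raise ValueError("panel_overlap must be in (0, 1]")
        if self.batch_sd < 0 or self.noise_sd < 0:
            raise ValueError("scales must be non-negative")
        planted = {**self.planted_up, **self.planted_down}
        for gid, eff in planted.items():
            if not (0 <= gid < self.n_genes):
                raise ValueError(f"planted gene id {gid} >= n_genes")
            if not np.isfinite(eff):
                raise ValueError(f"non-finite effect size for gene {gid}")
        overlap = set(self.planted_up) & set(self.planted_down)
        if overlap:
            raise ValueError(f"genes planted both up and down: {sorted(overlap)}")


def gene_name(i: int) -> str:
    return f"G{i:05d}"


def simulate_expression_studies(cfg: SimulationConfig) -> list[ExpressionStudy]:
    """Generate ``2 * n_studies_per_group`` studies (groups I and II).

    Each study's matrix is::

        baseline_g + batch_s + effect_g * 1[tumor] * sign + noise

    with baseline per gene drawn once (shared across studies), batch a
    per-study constant ~ N(0, batch_sd), planted effects on the log2
    scale (positive for up, negative for down) and iid Gaussian noise of
    scale ``noise_sd``.  Deterministic given the seed.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    genes = np.array([gene_name(i) for i in range(cfg.n_genes)])
    baseline = rng.normal(BASELINE_LOG2_MEAN, BASELINE_LOG2_SD, size=cfg.n_genes)
    effect = np.zeros(cfg.n_genes)
    for gid, eff in cfg.planted_up.items():
        effect[gid] = abs(eff)
    for gid, eff in cfg.planted_down.items():
        effect[gid] = -abs(eff)
    planted_ids = sorted(set(cfg.planted_up) | set(cfg.planted_down))

    n_tumor, n_control = cfg.samples_per_study
    panel_size = max(int(round(cfg.panel_overlap * cfg.n_genes)), len(planted_ids))
    studies: list[ExpressionStudy] = []
    for group in ("I", "II"):
        for s in range(cfg.n_studies_per_group):
            study_id = f"SIM_{group}_{s}"
            batch = rng.normal(0.0, cfg.batch_sd)
            # panel: random subset always containing the planted genes
            free = np.setdiff1d(np.arange(cfg.n_genes), planted_ids)
            n_extra = panel_size - len(planted_ids)
            chosen = rng.choice(free, size=n_extra, replace=False)
            panel = np.sort(np.concatenate([planted_ids, chosen]).astype(int))

            n_samples = n_tumor + n_control
            noise = rng.normal(0.0, cfg.noise_sd, size=(len(panel), n_samples))
            is_tumor = np.r_[np.ones(n_tumor), np.zeros(n_control)]
            mat = (
                baseline[panel, None]
                + batch
                + effect[panel, None] * is_tumor[None, :]
                + noise
            )
            sample_ids = [f"{study_id}_T{i}" for i in range(n_tumor)] + [
                f"{study_id}_C{i}" for i in range(n_control)
            ]
            classes = pd.Series(
                [TUMOR] * n_tumor + [CONTROL] * n_control, index=sample_ids
            )
            values = pd.DataFrame(mat, index=genes[panel], columns=sample_ids)
            studies.append(
                ExpressionStudy(
                    study_id=study_id,
                    platform_group=group,
                    values=values,
                    classes=classes,
                )
            )
    return studies


def planted_gene_names(cfg: SimulationConfig) -> tuple[set[str], set[str]]:
    """Ground-truth planted symbol sets (up, down)."""
    return (
        {gene_name(i) for i in cfg.planted_up},
        {gene_name(i) for i in cfg.planted_down},
    )


@dataclass
class NetworkSimConfig:
    """Configuration of the background-network simulator.

    ``planted_modules`` are (node id list, internal edge probability)
    pairs; module internal probability must exceed the background edge
    probability implied by ``background_degree``.  ``planted_hub``
    optionally names a node wired to every node in ``hub_targets``
    (e.g. planted DEGs), creating a known low-distance, high-degree hub.
    """

    n_nodes: int = 60
    background_degree: float = 1.2
    planted_modules: list[tuple[list[int], float]] = field(default_factory=list)
    planted_hub: int | None = None
    hub_targets: list[int] = field(default_factory=list)
    seed: int = 0
    preferential_attachment: bool = False

    @property
    def background_p(self) -> float:
        if self.n_nodes <= 1:
            return 0.0
        return min(self.background_degree / (self.n_nodes - 1), 1.0)

    def validate(self) -> None:
        if self.n_nodes < 0:
            raise ValueError("n_nodes must be non-negative")
        for nodes, p_in in self.planted_modules:
            if p_in <= self.background_p:
                raise ValueError(
                    "planted internal edge probability must exceed background "
                    f"({p_in} <= {self.background_p:.4g})"
                )
            for v in nodes:
                if not (0 <= v < self.n_nodes):
                    raise ValueError(f"planted module node {v} out of range")
        if self.planted_hub is not None and not (0 <= self.planted_hub < self.n_nodes):
            raise ValueError("planted_hub out of range")


def node_name(i: int) -> str:
    return f"P{i:04d}"


def simulate_network(cfg: NetworkSimConfig) -> nx.Graph:
    """Simple undirected background graph with planted dense modules.

    Background is Erdos-Renyi by default (preferential attachment behind
    a flag for degree-criterion testing); planted modules add internal
    edges at their own probability on top of the background.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    G = nx.Graph()
    G.add_nodes_from(node_name(i) for i in range(cfg.n_nodes))
    if cfg.n_nodes == 0:
        return G

    if cfg.preferential_attachment:
        m = max(int(round(cfg.background_degree / 2)), 1)
        seed_int = int(rng.integers(0, 2**31 - 1))
        bg = nx.barabasi_albert_graph(cfg.n_nodes, m, seed=seed_int)
        G.add_edges_from((node_name(a), node_name(b)) for a, b in bg.edges())
    else:
        p = cfg.background_p
        iu, ju = np.triu_indices(cfg.n_nodes, k=1)
        mask = rng.random(len(iu)) < p
        G.add_edges_from(
            (node_name(a), node_name(b)) for a, b in zip(iu[mask], ju[mask])
        )

    for nodes, p_in in cfg.planted_modules:
        nodes = sorted(nodes)
        for i, a in enumerate(nodes):
            for b in nodes[i + 1 :]:
                if rng.random() < p_in:
                    G.add_edge(node_name(a), node_name(b))

    if cfg.planted_hub is not None:
        hub = node_name(cfg.planted_hub)
        for t in cfg.hub_targets:
            if t != cfg.planted_hub:
                G.add_edge(hub, node_name(t))

    G.remove_edges_from(nx.selfloop_edges(G))
    return G


def write_pipeline_fixture(outdir, seed: int = 0) -> "Path":
    """Write a small but complete input bundle for the full pipeline.

    Six simulated expression studies (three per platform group, six
    planted DEGs among 150 genes), one held-out testing study, a
    deterministic interaction network containing a dense 8-node module
    (7-ring of the planted genes plus one linker, all spoked to a hub
    protein) with a sparse tail, a two-set GMT and a simulated IHC
    cohort.  Returns the path of a ready-to-run pipeline config (YAML).

    The planted module is sized so every downstream filter passes: the
    module has 8 nodes and density 0.5, and the hub (average DEG
    distance 1.0 against a lower quartile of 1.6, degree 7) is the
    unique node satisfying the hub rule.
    """
    from pathlib import Path

    import yaml

    from .io_formats import write_expression, write_edge_list, write_gmt
    from .io_formats import GeneSetCollection

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = SimulationConfig(
        n_genes=150,
        n_studies_per_group=3,
        samples_per_study=(10, 5),
        planted_up={0: 2.0, 1: 2.0, 2: 2.0, 3: 2.0},
        planted_down={4: 2.0, 5: 2.0},
        batch_sd=0.8,
        noise_sd=0.5,
        seed=seed,
    )
    studies = simulate_expression_studies(cfg)
    groups: dict[str, list[list[str]]] = {"I": [], "II": []}
    for s in studies:
        m = outdir / f"{s.study_id}_matrix.tsv"
        c = outdir / f"{s.study_id}_classes.tsv"
        write_expression(s, m, c)
        groups[s.platform_group].append([str(m), str(c)])

    test_cfg = SimulationConfig(
        n_genes=150,
        n_studies_per_group=1,
        samples_per_study=(10, 5),
        planted_up=cfg.planted_up,
        planted_down=cfg.planted_down,
        batch_sd=0.8,
        noise_sd=0.5,
        seed=seed + 1000,
    )
    test_study = simulate_expression_studies(test_cfg)[0]
    tm = outdir / "TEST_matrix.tsv"
    tc = outdir / "TEST_classes.tsv"
    write_expression(test_study, tm, tc)

    # deterministic network: 7-ring of the planted genes + linker, a hub
    # spoked to every ring node, and a sparse tail hanging off the module
    ring = [gene_name(i) for i in range(7)]
    hub = gene_name(7)
    edges = [(ring[i], ring[(i + 1) % 7]) for i in range(7)]
    edges += [(hub, r) for r in ring]
    tail = [gene_name(i) for i in range(10, 20)]
    edges += list(zip(tail, tail[1:]))
    edges += [(ring[0], tail[0]), (hub, tail[5])]
    edge_path = outdir / "interactions.tsv"
    write_edge_list(edges, edge_path)

    gmt_path = outdir / "sets.gmt"
    write_gmt(
        GeneSetCollection(
            sets={
                "PLANTED_UP": frozenset(gene_name(i) for i in range(4)),
                "TAIL": frozenset(tail),
            },
            descriptions={"PLANTED_UP": "planted up set", "TAIL": "background"},
        ),
        gmt_path,
    )

    ihc_params = {
        (grp, protein): dict(
            intensity_mean=mu_i, intensity_sd=0.5,
            percent_mean=mu_p, percent_sd=15.0,
        )
        for protein in ("MMP9", "BGH3", "PDIA3")
        for grp, mu_i, mu_p in (
            ("NOM", 1, 15), ("OLK", 2, 40), ("OSCC", 3, 75),
        )
    }
    ihc_table = simulate_ihc_cohort(
        ihc_params, {"NOM": 8, "OLK": 10, "OSCC": 12}, seed=seed + 17
    )
    ihc_path = outdir / "ihc.tsv"
    ihc_table.to_csv(ihc_path, sep="\t", index=False)

    config = {
        "group_I": groups["I"],
        "group_II": groups["II"],
        "testing": [[str(tm), str(tc)]],
        "edge_lists": [str(edge_path)],
        "gmt": str(gmt_path),
        "ihc": str(ihc_path),
        "fdr": 0.01,
        "fc": 2.0,
        "min_size": 7,
        "min_density": 0.3,
        "alpha": 0.05,
        "degree_min": 6,
        "n_perm": 500,
        "seed": seed,
    }
    config_path = outdir / "pipeline.yaml"
    with open(config_path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return config_path


def simulate_ihc_cohort(
    group_params: dict[tuple[str, str], dict[str, float]],
    n_per_group: dict[str, int],
    seed: int = 0,
) -> pd.DataFrame:
    """Per-specimen IHC table drawn from per-(group, protein) Gaussians.

    ``group_params`` maps (group, protein) to a dict with keys
    ``intensity_mean``, ``intensity_sd``, ``percent_mean``, ``percent_sd``.
    Intensity draws are rounded and clipped to the ordinal grades {0..3};
    percent positive is clipped to [0, 100].  Groups with n = 0 are absent
    from the output.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for (group, protein), params in sorted(group_params.items()):
        n = n_per_group.get(group, 0)
        if n < 0:
            raise ValueError(f"negative n for group {group}")
        for key in ("intensity_sd", "percent_sd"):
            if params[key] < 0:
                raise ValueError(f"negative SD in params for ({group}, {protein})")
        if not (0 <= params["intensity_mean"] <= 3):
            raise ValueError("intensity mean must lie in [0, 3]")
        if not (0 <= params["percent_mean"] <= 100):
            raise ValueError("percent mean must lie in [0, 100]")
        intensity = rng.normal(params["intensity_mean"], params["intensity_sd"], n)
        percent = rng.normal(params["percent_mean"], params["percent_sd"], n)
        intensity = np.clip(np.rint(intensity), 0, 3).astype(int)
        percent = np.clip(percent, 0.0, 100.0)
        for i in range(n):
            rows.append(
                {
                    "specimen": f"{group}_{protein}_{i:03d}",
                    "group": group,
                    "protein": protein,
                    "intensity": int(intensity[i]),
                    "percent_positive": float(percent[i]),
                }
            )
    return pd.DataFrame(
        rows, columns=["specimen", "group", "protein", "intensity", "percent_positive"]
    )
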