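"""End-to-end pipeline: DEG meta-analysis -> network -> modules -> hubs
-> validation -> enrichment (-> IHC summary), from a single config.

Every stage writes a schema-stable JSON artifact (GraphML for the
subnetwork) into the output directory, and a manifest ties the stages
together with SHA-256 hashes of all inputs and outputs.  Outputs carry
no timestamps, so a rerun with the same config and seed is byte-identical.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import (
    deg_meta,
    enrichment,
    hub_analysis,
    ihc_stats,
    io_formats,
    module_detection,
    ppi_network,
    validation_rates,
)


class PipelineError(RuntimeError):
    """Stage failure; message carries the stage name and cause."""


@dataclass
class PipelineConfig:
    """All inputs and thresholds of one pipeline run.

    ``group_I`` / ``group_II`` / ``testing`` are lists of
    (matrix TSV, class TSV) path pairs; thresholds default to the
    pipeline's reference values (pfp < 0.01 and fold change >= 2 for DEG
    calls; module size >= 7, density >= 0.3, p < 0.05; hub degree >= 6).
    """

    group_I: list[tuple[str, str]] = field(default_factory=list)
    group_II: list[tuple[str, str]] = field(default_factory=list)
    testing: list[tuple[str, str]] = field(default_factory=list)
    edge_lists: list[str] = field(default_factory=list)
    gmt: str | None = None
    ihc: str | None = None
    fdr: float = 0.01
    fc: float = 2.0
    min_size: int = 7
    min_density: float = 0.3
    alpha: float = 0.05
    degree_min: int = 6
    n_perm: int = 1000
    seed: int | None = None

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("group_I", "group_II", "testing"):
            if key in raw:
                raw[key] = [tuple(pair) for pair in raw[key]]
        return cls(**raw)

    def validate(self) -> None:
        if not self.group_I or not self.group_II:
            raise ValueError("both platform groups need at least one study")
        if self.seed is None:
            raise ValueError("seed is mandatory (permutation null is stochastic)")
        if not (0 < self.fdr <= 1) or self.fc < 1:
            raise ValueError("fdr must be in (0,1], fc >= 1")
        if self.min_size < 1 or not (0 <= self.min_density <= 1):
            raise ValueError("invalid module thresholds")
        if not (0 < self.alpha <= 1) or self.degree_min < 0:
            raise ValueError("invalid alpha or degree_min")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _read_studies(pairs, group_tag):
    return [
        io_formats.read_expression(m, c, group_tag) for m, c in pairs
    ]


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage in order and return the manifest (also written to
    ``manifest.json``).  Any stage error aborts with the stage name."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": _config_dict(config), "stages": []}

    def stage(name):
        def wrap(fn):
            try:
                outputs = fn()
            except PipelineError:
                raise
            except Exception as e:
                raise PipelineError(f"stage {name!r} failed: {e}") from e
            manifest["stages"].append(
                {
                    "name": name,
                    "outputs": {
                        str(p.name): _sha256(p) for p in outputs
                    },
                }
            )
            return outputs

        return wrap

    # --- DEG meta-analysis ------------------------------------------------
    state: dict = {}

    @stage("deg")
    def _deg():
        studies_I = _read_studies(config.group_I, "I")
        studies_II = _read_studies(config.group_II, "II")
        meta_I = deg_meta.group_meta(studies_I, config.n_perm, config.seed)
        meta_II = deg_meta.group_meta(studies_II, config.n_perm, config.seed + 2)
        degs_I = deg_meta.call_degs(meta_I, config.fdr, config.fc)
        degs_II = deg_meta.call_degs(meta_II, config.fdr, config.fc)
        combined = deg_meta.intersect_groups(degs_I, degs_II)
        state.update(
            studies_I=studies_I,
            studies_II=studies_II,
            meta_I=meta_I,
            meta_II=meta_II,
            degs=combined,
        )
        out = outdir / "degs.json"
        io_formats.write_report(
            {
                "group_I": {"up": degs_I.up, "down": degs_I.down},
                "group_II": {"up": degs_II.up, "down": degs_II.down},
                "combined": {"up": combined.up, "down": combined.down},
                "thresholds": {"fdr": config.fdr, "fc": config.fc,
                               "n_perm": config.n_perm, "seed": config.seed},
            },
            out,
        )
        return [out]

    # --- Background network + Steiner subnetwork --------------------------
    @stage("network")
    def _network():
        if not config.edge_lists:
            raise PipelineError(
                "stage 'network' failed: no edge lists configured"
            )
        pairs = io_formats.read_edge_lists(*config.edge_lists)
        background = ppi_network.integrate_background(pairs)
        subnet = ppi_network.analysis_subnetwork(background, state["degs"])
        state.update(background=background, subnet=subnet)
        out = outdir / "subnet.graphml"
        io_formats.export_graphml(subnet, out)
        summary = outdir / "network.json"
        terminals, unmapped = ppi_network.map_terminals(background, state["degs"])
        io_formats.write_report(
            {
                "background_nodes": background.number_of_nodes(),
                "background_edges": background.number_of_edges(),
                "subnet_nodes": subnet.number_of_nodes(),
                "subnet_edges": subnet.number_of_edges(),
                "terminals": sorted(terminals),
                "unmapped_degs": sorted(unmapped),
            },
            summary,
        )
        return [out, summary]

    # --- Dense modules ----------------------------------------------------
    @stage("modules")
    def _modules():
        modules = module_detection.detect_modules(
            state["subnet"],
            min_size=config.min_size,
            min_density=config.min_density,
            alpha=config.alpha,
        )
        state["modules"] = modules
        out = outdir / "modules.json"
        io_formats.write_report([m.as_dict() for m in modules], out)
        return [out]

    # --- Hub genes --------------------------------------------------------
    @stage("hubs")
    def _hubs():
        deg_nodes = {
            n for n in state["subnet"]
            if state["subnet"].nodes[n].get("is_deg")
        }
        reports = []
        for m in state["modules"]:
            if len(m.nodes) < 4:
                continue
            rep = hub_analysis.select_hubs(
                m.nodes,
                state["subnet"],
                deg_nodes,
                degree_min=config.degree_min,
                module_id=m.id,
            )
            reports.append(rep)
        state["hub_reports"] = reports
        out = outdir / "hubs.json"
        io_formats.write_report(
            [
                {
                    "module": rep.module_id,
                    "quartile_cutoff": rep.quartile_cutoff,
                    "degree_min": rep.degree_min,
                    "hubs": rep.hubs,
                    "nodes": {
                        str(n): {
                            "avg_dist": row["avg_dist"],
                            "degree": int(row["degree"]),
                            "is_hub": bool(row["is_hub"]),
                        }
                        for n, row in rep.table.iterrows()
                    },
                }
                for rep in reports
            ],
            out,
        )
        return [out]

    # --- Validated rates --------------------------------------------------
    @stage("validation")
    def _validation():
        hubs = sorted({h for rep in state["hub_reports"] for h in rep.hubs})
        directions = state["degs"].direction_of()
        # hubs need not be DEGs; fall back to the sign of the combined FC
        fc_tables = [state["meta_I"].table, state["meta_II"].table]
        genes = {}
        for g in hubs:
            if g in directions:
                genes[g] = directions[g]
            else:
                import numpy as np

                log_fcs = [
                    np.log2(t.loc[g, "fc"])
                    for t in fc_tables
                    if g in t.index and np.isfinite(t.loc[g, "fc"])
                ]
                genes[g] = (
                    deg_meta.UP
                    if not log_fcs or float(np.mean(log_fcs)) >= 0
                    else deg_meta.DOWN
                )
        training = state["studies_I"] + state["studies_II"]
        testing = _read_studies(config.testing, "I") if config.testing else []
        report = validation_rates.validation_table(genes, training, testing)
        state["validation"] = report
        out = outdir / "validation.json"
        io_formats.write_report(
            {
                "per_dataset": report.per_dataset.to_dict(orient="records"),
                "pooled": report.pooled.to_dict(orient="records"),
            },
            out,
        )
        return [out]

    # --- Enrichment -------------------------------------------------------
    if config.gmt:

        @stage("enrichment")
        def _enrichment():
            sets = io_formats.read_gmt(config.gmt)
            background = set().union(
                *(s.genes for s in state["studies_I"] + state["studies_II"])
            )
            degs = (state["degs"].up | state["degs"].down) & background
            table = enrichment.enrich(degs, background, sets, config.alpha)
            out = outdir / "enrichment.json"
            io_formats.write_report(table.to_dict(orient="records"), out)
            return [out]

    # --- IHC summary ------------------------------------------------------
    if config.ihc:

        @stage("ihc")
        def _ihc():
            import pandas as pd

            records = pd.read_csv(config.ihc, sep="\t")
            summary = ihc_stats.group_summary(records)
            corr = ihc_stats.protein_correlations(records)
            scored = ihc_stats.add_irs(records)
            anova = {}
            for protein, sub in scored.groupby("protein"):
                groups = [
                    g["irs"].to_numpy() for _, g in sub.groupby("group")
                    if len(g) >= 2
                ]
                if len(groups) >= 2:
                    F, p = ihc_stats.one_way_anova(*groups)
                    anova[protein] = {"F": F, "p": p}
            out = outdir / "ihc.json"
            io_formats.write_report(
                {
                    "summary": summary.to_dict(orient="records"),
                    "correlations": corr.to_dict(orient="records"),
                    "anova": anova,
                },
                out,
            )
            return [out]

    manifest["inputs"] = {
        str(p): _sha256(Path(p))
        for p in _input_paths(config)
    }
    out = outdir / "manifest.json"
    io_formats.write_report(manifest, out)
    return manifest


def _config_dict(config: PipelineConfig) -> dict:
    d = {}
    for name in config.__dataclass_fields__:
        v = getattr(config, name)
        if isinstance(v, list):
            v = [list(x) if isinstance(x, tuple) else x for x in v]
        d[name] = v
    return d


def _input_paths(config: PipelineConfig) -> list[str]:
    paths: list[str] = []
    for pair in config.group_I + config.group_II + config.testing:
        paths.extend(pair)
    paths.extend(config.edge_lists)
    for p in (config.gmt, config.ihc):
        if p:
            paths.append(p)
    return sorted(paths)
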