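"""Rank-product DE meta-analysis on simulated multi-study data.

Simulates two platform groups of three microarray studies each, with ten
up- and ten down-regulated genes planted at log2 effect 1.5, runs the
rank-product meta-analysis per group and intersects the calls.
"""

from metanet import (
    SimulationConfig,
    call_degs,
    group_meta,
    intersect_groups,
    simulate_expression_studies,
)
from metanet.synthetic import planted_gene_names

cfg = SimulationConfig(
    n_genes=500,
    n_studies_per_group=3,
    samples_per_study=(20, 10),
    planted_up={i: 1.5 for i in range(10)},
    planted_down={i: 1.5 for i in range(10, 20)},
    batch_sd=1.0,
    noise_sd=0.7,
    seed=1,
)
studies = simulate_expression_studies(cfg)
by_group = {g: [s for s in studies if s.platform_group == g] for g in ("I", "II")}

meta_I = group_meta(by_group["I"], n_perm=1000, seed=11)
meta_II = group_meta(by_group["II"], n_perm=1000, seed=22)
degs = intersect_groups(call_degs(meta_I), call_degs(meta_II))

up_true, down_true = planted_gene_names(cfg)
print(f"called up:   {len(degs.up):3d}  (planted up recovered: "
      f"{len(degs.up & up_true)}/{len(up_true)})")
print(f"called down: {len(degs.down):3d}  (planted down recovered: "
      f"{len(degs.down & down_true)}/{len(down_true)})")
false = (degs.up | degs.down) - (up_true | down_true)
print(f"false calls: {len(false)}")

top = meta_I.table.sort_values("pfp_up").head(3)
print("\ntop group-I genes by up-direction pfp:")
print(top[["rp_up", "pfp_up", "fc"]].round(3))
# A gene is a DEG when its permutation FDR (pfp) is below 0.01 and its
# group geometric-mean fold change is at least 2 in BOTH platform groups
# with the same direction; at these settings the planted signal is
# recovered nearly completely with no false calls.
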