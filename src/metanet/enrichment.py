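"""Gene-set over-representation of a DEG list against a measured background.

One-sided hypergeometric upper-tail test per gene set — P(X >= k) for k
DEGs among the set's K background-measured members, drawing n DEGs from
a background of N genes — with Benjamini-Hochberg correction across the
tested sets.  Sets are intersected with the background before testing
and sets with zero overlap are excluded before correction.

The background defaults to the union of genes actually measured in the
expression studies (not the whole genome), the standard correction for
platform coverage.
"""

from __future__ import annotations

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io_formats import GeneSetCollection, canonicalize


def enrich(
    deg_genes,
    background_genes,
    sets: GeneSetCollection,
    fdr_thresh: float = 0.05,
) -> pd.DataFrame:
    """Over-representation table, one row per tested set, sorted by FDR.

    Columns: set, k (overlap), K (set size in background), n (DEG count),
    N (background size), p (hypergeometric upper tail), fdr (BH),
    significant (fdr < fdr_thresh), overlap_genes.
    """
    background = {canonicalize(g) for g in background_genes}
    if not background:
        raise ValueError("empty background")
    degs = {canonicalize(g) for g in deg_genes}
    stray = degs - background
    if stray:
        raise ValueError(
            f"DEG(s) not in background: {sorted(stray)[:5]}"
            f"{'...' if len(stray) > 5 else ''}"
        )
    N = len(background)
    n = len(degs)
    rows = []
    for name, members in sorted(sets.items()):
        in_bg = {canonicalize(g) for g in members} & background
        overlap = in_bg & degs
        k, K = len(overlap), len(in_bg)
        if k == 0:
            continue
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "set": name,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p": p,
                "overlap_genes": sorted(overlap),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["set", "k", "K", "n", "N", "p", "fdr", "significant",
                     "overlap_genes"]
        )
    table = pd.DataFrame(rows)
    _, fdr, _, _ = multipletests(table["p"], method="fdr_bh")
    table["fdr"] = fdr
    table["significant"] = table["fdr"] < fdr_thresh
    table = table.sort_values(["fdr", "p", "set"], kind="stable").reset_index(
        drop=True
    )
    return table[
        ["set", "k", "K", "n", "N", "p", "fdr", "significant", "overlap_genes"]
    ]
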