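"""Rank-product meta-analysis of fold changes across studies.

Within each platform group every study contributes one fold-change
ranking of its measured genes; a gene's rank product is the geometric
mean of its ranks across the studies that measure it, small values
indicating consistently extreme regulation in the requested direction.
Significance is attached as the pfp (proportion of false predictions, a
permutation-based FDR estimate): each study's rank vector is permuted
independently, null rank products are pooled, and the expected number of
null values at least as extreme as an observed one is divided by the
observed value's position in the ranking.

One rank vector per study is built from the class-mean fold change; the
original all-pairs formulation (every tumor-control sample pair ranked
separately) is available via ``pairwise=True``.

Batch effects that are additive per study cancel inside the tumor-minus-
control contrast, which is why ranking within studies and aggregating
ranks is robust where pooling raw intensities across platforms is not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io_formats import CONTROL, TUMOR, ExpressionStudy

UP = "up"
DOWN = "down"

#: relative slack when counting null rank products <= an observed one, so
#: exact rational ties (ubiquitous at toy scale) are counted regardless of
#: floating-point rounding path
_TIE_RTOL = 1e-12

MIN_PERMUTATIONS = 100


def study_fold_changes(study: ExpressionStudy, *, pairwise: bool = False) -> pd.Series:
    """Per-gene linear fold change, FC = 2^(mean log2 tumor - mean log2 control).

    With ``pairwise=True`` returns a DataFrame of per-pair fold changes
    (one column per tumor x control sample pair) instead.
    """
    tumor = study.samples_of(TUMOR)
    control = study.samples_of(CONTROL)
    if not tumor or not control:
        raise ValueError(
            f"study {study.study_id} needs >=1 tumor and >=1 control sample"
        )
    tmat = study.values[tumor]
    cmat = study.values[control]
    if tmat.isna().all(axis=1).any() or cmat.isna().all(axis=1).any():
        bad = study.values.index[
            tmat.isna().all(axis=1) | cmat.isna().all(axis=1)
        ][0]
        raise ValueError(f"gene {bad} has all-missing values in one class")
    if pairwise:
        cols = {}
        for t in tumor:
            for c in control:
                cols[f"{t}|{c}"] = np.power(2.0, study.values[t] - study.values[c])
        return pd.DataFrame(cols)
    diff = tmat.mean(axis=1) - cmat.mean(axis=1)
    return np.power(2.0, diff)


def rank_within_study(fc: pd.Series, direction: str) -> pd.Series:
    """Rank genes by fold change; rank 1 = most extreme in ``direction``.

    Largest FC ranks first for "up", smallest for "down"; ties receive
    the average rank.
    """
    if len(fc) < 2:
        raise ValueError("need >=2 genes to rank")
    if direction == UP:
        ranks = rankdata(-fc.to_numpy())
    elif direction == DOWN:
        ranks = rankdata(fc.to_numpy())
    else:
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    return pd.Series(ranks, index=fc.index)


def rank_product(ranks) -> float:
    """Geometric mean of a gene's ranks across the studies measuring it."""
    arr = np.asarray(list(ranks), dtype=float)
    if arr.size == 0:
        raise ValueError("empty rank list")
    return float(np.exp(np.mean(np.log(arr))))


def _rank_matrix(
    studies: list[ExpressionStudy], direction: str, *, pairwise: bool = False
) -> tuple[pd.DataFrame, pd.Index]:
    """Stack per-study rank vectors into a studies x genes matrix (NaN =
    gene not on that study's panel).  In pairwise mode each tumor-control
    pair of each study contributes one ranking."""
    all_genes = pd.Index(sorted(set().union(*(s.genes for s in studies))))
    rows = []
    for s in studies:
        if pairwise:
            fc_pairs = study_fold_changes(s, pairwise=True)
            for col in fc_pairs.columns:
                rows.append(rank_within_study(fc_pairs[col], direction))
        else:
            rows.append(rank_within_study(study_fold_changes(s), direction))
    R = pd.DataFrame([r.reindex(all_genes) for r in rows])
    R.index = range(len(rows))
    return R, all_genes


def _null_rank_products(
    R: np.ndarray, k_per_gene: np.ndarray, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Null RPs from permuting each ranking's values among its measured
    genes, independently per ranking and permutation.  Returns a flat array
    of n_perm * n_ranked values (genes measured in >=2 rankings only)."""
    n_rankings, n_genes = R.shape
    log_sum = np.zeros((n_perm, n_genes))
    for i in range(n_rankings):
        measured = ~np.isnan(R[i])
        vals = np.log(R[i, measured])
        tiled = np.broadcast_to(vals, (n_perm, vals.size)).copy()
        log_sum[:, measured] += rng.permuted(tiled, axis=1)
    ranked = k_per_gene >= 2
    null_rp = np.exp(log_sum[:, ranked] / k_per_gene[ranked])
    return null_rp.ravel()


def _pfp_from_null(
    rp_obs: np.ndarray, null_sorted: np.ndarray, n_perm: int
) -> np.ndarray:
    """pfp for each observed RP: expected null count at or below it,
    divided by its 1-based position in the observed ranking; then made
    monotone non-decreasing down the ranking and capped at 1."""
    order = np.argsort(rp_obs, kind="stable")
    pfp = np.empty_like(rp_obs)
    counts = np.searchsorted(
        null_sorted, rp_obs[order] * (1.0 + _TIE_RTOL), side="right"
    )
    x = np.arange(1, len(order) + 1)
    vals = counts / (n_perm * x)
    vals = np.minimum(np.maximum.accumulate(vals), 1.0)
    pfp[order] = vals
    return pfp


def estimate_pfp(
    studies: list[ExpressionStudy],
    direction: str,
    n_perm: int,
    seed: int,
    *,
    pairwise: bool = False,
) -> pd.DataFrame:
    """Observed rank products and permutation pfp for one direction.

    Returns a DataFrame indexed by gene with columns ``rp``, ``pfp`` and
    ``k`` (number of rankings containing the gene).  Genes measured in
    fewer than 2 rankings are reported with NaN rp/pfp but never ranked.
    """
    if n_perm < MIN_PERMUTATIONS:
        raise ValueError(
            f"n_perm={n_perm} too small; use at least {MIN_PERMUTATIONS} "
            "permutations for a usable pfp estimate"
        )
    R_df, genes = _rank_matrix(studies, direction, pairwise=pairwise)
    R = R_df.to_numpy()
    k = (~np.isnan(R)).sum(axis=0)
    ranked = k >= 2

    with np.errstate(invalid="ignore"):
        log_sum = np.nansum(np.log(R), axis=0)
    rp = np.full(len(genes), np.nan)
    rp[ranked] = np.exp(log_sum[ranked] / k[ranked])

    rng = np.random.default_rng(seed)
    null_sorted = np.sort(_null_rank_products(R, k, n_perm, rng))
    pfp = np.full(len(genes), np.nan)
    pfp[ranked] = _pfp_from_null(rp[ranked], null_sorted, n_perm)
    return pd.DataFrame({"rp": rp, "pfp": pfp, "k": k}, index=genes)


@dataclass
class RankProductResult:
    """Per-gene meta-analysis result for one platform group."""

    group: str
    table: pd.DataFrame  # columns: rp_up, pfp_up, rp_down, pfp_down, fc, k
    n_perm: int
    seed: int

    def __post_init__(self) -> None:
        ranked = self.table["k"] >= 2
        for col in ("rp_up", "rp_down"):
            vals = self.table.loc[ranked, col]
            if (vals < 1 - 1e-9).any():
                raise ValueError("rank product below 1")


def group_meta(
    studies: list[ExpressionStudy],
    n_perm: int = 10_000,
    seed: int = 0,
    *,
    pairwise: bool = False,
) -> RankProductResult:
    """Full two-direction rank-product analysis of one platform group.

    The per-group fold change is the geometric mean of the per-study fold
    changes (arithmetic mean of per-study log2 fold changes), consistent
    with ranks being aggregated on the log scale.
    """
    if not studies:
        raise ValueError("no studies supplied")
    groups = {s.platform_group for s in studies}
    if len(groups) > 1:
        raise ValueError(f"studies span multiple platform groups: {sorted(groups)}")
    up = estimate_pfp(studies, UP, n_perm, seed, pairwise=pairwise)
    down = estimate_pfp(studies, DOWN, n_perm, seed + 1, pairwise=pairwise)

    log_fc = pd.DataFrame(
        {s.study_id: np.log2(study_fold_changes(s)) for s in studies}
    )
    fc_geo = np.power(2.0, log_fc.mean(axis=1, skipna=True)).reindex(up.index)

    table = pd.DataFrame(
        {
            "rp_up": up["rp"],
            "pfp_up": up["pfp"],
            "rp_down": down["rp"],
            "pfp_down": down["pfp"],
            "fc": fc_geo,
            "k": up["k"],
        }
    )
    return RankProductResult(
        group=studies[0].platform_group, table=table, n_perm=n_perm, seed=seed
    )


@dataclass
class DEGSet:
    """Directional DEG calls with the thresholds that produced them."""

    up: set[str] = field(default_factory=set)
    down: set[str] = field(default_factory=set)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = self.up & self.down
        if overlap:
            raise ValueError(f"genes called both up and down: {sorted(overlap)}")

    def direction_of(self) -> dict[str, str]:
        d = {g: UP for g in self.up}
        d.update({g: DOWN for g in self.down})
        return d

    def __len__(self) -> int:
        return len(self.up) + len(self.down)


def call_degs(
    result: RankProductResult, fdr_thresh: float = 0.01, fc_thresh: float = 2.0
) -> DEGSet:
    """Threshold DEG calling: pfp below ``fdr_thresh`` and group
    geometric-mean fold change at least ``fc_thresh`` (up) or at most its
    reciprocal (down); the fold-change cut is inclusive."""
    if fdr_thresh <= 0 or fc_thresh <= 0:
        raise ValueError("thresholds must be positive")
    if fc_thresh < 1:
        raise ValueError("fc_thresh below 1 makes up/down calls overlap")
    t = result.table
    up = set(t.index[(t["pfp_up"] < fdr_thresh) & (t["fc"] >= fc_thresh)])
    down = set(t.index[(t["pfp_down"] < fdr_thresh) & (t["fc"] <= 1.0 / fc_thresh)])
    return DEGSet(
        up=up,
        down=down,
        provenance={
            "group": result.group,
            "fdr_thresh": fdr_thresh,
            "fc_thresh": fc_thresh,
            "n_perm": result.n_perm,
            "seed": result.seed,
        },
    )


def intersect_groups(degs_a: DEGSet, degs_b: DEGSet) -> DEGSet:
    """Genes called in BOTH groups with the SAME direction."""
    return DEGSet(
        up=degs_a.up & degs_b.up,
        down=degs_a.down & degs_b.down,
        provenance={"intersection_of": [degs_a.provenance, degs_b.provenance]},
    )
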