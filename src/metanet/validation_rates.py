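"""Per-dataset fold change and the "validated rate" concordance statistic.

The validated rate of an up-regulated candidate gene in one dataset is
the fraction of tumor samples whose expression lies strictly above the
mean of the control samples (strictly below it for a down-regulated
gene).  Rates pooled across datasets are count-weighted — total
concordant tumor samples over total tumor samples — never the mean of
per-dataset rates.  Comparisons happen on the stored log2 scale, which
is equivalent to linear for a monotone threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .deg_meta import DOWN, UP, study_fold_changes
from .io_formats import CONTROL, TUMOR, ExpressionStudy


def validated_counts(
    study: ExpressionStudy, gene: str, direction: str
) -> tuple[int, int]:
    """(concordant tumor samples, total tumor samples) for one gene.

    The threshold is the mean control intensity; a tumor sample exactly
    at the threshold does not validate.
    """
    if direction not in (UP, DOWN):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    if gene not in study.values.index:
        raise KeyError(f"gene {gene!r} not measured in study {study.study_id}")
    controls = study.samples_of(CONTROL)
    tumors = study.samples_of(TUMOR)
    if not controls:
        raise ValueError(f"study {study.study_id} has no control samples")
    threshold = float(study.values.loc[gene, controls].mean())
    vals = study.values.loc[gene, tumors].to_numpy(dtype=float)
    if direction == UP:
        k = int(np.sum(vals > threshold))
    else:
        k = int(np.sum(vals < threshold))
    return k, len(tumors)


def validated_rate(study: ExpressionStudy, gene: str, direction: str) -> float:
    """Fraction of tumor samples on the DEG-direction side of the control
    mean."""
    k, n = validated_counts(study, gene, direction)
    return k / n


@dataclass
class ValidationReport:
    """Per gene x dataset fold changes and rates plus pooled totals."""

    per_dataset: pd.DataFrame  # gene, dataset, split, fc, rate, k, n_tumor
    pooled: pd.DataFrame  # gene, split, rate, k, n_tumor


def validation_table(
    genes: dict[str, str],
    training_studies: list[ExpressionStudy],
    testing_studies: list[ExpressionStudy],
) -> ValidationReport:
    """Validated rate and fold change of each candidate gene in every
    training and testing dataset, with count-pooled totals.

    ``genes`` maps gene symbol to its direction fixed at the DEG stage.
    Genes absent from a dataset get an NA row there and contribute
    nothing to that split's pooled totals.
    """
    rows = []
    splits = [("training", training_studies), ("testing", testing_studies)]
    for split, studies in splits:
        for study in studies:
            fc = study_fold_changes(study)
            for gene, direction in genes.items():
                if gene in study.values.index:
                    k, n = validated_counts(study, gene, direction)
                    rows.append(
                        {
                            "gene": gene,
                            "dataset": study.study_id,
                            "split": split,
                            "direction": direction,
                            "fc": float(fc[gene]),
                            "rate": k / n,
                            "k": k,
                            "n_tumor": n,
                        }
                    )
                else:
                    rows.append(
                        {
                            "gene": gene,
                            "dataset": study.study_id,
                            "split": split,
                            "direction": direction,
                            "fc": np.nan,
                            "rate": np.nan,
                            "k": 0,
                            "n_tumor": 0,
                        }
                    )
    per_dataset = pd.DataFrame(
        rows,
        columns=["gene", "dataset", "split", "direction", "fc", "rate", "k", "n_tumor"],
    )

    pooled_rows = []
    for gene in genes:
        sub_g = per_dataset[per_dataset["gene"] == gene]
        for split in ("training", "testing", "overall"):
            sub = sub_g if split == "overall" else sub_g[sub_g["split"] == split]
            k = int(sub["k"].sum())
            n = int(sub["n_tumor"].sum())
            pooled_rows.append(
                {
                    "gene": gene,
                    "split": split,
                    "rate": k / n if n else np.nan,
                    "k": k,
                    "n_tumor": n,
                }
            )
    pooled = pd.DataFrame(pooled_rows, columns=["gene", "split", "rate", "k", "n_tumor"])
    return ValidationReport(per_dataset=per_dataset, pooled=pooled)
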