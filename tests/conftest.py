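import numpy as np
import pandas as pd
import pytest

from metanet.io_formats import CONTROL, TUMOR, ExpressionStudy


def make_study(
    values: dict[str, list[float]],
    n_tumor: int,
    study_id: str = "S1",
    group: str = "I",
) -> ExpressionStudy:
    """Build a study from {gene: per-sample log2 values}; the first
    ``n_tumor`` samples are tumors, the rest controls."""
    mat = pd.DataFrame(values).T
    n = mat.shape[1]
    samples = [f"{study_id}_s{i}" for i in range(n)]
    mat.columns = samples
    classes = pd.Series(
        [TUMOR] * n_tumor + [CONTROL] * (n - n_tumor), index=samples
    )
    return ExpressionStudy(
        study_id=study_id, platform_group=group, values=mat, classes=classes
    )


@pytest.fixture
def toy_study():
    # gene A: tumor mean 3, control mean 1 -> FC 4; B flat; C down
    return make_study(
        {
            "A": [3.0, 3.0, 1.0, 1.0],
            "B": [2.0, 2.0, 2.0, 2.0],
            "C": [1.0, 1.0, 3.0, 3.0],
        },
        n_tumor=2,
    )


def studies_with_ranks(rank_rows: list[list[int]]) -> list:
    """Two-class studies whose 'up' fold-change ranking equals the given
    rank rows (rank 1 = largest FC).  One study per row."""
    out = []
    for si, ranks in enumerate(rank_rows):
        g = len(ranks)
        # FC = 2^(g - rank): strictly decreasing in rank
        values = {
            f"G{j}": [float(g - ranks[j]), 0.0] for j in range(g)
        }
        out.append(
            make_study(values, n_tumor=1, study_id=f"R{si}", group="I")
        )
    return out


rng_global = np.random.default_rng  # convenience alias for tests
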