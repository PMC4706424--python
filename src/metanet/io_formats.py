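"""Readers and writers for the on-disk formats the pipeline touches.

Expression matrices and sample-class tables are plain TSV; interaction
edge lists come as two-column TSV or SIF; gene sets as GMT; networks are
exported as GraphML (node attributes preserved); reports as JSON.

Gene symbols are canonicalized by whitespace-stripping and upper-casing
only.  Alias resolution (e.g. BGH3/TGFBI) is deliberately out of scope:
alias maps are version-dependent, so mismatches are documented rather
than silently rewritten.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

TUMOR = "tumor"
CONTROL = "control"

#: decimal places kept by the matrix writers; round-trips are lossless
#: at this precision
MATRIX_PRECISION = 6


def canonicalize(symbol: str) -> str:
    """Canonical gene symbol: stripped and upper-cased, nothing else."""
    return str(symbol).strip().upper()


@dataclass
class ExpressionStudy:
    """One normalized gene-by-sample log2 expression matrix.

    Attributes
    ----------
    study_id : str
        Stable identifier of the study (dataset accession or synthetic id).
    platform_group : str
        Platform-compatibility group tag, ``"I"`` or ``"II"``; studies are
        meta-analyzed within a group and the DEG calls intersected across
        groups.
    values : pandas.DataFrame
        genes x samples matrix of log2 intensities; index = canonical gene
        symbols, columns = sample ids.
    classes : pandas.Series
        sample id -> ``"tumor"`` / ``"control"``.
    """

    study_id: str
    platform_group: str
    values: pd.DataFrame
    classes: pd.Series

    def __post_init__(self) -> None:
        self.classes = self.classes.reindex(self.values.columns)
        self.validate()

    def validate(self) -> None:
        if self.platform_group not in ("I", "II"):
            raise ValueError(
                f"platform_group must be 'I' or 'II', got {self.platform_group!r}"
            )
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate gene symbol after canonicalization: {dup}")
        if self.classes.isna().any():
            missing = list(self.classes.index[self.classes.isna()])
            raise ValueError(
                f"samples without a class label in study {self.study_id}: {missing}"
            )
        bad = set(self.classes.unique()) - {TUMOR, CONTROL}
        if bad:
            raise ValueError(f"unknown sample classes {sorted(bad)}")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError(f"non-finite values in study {self.study_id}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def samples_of(self, cls: str) -> list[str]:
        return list(self.classes.index[self.classes == cls])

    @property
    def n_tumor(self) -> int:
        return int((self.classes == TUMOR).sum())

    @property
    def n_control(self) -> int:
        return int((self.classes == CONTROL).sum())


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT), symbols canonicalized like expression data."""

    sets: dict[str, frozenset[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()


def read_expression(
    matrix_path: str | Path,
    class_path: str | Path,
    group_tag: str,
    *,
    study_id: str | None = None,
    linear: bool = False,
) -> ExpressionStudy:
    """Read a genes x samples TSV plus its two-column sample-class TSV.

    The matrix has a header row of sample ids and gene symbols in the first
    column.  Duplicate gene rows (after canonicalization) are collapsed by
    per-sample mean.  ``linear=True`` declares linear-scale intensities,
    which are log2(x+1)-transformed on load; matrices are otherwise assumed
    to be log2 already (RMA-style output).
    """
    matrix_path = Path(matrix_path)
    mat = pd.read_csv(matrix_path, sep="\t", index_col=0)
    mat.index = [canonicalize(g) for g in mat.index]
    mat.columns = [str(c).strip() for c in mat.columns]
    if mat.index.duplicated().any():
        mat = mat.groupby(level=0, sort=False).mean()
    if linear:
        mat = np.log2(mat + 1.0)

    cls = pd.read_csv(class_path, sep="\t", header=None, names=["sample", "cls"])
    cls["sample"] = cls["sample"].astype(str).str.strip()
    cls["cls"] = cls["cls"].astype(str).str.strip().str.lower()
    class_of = cls.set_index("sample")["cls"]
    extra = set(class_of.index) - set(mat.columns)
    if extra:
        raise ValueError(
            f"sample(s) in class file absent from matrix: {sorted(extra)}"
        )
    missing = set(mat.columns) - set(class_of.index)
    if missing:
        raise ValueError(
            f"sample(s) in matrix missing from class file: {sorted(missing)}"
        )
    study = ExpressionStudy(
        study_id=study_id or matrix_path.stem,
        platform_group=group_tag,
        values=mat,
        classes=class_of.reindex(mat.columns),
    )
    # fewer than 2 samples in a class is flagged (rank products on a
    # single pair still work) but not fatal
    if study.n_tumor < 2 or study.n_control < 2:
        import warnings

        warnings.warn(
            f"study {study.study_id}: fewer than 2 samples in a class "
            f"(tumor={study.n_tumor}, control={study.n_control})",
            stacklevel=2,
        )
    return study


def write_expression(
    study: ExpressionStudy, matrix_path: str | Path, class_path: str | Path
) -> None:
    """Write the matrix and class table back as TSV (6-decimal precision)."""
    study.values.round(MATRIX_PRECISION).to_csv(
        matrix_path, sep="\t", float_format=f"%.{MATRIX_PRECISION}f"
    )
    study.classes.to_csv(class_path, sep="\t", header=False)


def read_edge_lists(*paths: str | Path) -> list[tuple[str, str]]:
    """Read interaction pairs from two-column TSV or SIF files.

    SIF is recognized by the ``.sif`` extension and must have exactly three
    whitespace-separated fields per line (source, interaction type, target);
    TSV must have exactly two tab-separated columns.  Pair order is
    preserved for provenance; confidence scores are not parsed.
    """
    pairs: list[tuple[str, str]] = []
    for path in paths:
        path = Path(path)
        is_sif = path.suffix.lower() == ".sif"
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                if is_sif:
                    fields = line.split()
                    if len(fields) != 3:
                        raise ValueError(
                            f"{path}:{lineno}: SIF line must have 3 fields, "
                            f"got {len(fields)}"
                        )
                    a, _, b = fields
                else:
                    fields = line.split("\t")
                    if len(fields) != 2:
                        raise ValueError(
                            f"{path}:{lineno}: TSV line must have 2 columns, "
                            f"got {len(fields)}"
                        )
                    a, b = fields
                pairs.append((canonicalize(a), canonicalize(b)))
    return pairs


def write_edge_list(pairs: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, b in pairs:
            fh.write(f"{a}\t{b}\n")


def write_sif(
    pairs: Iterable[tuple[str, str]], path: str | Path, interaction: str = "pp"
) -> None:
    with open(path, "w") as fh:
        for a, b in pairs:
            fh.write(f"{a} {interaction} {b}\n")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: name <tab> description <tab> member symbols."""
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs >=3 fields, got {len(fields)}"
                )
            name = fields[0].strip()
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            members = frozenset(canonicalize(g) for g in fields[2:] if g.strip())
            sets[name] = members
            descriptions[name] = fields[1]
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def write_report(obj: Mapping | Sequence, path: str | Path) -> None:
    """Write a schema-stable JSON report (sorted keys, no timestamps)."""
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_report(path: str | Path):
    with open(path) as fh:
        return json.load(fh)


def export_graphml(network: nx.Graph, path: str | Path) -> None:
    """Write a network as GraphML, preserving node/edge attributes."""
    nx.write_graphml(network, path)


def read_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(path)
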