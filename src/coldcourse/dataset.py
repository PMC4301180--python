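"""Containers for time-series expression data and their on-disk TSV dialect.

The measured quantity is a genes x samples matrix of linear-scale,
non-negative hybridization intensities.  Samples are described by a design
table mapping each sample id to a (time point, replicate) pair; time points
are hours of treatment with 0 h the untreated control.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "read_dataset",
    "read_annotation",
    "write_annotation",
]


def format_timepoint(t: float) -> str:
    """Render a time point in hours without a trailing ``.0`` (``24`` not ``24.0``)."""
    t = float(t)
    return str(int(t)) if t == int(t) else str(t)


def pair_label(a: float, b: float) -> str:
    """Label an ordered time-point comparison, e.g. ``'0h/24h'``."""
    return f"{format_timepoint(a)}h/{format_timepoint(b)}h"


@dataclass
class ExpressionDataset:
    """Linear-scale intensity matrix plus its sample design.

    Parameters
    ----------
    matrix
        genes x samples DataFrame of non-negative intensities.  The index
        holds gene ids, the columns sample ids.
    design
        DataFrame indexed by sample id with columns ``time_point_h`` (float)
        and ``replicate`` (int).  Every matrix column must appear exactly
        once in the design.
    """

    matrix: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        if not isinstance(self.matrix, pd.DataFrame):
            self.matrix = pd.DataFrame(self.matrix)
        if self.matrix.shape[0] < 1 or self.matrix.shape[1] < 1:
            raise ValueError("expression matrix must have at least one gene and one sample")
        missing = {"time_point_h", "replicate"} - set(self.design.columns)
        if missing:
            raise ValueError(f"design table lacks columns: {sorted(missing)}")
        if self.design.index.has_duplicates:
            raise ValueError("design maps a sample id to more than one (time point, replicate)")
        if set(self.matrix.columns) != set(self.design.index):
            raise ValueError("matrix columns and design sample ids differ")
        if self.matrix.index.has_duplicates:
            raise ValueError("gene ids are not unique")
        values = self.matrix.to_numpy(float)
        if np.isnan(values).any():
            raise ValueError("expression matrix contains missing values")
        if (values < 0).any():
            raise ValueError("expression intensities must be non-negative")
        # align design to matrix column order
        self.design = self.design.loc[self.matrix.columns]

    @property
    def gene_ids(self) -> pd.Index:
        return self.matrix.index

    @property
    def time_points(self) -> list[float]:
        return sorted(float(t) for t in self.design["time_point_h"].unique())

    def groups(self) -> dict[float, list[str]]:
        """Map each time point to the sample ids measuring it."""
        out: dict[float, list[str]] = {}
        for sid, t in self.design["time_point_h"].items():
            out.setdefault(float(t), []).append(sid)
        return {t: out[t] for t in sorted(out)}

    def group_index(self) -> np.ndarray:
        """Integer group label per matrix column, ordered by time point."""
        tps = self.time_points
        lookup = {t: i for i, t in enumerate(tps)}
        return np.array([lookup[float(t)] for t in self.design["time_point_h"]])

    def to_tsv(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.matrix.rename_axis("gene_id").to_csv(outdir / "matrix.tsv", sep="\t")
        self.design.rename_axis("sample_id").to_csv(outdir / "design.tsv", sep="\t")


def read_dataset(matrix_path: str | Path, design_path: str | Path) -> ExpressionDataset:
    """Load a dataset from the matrix/design TSV dialect written by ``to_tsv``."""
    matrix = pd.read_csv(matrix_path, sep="\t", index_col=0)
    design = pd.read_csv(design_path, sep="\t", index_col=0)
    return ExpressionDataset(matrix=matrix, design=design)


def write_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    """Write a gene annotation table (gene_id, tap_family, orphan {0,1}, go_terms)."""
    out = annotation.copy()
    out["orphan"] = out["orphan"].astype(int)
    out["go_terms"] = [";".join(sorted(t)) for t in out["go_terms"]]
    out["tap_family"] = out["tap_family"].fillna("")
    out.rename_axis("gene_id").to_csv(path, sep="\t")


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read an annotation TSV back into the in-memory form (go_terms as frozensets)."""
    ann = pd.read_csv(path, sep="\t", index_col=0, keep_default_na=False)
    ann["orphan"] = ann["orphan"].astype(int).astype(bool)
    ann["go_terms"] = [
        frozenset(t.split(";")) if t else frozenset() for t in ann["go_terms"].astype(str)
    ]
    ann["tap_family"] = ann["tap_family"].replace("", np.nan)
    return ann
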