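"""Reading and writing the labeled-matrix tables used by the gold-standard
drug-target benchmarks.

The dialect is a plain tab-delimited table: one header row of column labels,
one leading column of row labels, UTF-8, ``\\n`` line endings.  Interaction
tables are binary adjacency matrices; similarity tables are square and
symmetric; score tables hold real-valued predictions at full precision.

The canonical in-memory orientation is drugs-in-rows.  The public benchmark
files are distributed targets-in-rows, so :func:`read_interaction_table`
takes an explicit ``orientation`` flag rather than guessing from shape.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "InteractionData",
    "ScoreMatrix",
    "read_interaction_table",
    "read_similarity_table",
    "write_interaction_table",
    "write_scores",
    "read_scores",
]

Orientation = Literal["drugs_in_rows", "targets_in_rows"]


def _check_labels(labels: Sequence[str], what: str) -> list[str]:
    labels = [str(x) for x in labels]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate {what} labels")
    for lab in labels:
        if "\t" in lab or "\n" in lab:
            raise ValueError(f"{what} label contains tab/newline: {lab!r}")
    return labels


@dataclasses.dataclass
class InteractionData:
    """A partially observed binary drug-target adjacency matrix.

    ``values`` holds the known interactions (1 = known interaction), with
    drugs in rows and targets in columns.  ``mask`` is the sampling
    operator: 1 marks a cell usable for training.  Unobserved status is
    carried only by the mask — the file dialect has no missing-value cells;
    cross-validation plans blind cells by zeroing mask entries.
    """

    values: np.ndarray
    mask: np.ndarray
    drug_ids: list[str]
    target_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=float)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("interaction matrix must be 2-D and nonempty")
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape differs from values shape")
        if not np.isin(self.values, (0.0, 1.0)).all():
            raise ValueError("interaction values must be 0/1")
        if not np.isin(self.mask, (0.0, 1.0)).all():
            raise ValueError("mask entries must be 0/1")
        self.drug_ids = _check_labels(self.drug_ids, "drug")
        self.target_ids = _check_labels(self.target_ids, "target")
        m, n = self.values.shape
        if len(self.drug_ids) != m or len(self.target_ids) != n:
            raise ValueError("label lists do not match matrix shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy(self) -> "InteractionData":
        return InteractionData(
            self.values.copy(), self.mask.copy(),
            list(self.drug_ids), list(self.target_ids),
        )


@dataclasses.dataclass
class ScoreMatrix:
    """Real-valued predicted interaction scores (the recovered matrix Z)."""

    scores: np.ndarray
    drug_ids: list[str]
    target_ids: list[str]

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2:
            raise ValueError("score matrix must be 2-D")
        if not np.isfinite(self.scores).all():
            raise ValueError("score matrix contains non-finite entries")
        self.drug_ids = _check_labels(self.drug_ids, "drug")
        self.target_ids = _check_labels(self.target_ids, "target")
        m, n = self.scores.shape
        if len(self.drug_ids) != m or len(self.target_ids) != n:
            raise ValueError("label lists do not match matrix shape")


def _read_labeled_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, header=0, dtype=str,
                     keep_default_na=False, encoding="utf-8")
    if df.shape[1] == 0:
        raise ValueError(f"{path}: no data columns found")
    widths = {len(line.rstrip("\n").split("\t"))
              for line in Path(path).read_text(encoding="utf-8").splitlines()
              if line.strip()}
    if len(widths) != 1:
        raise ValueError(f"{path}: ragged rows (widths {sorted(widths)})")
    return df


def read_interaction_table(
    path: str | Path, orientation: Orientation = "drugs_in_rows"
) -> InteractionData:
    """Read a binary interaction table.

    ``orientation`` states how the *file* is laid out; the returned object
    is always drugs-in-rows (a transpose is applied for
    ``targets_in_rows``).  The mask is initialized to all ones: every cell
    is a training observation until a CV plan blinds some.
    """
    df = _read_labeled_table(path)
    vals = np.empty(df.shape, dtype=float)
    for i, (rlab, row) in enumerate(df.iterrows()):
        for j, cell in enumerate(row):
            if cell not in ("0", "1"):
                raise ValueError(
                    f"{path}: non-binary cell {cell!r} at row {rlab!r}, "
                    f"column {df.columns[j]!r}"
                )
            vals[i, j] = float(cell)
    row_ids = list(df.index.astype(str))
    col_ids = list(df.columns.astype(str))
    if orientation == "targets_in_rows":
        vals = vals.T
        row_ids, col_ids = col_ids, row_ids
    elif orientation != "drugs_in_rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    return InteractionData(vals, np.ones_like(vals), row_ids, col_ids)


def read_similarity_table(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Read a square labeled similarity table.

    Mild asymmetry (≤ 1e-8, e.g. from printed rounding) is symmetrized as
    (S + Sᵀ)/2; anything larger is an error.
    """
    df = _read_labeled_table(path)
    if df.shape[0] != df.shape[1]:
        raise ValueError(f"{path}: similarity table is not square {df.shape}")
    rows = list(df.index.astype(str))
    cols = list(df.columns.astype(str))
    if set(rows) != set(cols):
        raise ValueError(f"{path}: row and column label sets differ")
    if rows != cols:
        df = df[rows]
    S = df.to_numpy(dtype=float)
    if np.abs(S - S.T).max() > 1e-8:
        raise ValueError(f"{path}: similarity table asymmetric beyond 1e-8")
    return (S + S.T) / 2.0, _check_labels(rows, "similarity")


def _write_labeled_table(values: np.ndarray, row_ids: Sequence[str],
                         col_ids: Sequence[str], path: str | Path,
                         fmt: str) -> None:
    row_ids = _check_labels(row_ids, "row")
    col_ids = _check_labels(col_ids, "column")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t" + "\t".join(col_ids) + "\n")
        for lab, row in zip(row_ids, values):
            fh.write(lab + "\t" + "\t".join(format(v, fmt) for v in row) + "\n")


def write_interaction_table(data: InteractionData, path: str | Path) -> None:
    _write_labeled_table(data.values, data.drug_ids, data.target_ids, path, ".0f")


def write_scores(result: ScoreMatrix, path: str | Path) -> None:
    """Write a score table at full float precision (round-trips to ≤ 1e-12)."""
    if not np.isfinite(result.scores).all():
        raise ValueError("refusing to write non-finite scores")
    _write_labeled_table(result.scores, result.drug_ids, result.target_ids,
                         path, ".17g")


def read_scores(path: str | Path) -> ScoreMatrix:
    df = _read_labeled_table(path)
    return ScoreMatrix(df.to_numpy(dtype=float),
                       list(df.index.astype(str)),
                       list(df.columns.astype(str)))
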