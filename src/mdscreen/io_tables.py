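"""Delimited-text IO for expression matrices, sample designs, score tables
and qPCR Ct tables, with strict validation.

All tables are plain delimited text (tab by default). The expression matrix
is assumed to be already normalized and on log2 scale: array preprocessing
(background correction, normalization, probe-to-gene collapsing) is upstream
of this package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .scoring import GeneScore, GroupLabel

logger = logging.getLogger(__name__)

SUBSETS = frozenset({"Mo", "Gr"})
CONDITIONS = frozenset({"control", "treated"})

#: float format that round-trips IEEE doubles exactly (stronger than the
#: 12-significant-digit contract of the score table)
_FLOAT_FMT = "%.17g"

SCORE_COLUMNS = (
    "gene_id",
    "delta_mo",
    "delta_gr",
    "fold",
    "influence_factor",
    "distance",
    "group",
)

QPCR_COLUMNS = (
    "gene_id",
    "ct_target_treated",
    "ct_ref_treated",
    "ct_target_control",
    "ct_ref_control",
)


class TableFormatError(ValueError):
    """Raised when an input table violates the documented contract."""


@dataclass
class ExpressionExperiment:
    """A normalized log2 expression matrix plus its sample design.

    Attributes
    ----------
    gene_ids : list of str
        Unique, non-empty gene identifiers (matrix row order).
    values : ndarray, shape (n_genes, n_samples)
        Normalized log2 intensities; no missing values.
    sample_ids : list of str
        Sample identifiers, one per matrix column.
    design : DataFrame
        One row per sample (aligned with ``sample_ids``) with columns
        ``subset`` (Mo|Gr), ``condition`` (control|treated) and ``replicate``
        (positive int, unique within each subset x condition cell).
    """

    gene_ids: list[str]
    values: np.ndarray
    sample_ids: list[str]
    design: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.validate()

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        if len(self.gene_ids) != len(set(self.gene_ids)):
            dupes = _duplicates(self.gene_ids)
            raise TableFormatError(f"duplicate gene id(s): {dupes}")
        if any(not g for g in self.gene_ids):
            raise TableFormatError("empty gene id")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise TableFormatError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            raise TableFormatError("expression matrix contains missing or non-finite values")
        if list(self.design.index) != list(self.sample_ids):
            raise TableFormatError("design rows are not aligned with matrix columns")
        bad_subset = set(self.design["subset"]) - SUBSETS
        if bad_subset:
            raise TableFormatError(f"unknown subset token(s): {sorted(bad_subset)}")
        bad_cond = set(self.design["condition"]) - CONDITIONS
        if bad_cond:
            raise TableFormatError(f"unknown condition token(s): {sorted(bad_cond)}")
        reps = self.design["replicate"]
        if (reps <= 0).any() or (reps != reps.astype(int)).any():
            raise TableFormatError("replicate indices must be positive integers")
        for subset in sorted(SUBSETS):
            for cond in sorted(CONDITIONS):
                cell = self.design[
                    (self.design["subset"] == subset) & (self.design["condition"] == cond)
                ]
                if len(cell) == 0:
                    raise TableFormatError(f"empty design cell {subset}/{cond}")
                if cell["replicate"].duplicated().any():
                    raise TableFormatError(
                        f"duplicate replicate index in design cell {subset}/{cond}"
                    )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


@dataclass(frozen=True)
class QpcrRecord:
    """One gene's (optionally replicate-averaged) Ct quadruple.

    ``subset`` is optional: when the table carries per-subset measurements
    (needed for qPCR-based re-ranking) each gene appears once per subset.
    """

    gene_id: str
    ct_target_treated: float
    ct_ref_treated: float
    ct_target_control: float
    ct_ref_control: float
    subset: str | None = None

    def __post_init__(self) -> None:
        for name in ("ct_target_treated", "ct_ref_treated", "ct_target_control", "ct_ref_control"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise TableFormatError(f"{self.gene_id}: {name} must be finite and > 0, got {v}")
        if self.subset is not None and self.subset not in SUBSETS:
            raise TableFormatError(f"{self.gene_id}: unknown subset {self.subset!r}")


def _duplicates(items: Iterable[str]) -> list[str]:
    seen: set[str] = set()
    dup: list[str] = []
    for x in items:
        if x in seen and x not in dup:
            dup.append(x)
        seen.add(x)
    return dup


# -- expression matrix + design -------------------------------------------

def read_expression(
    matrix_path: str | Path,
    design_path: str | Path,
    delimiter: str = "\t",
    drop_missing: bool = False,
) -> ExpressionExperiment:
    """Read an expression matrix and its sample design, join and validate.

    The matrix file has a ``gene_id`` first column and one column per
    sample; the design file has columns ``sample_id, subset, condition,
    replicate``. Column order of the matrix and row order of the design are
    irrelevant: samples are joined on id and canonicalized to sorted
    sample-id order.

    Parameters
    ----------
    drop_missing : bool
        When False (default) any missing cell is an error. When True, genes
        with at least one missing value are dropped and the count is logged.
    """
    mat = pd.read_csv(matrix_path, sep=delimiter, dtype={0: str}, float_precision="round_trip")
    if mat.columns[0] != "gene_id":
        raise TableFormatError(f"first matrix column must be 'gene_id', got {mat.columns[0]!r}")
    design = pd.read_csv(design_path, sep=delimiter, dtype={"sample_id": str})
    missing_cols = {"sample_id", "subset", "condition", "replicate"} - set(design.columns)
    if missing_cols:
        raise TableFormatError(f"design lacks column(s): {sorted(missing_cols)}")
    if design["sample_id"].duplicated().any():
        raise TableFormatError(
            f"duplicate sample id(s) in design: {_duplicates(design['sample_id'])}"
        )

    matrix_samples = list(mat.columns[1:])
    design_samples = list(design["sample_id"])
    only_matrix = sorted(set(matrix_samples) - set(design_samples))
    if only_matrix:
        raise TableFormatError(f"sample not in design: {only_matrix}")
    only_design = sorted(set(design_samples) - set(matrix_samples))
    if only_design:
        raise TableFormatError(f"design sample absent from matrix: {only_design}")

    gene_ids = mat["gene_id"].tolist()
    order = sorted(matrix_samples)  # canonical: column/row order independent
    try:
        values = mat[order].apply(pd.to_numeric, errors="raise").to_numpy(dtype=float)
    except (ValueError, TypeError) as exc:
        raise TableFormatError(f"non-numeric expression cell: {exc}") from exc

    if drop_missing:
        keep = np.isfinite(values).all(axis=1)
        n_dropped = int((~keep).sum())
        if n_dropped:
            logger.info("dropped %d gene(s) with missing values", n_dropped)
        gene_ids = [g for g, k in zip(gene_ids, keep) if k]
        values = values[keep]

    design_idx = design.set_index("sample_id").loc[order]
    try:
        design_idx["replicate"] = design_idx["replicate"].astype(int)
    except (ValueError, TypeError) as exc:
        raise TableFormatError(f"non-integer replicate index: {exc}") from exc
    return ExpressionExperiment(gene_ids, values, order, design_idx)


def write_expression(
    exp: ExpressionExperiment,
    matrix_path: str | Path,
    design_path: str | Path,
    delimiter: str = "\t",
) -> None:
    """Write the matrix and design back out as delimited text."""
    mat = pd.DataFrame(exp.values, columns=exp.sample_ids)
    mat.insert(0, "gene_id", exp.gene_ids)
    mat.to_csv(matrix_path, sep=delimiter, index=False, float_format=_FLOAT_FMT)
    design = exp.design.reset_index().rename(columns={"index": "sample_id"})
    if "sample_id" not in design.columns:
        design = design.rename(columns={design.columns[0]: "sample_id"})
    design.to_csv(design_path, sep=delimiter, index=False)


# -- score tables ----------------------------------------------------------

def write_scores(scores: Sequence[GeneScore], path: str | Path, delimiter: str = "\t") -> None:
    """Write a score table (the Fig.-2C-style plot coordinates live in the
    ``fold`` and ``influence_factor`` columns). Unassigned groups are blank."""
    rows = [
        (
            s.gene_id,
            s.delta_mo,
            s.delta_gr,
            s.fold,
            s.influence_factor,
            s.distance,
            "" if s.group is None else s.group.value,
        )
        for s in scores
    ]
    df = pd.DataFrame(rows, columns=SCORE_COLUMNS)
    df.to_csv(path, sep=delimiter, index=False, float_format=_FLOAT_FMT)


def read_scores(path: str | Path, delimiter: str = "\t") -> list[GeneScore]:
    """Read a score table written by :func:`write_scores`."""
    df = pd.read_csv(
        path, sep=delimiter, dtype={"gene_id": str, "group": str}, float_precision="round_trip"
    )
    missing = set(SCORE_COLUMNS) - set(df.columns)
    if missing:
        raise TableFormatError(f"score table lacks column(s): {sorted(missing)}")
    if df["gene_id"].duplicated().any():
        raise TableFormatError(f"duplicate gene id(s): {_duplicates(df['gene_id'])}")
    out: list[GeneScore] = []
    for row in df.itertuples(index=False):
        group_cell = row.group
        group = None
        if isinstance(group_cell, str) and group_cell.strip():
            group = GroupLabel(group_cell.strip())
        out.append(
            GeneScore(
                gene_id=row.gene_id,
                delta_mo=float(row.delta_mo),
                delta_gr=float(row.delta_gr),
                fold=float(row.fold),
                influence_factor=float(row.influence_factor),
                distance=float(row.distance),
                group=group,
            )
        )
    return out


# -- qPCR Ct tables --------------------------------------------------------

def read_qpcr(path: str | Path, delimiter: str = "\t") -> list[QpcrRecord]:
    """Read a qPCR Ct table: one row per gene (or per gene and subset when a
    ``subset`` column is present)."""
    df = pd.read_csv(path, sep=delimiter, dtype={"gene_id": str}, float_precision="round_trip")
    missing = set(QPCR_COLUMNS) - set(df.columns)
    if missing:
        raise TableFormatError(f"qPCR table lacks column(s): {sorted(missing)}")
    has_subset = "subset" in df.columns
    key = df["gene_id"] + ("/" + df["subset"].astype(str) if has_subset else "")
    if key.duplicated().any():
        raise TableFormatError(f"duplicate qPCR row(s): {_duplicates(key)}")
    records: list[QpcrRecord] = []
    for row in df.itertuples(index=False):
        cts = {}
        for name in QPCR_COLUMNS[1:]:
            raw = getattr(row, name)
            try:
                cts[name] = float(raw)
            except (ValueError, TypeError) as exc:
                raise TableFormatError(f"{row.gene_id}: non-numeric Ct {raw!r}") from exc
            if not np.isfinite(cts[name]):
                raise TableFormatError(f"{row.gene_id}: non-finite Ct in {name}")
        records.append(
            QpcrRecord(
                gene_id=row.gene_id,
                subset=str(row.subset) if has_subset else None,
                **cts,
            )
        )
    return records
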