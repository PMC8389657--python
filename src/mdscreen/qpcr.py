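"""Relative quantification of qPCR data by the classic ddCt method.

For one gene with threshold-cycle (Ct) values of the target and of a
reference gene (e.g. GAPDH) under treated and control conditions:

    dCt_treated  = Ct_target_treated  - Ct_ref_treated
    dCt_control  = Ct_target_control  - Ct_ref_control
    ddCt         = dCt_treated - dCt_control
    fold_linear  = 2 ** (-ddCt)          (relative expression, treated vs control)
    log2_fold    = -ddCt

Amplification efficiency is fixed at 2 per cycle (no efficiency
correction); replicate Cts are expected to be arithmetically averaged
before entry.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import math

from .io_tables import QpcrRecord


@dataclass(frozen=True)
class RelativeExpression:
    """2^-ddCt relative expression of one gene (treated vs control)."""

    gene_id: str
    ddct: float
    fold_linear: float
    log2_fold: float
    subset: str | None = None


def qpcr_ddct(rec: QpcrRecord) -> RelativeExpression:
    """Compute the ddCt relative expression for one Ct quadruple."""
    for name in ("ct_target_treated", "ct_ref_treated", "ct_target_control", "ct_ref_control"):
        if not math.isfinite(getattr(rec, name)):
            raise ValueError(f"{rec.gene_id}: non-finite Ct in {name}")
    dct_treated = rec.ct_target_treated - rec.ct_ref_treated
    dct_control = rec.ct_target_control - rec.ct_ref_control
    ddct = dct_treated - dct_control
    return RelativeExpression(
        gene_id=rec.gene_id,
        ddct=ddct,
        fold_linear=2.0 ** (-ddct),
        log2_fold=-ddct,
        subset=rec.subset,
    )


def qpcr_log2fc_by_subset(records: Iterable[QpcrRecord]) -> dict[str, tuple[float, float]]:
    """Per-gene (delta_mo, delta_gr) qPCR log2 fold changes for re-ranking.

    Requires every record to carry a ``subset`` label and every gene to be
    measured in both subsets; the log2 fold change is ``-ddCt``.
    """
    per_gene: dict[str, dict[str, float]] = {}
    for rec in records:
        if rec.subset is None:
            raise ValueError(
                f"{rec.gene_id}: qPCR record lacks a subset label; "
                "re-ranking needs per-subset measurements"
            )
        per_gene.setdefault(rec.gene_id, {})[rec.subset] = qpcr_ddct(rec).log2_fold
    out: dict[str, tuple[float, float]] = {}
    for gene, by_subset in per_gene.items():
        missing = {"Mo", "Gr"} - set(by_subset)
        if missing:
            raise ValueError(f"{gene}: missing qPCR measurement for subset(s) {sorted(missing)}")
        out[gene] = (by_subset["Mo"], by_subset["Gr"])
    return out


def relative_expression_frame(records: Sequence[QpcrRecord]):
    """ddCt results as a DataFrame (gene_id, [subset,] ddct, fold_linear, log2_fold)."""
    import pandas as pd

    rels = [qpcr_ddct(r) for r in records]
    cols = ["gene_id", "ddct", "fold_linear", "log2_fold"]
    if any(r.subset is not None for r in rels):
        cols.insert(1, "subset")
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in rels], columns=cols)
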