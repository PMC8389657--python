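"""Fold screen, six-group classification and top-k Distance selection.

Screened genes (|F| above the fold threshold) are partitioned into six
groups by the sign of F and the position of IF relative to a symmetric band
(default +/-1): IF above the band means the Mo subset dominated the response
(``Mo-Up``/``Mo-Down``), below means Gr dominated (``Gr-Up``/``Gr-Down``),
inside means both subsets responded comparably (``Up``/``Down``). Within
each group genes are ranked by Distance and the top k (default 3) are
selected; with all six groups populated this yields 6*k = 18 candidates.
The selection can then be re-ranked with qPCR-derived log2 fold changes,
recomputing F/IF/D per gene; the gene with the largest recalculated
Distance is the final target call.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .scoring import GROUP_ORDER, GeneScore, GroupLabel, compute_scores


@dataclass
class SelectionResult:
    """Outcome of screen -> classify -> select (-> qPCR re-rank)."""

    screened: list[GeneScore]
    groups: dict[GroupLabel, list[GeneScore]]
    selected: list[GeneScore]
    #: qPCR-recomputed scores per covered selected gene (empty until re-rank)
    qpcr_scores: dict[str, GeneScore] = field(default_factory=dict)
    #: selected genes, covered ones first in descending recalculated
    #: Distance, then uncovered ones in selection order
    final_ranking: list[GeneScore] = field(default_factory=list)
    final_target: str | None = None

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: gene, group, rank in group, Distances, target flag."""
        rank_in_group = {
            s.gene_id: r + 1 for members in self.groups.values() for r, s in enumerate(members)
        }
        rows = []
        for s in self.selected:
            q = self.qpcr_scores.get(s.gene_id)
            rows.append(
                {
                    "gene_id": s.gene_id,
                    "group": "" if s.group is None else s.group.value,
                    "rank_in_group": rank_in_group.get(s.gene_id),
                    "distance": s.distance,
                    "distance_qpcr": q.distance if q is not None else None,
                    "is_final_target": s.gene_id == self.final_target,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "gene_id",
                "group",
                "rank_in_group",
                "distance",
                "distance_qpcr",
                "is_final_target",
            ],
        )

    def write(self, path: str | Path, delimiter: str = "\t") -> None:
        self.to_frame().to_csv(path, sep=delimiter, index=False, float_format="%.17g")


def screen_by_fold(scores: Sequence[GeneScore], threshold: float = 2.5) -> list[GeneScore]:
    """Retain genes with |Fold| strictly greater than ``threshold``.

    The screen is on the magnitude of F so that down-regulated genes
    (negative F) survive alongside up-regulated ones; order is preserved.
    """
    if not threshold > 0:
        raise ValueError(f"fold threshold must be > 0, got {threshold}")
    return [s for s in scores if abs(s.fold) > threshold]


def assign_group(score: GeneScore, if_threshold: float = 1.0) -> GroupLabel:
    """Classify one screened gene by (sign of Fold, IF band).

    IF exactly on the band boundary falls into the central Up/Down band
    (the flanking groups require strict inequality).
    """
    if not if_threshold > 0:
        raise ValueError(f"IF threshold must be > 0, got {if_threshold}")
    if score.fold == 0:
        raise ValueError(
            f"{score.gene_id}: fold is 0; group is defined only for screened genes"
        )
    up = score.fold > 0
    if score.influence_factor > if_threshold:
        return GroupLabel.MO_UP if up else GroupLabel.MO_DOWN
    if score.influence_factor < -if_threshold:
        return GroupLabel.GR_UP if up else GroupLabel.GR_DOWN
    return GroupLabel.UP if up else GroupLabel.DOWN


def classify(scores: Sequence[GeneScore], if_threshold: float = 1.0) -> list[GeneScore]:
    """Assign a group label to every screened score (in place); returns them."""
    for s in scores:
        s.group = assign_group(s, if_threshold)
    return list(scores)


def select_top_k(screened: Sequence[GeneScore], k: int = 3) -> SelectionResult:
    """Take the top-``k`` Distance genes of each of the six groups.

    Within a group, genes are sorted by Distance descending with ties broken
    by gene id ascending, making the selection invariant to input order.
    ``selected`` concatenates the per-group winners in the fixed group order
    Up, Down, Gr-Up, Gr-Down, Mo-Up, Mo-Down.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    for s in screened:
        if s.group is None:
            raise ValueError(f"{s.gene_id}: no group label; run classify() first")
    groups: dict[GroupLabel, list[GeneScore]] = {g: [] for g in GROUP_ORDER}
    for s in screened:
        groups[s.group].append(s)
    for g in groups:
        groups[g].sort(key=lambda s: (-s.distance, s.gene_id))
    selected = [s for g in GROUP_ORDER for s in groups[g][:k]]
    return SelectionResult(screened=list(screened), groups=groups, selected=selected)


def rerank_with_qpcr(
    selection: SelectionResult,
    qpcr_deltas: Mapping[str, tuple[float, float]],
) -> SelectionResult:
    """Re-rank the selected genes by Distance recomputed from qPCR deltas.

    ``qpcr_deltas`` maps gene id to (delta_mo, delta_gr) log2 fold changes
    derived from ddCt relative expressions. F/IF/D are recomputed per
    covered gene; the final target is the covered gene with the largest
    recalculated Distance. Selected genes without qPCR coverage are kept at
    the tail of the ranking and can never become the final target.
    """
    covered = [s for s in selection.selected if s.gene_id in qpcr_deltas]
    if not covered:
        raise ValueError("no selected gene has qPCR coverage")
    qpcr_scores: dict[str, GeneScore] = {}
    for s in covered:
        dmo, dgr = qpcr_deltas[s.gene_id]
        fold, influence, distance = compute_scores(dmo, dgr)
        qpcr_scores[s.gene_id] = GeneScore(
            s.gene_id, float(dmo), float(dgr), fold, influence, distance, group=s.group
        )
    covered_sorted = sorted(
        covered, key=lambda s: (-qpcr_scores[s.gene_id].distance, s.gene_id)
    )
    uncovered = [s for s in selection.selected if s.gene_id not in qpcr_deltas]
    return dataclasses.replace(
        selection,
        qpcr_scores=qpcr_scores,
        final_ranking=covered_sorted + uncovered,
        final_target=covered_sorted[0].gene_id,
    )
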