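"""End-to-end orchestration: score -> screen -> classify -> select -> re-rank.

All thresholds live in :class:`PipelineConfig`; its defaults are the
published constants of the screen (|Fold| > 2.5, IF band +/-1, top 3 per
group). Gene counts at every stage are logged at INFO level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .io_tables import ExpressionExperiment, QpcrRecord
from .qpcr import qpcr_log2fc_by_subset
from .scoring import GROUP_ORDER, GeneScore, score_experiment
from .selection import SelectionResult, classify, rerank_with_qpcr, screen_by_fold, select_top_k

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Tunable constants of the screen (defaults = published values)."""

    fold_threshold: float = 2.5
    if_threshold: float = 1.0
    top_k: int = 3
    delimiter: str = "\t"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not self.fold_threshold > 0:
            raise ValueError("fold_threshold must be > 0")
        if not self.if_threshold > 0:
            raise ValueError("if_threshold must be > 0")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load from a flat key: value text file; keyword overrides win."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} must contain key: value pairs")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)


def run_pipeline(
    exp: ExpressionExperiment,
    qpcr: Sequence[QpcrRecord] | None = None,
    cfg: PipelineConfig | None = None,
) -> SelectionResult:
    """Run the full prioritization on a scored experiment.

    Without qPCR records the result stops at the 6*top_k selection (no
    final target); with per-subset qPCR records, the selection is re-ranked
    by recalculated Distance and the top gene is called as the final target.
    An empty screened set yields an empty-but-valid result with a warning.
    """
    cfg = cfg or PipelineConfig()
    scores = score_experiment(exp)
    logger.info("input genes: %d", len(scores))
    screened = screen_by_fold(scores, cfg.fold_threshold)
    logger.info("screened (|Fold| > %g): %d", cfg.fold_threshold, len(screened))
    if not screened:
        logger.warning("no gene passed the fold screen; returning empty selection")
        return SelectionResult(screened=[], groups={g: [] for g in GROUP_ORDER}, selected=[])
    classify(screened, cfg.if_threshold)
    result = select_top_k(screened, cfg.top_k)
    for g in GROUP_ORDER:
        logger.info("group %s: %d gene(s)", g.value, len(result.groups[g]))
    logger.info("selected (top %d per group): %d", cfg.top_k, len(result.selected))
    if qpcr:
        deltas = qpcr_log2fc_by_subset(qpcr)
        result = rerank_with_qpcr(result, deltas)
        logger.info(
            "qPCR re-ranking: %d/%d covered; final target %s",
            len(result.qpcr_scores),
            len(result.selected),
            result.final_target,
        )
    return result


def plot_coordinates(scores: Sequence[GeneScore]) -> pd.DataFrame:
    """(Fold, IF) plot coordinates plus group key, one row per gene.

    This is the tabular form of the two-dimensional gene plot: x = Fold,
    y = Influence Factor; the ``group`` column doubles as the color key.
    Unclassified genes are keyed by the band the sign of Fold would put
    them in ("Up-band"/"Down-band"/"origin").
    """
    rows = []
    for s in scores:
        if s.group is not None:
            key = s.group.value
        elif s.fold > 0:
            key = "Up-band"
        elif s.fold < 0:
            key = "Down-band"
        else:
            key = "origin"
        rows.append({"gene_id": s.gene_id, "fold": s.fold, "influence_factor": s.influence_factor, "group": key})
    return pd.DataFrame(rows, columns=["gene_id", "fold", "influence_factor", "group"])
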