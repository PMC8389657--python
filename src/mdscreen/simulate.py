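"""Synthetic expression experiments with known ground truth.

The generator emulates the screen's experimental design — two MDSC subsets
(Mo, Gr) x two conditions (control, TGF-beta treated) x three independent
replicate arrays — as a gene x sample matrix of normalized log2 intensities.
Each gene has a baseline drawn once from N(baseline_mean, baseline_sd);
treated samples of subset s add that gene's planted log2 effect for s; every
measurement carries i.i.d. Gaussian replicate noise of SD ``noise_sd``
(homoscedastic across genes). Planted effects, and the F/IF/D scores and
group labels they imply, are recorded as a truth table so that recovery can
be tested without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io_tables import ExpressionExperiment
from .scoring import GeneScore, GroupLabel, compute_scores
from .selection import assign_group

_SUBSETS = ("Mo", "Gr")
_CONDITIONS = ("control", "treated")


@dataclass(frozen=True)
class PlantedEffect:
    """True per-subset log2 effect of one gene."""

    gene_id: str
    true_delta_mo: float
    true_delta_gr: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.true_delta_mo) and np.isfinite(self.true_delta_gr)):
            raise ValueError(f"{self.gene_id}: planted deltas must be finite")


@dataclass
class SyntheticConfig:
    """Parameters of a synthetic experiment.

    Defaults mirror the emulated design: 3 replicate arrays per
    subset x condition cell, 0.2 log2 units of replicate noise, gene
    baselines drawn from N(7.0, 1.5) log2 intensity.
    """

    n_genes: int
    seed: int
    n_replicates: int = 3
    noise_sd: float = 0.2
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5
    planted: list[PlantedEffect] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        ids = [p.gene_id for p in self.planted]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate planted gene ids")
        if len(self.planted) > self.n_genes:
            raise ValueError("more planted effects than genes")


@dataclass
class SyntheticTruth:
    """Planted effects plus the scores and groups they imply at zero noise.

    ``true_scores`` carries a group label only for genes whose true |Fold|
    exceeds ``screen_threshold`` (screen-then-classify order); genes that
    would not survive the screen stay unlabeled.
    """

    true_scores: list[GeneScore]
    screen_threshold: float = 2.5

    @property
    def by_gene(self) -> dict[str, GeneScore]:
        return {s.gene_id: s for s in self.true_scores}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gene_id": s.gene_id,
                    "true_delta_mo": s.delta_mo,
                    "true_delta_gr": s.delta_gr,
                    "true_fold": s.fold,
                    "true_influence_factor": s.influence_factor,
                    "true_distance": s.distance,
                    "true_group": "" if s.group is None else s.group.value,
                }
                for s in self.true_scores
            ]
        )

    def write(self, path: str | Path, delimiter: str = "\t") -> None:
        self.to_frame().to_csv(path, sep=delimiter, index=False, float_format="%.17g")


def _truth_from_planted(
    planted: Sequence[PlantedEffect], screen_threshold: float
) -> SyntheticTruth:
    scores: list[GeneScore] = []
    for p in planted:
        fold, influence, distance = compute_scores(p.true_delta_mo, p.true_delta_gr)
        s = GeneScore(p.gene_id, p.true_delta_mo, p.true_delta_gr, fold, influence, distance)
        if abs(fold) > screen_threshold:
            s.group = assign_group(s)
        scores.append(s)
    return SyntheticTruth(true_scores=scores, screen_threshold=screen_threshold)


def generate_experiment(
    cfg: SyntheticConfig, screen_threshold: float = 2.5
) -> tuple[ExpressionExperiment, SyntheticTruth]:
    """Simulate one experiment; fully reproducible from ``cfg.seed``.

    Returns the experiment and the truth table of the planted genes.
    Unplanted genes have zero true effect in both subsets and appear only in
    the experiment, not in the truth table.
    """
    rng = np.random.default_rng(cfg.seed)
    gene_ids = [f"gene{i:05d}" for i in range(cfg.n_genes)]
    planted_ids = {p.gene_id for p in cfg.planted}
    unknown = planted_ids - set(gene_ids)
    if unknown:
        # planted ids name genes directly; re-map custom ids onto the grid
        raise ValueError(f"planted gene ids not in generated gene set: {sorted(unknown)}")

    deltas = {s: np.zeros(cfg.n_genes) for s in _SUBSETS}
    index = {g: i for i, g in enumerate(gene_ids)}
    for p in cfg.planted:
        deltas["Mo"][index[p.gene_id]] = p.true_delta_mo
        deltas["Gr"][index[p.gene_id]] = p.true_delta_gr

    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_genes)
    columns: list[np.ndarray] = []
    sample_ids: list[str] = []
    design_rows: list[dict] = []
    for subset in _SUBSETS:
        for condition in _CONDITIONS:
            shift = deltas[subset] if condition == "treated" else 0.0
            for rep in range(1, cfg.n_replicates + 1):
                noise = rng.normal(0.0, cfg.noise_sd, size=cfg.n_genes) if cfg.noise_sd else 0.0
                columns.append(baseline + shift + noise)
                sid = f"{subset}_{condition}_{rep}"
                sample_ids.append(sid)
                design_rows.append(
                    {"sample_id": sid, "subset": subset, "condition": condition, "replicate": rep}
                )

    values = np.column_stack(columns)
    # canonicalize to sorted sample order, matching read_expression
    order = sorted(range(len(sample_ids)), key=lambda i: sample_ids[i])
    sample_ids = [sample_ids[i] for i in order]
    values = values[:, order]
    design = (
        pd.DataFrame([design_rows[i] for i in order]).set_index("sample_id")
    )
    exp = ExpressionExperiment(gene_ids, values, sample_ids, design)
    return exp, _truth_from_planted(cfg.planted, screen_threshold)


def six_group_scenario(
    per_group: int = 5,
    seed: int = 0,
    n_null_genes: int = 120,
    noise_sd: float = 0.2,
    n_replicates: int = 3,
) -> SyntheticConfig:
    """Plant ``per_group`` genes in each of the six groups.

    True |Fold| is drawn uniformly in [3, 6] (safely past the 2.5 screen at
    zero noise) and IF is placed beyond the +/-1 band for the Mo-*/Gr-*
    groups (|IF| in [1.5, 3]) or well inside it for Up/Down (|IF| <= 0.5).
    Given targets (F, IF), the planted deltas are recovered from
    dMo - dGr = IF / F, so dMo = (F + IF/F) / 2 and dGr = (F - IF/F) / 2 —
    the construction inverts the scoring map exactly. The IF magnitudes are
    deliberately kept on the same scale as Fold so that every group's
    Distances are comparable: the estimated IF of any gene wanders by about
    |F| times the noise of the subset-difference estimate, so genes near the
    band routinely cross it, and recovery then relies on Distance rank
    rather than on a stable group call. ``n_null_genes`` unresponsive genes
    are added as background.
    """
    if per_group < 1:
        raise ValueError("per_group must be >= 1")
    rng = np.random.default_rng(seed)
    # (group, fold sign, IF sampler)
    recipes = [
        (GroupLabel.UP, +1, lambda: rng.uniform(-0.5, 0.5)),
        (GroupLabel.DOWN, -1, lambda: rng.uniform(-0.5, 0.5)),
        (GroupLabel.GR_UP, +1, lambda: -rng.uniform(1.5, 3.0)),
        (GroupLabel.GR_DOWN, -1, lambda: -rng.uniform(1.5, 3.0)),
        (GroupLabel.MO_UP, +1, lambda: rng.uniform(1.5, 3.0)),
        (GroupLabel.MO_DOWN, -1, lambda: rng.uniform(1.5, 3.0)),
    ]
    n_genes = 6 * per_group + n_null_genes
    gene_ids = [f"gene{i:05d}" for i in range(n_genes)]
    planted: list[PlantedEffect] = []
    slot = 0
    for _group, sign, if_sampler in recipes:
        for _ in range(per_group):
            fold = sign * rng.uniform(3.0, 6.0)
            influence = if_sampler()
            diff = influence / fold
            dmo = (fold + diff) / 2.0
            dgr = (fold - diff) / 2.0
            planted.append(PlantedEffect(gene_ids[slot], dmo, dgr))
            slot += 1
    return SyntheticConfig(
        n_genes=n_genes,
        seed=int(rng.integers(0, 2**31 - 1)),
        n_replicates=n_replicates,
        noise_sd=noise_sd,
        planted=planted,
    )
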