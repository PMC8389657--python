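"""Composite Fold / Influence-Factor / Distance statistics.

The screen contrasts two myeloid-derived suppressor cell (MDSC) subsets —
monocytic (Mo) and granulocytic (Gr) — before and after TGF-beta treatment.
For each gene, let dMo and dGr be the subset log2 fold changes
(treated minus control, replicate-averaged, both on log2 scale). Three
statistics are derived:

    Fold             F  = dMo + dGr
    Influence Factor IF = F * (dMo - dGr)
    Distance         D  = sqrt(F**2 + IF**2)

``F`` summarises the overall up/down response across both subsets, the sign
of ``IF`` encodes which subset responded more strongly (positive means Mo,
for up- and down-regulated genes alike, because the shared factor ``F``
cancels the direction), and ``D`` — the distance from the origin in the
(F, IF) plane — is the prioritization score.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np


class GroupLabel(str, enum.Enum):
    """Six-way classification of a screened gene by (sign of F, IF band).

    ``Mo-*`` groups hold genes whose TGF-beta response was dominated by the
    monocytic subset (IF above the band), ``Gr-*`` the granulocytic ones
    (IF below the band), and plain ``Up``/``Down`` genes respond comparably
    in both subsets (IF within the band).
    """

    UP = "Up"
    DOWN = "Down"
    MO_UP = "Mo-Up"
    MO_DOWN = "Mo-Down"
    GR_UP = "Gr-Up"
    GR_DOWN = "Gr-Down"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Output column order of Table-1-style listings: central band first, then
#: the Gr-dominated groups, then the Mo-dominated ones.
GROUP_ORDER: tuple[GroupLabel, ...] = (
    GroupLabel.UP,
    GroupLabel.DOWN,
    GroupLabel.GR_UP,
    GroupLabel.GR_DOWN,
    GroupLabel.MO_UP,
    GroupLabel.MO_DOWN,
)


@dataclass
class GeneScore:
    """Per-gene subset fold changes and the derived F/IF/D statistics."""

    gene_id: str
    delta_mo: float
    delta_gr: float
    fold: float
    influence_factor: float
    distance: float
    group: GroupLabel | None = None


def compute_scores(delta_mo, delta_gr):
    """Compute (Fold, Influence Factor, Distance) from subset log2 FCs.

    Parameters
    ----------
    delta_mo, delta_gr : float or array-like
        Log2 fold changes (treated vs control) in the Mo- and Gr-MDSC
        subsets. Scalars and arrays are both accepted; arrays are processed
        vectorized.

    Returns
    -------
    (fold, influence_factor, distance)
        Scalars for scalar input, ``numpy`` arrays otherwise.

    Raises
    ------
    ValueError
        If any input is non-finite.
    """
    dmo = np.asarray(delta_mo, dtype=float)
    dgr = np.asarray(delta_gr, dtype=float)
    if not (np.all(np.isfinite(dmo)) and np.all(np.isfinite(dgr))):
        raise ValueError("delta_mo and delta_gr must be finite")
    fold = dmo + dgr
    influence = fold * (dmo - dgr)
    distance = np.hypot(fold, influence)
    if np.ndim(delta_mo) == 0 and np.ndim(delta_gr) == 0:
        return float(fold), float(influence), float(distance)
    return fold, influence, distance


def subset_log2fc(exp, subset: str) -> dict[str, float]:
    """Per-gene log2 fold change of one subset: mean(treated) - mean(control).

    ``exp`` is an :class:`~mdscreen.io_tables.ExpressionExperiment` whose
    values are already on log2 scale, so the difference of replicate means
    is the log2 of the geometric-mean expression ratio.
    """
    from .io_tables import CONDITIONS, SUBSETS  # local import avoids cycle

    if subset not in SUBSETS:
        raise ValueError(f"unknown subset {subset!r}; expected one of {sorted(SUBSETS)}")
    design = exp.design
    cols_treated = np.flatnonzero(
        (design["subset"] == subset).to_numpy() & (design["condition"] == "treated").to_numpy()
    )
    cols_control = np.flatnonzero(
        (design["subset"] == subset).to_numpy() & (design["condition"] == "control").to_numpy()
    )
    if cols_treated.size == 0 or cols_control.size == 0:
        raise ValueError(f"subset {subset!r} lacks treated or control samples")
    delta = exp.values[:, cols_treated].mean(axis=1) - exp.values[:, cols_control].mean(axis=1)
    return dict(zip(exp.gene_ids, delta.tolist()))


def score_experiment(exp) -> list[GeneScore]:
    """Score every gene of an experiment: subset log2 FCs, then F/IF/D."""
    dmo = subset_log2fc(exp, "Mo")
    dgr = subset_log2fc(exp, "Gr")
    return score_deltas(exp.gene_ids, dmo, dgr)


def score_deltas(
    gene_ids: Sequence[str] | Iterable[str],
    delta_mo: Mapping[str, float],
    delta_gr: Mapping[str, float],
) -> list[GeneScore]:
    """Build :class:`GeneScore` records from per-gene delta maps."""
    ids = list(gene_ids)
    dmo = np.array([delta_mo[g] for g in ids], dtype=float)
    dgr = np.array([delta_gr[g] for g in ids], dtype=float)
    fold, influence, distance = compute_scores(dmo, dgr)
    return [
        GeneScore(g, float(a), float(b), float(f), float(i), float(d))
        for g, a, b, f, i, d in zip(ids, dmo, dgr, fold, influence, distance)
    ]


def score_pair(gene_id: str, delta_mo: float, delta_gr: float) -> GeneScore:
    """Scalar convenience wrapper around :func:`compute_scores`."""
    fold, influence, distance = compute_scores(delta_mo, delta_gr)
    return GeneScore(gene_id, float(delta_mo), float(delta_gr), fold, influence, distance)
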