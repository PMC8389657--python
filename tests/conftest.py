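import numpy as np
import pandas as pd
import pytest

from mdscreen import ExpressionExperiment


def make_experiment(gene_values: dict[str, dict[tuple[str, str], list[float]]],
                    n_replicates: int = 3) -> ExpressionExperiment:
    """Build a small experiment from per-gene, per-(subset, condition) replicates.

    ``gene_values[gene][(subset, condition)]`` is the list of replicate log2
    values (length ``n_replicates``) for that design cell.
    """
    gene_ids = list(gene_values)
    sample_ids = []
    design_rows = []
    for subset in ("Mo", "Gr"):
        for condition in ("control", "treated"):
            for rep in range(1, n_replicates + 1):
                sid = f"{subset}_{condition}_{rep}"
                sample_ids.append(sid)
                design_rows.append(
                    {"sample_id": sid, "subset": subset, "condition": condition, "replicate": rep}
                )
    order = sorted(range(len(sample_ids)), key=lambda i: sample_ids[i])
    sample_ids = [sample_ids[i] for i in order]
    design = pd.DataFrame([design_rows[i] for i in order]).set_index("sample_id")
    values = np.zeros((len(gene_ids), len(sample_ids)))
    for gi, gene in enumerate(gene_ids):
        for si, sid in enumerate(sample_ids):
            subset, condition, rep = sid.rsplit("_", 2)
            values[gi, si] = gene_values[gene][(subset, condition)][int(rep) - 1]
    return ExpressionExperiment(gene_ids, values, sample_ids, design)


@pytest.fixture
def flat_experiment():
    """4 genes x 12 samples, constant replicates, hand-chosen effects."""
    return make_experiment(
        {
            # treated mean - control mean per subset:
            "geneA": {("Mo", "control"): [3.0] * 3, ("Mo", "treated"): [5.0] * 3,
                      ("Gr", "control"): [4.0] * 3, ("Gr", "treated"): [4.5] * 3},   # (2.0, 0.5)
            "geneB": {("Mo", "control"): [6.0] * 3, ("Mo", "treated"): [4.0] * 3,
                      ("Gr", "control"): [5.0] * 3, ("Gr", "treated"): [4.0] * 3},   # (-2.0, -1.0)
            "geneC": {("Mo", "control"): [7.0] * 3, ("Mo", "treated"): [7.0] * 3,
                      ("Gr", "control"): [7.0] * 3, ("Gr", "treated"): [7.0] * 3},   # (0, 0)
            "geneD": {("Mo", "control"): [3.0, 3.1, 2.9], ("Mo", "treated"): [4.1, 4.3, 4.2],
                      ("Gr", "control"): [5.0] * 3, ("Gr", "treated"): [6.0] * 3},   # (1.2, 1.0)
        }
    )
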