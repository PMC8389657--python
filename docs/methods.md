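# Methods

## The screening procedure

The pipeline prioritizes genes by how strongly, and how asymmetrically, two
MDSC subsets (monocytic Mo, granulocytic Gr) respond to TGF-β treatment.
Inputs are a normalized log2 expression matrix over a
2 subsets × 2 conditions × *n* replicates design. For each gene the
per-subset log2 fold change is the difference of replicate means,

ΔMo = mean(log2 treated, Mo) − mean(log2 control, Mo), and likewise ΔGr.

Since the input is on log2 scale this equals the log2 of the geometric-mean
expression ratio. No variance moderation, shrinkage or significance testing
is applied anywhere: the screen is intentionally a pure effect-size
procedure, so its output is a ranked candidate list, not a set of p-values.

From the two deltas:

- F = ΔMo + ΔGr (Fold, log2 units),
- IF = F · (ΔMo − ΔGr) (Influence Factor, squared-log2 units),
- D = √(F² + IF²) (Distance, the prioritization score).

The sign structure of IF is the design's key property: when both subsets
move in the same direction, IF > 0 exactly when the Mo response is larger in
magnitude, for up- and down-regulated genes alike, because the common factor
F carries the direction and cancels it out of the comparison. The test suite
asserts this by exhaustive sign-quadrant enumeration and by randomized
sampling.

Screening keeps genes with |F| strictly greater than the fold threshold.
The threshold is applied to |F|, not F: the classification includes
down-regulated groups, which only an absolute-value screen can populate.
Survivors are classified by sign(F) and the IF band: IF > t → Mo-Up/Mo-Down,
IF < −t → Gr-Up/Gr-Down, |IF| ≤ t → Up/Down, with band boundary values
(IF = ±t) assigned to the central band because the flanking groups are
defined by strict inequalities. Within each group genes are ranked by D
descending, ties broken by gene id ascending (ties do not arise in real
data; the rule exists to make selection invariant to input order), and the
top k per group are selected. The selection is concatenated in the fixed
group order Up, Down, Gr-Up, Gr-Down, Mo-Up, Mo-Down.

### Parameters

| parameter        | default | units       | role |
|------------------|---------|-------------|------|
| `fold_threshold` | 2.5     | log2        | screen on |F| (strict) |
| `if_threshold`   | 1.0     | log2²       | half-width of the central IF band |
| `top_k`          | 3       | genes       | selected per group |
| `noise_sd`       | 0.2     | log2        | simulated replicate noise SD |
| `n_replicates`   | 3       | arrays      | per subset × condition cell |
| `baseline_mean/sd` | 7.0 / 1.5 | log2    | simulated gene baseline distribution |

The three pipeline constants default to the published values of the screen
this package implements; all are exposed in `PipelineConfig` and on the CLI.

## qPCR re-ranking (ΔΔCT)

Relative expression is computed by the classic ΔΔCT method with
amplification efficiency fixed at 2 (no efficiency correction):
ΔCt = Ct(target) − Ct(reference) within each condition,
ΔΔCt = ΔCt(treated) − ΔCt(control), relative expression = 2^−ΔΔCt, so the
qPCR log2 fold change is −ΔΔCt. Replicate Ct values are expected to be
arithmetically averaged before entry; the package does not model Ct-level
replication. For re-ranking, the Ct table carries one row per gene and
subset, yielding per-subset qPCR deltas from which F/IF/D are recomputed by
the same scoring function. Covered candidates are re-ordered by
recalculated Distance; candidates without qPCR coverage remain listed but
can never become the final target call.

## The synthetic-experiment generator

No public data deposit exists for this design, so testing is built on
simulation. `generate_experiment` draws each gene's baseline once from
N(baseline_mean, baseline_sd), adds the gene × subset planted effect to
treated samples, and adds i.i.d. N(0, noise_sd²) replicate noise to every
measurement. This emulates normalized log2 microarray data with three
independent arrays per design cell. It deliberately omits features of real
arrays: mean–variance dependence (noise is homoscedastic across genes),
probe-level structure, batch effects, correlated genes and missing values.
Passing recovery tests therefore demonstrates the pipeline's statistical
behaviour under clean Gaussian replicate noise, not robustness to array
artefacts — those belong to upstream preprocessing.

`six_group_scenario` plants `per_group` genes in each of the six groups by
inverting the scoring map: a target (F, IF) pair determines
ΔMo = (F + IF/F)/2 and ΔGr = (F − IF/F)/2 exactly. True |F| is drawn
uniformly in [3, 6], safely past the 2.5 screen at zero noise. IF placement
required a real design decision. The estimated IF of a gene fluctuates with
SD ≈ |F| · σ_Δ, where σ_Δ = noise_sd · √(2/n_replicates) · √2 ≈ 0.23 at the
defaults — about 1 in squared-log2 units, the same size as the band
half-width. Group membership near the band is therefore intrinsically
unstable under noise, and no placement can prevent boundary crossings.
Instead, the scenario keeps every group's Distances on a common scale —
flanking |IF| ~ U(1.5, 3), central IF ~ U(−0.5, 0.5) — so that a top gene
whose estimated IF crosses the band still wins selection in the
neighbouring group on Distance rank. With 5 genes per group, 0.2 noise and
3 replicates, each group's true top-Distance gene lands in the selected 18
in 94–97% of seeded runs (measured over 200 seeds), and the suite asserts
≥ 90% over 50 runs. A background of 120 unresponsive genes (zero true
effect) stands in for the bulk of the array at desk scale; at zero noise
they have F = 0 and never reach the screen.

The truth table stores each planted gene's deltas, F/IF/D, and its group
label only when its true |F| passes the screen, mirroring the pipeline's
screen-then-classify order.

## Numerical and interface choices

- Scoring is vectorized with numpy; D uses `hypot` for a numerically stable
  Euclidean norm. The vectorized path is checked against scalar arithmetic
  at 1e-12 relative tolerance.
- Tables are tab-delimited text (comma available via `--delimiter`). Floats
  are written with `%.17g` and parsed with pandas' `round_trip` converter,
  making write → read lossless at full IEEE-double precision (the documented
  contract is 12 significant digits).
- Loading is order-canonical: matrix columns and design rows may arrive in
  any order; samples are joined on id and sorted, so permuted inputs yield
  identical in-memory experiments and byte-identical outputs.
- Missing expression values are a hard error by default; `--drop-missing`
  removes affected genes and logs the count. No imputation is offered.
- Degenerate inputs: an empty screen result returns an empty-but-valid
  selection with a warning; `assign_group` refuses F = 0 (undefined
  direction, unreachable after a strict positive screen); qPCR records must
  have finite positive Ct values.
- All simulation randomness flows from a single integer seed through
  `numpy.random.default_rng`; identical inputs, config and seed give
  byte-identical outputs.

## Known limitations

- The screen has no error control; with many genes and few replicates the
  selected list will contain noise-driven candidates by construction. The
  qPCR re-ranking stage is the procedure's only independent confirmation.
- Group labels near |IF| = 1 are unstable at realistic noise (see above);
  downstream interpretation should rely on Distance rank, not on the label
  of a borderline gene.
- Gene-level input is assumed pre-collapsed; probe-to-gene mapping and
  normalization are out of scope.
- The ΔΔCT implementation assumes perfect doubling per cycle and
  pre-averaged Cts; no standard-curve efficiency correction or melt-curve
  QC is provided.
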