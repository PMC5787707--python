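# hetscore

Heterogeneity-aware scoring of arrayed CRISPR-Cas9 image-based screens.

Transient transfection of a Cas9/gRNA plasmid leaves each screening well a
*mixed* population: non-transfected cells T(−), which are genetically wild
type, and transfected cells T(+), of which only a fraction (the
*penetrance*) is functionally perturbed. `hetscore` turns this mixture
from a nuisance into the readout. For every well it trains bootstrapped,
cross-validated L1-penalized logistic regression classifiers to separate
T(+) from T(−) cells in multivariate single-cell feature space and scores
the perturbation by

```
classification score = 0.5 − mean CV misclassification error
```

(0 ≈ no phenotypic effect, 0.5 = perfect separation). Each cell's
bootstrap-averaged linear predictor — the **predicted value, PV** — then
gates *individual* phenotypically perturbed cells: T(+) cells with
PV > mean + 3 SD of control-well T(+) PVs enter single-cell profiling.
Per perturbation the package also reports a **phenotypic score** (the
two-sample Kolmogorov–Smirnov statistic between the well's and the
controls' T(+) PV distributions), calls hits against the Tukey fence
Q3 + 1.5 × IQR of non-targeting-control scores, and characterizes hits by
mean standardized feature profiles of their gated cells (replicate-guide
Pearson correlations, hierarchical clustering).

Also included:

- the classical **between-well baseline**: B-score plate correction
  (Tukey median polish + MAD scaling) of well mean profiles, Mahalanobis
  distance of each profile from the distribution of all profiles,
  Q3 + 3 × IQR fence;
- **hypergeometric enrichment** of annotation terms among hit genes
  relative to the screened library;
- **library-design informatics**: rule-based guide selection (terminal-exon
  avoidance, on-target score ≥ 0.7, one guide per exon region, transcript
  coverage preference) and barcoded colony deconvolution from read counts
  (≥ 50 reads, top guide > 5× runner-up);
- a **synthetic-screen generator** with configurable transfection rate,
  penetrance, effect vector, well-level technical offsets, and plate
  gradients, so the full pipeline is testable with no external data.

See `docs/methods.md` for the model, assumptions and numerical choices.

## Worked example

Simulate a 12-well screen (8 targeting wells with a 3-SD single-feature
effect at penetrance 0.6, 4 non-targeting controls, ~800 cells/well) and
run the within-well analysis:

```sh
hetscore simulate --config sim.yaml --out-dir demo
hetscore run --config screen.yaml --cells demo/cells.csv \
    --platemap demo/platemap.csv --out-dir demo/results
```

`demo/results/screen_result.csv` (seed 42, 20 bootstraps of 250
cells/class, 5-fold CV):

```
well perturbation  n_tpos  classification_score  phenotypic_score  n_gated  is_hit
 A03   NT_P01_A03     395                 0.036             0.032        0   False
 A04   PT_P01_A04     399                 0.223             0.587      225    True
 A05   PT_P01_A05     405                 0.218             0.548      216    True
 A06   PT_P01_A06     380                 0.248             0.609      227    True
 A07   NT_P01_A07     437                 0.029             0.120        0   False
 ...
```

Reading this: control wells (NT) score ≈ 0.03–0.06 — their T(+) and T(−)
cells are essentially indistinguishable — while every targeting well
scores ≈ 0.21–0.25 and is called a hit against the control fence (0.079
here). `n_gated` counts the T(+) cells above the PV gate (0.686 for this
screen): ≈ 220 of ≈ 400 T(+) cells per targeting well, matching the
simulated penetrance of 0.6, and (almost) none in control wells. The
phenotypic score ≈ 0.55–0.61 quantifies how strongly each perturbation
shifts the T(+) PV distribution away from the controls'. Per-cell PVs,
gated-cell lists and gated-cell feature profiles are written alongside.

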