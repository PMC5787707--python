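# Methods

## The problem

In arrayed CRISPR-Cas9 screens built on transient transfection, every well
contains a mixture: non-transfected cells T(−) that are genetically wild
type, and transfected cells T(+) of which only a fraction — the
*penetrance* — is actually functionally perturbed, because editing can fail
or repair in frame. Averaging features over the whole well therefore
dilutes every phenotype with wild-type cells and confounds it with
well-to-well technical variation. `hetscore` implements a within-well,
classifier-based analysis that uses each well's own wild-type cells as a
built-in control, plus the classical between-well profile analysis as a
baseline.

## Within-well scoring

1. **Well QC.** Wells with fewer than `min_tpos = 300` transfected cells
   are excluded (configurable). A second guard, `min_tneg = 100`, ensures a
   stable in-well control estimate; the screen protocol fixes only the
   T(+) minimum, the T(−) minimum is this package's addition.
2. **In-well standardization.** Every feature of every cell is
   standardized by the mean and sample standard deviation (n−1 denominator)
   of the well's T(−) population. Additive well-level technical offsets
   cancel exactly at this step. Features whose T(−) SD falls below
   `sd_epsilon = 1e-8` in any well are dropped screen-wide so all wells
   share one feature space.
3. **Pooled PCA.** One PCA is fitted on all cells pooled across wells
   (components sign-fixed so the largest-magnitude loading is positive);
   `pca_k` defaults to 30, with 50 recommended for broad morphology
   panels. Fitting per screen rather than per well keeps predicted values
   comparable across wells.
4. **Bootstrapped CV LASSO logistic regression.** Per well, 100 bootstraps
   each draw 500 T(+) and 500 T(−) cells with replacement and fit an
   L1-penalized logistic regression over a 10-point penalty grid
   (`C ∈ logspace(−2.5, 1.5)`), selecting the penalty that minimizes the
   10-fold stratified cross-validated misclassification error. The model is
   then refitted on the full bootstrap sample at that penalty and every
   cell in the well is scored with the linear predictor (log-odds of the
   T(+)-coded class) — the predicted value, PV. Balanced resampling makes
   the error a balanced error regardless of the well's transfection rate.
5. **Classification score.** `score = 0.5 − mean CV misclassification`
   over bootstraps: 0 for indistinguishable populations, 0.5 for perfect
   separation. Per-cell PVs are averaged over bootstraps.
6. **PV gate.** The gate is `mean + 3 × SD` of the pooled PVs of T(+)
   cells from all non-targeting-control wells (screen-wide pooling, one
   gate per screen). T(+) cells with PV strictly above the gate are the
   phenotypically perturbed single cells used for profiling.
7. **Phenotypic score.** The two-sample Kolmogorov–Smirnov statistic
   between a well's T(+) PV distribution and the pooled control T(+) PV
   distribution (statistic only; no p-value).
8. **Hit calling.** A perturbation is a hit when its classification score
   strictly exceeds the Tukey fence `Q3 + 1.5 × IQR` of control scores
   (quantiles by linear interpolation; at least 4 control wells required).
9. **Profiles.** Mean standardized feature vectors over gated cells,
   referenced to the mean over control T(+) cells; withheld below
   `min_gated = 20` cells. Replicate-guide agreement is summarized by
   Pearson correlations (within-gene vs between-gene pairs) and by
   average-linkage hierarchical clustering on the `1 − r` distance
   (rows sorted by id first, making merges deterministic).

### Numerical and design choices

- **PV scale.** The PV is the logit (linear predictor), not the
  probability: the decision boundary at 0 then coincides with "classified
  into the perturbed class", and bootstrap averaging happens on an
  unbounded scale.
- **Penalty selection** is minimum-CV-misclassification, not a 1-SE rule;
  the recorded error is the CV estimate at the chosen penalty.
- **Determinism.** Every well's classifier draws from a substream keyed by
  (screen seed, plate, well); liblinear's internal shuffling is seeded
  explicitly. Cells are put in canonical (plate, well, cell) order before
  resampling, so results are independent of input row order.
- **Degenerate folds** are prevented by stratified fold assignment on the
  balanced bootstrap sample.

## Between-well baseline

Mean feature profiles per (well, population) are corrected for plate
positional effects by B-score — two-way Tukey median polish over the well
grid per (plate, population, feature), residuals divided by
`1.4826 × median |residual|`, with a zero guard for constant plates — and
each profile's Mahalanobis distance from the distribution of all profiles
is computed under a Ledoit–Wolf shrinkage covariance (analytic intensity,
pseudo-inverse fallback). The unregularized covariance is available as
`shrinkage="none"`, and is exactly affine-invariant on well-conditioned
inputs. Between-well hits use the wider fence `Q3 + 3 × IQR` of control
T(+) distances.

Two caveats. Median polish fixed points are not unique: with row sweeps
first, adding a constant to a plate *row* leaves B-scores exactly
unchanged, but a constant added to a *column* is only absorbed exactly
when the plate is additive. And a plate whose wells occupy a single row
(or column) is degenerate — each column effect then absorbs its single
observation — so analyses of small simulated screens should lay wells out
over a two-dimensional block.

## Synthetic screens

The generator emulates the assumed data-generating process, not any real
microscope output. Per well: the cell count is Poisson(`cells_per_well`);
each cell is T(+) with probability `transfection_rate`; in targeting wells
each T(+) cell is latently perturbed with probability `penetrance`.
Wild-type features are independent unit-variance Gaussians; a perturbation
adds `effect_vector` (units of wild-type SD) to the perturbed cells'
means; technical structure is a per-well offset vector drawn
N(0, `well_sigma`²) per feature plus linear row/column gradients. Control
wells carry no effect. Each well's draws come from a substream keyed by
(seed, plate, well), so extending a screen never changes existing wells.
Wells fill a 16×24 grid, leaving the outer two columns on each side empty,
mirroring edge-well exclusion in screening practice.

Defaults are one choice of realistic study conditions: 96 wells,
2,000 cells per well (a desk-scale stand-in for the ~4,000 imaged cells
per well of a production screen), transfection rate 0.5, penetrance 0.6
(production guide selection achieves >30% perturbed transfected cells for
most plasmids, with a broad range), a 3-SD single-feature effect,
`well_sigma = 0.3`, gradients 0.01/step, 12.5% control wells.

What the generator deliberately does not model: correlated features,
non-Gaussian (e.g. lognormal intensity) distributions, segmentation
errors, cell-cycle or density covariates, spatially heterogeneous
transfection, or intensity-based transfection calling (the T(+) flag is
emitted as a clean boolean). Passing tests therefore demonstrate the
statistical machinery under the assumed model, not robustness to the full
messiness of imaging data.

## Library-design rules

Guide selection per gene: exon regions terminal (first or last) in
strictly more than 25% of the transcripts containing them are excluded;
candidates need an on-target activity score ≥ 0.7 (inclusive); at most one
guide per region; preference order is (more transcripts hit, higher score,
guide id), with a score-ranked fallback to below-threshold candidates when
the primary pool cannot fill the request. Colony deconvolution keeps a
well when it has ≥ 50 mapped reads (inclusive) and its top guide count
strictly exceeds 5× the runner-up; re-arraying keeps, per guide, the
retained well with the highest top count (ties to the lexicographically
smaller well key).

## Problem sizes in the test-suite and reproduction script

The packaged defaults (100 bootstraps, 500 cells/class, 10 folds) are used
for the single-well reproduction in `scripts/acceptance.py`. Multi-well
test suites run the same procedure at reduced size — typically 2–8
bootstraps, 100–200 cells per class, 4–5 folds, 4–6 penalty points,
300–1,000 cells per well — sizes chosen so the whole suite runs on a
laptop in minutes while the qualitative behaviour (score formula,
penetrance recovery, fence calibration, sensitivity ordering) is
unchanged.

## Known limitations

- The KS phenotypic score is reported without a p-value; no multiplicity
  control is applied to hit calling (fence thresholds only).
- The hypergeometric enrichment takes flat term→gene sets; ontology
  structure (term propagation) is out of scope.
- Guide "mutation-free" verification is reduced to exact 20-mer matching
  upstream of this package; read counts are consumed as given.
- B-score sweep-order effects discussed above.
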