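"""Pooled PCA and per-well bootstrapped CV L1-logistic classification.

Per well, the method asks how separable the transfected T(+) cells are from
the in-well wild-type T(-) cells. Each of ``n_boot`` bootstraps draws
``n_per_class`` cells per class with replacement, runs a 10-fold
cross-validated L1-penalized logistic regression over a penalty grid,
records the CV misclassification error at the best penalty, refits on the
full bootstrap sample and scores EVERY cell in the well with the linear
predictor (log-odds of the T(+)-coded class) — the predicted value (PV).

classification_score = 0.5 - mean CV misclassification over bootstraps:
0 means T(+) and T(-) are indistinguishable (a 50% balanced error), 0.5
means perfect separation. PVs are averaged over bootstraps; a positive PV
puts a cell on the phenotypically perturbed side of the decision boundary.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold

from ._util import substream_seed
from .io import CellTable, FeatureSet, PlateMap, StandardizedCellTable

# L1 penalty grid (inverse regularization strength), strong -> weak
DEFAULT_CS: tuple[float, ...] = tuple(np.logspace(-2.5, 1.5, 10))


@dataclasses.dataclass
class PCModel:
    """Pooled principal-component model of the standardized feature space."""

    feature_names: list[str]
    feature_means: np.ndarray
    loadings: np.ndarray  # (n_features, k), orthonormal columns
    explained_variance: np.ndarray

    @property
    def k(self) -> int:
        return self.loadings.shape[1]


@dataclasses.dataclass
class WellClassifierResult:
    plate: str
    well: str
    n_bootstraps: int
    n_tpos: int
    n_tneg: int
    mean_misclassification: float
    pv_per_cell: pd.Series  # index: cell id, value: mean linear predictor
    selected_feature_frequency: np.ndarray  # per component

    @property
    def classification_score(self) -> float:
        return 0.5 - self.mean_misclassification


def fit_pca(cells: StandardizedCellTable | CellTable, features: FeatureSet | None = None, k: int = 30) -> PCModel:
    """Fit PCA once on all cells pooled across wells.

    Components are ordered by decreasing explained variance; each component
    is sign-fixed so its largest-magnitude loading is positive, making
    loadings reproducible.
    """
    names = list(features.features) if features is not None else list(cells.feature_names)
    if k > len(names):
        raise ValueError(f"k={k} exceeds number of features ({len(names)})")
    X = cells.data[names].to_numpy()
    if X.shape[0] < k + 1:
        raise ValueError("need at least k+1 pooled cells to fit PCA")
    pca = PCA(n_components=k, svd_solver="full")
    pca.fit(X)
    loadings = pca.components_.T.copy()  # (features, k)
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
    return PCModel(
        feature_names=names,
        feature_means=pca.mean_.copy(),
        loadings=loadings,
        explained_variance=pca.explained_variance_.copy(),
    )


def project(cells: StandardizedCellTable | CellTable | pd.DataFrame, model: PCModel) -> pd.DataFrame:
    """Centered projection of cells onto the PC loadings.

    Returns a table with plate/well/cell/transfected plus columns
    ``pc00..`` when given a cell table, or just the component scores when
    given a bare feature frame.
    """
    if isinstance(cells, CellTable):
        df = cells.data
    else:
        df = cells
    missing = [f for f in model.feature_names if f not in df.columns]
    if missing:
        raise ValueError(f"cells lack features required by the PC model: {missing}")
    Z = (df[model.feature_names].to_numpy() - model.feature_means) @ model.loadings
    comp_names = [f"pc{j:02d}" for j in range(model.k)]
    scores = pd.DataFrame(Z, columns=comp_names, index=df.index)
    if isinstance(cells, CellTable):
        out = df[["plate", "well", "cell", "transfected"]].copy()
        return pd.concat([out, scores], axis=1)
    return scores


def fit_well_classifier(
    X: np.ndarray,
    y: np.ndarray,
    cell_ids: Sequence[int] | None = None,
    *,
    n_boot: int = 100,
    n_per_class: int = 500,
    n_folds: int = 10,
    Cs: Sequence[float] = DEFAULT_CS,
    seed: int = 0,
    plate: str = "",
    well: str = "",
) -> WellClassifierResult:
    """Bootstrapped 10-fold CV LASSO logistic classification of one well.

    ``X`` is the (cells x components) score matrix, ``y`` the transfected
    flag (True = T(+), coded as the positive / phenotypically perturbed
    class). The penalty minimizing CV misclassification error is chosen per
    bootstrap; the recorded error is the CV estimate at that penalty.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=bool)
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    pos_idx = np.flatnonzero(y)
    neg_idx = np.flatnonzero(~y)
    if len(pos_idx) == 0 or len(neg_idx) == 0:
        raise ValueError(f"well ({plate}, {well}): both T(+) and T(-) cells are required")
    if cell_ids is None:
        cell_ids = np.arange(len(y))
    rng = np.random.default_rng(seed)
    mis_errors = np.empty(n_boot)
    pv_sum = np.zeros(len(y))
    nonzero = np.zeros(X.shape[1])
    yb = np.concatenate([np.ones(n_per_class, dtype=bool), np.zeros(n_per_class, dtype=bool)])
    for b in range(n_boot):
        bi = np.concatenate(
            [rng.choice(pos_idx, n_per_class, replace=True), rng.choice(neg_idx, n_per_class, replace=True)]
        )
        Xb = X[bi]
        fold_seed = int(rng.integers(2**31))
        cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=fold_seed)
        with warnings.catch_warnings():
            # scikit-learn >=1.8 pre-announces an API change for penalty=;
            # the l1/liblinear behaviour used here is unchanged
            warnings.filterwarnings("ignore", category=FutureWarning)
            clf = LogisticRegressionCV(
                Cs=list(Cs), cv=cv, penalty="l1", solver="liblinear",
                scoring="accuracy", refit=True, max_iter=500, tol=1e-4, n_jobs=None,
                random_state=fold_seed,  # liblinear's internal shuffling
            )
            clf.fit(Xb, yb)
        scores = next(iter(clf.scores_.values()))  # (n_folds, n_Cs) accuracies
        mean_acc = scores.mean(axis=0)
        ci = int(np.argmin(np.abs(np.log(clf.Cs_) - np.log(clf.C_[0]))))
        mis_errors[b] = 1.0 - float(mean_acc[ci])
        pv_sum += clf.decision_function(X)  # positive => T(+)-coded class
        nonzero += (clf.coef_.ravel() != 0).astype(float)
    return WellClassifierResult(
        plate=plate,
        well=well,
        n_bootstraps=n_boot,
        n_tpos=int(len(pos_idx)),
        n_tneg=int(len(neg_idx)),
        mean_misclassification=float(mis_errors.mean()),
        pv_per_cell=pd.Series(pv_sum / n_boot, index=pd.Index(cell_ids, name="cell")),
        selected_feature_frequency=nonzero / n_boot,
    )


def classify_screen(
    std_cells: StandardizedCellTable,
    features: FeatureSet | None = None,
    *,
    pca_k: int = 30,
    n_boot: int = 100,
    n_per_class: int = 500,
    n_folds: int = 10,
    Cs: Sequence[float] = DEFAULT_CS,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, PCModel]:
    """Run the within-well classifier over every well of a screen.

    Returns (well table, per-cell PV table, fitted PC model). Each well's
    random stream is derived from (seed, plate, well), so results do not
    depend on well order.
    """
    model = fit_pca(std_cells, features, k=pca_k)
    projected = project(std_cells, model)
    # canonical cell order: results do not depend on input row order
    projected = projected.sort_values(["plate", "well", "cell"]).reset_index(drop=True)
    comp_cols = [c for c in projected.columns if c.startswith("pc")]
    well_rows, pv_frames = [], []
    for (plate, well), sub in projected.groupby(["plate", "well"], sort=True):
        res = fit_well_classifier(
            sub[comp_cols].to_numpy(),
            sub["transfected"].to_numpy(),
            cell_ids=sub["cell"].to_numpy(),
            n_boot=n_boot,
            n_per_class=n_per_class,
            n_folds=n_folds,
            Cs=Cs,
            seed=substream_seed(seed, "classify", plate, well),
            plate=plate,
            well=well,
        )
        well_rows.append(
            {
                "plate": plate, "well": well, "n_tpos": res.n_tpos, "n_tneg": res.n_tneg,
                "n_bootstraps": res.n_bootstraps,
                "mean_misclassification": res.mean_misclassification,
                "classification_score": res.classification_score,
            }
        )
        pv = sub[["plate", "well", "cell", "transfected"]].copy()
        pv["pv"] = res.pv_per_cell.to_numpy()
        pv_frames.append(pv)
    wells = pd.DataFrame(well_rows)
    pvs = pd.concat(pv_frames, ignore_index=True)
    return wells, pvs, model
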