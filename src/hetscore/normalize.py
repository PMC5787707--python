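"""Well QC, in-well T(-) standardization, well profiles and B-score correction.

The in-well standardization is the method's answer to technical
well-to-well variability: every feature of every cell is re-expressed in
units of the well's own non-transfected (wild-type) population, so additive
well-level offsets cancel exactly. The B-score branch instead corrects
well-LEVEL mean profiles for plate positional effects by two-way Tukey
median polish with MAD scaling, for use by the between-well baseline.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from ._util import well_position
from .io import CellTable, FeatureSet, StandardizedCellTable

MAD_CONSTANT = 1.4826  # makes the MAD a consistent SD estimate under normality


class WellPreconditionError(ValueError):
    """A well violates a precondition (e.g. too few T(-) cells)."""


@dataclasses.dataclass
class QCReport:
    excluded: pd.DataFrame  # plate, well, n_tpos, n_tneg, reason

    @property
    def n_excluded(self) -> int:
        return len(self.excluded)


def well_counts(cells: CellTable) -> pd.DataFrame:
    g = cells.data.groupby(["plate", "well"], sort=True)["transfected"]
    out = g.agg(n_tpos="sum", n_total="size").reset_index()
    out["n_tpos"] = out["n_tpos"].astype(int)
    out["n_tneg"] = out["n_total"] - out["n_tpos"]
    return out[["plate", "well", "n_tpos", "n_tneg"]]


def qc_wells(cells: CellTable, min_tpos: int = 300, min_tneg: int = 100) -> tuple[CellTable, QCReport]:
    """Drop wells with too few transfected (or too few control) cells.

    ``min_tpos=300`` is the screen's well-exclusion rule; ``min_tneg``
    guards the in-well standardization estimate.
    """
    counts = well_counts(cells)
    reasons = []
    for _, r in counts.iterrows():
        why = []
        if r["n_tpos"] < min_tpos:
            why.append(f"n_tpos {r['n_tpos']} < {min_tpos}")
        if r["n_tneg"] < min_tneg:
            why.append(f"n_tneg {r['n_tneg']} < {min_tneg}")
        if why:
            reasons.append(
                {"plate": r["plate"], "well": r["well"], "n_tpos": int(r["n_tpos"]),
                 "n_tneg": int(r["n_tneg"]), "reason": "; ".join(why)}
            )
    excluded = pd.DataFrame(reasons, columns=["plate", "well", "n_tpos", "n_tneg", "reason"])
    bad = set(zip(excluded["plate"], excluded["well"])) if len(excluded) else set()
    if not bad:
        return cells, QCReport(excluded)
    keys = pd.MultiIndex.from_frame(cells.data[["plate", "well"]])
    keep = ~keys.isin(bad)
    retained = CellTable(cells.data[keep].reset_index(drop=True), cells.feature_names)
    return retained, QCReport(excluded)


def standardize_within_well(
    cells: CellTable, features: FeatureSet | None = None, sd_epsilon: float = 1e-8
) -> StandardizedCellTable:
    """Standardize each feature by the well's T(-) mean and sample SD (n-1).

    Features whose T(-) sample SD falls at or below ``sd_epsilon`` in ANY
    well are dropped screen-wide (with a warning) so all wells keep a
    common feature space for the pooled PCA.
    """
    names = list(features.features) if features is not None else list(cells.feature_names)
    if features is not None:
        features.validate_against(cells)
    df = cells.data
    tneg = df[~df["transfected"]]
    n_tneg = tneg.groupby(["plate", "well"], sort=True).size()
    all_wells = df.groupby(["plate", "well"], sort=True).size()
    for key in all_wells.index:
        if n_tneg.get(key, 0) < 2:
            raise WellPreconditionError(
                f"well {key} has {int(n_tneg.get(key, 0))} T(-) cells; >=2 required for standardization"
            )
    g = tneg.groupby(["plate", "well"], sort=True)
    mu = g[names].mean()
    sd = g[names].std(ddof=1)
    degenerate = sorted(f for f in names if (sd[f] <= sd_epsilon).any())
    if degenerate:
        warnings.warn(
            f"dropping feature(s) with degenerate T(-) spread in >=1 well: {degenerate}",
            stacklevel=2,
        )
    kept = [f for f in names if f not in degenerate]
    if not kept:
        raise WellPreconditionError("all features degenerate after T(-) SD screening")
    keys = pd.MultiIndex.from_frame(df[["plate", "well"]])
    out = df[["plate", "well", "cell", "transfected"]].copy()
    mu_rows = mu.loc[keys, kept].to_numpy()
    sd_rows = sd.loc[keys, kept].to_numpy()
    std_vals = (df[kept].to_numpy() - mu_rows) / sd_rows
    for j, f in enumerate(kept):
        out[f] = std_vals[:, j]
    provenance = {
        key: {f: (float(mu.loc[key, f]), float(sd.loc[key, f])) for f in kept}
        for key in mu.index
    }
    return StandardizedCellTable(
        out.reset_index(drop=True), kept, provenance=provenance, dropped_features=degenerate
    )


def well_mean_profiles(cells: CellTable, features: FeatureSet | None = None) -> pd.DataFrame:
    """Mean feature vector per (plate, well, population in {T(+), T(-)}).

    Adds 0-based plate geometry columns ``row``/``col``. A well with an
    empty population contributes no row for it (warning emitted).
    """
    names = list(features.features) if features is not None else list(cells.feature_names)
    rows = []
    for (plate, well), sub in cells.data.groupby(["plate", "well"], sort=True):
        for pop, flag in (("T(+)", True), ("T(-)", False)):
            part = sub[sub["transfected"] == flag]
            if part.empty:
                warnings.warn(f"well ({plate}, {well}) has no {pop} cells; profile omitted", stacklevel=2)
                continue
            r, c = well_position(well)
            rows.append(
                {"plate": plate, "well": well, "population": pop, "row": r, "col": c,
                 **{f: float(part[f].mean()) for f in names}}
            )
    return pd.DataFrame(rows)


def median_polish(grid: np.ndarray, max_iter: int = 10, tol: float = 1e-6) -> np.ndarray:
    """Residuals of a two-way Tukey median polish; NaN marks absent wells."""
    resid = np.array(grid, dtype=float)
    for _ in range(max_iter):
        delta = 0.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows/cols
            rmed = np.nanmedian(resid, axis=1)
            rmed = np.where(np.isfinite(rmed), rmed, 0.0)
            resid -= rmed[:, None]
            delta = max(delta, float(np.max(np.abs(rmed), initial=0.0)))
            cmed = np.nanmedian(resid, axis=0)
            cmed = np.where(np.isfinite(cmed), cmed, 0.0)
            resid -= cmed[None, :]
            delta = max(delta, float(np.max(np.abs(cmed), initial=0.0)))
        if delta < tol:
            break
    return resid


def bscore(
    profiles: pd.DataFrame, features: FeatureSet | None = None,
    max_iter: int = 10, tol: float = 1e-6, scale_epsilon: float = 1e-12,
) -> pd.DataFrame:
    """B-score well-level profiles per plate: median-polish residuals / (1.4826 x MAD).

    Operates independently per (plate, population, feature) over the well
    grid. A constant plate yields all-zero scores (scale guard), never NaN.
    """
    names = list(features.features) if features is not None else [
        c for c in profiles.columns if c not in ("plate", "well", "population", "row", "col")
    ]
    out = profiles.copy()
    for (plate, pop), sub in profiles.groupby(["plate", "population"], sort=True):
        if len(sub) < 2:
            raise ValueError(f"plate {plate!r} ({pop}) has a single well; median polish undefined")
        rmax, cmax = int(sub["row"].max()), int(sub["col"].max())
        for f in names:
            grid = np.full((rmax + 1, cmax + 1), np.nan)
            grid[sub["row"].to_numpy(), sub["col"].to_numpy()] = sub[f].to_numpy()
            resid = median_polish(grid, max_iter=max_iter, tol=tol)
            vals = resid[sub["row"].to_numpy(), sub["col"].to_numpy()]
            mad = float(np.median(np.abs(vals)))
            scale = MAD_CONSTANT * mad
            out.loc[sub.index, f] = vals / scale if scale > scale_epsilon else 0.0
    return out
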