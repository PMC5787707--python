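"""Screen-level scoring: PV gate, KS phenotypic score, Tukey-fence hit calling.

Non-targeting control wells define every null distribution here:
- the PV gate (control T(+) mean + 3 SD) above which a transfected cell is
  deemed phenotypically perturbed and enters single-cell profiling;
- the hit fence (Q3 + 1.5 x IQR of control classification scores);
- the reference PV sample for the per-perturbation KS phenotypic score.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .io import PlateMap


@dataclasses.dataclass(frozen=True)
class PVGate:
    """Threshold for phenotypically perturbed single cells."""

    threshold: float
    control_mean: float
    control_sd: float
    multiplier: float = 3.0


@dataclasses.dataclass(frozen=True)
class HitThreshold:
    """Tukey fence over control classification scores."""

    value: float
    q3: float
    iqr: float
    multiplier: float = 1.5


def _control_mask(df: pd.DataFrame, pmap: PlateMap) -> pd.Series:
    ctl = set(pmap.control_wells())
    keys = pd.MultiIndex.from_frame(df[["plate", "well"]])
    return pd.Series(keys.isin(ctl), index=df.index)


def control_tpos_pvs(pvs: pd.DataFrame, pmap: PlateMap) -> np.ndarray:
    """Pooled PVs of T(+) cells from all non-targeting-control wells."""
    mask = _control_mask(pvs, pmap) & pvs["transfected"]
    return pvs.loc[mask, "pv"].to_numpy()


def compute_pv_gate(pvs: pd.DataFrame, pmap: PlateMap, multiplier: float = 3.0) -> PVGate:
    """Gate = mean + multiplier x sample SD of pooled control T(+) PVs."""
    pool = control_tpos_pvs(pvs, pmap)
    if len(pool) == 0:
        raise ValueError("no T(+) cells in non-targeting control wells; cannot set PV gate")
    mean = float(np.mean(pool))
    sd = float(np.std(pool, ddof=1)) if len(pool) > 1 else 0.0
    return PVGate(threshold=mean + multiplier * sd, control_mean=mean, control_sd=sd, multiplier=multiplier)


def gate_cells(pvs: pd.DataFrame, gate: PVGate) -> pd.DataFrame:
    """T(+) cells with PV strictly above the gate (rows of the PV table)."""
    mask = pvs["transfected"] & (pvs["pv"] > gate.threshold)
    return pvs.loc[mask].reset_index(drop=True)


def phenotypic_score(target_pvs: np.ndarray, control_pvs: np.ndarray) -> float:
    """Two-sample KS statistic D between T(+) PV distributions (no p-value).

    D = sup_x |F_target(x) - F_control(x)|; 0 when the perturbation leaves
    transfected cells indistinguishable from control transfected cells,
    1 when their PV supports are disjoint.
    """
    target_pvs = np.asarray(target_pvs, dtype=float)
    control_pvs = np.asarray(control_pvs, dtype=float)
    if len(target_pvs) == 0 or len(control_pvs) == 0:
        raise ValueError("phenotypic_score requires non-empty PV samples")
    # method affects only the (unused) p-value; asymp avoids exact-mode
    # tie warnings and cost on large cell counts
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # p-value edge cases
        res = stats.ks_2samp(target_pvs, control_pvs, alternative="two-sided", method="asymp")
    return float(res.statistic)


def call_hits(
    wells: pd.DataFrame, pmap: PlateMap, multiplier: float = 1.5,
    score_column: str = "classification_score",
) -> tuple[HitThreshold, pd.DataFrame]:
    """Flag wells whose score strictly exceeds Q3 + multiplier x IQR of controls.

    Quantiles use linear interpolation between order statistics. Requires
    at least 4 control wells so the IQR is meaningful.
    """
    is_ctl = _control_mask(wells, pmap)
    ctl_scores = wells.loc[is_ctl, score_column].to_numpy()
    if len(ctl_scores) < 4:
        raise ValueError(f"need >=4 control wells to set a hit fence, got {len(ctl_scores)}")
    q1, q3 = np.quantile(ctl_scores, [0.25, 0.75])  # linear interpolation
    iqr = float(q3 - q1)
    thr = HitThreshold(value=float(q3 + multiplier * iqr), q3=float(q3), iqr=iqr, multiplier=multiplier)
    out = wells.copy()
    out["is_control"] = is_ctl.to_numpy()
    out["is_hit"] = out[score_column] > thr.value
    return thr, out
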