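"""Perturbation characterization: gated-cell profiles, replicate
correlations, hierarchical clustering, and the between-well Mahalanobis
baseline.

The within-well branch profiles only the PV-gated (phenotypically
perturbed) transfected cells, referenced to control transfected cells, so
dilution by phenotypically wild-type T(+) cells is removed. The
between-well branch measures each well-level mean profile's Mahalanobis
distance from the distribution of all profiles under a shrinkage
covariance — the classical well-averaged analysis used as a baseline.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.covariance import LedoitWolf

from .io import FeatureSet, PlateMap, StandardizedCellTable
from .score import _control_mask


@dataclasses.dataclass
class PerturbationProfile:
    perturbation_id: str
    gene: str
    n_gated: int
    features: list[str]
    profile: np.ndarray  # control-referenced mean standardized features


def perturbed_cell_profiles(
    std_cells: StandardizedCellTable,
    gated: pd.DataFrame,
    pmap: PlateMap,
    features: FeatureSet | None = None,
    min_gated: int = 20,
) -> tuple[list[PerturbationProfile], pd.DataFrame]:
    """Mean standardized feature vectors over gated cells, per perturbation.

    Profiles are referenced to (minus) the mean over control-well T(+)
    cells. Perturbations with fewer than ``min_gated`` gated cells are
    withheld and listed in the returned report.
    """
    names = list(features.features) if features is not None else list(std_cells.feature_names)
    df = std_cells.data
    ctl_mask = _control_mask(df, pmap) & df["transfected"]
    if not ctl_mask.any():
        raise ValueError("no control T(+) cells available as profile reference")
    ref = df.loc[ctl_mask, names].mean().to_numpy()

    cell_keys = df.set_index(["plate", "well", "cell"])
    gated_keys = pd.MultiIndex.from_frame(gated[["plate", "well", "cell"]])
    gated_feats = cell_keys.loc[gated_keys]
    pm = pmap.data.set_index(["plate", "well"])
    well_of_gated = pd.MultiIndex.from_frame(gated[["plate", "well"]])
    perts = pm.loc[well_of_gated, ["perturbation", "gene"]].reset_index(drop=True)
    gated_feats = gated_feats.reset_index(drop=True)
    gated_feats["perturbation"] = perts["perturbation"].to_numpy()
    gated_feats["gene"] = perts["gene"].to_numpy()

    profiles: list[PerturbationProfile] = []
    withheld = []
    for (pert, gene), sub in gated_feats.groupby(["perturbation", "gene"], sort=True):
        if len(sub) < min_gated:
            withheld.append({"perturbation": pert, "gene": gene, "n_gated": len(sub),
                             "reason": f"n_gated {len(sub)} < {min_gated}"})
            continue
        vec = sub[names].mean().to_numpy() - ref
        profiles.append(PerturbationProfile(pert, gene, int(len(sub)), names, vec))
    report = pd.DataFrame(withheld, columns=["perturbation", "gene", "n_gated", "reason"])
    return profiles, report


def profiles_frame(profiles: Sequence[PerturbationProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        rows.append({"perturbation": p.perturbation_id, "gene": p.gene, "n_gated": p.n_gated,
                     **dict(zip(p.features, p.profile))})
    return pd.DataFrame(rows)


def replicate_correlation(profiles: Sequence[PerturbationProfile]) -> pd.DataFrame:
    """Pearson r for every profile pair, labelled within-gene / between-gene.

    A pair involving a constant profile has undefined correlation and is
    flagged (``r`` = NaN, ``defined`` = False).
    """
    rows = []
    for a, b in itertools.combinations(profiles, 2):
        const = np.std(a.profile) == 0 or np.std(b.profile) == 0
        r = np.nan if const else float(np.corrcoef(a.profile, b.profile)[0, 1])
        rows.append(
            {
                "perturbation_a": a.perturbation_id, "perturbation_b": b.perturbation_id,
                "gene_a": a.gene, "gene_b": b.gene,
                "within_gene": a.gene == b.gene, "r": r, "defined": not const,
            }
        )
    return pd.DataFrame(rows)


@dataclasses.dataclass
class ClusteringResult:
    ids: list[str]  # input order (sorted by id)
    linkage: np.ndarray
    leaf_order: list[str]
    newick: str


def cluster_profiles(profile_matrix: pd.DataFrame, id_column: str = "perturbation") -> ClusteringResult:
    """Average-linkage hierarchical clustering with distance 1 - Pearson r.

    Rows are sorted by id before clustering, making merge order (and hence
    the tie-break between equal distances) deterministic.
    """
    if len(profile_matrix) < 2:
        raise ValueError("clustering requires >=2 profiles")
    mat = profile_matrix.sort_values(id_column).reset_index(drop=True)
    ids = mat[id_column].astype(str).tolist()
    feat_cols = [c for c in mat.columns if c not in (id_column, "gene", "n_gated")]
    X = mat[feat_cols].to_numpy(dtype=float)
    corr = np.corrcoef(X)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    order = hierarchy.leaves_list(Z)
    tree = hierarchy.to_tree(Z)

    def _newick(node) -> str:
        if node.is_leaf():
            return ids[node.id]
        left, right = node.get_left(), node.get_right()
        dl = max(node.dist - left.dist, 0.0)
        dr = max(node.dist - right.dist, 0.0)
        return f"({_newick(left)}:{dl:.6g},{_newick(right)}:{dr:.6g})"

    return ClusteringResult(
        ids=ids, linkage=Z, leaf_order=[ids[i] for i in order], newick=_newick(tree) + ";"
    )


def mahalanobis_profiles(
    profiles: pd.DataFrame,
    pmap: PlateMap,
    features: FeatureSet | None = None,
    multiplier: float = 3.0,
    shrinkage: str = "lw",
) -> tuple[pd.DataFrame, float]:
    """Mahalanobis distance of each well profile from the distribution of all.

    The covariance of all profiles is estimated with Ledoit-Wolf shrinkage
    toward a scaled identity (``shrinkage="lw"``, the default, robust when
    profiles do not greatly outnumber features) or as the plain empirical
    covariance (``shrinkage="none"``); a pseudo-inverse guards residual
    singularity in either case. A profile is a hit when its distance
    strictly exceeds Q3 + multiplier x IQR of control T(+) profile
    distances.
    """
    names = list(features.features) if features is not None else [
        c for c in profiles.columns if c not in ("plate", "well", "population", "row", "col")
    ]
    X = profiles[names].to_numpy(dtype=float)
    mu = X.mean(axis=0)
    if shrinkage == "lw":
        cov = LedoitWolf(assume_centered=False).fit(X).covariance_
    elif shrinkage == "none":
        cov = np.cov(X, rowvar=False, ddof=1)
    else:
        raise ValueError(f"unknown shrinkage mode {shrinkage!r}")
    prec = np.linalg.pinv(cov, hermitian=True)
    diffs = X - mu
    d2 = np.einsum("ij,jk,ik->i", diffs, prec, diffs)
    dists = np.sqrt(np.clip(d2, 0.0, None))
    out = profiles[[c for c in ("plate", "well", "population", "row", "col") if c in profiles.columns]].copy()
    out["mahalanobis_distance"] = dists
    is_ctl = _control_mask(out, pmap)
    out["is_control"] = is_ctl.to_numpy()
    ctl_mask = out["is_control"]
    if "population" in out.columns:
        ctl_mask = ctl_mask & (out["population"] == "T(+)")
    ctl_d = out.loc[ctl_mask, "mahalanobis_distance"].to_numpy()
    if len(ctl_d) < 4:
        raise ValueError(f"need >=4 control T(+) profiles for the distance fence, got {len(ctl_d)}")
    q1, q3 = np.quantile(ctl_d, [0.25, 0.75])
    threshold = float(q3 + multiplier * (q3 - q1))
    out["threshold"] = threshold
    out["is_hit"] = out["mahalanobis_distance"] > threshold
    return out, threshold
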