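"""Gated-cell profiles, replicate correlations, clustering, Mahalanobis baseline."""

import numpy as np
import pandas as pd
import pytest

import hetscore as hs
from hetscore.profile import (PerturbationProfile, cluster_profiles,
                              mahalanobis_profiles, perturbed_cell_profiles,
                              profiles_frame, replicate_correlation)


def _screen_frame(well_specs, rng):
    """well_specs: (plate, well, is_control, tpos_shift array or None)."""
    frames, pmap_rows = [], []
    n_feat = 3
    for plate, well, is_ctl, shift in well_specs:
        n = 120
        tr = np.zeros(n, dtype=bool)
        tr[: n // 2] = True
        X = rng.standard_normal((n, n_feat))
        if shift is not None:
            X[tr] += shift
        df = pd.DataFrame(X, columns=[f"f{j:02d}" for j in range(n_feat)])
        df.insert(0, "transfected", tr)
        df.insert(0, "cell", np.arange(n))
        df.insert(0, "well", well)
        df.insert(0, "plate", plate)
        frames.append(df)
        pmap_rows.append({"plate": plate, "well": well, "perturbation": f"pert_{well}",
                          "gene": f"gene_{well}", "guide": "g", "is_control": is_ctl})
    cells = hs.CellTable(pd.concat(frames, ignore_index=True),
                         [f"f{j:02d}" for j in range(n_feat)])
    return cells, hs.PlateMap(pd.DataFrame(pmap_rows))


def _as_std(cells):
    return hs.StandardizedCellTable(cells.data, cells.feature_names)


def test_profile_of_control_like_cells_is_near_zero():
    rng = np.random.default_rng(0)
    cells, pmap = _screen_frame(
        [("P01", "A03", True, None), ("P01", "A04", False, None)], rng
    )
    std = _as_std(cells)
    gated = std.data[std.data["transfected"] & (std.data["well"] == "A04")][
        ["plate", "well", "cell"]
    ]
    profiles, _ = perturbed_cell_profiles(std, gated, pmap, min_gated=10)
    assert len(profiles) == 1
    assert np.abs(profiles[0].profile).max() < 0.4


def test_single_gated_cell_profile_is_that_cell():
    rng = np.random.default_rng(1)
    cells, pmap = _screen_frame(
        [("P01", "A03", True, None), ("P01", "A04", False, np.array([2.0, 0, 0]))], rng
    )
    std = _as_std(cells)
    one = std.data[(std.data["well"] == "A04") & std.data["transfected"]].iloc[[0]]
    gated = one[["plate", "well", "cell"]]
    profiles, _ = perturbed_cell_profiles(std, gated, pmap, min_gated=1)
    ctl_ref = std.data[(std.data["well"] == "A03") & std.data["transfected"]][
        std.feature_names
    ].mean().to_numpy()
    np.testing.assert_allclose(
        profiles[0].profile, one[std.feature_names].to_numpy()[0] - ctl_ref, atol=1e-12
    )


def test_too_few_gated_cells_withheld():
    rng = np.random.default_rng(2)
    cells, pmap = _screen_frame(
        [("P01", "A03", True, None), ("P01", "A04", False, None)], rng
    )
    std = _as_std(cells)
    gated = std.data[std.data["transfected"] & (std.data["well"] == "A04")].head(3)[
        ["plate", "well", "cell"]
    ]
    profiles, report = perturbed_cell_profiles(std, gated, pmap, min_gated=20)
    assert len(profiles) == 0
    assert len(report) == 1 and "n_gated 3 < 20" in report.iloc[0]["reason"]


def test_effect_vector_recovery_with_full_penetrance(small_screen):
    """With penetrance 1 and a permissive gate, the gated-cell profile recovers
    the simulated effect vector feature-wise."""
    cfg = hs.SimulationConfig(
        wells_per_plate=4, cells_per_well=2000, penetrance=1.0,
        effect_vector=hs.simulate.default_effect_vector(6, 3.0), n_features=6,
        control_fraction=0.25, seed=21,
    )
    cells, pmap, truth = hs.generate_screen(cfg)
    std = hs.standardize_within_well(cells)
    tgt_wells = [w for w in std.wells() if (w not in pmap.control_wells())]
    gated = std.data[std.data["transfected"]][["plate", "well", "cell"]]
    gated = gated[pd.MultiIndex.from_frame(gated[["plate", "well"]]).isin(tgt_wells)]
    profiles, _ = perturbed_cell_profiles(std, gated, pmap, min_gated=20)
    for p in profiles:
        np.testing.assert_allclose(p.profile, np.asarray(cfg.effect_vector), atol=0.2)


def _profile(pid, gene, vec):
    return PerturbationProfile(pid, gene, 50, [f"f{j}" for j in range(len(vec))],
                               np.asarray(vec, float))


def test_replicate_correlation_basics():
    a = _profile("a", "G1", [1.0, 2.0, 3.0, -1.0])
    b = _profile("b", "G1", [1.0, 2.0, 3.0, -1.0])
    c = _profile("c", "G2", [-1.0, -2.0, -3.0, 1.0])
    flat = _profile("d", "G3", [2.0, 2.0, 2.0, 2.0])
    table = replicate_correlation([a, b, c, flat])
    ab = table[(table["perturbation_a"] == "a") & (table["perturbation_b"] == "b")].iloc[0]
    assert ab["within_gene"] and ab["r"] == pytest.approx(1.0)
    ac = table[(table["perturbation_a"] == "a") & (table["perturbation_b"] == "c")].iloc[0]
    assert not ac["within_gene"] and ac["r"] == pytest.approx(-1.0)
    fd = table[(table["perturbation_b"] == "d")]
    assert (~fd["defined"]).all() and fd["r"].isna().all()


def test_clustering_identical_pair_merges_first_and_tie_break():
    mat = profiles_frame([
        _profile("p1", "G1", [1.0, 1.0, -1.0]),
        _profile("p2", "G1", [1.0, 1.0, -1.0]),
        _profile("p3", "G2", [-1.0, -1.0, 1.0]),
    ])
    res = cluster_profiles(mat)
    # first merge joins the identical pair (leaves 0 and 1 after id sort)
    assert set(res.linkage[0, :2].astype(int)) == {0, 1}
    assert res.newick.endswith(";") and "p1" in res.newick
    with pytest.raises(ValueError):
        cluster_profiles(mat.iloc[[0]])


def test_clustering_row_order_invariant():
    rng = np.random.default_rng(3)
    mat = profiles_frame([_profile(f"p{i}", "G", rng.standard_normal(5)) for i in range(6)])
    res1 = cluster_profiles(mat)
    res2 = cluster_profiles(mat.sample(frac=1.0, random_state=1).reset_index(drop=True))
    np.testing.assert_allclose(res1.linkage, res2.linkage)
    assert res1.leaf_order == res2.leaf_order


def test_clustering_groups_guides_by_gene():
    rng = np.random.default_rng(4)
    effects = {"G1": np.array([3.0, 0, 0, 0]), "G2": np.array([0, 3.0, 0, 0]),
               "G3": np.array([0, 0, 3.0, 0])}
    profs = []
    for gene, eff in effects.items():
        for rep in range(2):
            profs.append(_profile(f"{gene}_r{rep}", gene, eff + rng.normal(0, 0.2, 4)))
    res = cluster_profiles(profiles_frame(profs))
    from scipy.cluster.hierarchy import fcluster
    labels = fcluster(res.linkage, t=3, criterion="maxclust")
    by_gene = {}
    for pid, lab in zip(res.ids, labels):
        by_gene.setdefault(pid.split("_")[0], set()).add(lab)
    assert all(len(v) == 1 for v in by_gene.values())
    assert len(set.union(*by_gene.values())) == 3


def _dist_pmap(wells):
    return hs.PlateMap(pd.DataFrame(
        {"plate": "P01", "well": wells, "perturbation": wells, "gene": "g",
         "guide": "gd", "is_control": [True] * len(wells)}
    ))


def _profile_rows(X, wells=None, population="T(+)"):
    n = len(X)
    wells = wells or [f"A{i+3:02d}" for i in range(n)]
    df = pd.DataFrame(X, columns=[f"f{j:02d}" for j in range(X.shape[1])])
    df.insert(0, "population", population)
    df.insert(0, "well", wells)
    df.insert(0, "plate", "P01")
    return df


def test_mahalanobis_grand_mean_has_zero_distance():
    rng = np.random.default_rng(5)
    X = rng.standard_normal((19, 3))
    X = np.vstack([X, X.mean(axis=0) * 20 - X.sum(axis=0)])  # force last = grand mean
    assert np.allclose(X[-1], X[:].mean(axis=0))
    out, _ = mahalanobis_profiles(_profile_rows(X), _dist_pmap([f"A{i+3:02d}" for i in range(20)]))
    assert out["mahalanobis_distance"].iloc[-1] == pytest.approx(0.0, abs=1e-8)


def test_mahalanobis_identity_covariance_matches_euclidean():
    # large sample of independent unit-variance profiles: the shrinkage
    # covariance approaches identity and distances approach Euclidean
    rng = np.random.default_rng(6)
    X = rng.standard_normal((2000, 4))
    wells = [f"W{i + 10}" for i in range(len(X))]  # ids already in normal form
    out, _ = mahalanobis_profiles(_profile_rows(X, wells=wells), _dist_pmap(wells))
    d_e = np.linalg.norm(X - X.mean(axis=0), axis=1)
    rel = np.abs(out["mahalanobis_distance"].to_numpy() - d_e) / d_e
    assert np.median(rel) < 0.05


def test_mahalanobis_quadratic_form_oracle():
    X = np.array([[0.0, 0.0], [2.0, 1.0], [1.0, 3.0], [3.0, 2.0], [0.5, 1.5]])
    out, thr = mahalanobis_profiles(
        _profile_rows(X), _dist_pmap([f"A{i+3:02d}" for i in range(5)]),
        shrinkage="none",
    )
    mu = X.mean(axis=0)
    Sinv = np.linalg.inv(np.cov(X, rowvar=False, ddof=1))
    expected = [np.sqrt((x - mu) @ Sinv @ (x - mu)) for x in X]
    np.testing.assert_allclose(out["mahalanobis_distance"], expected, atol=1e-6)


def test_mahalanobis_affine_invariance_unregularized():
    rng = np.random.default_rng(7)
    X = rng.standard_normal((40, 3))
    A = np.array([[2.0, 0.3, 0.0], [0.0, 1.5, -0.2], [0.1, 0.0, 0.8]])
    b = np.array([5.0, -2.0, 1.0])
    wells = [f"A{i+3:02d}" for i in range(20)] + [f"B{i+3:02d}" for i in range(20)]
    pmap = _dist_pmap(wells)
    d1, _ = mahalanobis_profiles(_profile_rows(X, wells=wells), pmap, shrinkage="none")
    d2, _ = mahalanobis_profiles(_profile_rows(X @ A.T + b, wells=wells), pmap, shrinkage="none")
    np.testing.assert_allclose(
        d1["mahalanobis_distance"], d2["mahalanobis_distance"], atol=1e-6
    )


def test_mahalanobis_requires_enough_control_profiles():
    X = np.random.default_rng(8).standard_normal((3, 2))
    with pytest.raises(ValueError, match=">=4 control"):
        mahalanobis_profiles(_profile_rows(X), _dist_pmap(["A03", "A04", "A05"]))
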