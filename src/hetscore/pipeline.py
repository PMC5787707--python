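"""End-to-end orchestration of the within-well and between-well analyses.

``run_within_well``: QC -> in-well standardization -> pooled PCA ->
per-well bootstrapped classifiers -> PV gate -> KS phenotypic score ->
Tukey-fence hit calling -> gated-cell profiles.

``run_between_well``: well mean profiles -> B-score -> Mahalanobis
distances -> Q3 + 3 x IQR fence.

Both are pure functions of (inputs, config): re-running with the same
config reproduces every output table exactly. ``run_to_dir`` writes the
tables plus a manifest (config, seed, package versions) for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import DEFAULT_CS, classify_screen
from .io import (CellTable, FeatureSet, PlateMap, read_cell_table,
                 read_plate_map, validate_screen, write_table)
from .normalize import bscore, qc_wells, standardize_within_well, well_mean_profiles
from .profile import mahalanobis_profiles, perturbed_cell_profiles, profiles_frame
from .score import call_hits, compute_pv_gate, control_tpos_pvs, gate_cells, phenotypic_score

logger = logging.getLogger("hetscore")


@dataclasses.dataclass
class PipelineConfig:
    """Every tunable screen parameter, with screen-scale defaults.

    ``pca_k`` defaults to 30 (the marker-staining setting; use 50 for
    broad morphology panels). Classifier settings follow the standard
    protocol: 100 bootstraps of 500 cells per class with 10-fold CV.
    """

    features: list[str] | None = None
    feature_set_name: str = "features"
    pca_k: int = 30
    n_boot: int = 100
    n_per_class: int = 500
    n_folds: int = 10
    Cs: list[float] = dataclasses.field(default_factory=lambda: list(DEFAULT_CS))
    gate_multiplier: float = 3.0
    hit_multiplier: float = 1.5
    between_multiplier: float = 3.0
    min_tpos: int = 300
    min_tneg: int = 100
    min_gated: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pca_k", "n_boot", "n_per_class", "n_folds", "min_gated"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        for name in ("gate_multiplier", "hit_multiplier", "between_multiplier"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        self.Cs = [float(c) for c in self.Cs]  # plain floats for YAML round trips
        if self.features is not None:
            self.features = [str(f) for f in self.features]

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls(**doc)

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclasses.dataclass
class WithinWellRun:
    screen_result: pd.DataFrame
    pvs: pd.DataFrame
    gated: pd.DataFrame
    profiles: pd.DataFrame
    profile_report: pd.DataFrame
    gate_threshold: float
    hit_threshold: float
    qc_excluded: pd.DataFrame


@dataclasses.dataclass
class BetweenWellRun:
    distances: pd.DataFrame
    threshold: float


def _feature_set(cfg: PipelineConfig, cells: CellTable) -> FeatureSet | None:
    if cfg.features is None:
        return None
    return FeatureSet(cfg.feature_set_name, tuple(cfg.features))


def run_within_well(cells: CellTable, pmap: PlateMap, cfg: PipelineConfig) -> WithinWellRun:
    report = validate_screen(cells, pmap)
    if not report.passed:
        raise ValueError(f"screen validation failed:\n{report}")
    fs = _feature_set(cfg, cells)
    logger.info("QC: requiring >=%d T(+) and >=%d T(-) cells per well", cfg.min_tpos, cfg.min_tneg)
    retained, qc = qc_wells(cells, min_tpos=cfg.min_tpos, min_tneg=cfg.min_tneg)
    if qc.n_excluded:
        logger.warning("excluded %d well(s) in QC", qc.n_excluded)
    if retained.n_cells == 0:
        raise ValueError("no wells survive QC")
    std = standardize_within_well(retained, fs)
    logger.info("classifying %d wells (k=%d, %d bootstraps)", len(std.wells()), cfg.pca_k, cfg.n_boot)
    wells, pvs, _ = classify_screen(
        std, None, pca_k=min(cfg.pca_k, len(std.feature_names)),
        n_boot=cfg.n_boot, n_per_class=cfg.n_per_class, n_folds=cfg.n_folds,
        Cs=cfg.Cs, seed=cfg.seed,
    )
    gate = compute_pv_gate(pvs, pmap, multiplier=cfg.gate_multiplier)
    gated = gate_cells(pvs, gate)
    ctl_pool = control_tpos_pvs(pvs, pmap)
    pm = pmap.data.set_index(["plate", "well"])
    ks, n_gated, perts = [], [], []
    for _, w in wells.iterrows():
        key = (w["plate"], w["well"])
        perts.append(pm.loc[key, "perturbation"])
        tp = pvs[(pvs["plate"] == key[0]) & (pvs["well"] == key[1]) & pvs["transfected"]]["pv"].to_numpy()
        ks.append(phenotypic_score(tp, ctl_pool))
        n_gated.append(int(((gated["plate"] == key[0]) & (gated["well"] == key[1])).sum()))
    wells = wells.copy()
    wells["perturbation"] = perts
    wells["phenotypic_score"] = ks
    wells["n_gated"] = n_gated
    thr, wells = call_hits(wells, pmap, multiplier=cfg.hit_multiplier)
    profs, prof_report = perturbed_cell_profiles(std, gated, pmap, fs, min_gated=cfg.min_gated)
    cols = ["plate", "well", "perturbation", "is_control", "n_tpos", "n_tneg",
            "mean_misclassification", "classification_score", "phenotypic_score",
            "n_gated", "is_hit"]
    return WithinWellRun(
        screen_result=wells[cols].sort_values(["plate", "well"]).reset_index(drop=True),
        pvs=pvs.sort_values(["plate", "well", "cell"]).reset_index(drop=True),
        gated=gated.sort_values(["plate", "well", "cell"]).reset_index(drop=True),
        profiles=profiles_frame(profs),
        profile_report=prof_report,
        gate_threshold=gate.threshold,
        hit_threshold=thr.value,
        qc_excluded=qc.excluded,
    )


def run_between_well(cells: CellTable, pmap: PlateMap, cfg: PipelineConfig) -> BetweenWellRun:
    report = validate_screen(cells, pmap)
    if not report.passed:
        raise ValueError(f"screen validation failed:\n{report}")
    fs = _feature_set(cfg, cells)
    retained, _ = qc_wells(cells, min_tpos=cfg.min_tpos, min_tneg=cfg.min_tneg)
    if retained.n_cells == 0:
        raise ValueError("no wells survive QC")
    profiles = well_mean_profiles(retained, fs)
    corrected = bscore(profiles, fs)
    distances, threshold = mahalanobis_profiles(corrected, pmap, fs, multiplier=cfg.between_multiplier)
    return BetweenWellRun(distances=distances.sort_values(["plate", "well", "population"]).reset_index(drop=True),
                          threshold=threshold)


def run_to_dir(
    cells_path: str | Path, platemap_path: str | Path, cfg: PipelineConfig,
    out_dir: str | Path, between_well: bool = False,
) -> Path:
    """File-based entry point: read inputs, run, write tables + manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cells = read_cell_table(cells_path)
    pmap = read_plate_map(platemap_path)
    manifest = {
        "hetscore_version": __version__,
        "config": dataclasses.asdict(cfg),
        "config_digest": cfg.digest(),
        "seed": cfg.seed,
        "inputs": {"cells": str(cells_path), "platemap": str(platemap_path)},
        "mode": "between_well" if between_well else "within_well",
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    if between_well:
        run = run_between_well(cells, pmap, cfg)
        write_table(run.distances, out / "distances.csv")
        manifest["threshold"] = run.threshold
    else:
        run = run_within_well(cells, pmap, cfg)
        write_table(run.screen_result, out / "screen_result.csv")
        write_table(run.pvs, out / "pv.csv")
        write_table(run.gated, out / "gated_cells.csv")
        write_table(run.profiles, out / "profiles.csv")
        write_table(run.qc_excluded, out / "qc_excluded.csv")
        manifest["gate_threshold"] = run.gate_threshold
        manifest["hit_threshold"] = run.hit_threshold
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
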